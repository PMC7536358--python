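"""Power - noise - shaping-time tradeoff for the future channel.

The preamplifier noise scales with its supply power as sigma ~ 1/sqrt(P).
Lowering the power therefore raises the noise floor, which can be bought
back by lengthening the shaping time (sigma ~ 1/sqrt(tau) for the ideal
channel, both noise components scaling as 1/tau).  The compensation curve
solves sigma(P, tau*) = sigma(P0, tau_ref) for tau*.

Two scopes are provided: ``csa_only`` scales only the CSA (preamplifier)
noise component with power - the literal reading of the power model - while
``total`` scales the whole output noise.  With the exact 1/tau scaling of
the ideal channel the compensation factor for a power fraction p is
reference-independent and available in closed form:

    csa_only: tau*/tau_ref = 1 + split*(1/p - 1)   (split = 4/5 -> 1.8 at p=1/2)
    total:    tau*/tau_ref = 1/p                    (2.0 at p=1/2)
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from . import noise as noise_mod
from .readout import ShaperConfig

__all__ = [
    "PowerOperatingPoint",
    "sigma_at",
    "required_shaping_time",
    "compensation_factor",
    "closed_form_factor",
]

SCOPES = ("csa_only", "total")


class PowerOperatingPoint(NamedTuple):
    """One point on the power / shaping-time / noise surface."""

    power: float        # multiple of P0 (sigma = 2 keV at tau = 40 ns)
    shaping_time_ns: float
    sigma_kev: float


def _component_variances_kev2(
    shaping_time_ns: float, sources: noise_mod.NoiseSources
) -> tuple[float, float]:
    cal = noise_mod.reference_calibration(sources)
    cfg = ShaperConfig.ideal(shaping_time_ns / 2)
    psd = noise_mod.output_psd(cfg, sources)
    vc, vf = psd.variance_mv2()
    return vc / cal.gain_mv_per_kev**2, vf / cal.gain_mv_per_kev**2


def sigma_at(
    power: float,
    shaping_time_ns: float,
    sources: noise_mod.NoiseSources | None = None,
    scope: str = "csa_only",
) -> float:
    """Ideal-channel output noise in keV at a power level and shaping time.

    ``power`` is a multiple of P0, the power giving sigma = 2 keV at 40 ns.
    Under ``csa_only`` the 1/power scaling applies to the CSA component
    alone; under ``total`` to the full output variance.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    sources = sources if sources is not None else noise_mod.NoiseSources()
    vc, vf = _component_variances_kev2(shaping_time_ns, sources)
    if scope == "csa_only":
        return float(np.sqrt(vc / power + vf))
    return float(np.sqrt((vc + vf) / power))


def required_shaping_time(
    power_factor: float,
    reference_tau_ns: float = 40.0,
    sources: noise_mod.NoiseSources | None = None,
    scope: str = "csa_only",
    tol_ns: float = 0.1,
    max_tau_ns: float = 1e4,
) -> float:
    """Shaping time holding the noise constant when power drops to
    ``power_factor`` x P0 (solved by bisection to ``tol_ns``)."""
    if not (0 < power_factor <= 1):
        raise ValueError("power factor must lie in (0, 1]")
    if power_factor == 1.0:
        return float(reference_tau_ns)
    target = sigma_at(1.0, reference_tau_ns, sources, scope)

    def excess(tau: float) -> float:
        return sigma_at(power_factor, tau, sources, scope) - target

    if excess(max_tau_ns) > 0:
        raise ValueError(
            f"no shaping time below {max_tau_ns} ns restores sigma for "
            f"power factor {power_factor}"
        )
    return float(brentq(excess, reference_tau_ns, max_tau_ns, xtol=tol_ns))


def compensation_factor(
    power_factor: float,
    reference_tau_ns: float = 40.0,
    sources: noise_mod.NoiseSources | None = None,
    scope: str = "csa_only",
) -> float:
    """Multiplicative shaping-time increase tau*/tau_ref at constant noise."""
    return required_shaping_time(power_factor, reference_tau_ns, sources, scope) / reference_tau_ns


def closed_form_factor(power_factor: float, split: float = 0.8, scope: str = "csa_only") -> float:
    """Analytic compensation factor under exact 1/tau variance scaling."""
    if scope == "csa_only":
        return 1.0 + split * (1.0 / power_factor - 1.0)
    if scope == "total":
        return 1.0 / power_factor
    raise ValueError(f"scope must be one of {SCOPES}")
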