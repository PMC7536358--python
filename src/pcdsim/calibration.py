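"""Fitting procedures: erfc threshold-scan fits, gain calibration and
grid-search recovery of the shaper time constants from pulse lengths.

A threshold scan of a monochromatic beam is an S-curve smeared by the
electronic noise; it is modelled by a modified complementary error function

    f(x) = 1/2 erfc((x-mu)/(sqrt(2) sigma)) (A1 (x-mu) + A2) + A3 (x-mu) + A4

whose centre mu locates the beam energy in threshold units and whose width
sigma is the noise.  Fitting mu at several beam energies and regressing mu
against energy yields the channel gain; dividing the noise-only sigma by
the gain expresses the noise in keV.

The shaper time constants (tau0, B_short) are recovered from measured pulse
lengths - each threshold-scan E1/2 point gives one (threshold, length)
sample of the pulse flank, with length = deadtime + clock/2 - by exhaustive
mean-square-error search over a (tau0, B_short) grid of simulated pulse
lengths, using one shared seeded pulse ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq
from scipy.optimize import curve_fit
from scipy.special import erfc
from scipy.stats import linregress

from .constants import NS, UA
from .counting import ThresholdScan
from .readout import CurrentPulse, FitError, ShaperConfig, VoltagePulse, pulse_length, transfer_function

__all__ = [
    "ErfFit",
    "ShapeFitResult",
    "PulseLengthMeasurement",
    "erfc_model",
    "fit_erfc",
    "calibrate_gain",
    "fit_shape_params",
]


def erfc_model(x, mu, sigma, a1, a2, a3, a4):
    """Modified complementary error function used for threshold-scan fits."""
    x = np.asarray(x, dtype=float)
    step = 0.5 * erfc((x - mu) / (np.sqrt(2.0) * sigma))
    return step * (a1 * (x - mu) + a2) + a3 * (x - mu) + a4


@dataclass
class ErfFit:
    """Result of a modified-erfc fit to a threshold scan."""

    mu: float
    sigma: float
    a: tuple  # (A1, A2, A3, A4)
    covariance: np.ndarray
    residual_ss: float

    def predict(self, x) -> np.ndarray:
        return erfc_model(x, self.mu, self.sigma, *self.a)

    @property
    def mu_stderr(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def sigma_stderr(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))


def _fit_once(x, y, p0, bounds):
    popt, pcov = curve_fit(erfc_model, x, y, p0=p0, bounds=bounds, maxfev=20000)
    resid = y - erfc_model(x, *popt)
    return popt, pcov, float(np.sum(resid**2))


def fit_erfc(
    scan: ThresholdScan | tuple,
    initial_guess: Sequence[float] | None = None,
    exclude_below_kev: float | None = None,
) -> ErfFit:
    """Least-squares modified-erfc fit to a threshold scan.

    Accepts a :class:`ThresholdScan` or an ``(x, y)`` pair.  Multi-start:
    a data-driven guess (centre at the half-plateau crossing) plus typical
    noise widths, and optionally a user guess.  Thresholds at or below
    ``exclude_below_kev`` are excluded (noise / triple-count region).
    """
    if isinstance(scan, ThresholdScan):
        x, y = scan.thresholds_kev, scan.counts.astype(float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in scan)
    if exclude_below_kev is not None:
        keep = x > exclude_below_kev
        x, y = x[keep], y[keep]
    if x.size < 10:
        raise FitError("threshold scan must contain at least 10 points")
    if not np.any(y > 0):
        raise FitError("threshold scan contains no counts")
    ymax = float(y.max())
    below = np.nonzero(y < 0.5 * ymax)[0]
    mu0 = float(x[below[0]]) if below.size else float(np.median(x))
    starts = [(mu0, 2.0), (mu0, 3.0), (mu0, 1.0)]
    if initial_guess is not None:
        starts.insert(0, tuple(initial_guess[:2]))
    span = float(x[-1] - x[0])
    bounds = (
        [x[0] - span, 1e-3, -np.inf, -np.inf, -np.inf, -np.inf],
        [x[-1] + span, span, np.inf, np.inf, np.inf, np.inf],
    )
    best = None
    for mu_g, sig_g in starts:
        p0 = [mu_g, sig_g, 0.0, ymax, 0.0, 0.0]
        try:
            popt, pcov, ss = _fit_once(x, y, p0, bounds)
        except (RuntimeError, ValueError):
            continue
        if best is None or ss < best[2]:
            best = (popt, pcov, ss)
    if best is None:
        raise FitError("erfc fit failed to converge from all starting points")
    popt, pcov, ss = best
    if not np.all(np.isfinite(popt)):
        raise FitError("erfc fit produced non-finite parameters")
    return ErfFit(float(popt[0]), float(abs(popt[1])), tuple(popt[2:]), pcov, ss)


def calibrate_gain(
    fits_by_energy: Mapping[float, "ErfFit | float"],
    noise_fit: "ErfFit | float",
) -> tuple[float, float]:
    """Gain (mV/keV) and noise (keV) from per-energy erfc fits.

    ``fits_by_energy`` maps beam energy to the fitted transition centre mu
    (in threshold/DAC units, here mV); ``noise_fit`` supplies the noise
    sigma in the same units.  The gain is the linear-regression slope of mu
    versus energy; sigma_keV = sigma / gain.
    """
    energies = sorted(e for e in fits_by_energy if e > 0)
    if len(energies) < 2:
        raise FitError("gain calibration needs at least two beam energies")
    mus = [
        fits_by_energy[e].mu if isinstance(fits_by_energy[e], ErfFit) else float(fits_by_energy[e])
        for e in energies
    ]
    res = linregress(energies, mus)
    gain = float(res.slope)
    sigma_mv = noise_fit.sigma if isinstance(noise_fit, ErfFit) else float(noise_fit)
    return gain, sigma_mv / gain


class PulseLengthMeasurement(NamedTuple):
    """One E1/2 observation: at threshold ``e_half_kev`` the pulse length is
    ``deadtime_ns + clock_ns/2``."""

    setting: str  # "long" or "short"
    energy_kev: float
    deadtime_ns: float
    e_half_kev: float


@dataclass
class ShapeFitResult:
    """Best-fitting shaper time constants from the grid search."""

    tau0_ns: float
    b_short: float
    mse_ns2: float
    tau0_step_ns: float
    b_step: float

    @property
    def tau_long_ns(self) -> float:
        return 2 * self.tau0_ns

    @property
    def tau_short_ns(self) -> float:
        return 2 * self.b_short * self.tau0_ns


def _mean_current(pulses: Sequence[CurrentPulse]) -> np.ndarray:
    n = max(p.samples_uA.size for p in pulses)
    acc = np.zeros(n)
    for p in pulses:
        acc[: p.samples_uA.size] += p.samples_uA
    return acc / len(pulses)


def fit_shape_params(
    measurements: Sequence[PulseLengthMeasurement],
    ensembles: Mapping[float, Sequence[CurrentPulse]],
    clock_ns: float = 10.0,
    tau0_grid_ns: np.ndarray | None = None,
    b_grid: np.ndarray | None = None,
    tau_s_ns: float = 14.0,
    dt_ns: float = 2.0,
    nfft: int = 4096,
) -> ShapeFitResult:
    """Exhaustive grid search for (tau0, B_short) matching measured lengths.

    For every grid point the shared pulse ensembles are shaped with the
    prototype transfer function (B=1 for "long", B_short for "short"), peak
    normalised to the nominal energy, and the pulse length at each measured
    E1/2 threshold is compared to the measured length deadtime + clock/2.
    Returns the unweighted-MSE minimum; ties break toward smaller tau0.
    """
    if not measurements:
        raise FitError("no pulse-length measurements supplied")
    if tau0_grid_ns is None:
        tau0_grid_ns = np.round(np.arange(10.0, 30.0 + 1e-9, 0.1), 10)
    if b_grid is None:
        b_grid = np.round(np.arange(0.5, 1.0 - 1e-9, 0.01), 10)
    energies = sorted({m.energy_kev for m in measurements})
    by_setting: dict[str, list[PulseLengthMeasurement]] = {"long": [], "short": []}
    for m in measurements:
        if m.setting not in by_setting:
            raise ValueError(f"unknown setting {m.setting!r}")
        by_setting[m.setting].append(m)
    freqs = rfftfreq(nfft, dt_ns * NS)
    currents = {
        e: rfft(_mean_current(ensembles[e]) * UA, nfft) for e in energies
    }

    def lengths_for(config: ShaperConfig, ms: Sequence[PulseLengthMeasurement]) -> np.ndarray:
        h = transfer_function(config, freqs)
        shaped = {}
        out = np.empty(len(ms))
        for i, m in enumerate(ms):
            if m.energy_kev not in shaped:
                v = irfft(currents[m.energy_kev] * h, nfft)
                shaped[m.energy_kev] = v / v.max() * m.energy_kev  # peak at nominal energy
            pulse = VoltagePulse(shaped[m.energy_kev], dt_ns=dt_ns)
            out[i] = pulse_length(pulse, m.e_half_kev)
        return out

    targets = {
        s: np.array([m.deadtime_ns + clock_ns / 2 for m in ms])
        for s, ms in by_setting.items()
    }
    n_total = len(measurements)
    best = (np.inf, None, None)
    for tau0 in tau0_grid_ns:
        sse_long = 0.0
        if by_setting["long"]:
            pred = lengths_for(ShaperConfig.prototype(tau0, 1.0, tau_s_ns=tau_s_ns),
                               by_setting["long"])
            sse_long = float(np.sum((pred - targets["long"]) ** 2))
        if by_setting["short"]:
            for b in b_grid:
                pred = lengths_for(ShaperConfig.prototype(tau0, float(b), tau_s_ns=tau_s_ns),
                                   by_setting["short"])
                sse = sse_long + float(np.sum((pred - targets["short"]) ** 2))
                if sse < best[0]:
                    best = (sse, float(tau0), float(b))
        else:
            if sse_long < best[0]:
                best = (sse_long, float(tau0), float(b_grid[0]))
    sse, tau0, b = best
    return ShapeFitResult(
        tau0, b, sse / n_total,
        float(np.round(np.diff(tau0_grid_ns).mean(), 10)),
        float(np.round(np.diff(b_grid).mean(), 10)),
    )
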