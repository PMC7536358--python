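"""Readout-channel models: shaper transfer functions and pulse shaping.

The channel is a charge-sense amplifier (CSA) followed by a pole-zero
cancellation stage, a shaper amplifier and two cascaded lossy Gm-C
integrator stages.  Its small-signal response to the detector current is the
rational transfer function

    H(s) = (1/Cf)(Cpz/Cs) * tau_s/(1+s*tau_s) * 2/(1+s*tau1) * 2/(1+s*tau2)

with the time constants set by the channel variant:

* ``prototype`` - current ASIC: tau_s fixed at 14 ns, tau1 = B*tau0,
  tau2 = 2*B*tau0 (the comparator load doubles the second stage's time
  constant).  The selectable shaping-time setting enters through B
  (B=1 "long", 0.5 <= B < 1 "short"); the shaping time is tau = 2*B*tau0.
* ``ideal`` - proposed future channel with negligible comparator load:
  tau_s = tau1 = tau2 = tau0 and tau = 2*tau0.

An alternative band-pass numerator (s*tau_s in place of the DC-coupled
tau_s) can be selected with ``bandpass_numerator``; the two forms differ
only below the shaper corner frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

from .constants import FF, MV, NS, UA

__all__ = [
    "InvalidConfigError",
    "WindowError",
    "FitError",
    "ShaperConfig",
    "CurrentPulse",
    "VoltagePulse",
    "transfer_function",
    "shape_pulse",
    "gain",
    "pulse_length",
]


class InvalidConfigError(ValueError):
    """Shaper configuration violates its invariants."""


class WindowError(RuntimeError):
    """Shaped pulse does not decay inside the maximum allowed window."""


class FitError(RuntimeError):
    """A least-squares fit could not be performed or did not converge."""


@dataclass(frozen=True)
class ShaperConfig:
    """Circuit and time constants of one readout-channel variant.

    ``tau_s_ns=None`` selects the variant default (14 ns for the prototype,
    ``tau0_ns`` for the ideal channel).
    """

    variant: str
    tau0_ns: float
    B: float = 1.0
    tau_s_ns: float | None = None
    Cf_fF: float = 200.0
    Cpz_fF: float = 1600.0
    Cs_fF: float = 200.0
    bandpass_numerator: bool = False

    def __post_init__(self) -> None:
        if self.variant not in ("prototype", "ideal"):
            raise InvalidConfigError(f"unknown variant {self.variant!r}")
        if not (self.tau0_ns > 0):
            raise InvalidConfigError("tau0 must be strictly positive")
        if self.variant == "prototype" and not (0.5 <= self.B <= 1.0):
            raise InvalidConfigError("prototype B must lie in [0.5, 1]")
        if self.tau_s_ns is None:
            default = 14.0 if self.variant == "prototype" else self.tau0_ns
            object.__setattr__(self, "tau_s_ns", default)
        if not (self.tau_s_ns > 0):
            raise InvalidConfigError("tau_s must be strictly positive")
        if min(self.Cf_fF, self.Cpz_fF, self.Cs_fF) <= 0:
            raise InvalidConfigError("capacitances must be strictly positive")

    @classmethod
    def prototype(cls, tau0_ns: float, B: float = 1.0, **kwargs) -> "ShaperConfig":
        return cls("prototype", tau0_ns, B=B, **kwargs)

    @classmethod
    def ideal(cls, tau0_ns: float, **kwargs) -> "ShaperConfig":
        return cls("ideal", tau0_ns, **kwargs)

    @property
    def tau1_ns(self) -> float:
        return self.B * self.tau0_ns if self.variant == "prototype" else self.tau0_ns

    @property
    def tau2_ns(self) -> float:
        return 2 * self.B * self.tau0_ns if self.variant == "prototype" else self.tau0_ns

    @property
    def shaping_time_ns(self) -> float:
        """tau = 2*B*tau0 (prototype) or 2*tau0 (ideal)."""
        return 2 * self.B * self.tau0_ns if self.variant == "prototype" else 2 * self.tau0_ns

    def with_B(self, B: float) -> "ShaperConfig":
        return replace(self, B=B)


@dataclass
class CurrentPulse:
    """Induced-current waveform on a uniform time grid (uA vs ns)."""

    samples_uA: np.ndarray
    dt_ns: float = 2.0
    energy_kev: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples_uA = np.asarray(self.samples_uA, dtype=float)
        if self.dt_ns <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.samples_uA)):
            raise ValueError("current samples must be finite")

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.samples_uA.size) * self.dt_ns

    @property
    def charge_fC(self) -> float:
        """Integrated charge in fC."""
        return float(np.sum(self.samples_uA) * self.dt_ns * UA * NS / 1e-15)


@dataclass
class VoltagePulse:
    """Shaped output waveform (mV vs ns)."""

    samples_mV: np.ndarray
    dt_ns: float = 2.0
    source_energy_kev: float = 0.0

    def __post_init__(self) -> None:
        self.samples_mV = np.asarray(self.samples_mV, dtype=float)

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.samples_mV.size) * self.dt_ns

    @property
    def peak_mV(self) -> float:
        """Maximum over the sampled grid (no sub-sample refinement)."""
        return float(np.max(self.samples_mV))


def transfer_function(config: ShaperConfig, frequencies_hz) -> np.ndarray:
    """Complex channel response H(j*2*pi*f) in ohm (output V per input A).

    The DC magnitude is (1/Cf)(Cpz/Cs)*tau_s*4 for the default numerator.
    """
    f = np.asarray(frequencies_hz, dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f < 0):
        raise ValueError("frequencies must be finite and non-negative")
    ts = config.tau_s_ns * NS
    t1 = config.tau1_ns * NS
    t2 = config.tau2_ns * NS
    s = 2j * np.pi * f
    k = (1.0 / (config.Cf_fF * FF)) * (config.Cpz_fF / config.Cs_fF)
    numerator = s * ts * ts if config.bandpass_numerator else ts
    return k * numerator / (1 + s * ts) * 2 / (1 + s * t1) * 2 / (1 + s * t2)


def shape_pulse(
    pulse: CurrentPulse,
    config: ShaperConfig,
    window_factor: float = 20.0,
    max_window_factor: float = 200.0,
) -> VoltagePulse:
    """Apply the channel transfer function to an induced-current pulse.

    The current is zero-padded to at least ``window_factor`` shaping times,
    transformed, multiplied by H(f) and transformed back.  The window is
    doubled (up to ``max_window_factor`` shaping times) until the response
    has decayed below 1% of its peak at the window end.
    """
    dt = pulse.dt_ns * NS
    tau = config.shaping_time_ns * NS
    n = max(pulse.samples_uA.size, int(np.ceil(window_factor * tau / dt)))
    while True:
        nfft = next_fast_len(n)
        freqs = rfftfreq(nfft, dt)
        spectrum = rfft(pulse.samples_uA * UA, nfft)
        volts = irfft(spectrum * transfer_function(config, freqs), nfft)
        peak = np.max(np.abs(volts))
        if peak == 0 or np.abs(volts[-1]) < 0.01 * peak:
            break
        if n * dt > max_window_factor * tau:
            raise WindowError(
                f"shaped pulse has not decayed below 1% of peak within "
                f"{max_window_factor} shaping times"
            )
        n *= 2
    return VoltagePulse(volts / MV, dt_ns=pulse.dt_ns, source_energy_kev=pulse.energy_kev)


def gain(config: ShaperConfig, ensembles: Mapping[float, Sequence[CurrentPulse]]) -> float:
    """Channel gain in mV/keV: slope of mean peak voltage versus energy.

    ``ensembles`` maps deposited energy (keV) to a pulse ensemble covering
    different interaction positions.
    """
    energies = sorted(ensembles)
    if len(set(energies)) < 2:
        raise FitError("gain fit needs at least two distinct energies")
    peaks = [
        float(np.mean([shape_pulse(p, config).peak_mV for p in ensembles[e]]))
        for e in energies
    ]
    slope, _ = np.polyfit(energies, peaks, 1)
    return float(slope)


def pulse_length(
    pulse: VoltagePulse,
    threshold: float,
    gain_mv_per_kev: float | None = None,
) -> float:
    """Duration (ns) between first upward and last downward threshold crossing.

    ``threshold`` is in mV, or in keV when ``gain_mv_per_kev`` is given.
    Crossings are linearly interpolated between grid samples.  Returns 0.0
    when the threshold is at or above the pulse peak (no crossing).
    """
    thr = threshold * gain_mv_per_kev if gain_mv_per_kev is not None else threshold
    v = pulse.samples_mV
    if thr >= np.max(v):
        return 0.0
    above = v > thr
    idx = np.nonzero(above)[0]
    first, last = idx[0], idx[-1]
    dt = pulse.dt_ns
    if first == 0:
        t_rise = 0.0
    else:
        t_rise = (first - 1 + (thr - v[first - 1]) / (v[first] - v[first - 1])) * dt
    if last == v.size - 1:
        t_fall = last * dt
    else:
        t_fall = (last + (v[last] - thr) / (v[last] - v[last + 1])) * dt
    return float(t_fall - t_rise)
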