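"""Clocked comparator bank, deadtime logic and count statistics.

The shaped output voltage is discretised by up to eight comparators whose
outputs are sampled every clock cycle (10 ns).  A sample above the lowest
threshold registers a count; the channel then enters a deadtime (a multiple
of the clock cycle) during which the pulse height is classified - the count
lands in the bin of the highest threshold exceeded inside the deadtime
window (peak-hold) - and no new counts are accepted.  Sampling resumes on
the first clock edge at or after deadtime expiry, so a pulse still above
threshold re-triggers: pulses longer than deadtime + clock are counted
twice.  The threshold at which the average double-count probability is 1/2,
E1/2, marks where the pulse length equals deadtime + clock/2; scanning the
lowest threshold therefore measures the pulse shape indirectly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import noise as noise_mod
from .readout import ShaperConfig, pulse_length, shape_pulse
from .transport import DetectorGeometry, standard_pulse_ensemble

__all__ = [
    "ExtractionError",
    "ComparatorBank",
    "PulseTrain",
    "ThresholdScan",
    "count_frame",
    "build_pulse_train",
    "simulate_threshold_scan",
    "extract_e_half",
    "deadtime_for",
    "count_rate_curve",
    "shaped_kernels",
]

#: lowest-threshold region dominated by noise and triple counts, excluded
#: from E1/2 extraction and curve fits
NOISE_EXCLUSION_KEV = 15.0


class ExtractionError(RuntimeError):
    """Threshold scan lacks the 2 -> 1 transition needed for E1/2."""


@dataclass(frozen=True)
class ComparatorBank:
    """Comparator thresholds and the clock/deadtime timing of one channel."""

    thresholds_kev: tuple
    deadtime_ns: float
    clock_ns: float = 10.0

    def __post_init__(self) -> None:
        thr = tuple(float(t) for t in self.thresholds_kev)
        if not 1 <= len(thr) <= 8:
            raise ValueError("bank supports 1 to 8 thresholds")
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds_kev", thr)
        if self.clock_ns <= 0 or self.deadtime_ns <= 0:
            raise ValueError("clock and deadtime must be positive")
        ratio = self.deadtime_ns / self.clock_ns
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("deadtime must be an integer multiple of the clock cycle")


@dataclass
class PulseTrain:
    """Summed voltage waveform of one frame plus the underlying truth."""

    waveform: np.ndarray  # keV-calibrated (or mV, caller's convention)
    dt_ns: float
    frame_us: float
    photon_times_ns: np.ndarray
    photon_energies_kev: np.ndarray
    flux_per_s: float = 0.0


def count_frame(
    waveform: np.ndarray,
    dt_ns: float,
    bank: ComparatorBank,
    rng: np.random.Generator,
    phase_ns: float | None = None,
) -> np.ndarray:
    """Counts per energy bin for one frame of a threshold-calibrated waveform.

    The comparator outputs are sampled every ``clock_ns`` with a random
    phase (uniform over one clock cycle per frame unless given).  Returns an
    array of length ``len(thresholds)``: element k counts pulses whose peak
    within the deadtime window lay between thresholds k and k+1.
    """
    step = bank.clock_ns / dt_ns
    if abs(step - round(step)) > 1e-9:
        raise ValueError("clock cycle must be a multiple of the waveform sampling")
    step = int(round(step))
    if phase_ns is None:
        phase = int(rng.integers(0, step))
    else:
        phase = int(round(phase_ns / dt_ns)) % step
    samples = waveform[phase::step]
    thresholds = np.asarray(bank.thresholds_kev)
    dead_steps = int(round(bank.deadtime_ns / bank.clock_ns))
    counts = np.zeros(thresholds.size, dtype=int)
    above = samples > thresholds[0]
    j, n = 0, samples.size
    while j < n:
        nxt = np.argmax(above[j:])
        if not above[j + nxt]:
            break
        j += nxt
        a = phase + j * step
        b = min(a + dead_steps * step, waveform.size)
        vmax = waveform[a:b].max() if b > a else waveform[a]
        counts[np.searchsorted(thresholds, vmax, side="right") - 1] += 1
        j += dead_steps
    return counts


@dataclass
class ThresholdScan:
    """Registered counts versus lowest-threshold value for one beam setting."""

    thresholds_kev: np.ndarray
    counts: np.ndarray
    n_pulses: int
    beam_energy_kev: float
    deadtime_ns: float
    normalization: float | None = None  # unique-count plateau level

    def __post_init__(self) -> None:
        self.thresholds_kev = np.asarray(self.thresholds_kev, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.normalization is None:
            self.normalization = float(self.n_pulses)

    @property
    def normalized(self) -> np.ndarray:
        return self.counts / self.normalization

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "threshold_keV": self.thresholds_kev,
                "counts": self.counts,
                "n_pulses": self.n_pulses,
                "beam_keV": self.beam_energy_kev,
                "deadtime_ns": self.deadtime_ns,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ThresholdScan":
        df = pd.read_csv(path)
        if len(df):
            n_pulses = int(df["n_pulses"].iloc[0])
            beam = float(df["beam_keV"].iloc[0])
            dead = float(df["deadtime_ns"].iloc[0])
        else:  # header-only degenerate scan
            name = Path(path).stem
            n_pulses, beam, dead = 0, float("nan"), float("nan")
            parts = dict(p.split("=") for p in name.split("_") if "=" in p)
            beam = float(parts.get("e", "nan"))
            dead = float(parts.get("td", "nan"))
        return cls(
            df["threshold_keV"].to_numpy(), df["counts"].to_numpy(),
            n_pulses, beam, dead,
        )


def shaped_kernels(
    config: ShaperConfig,
    geometry: DetectorGeometry | None = None,
    energy_kev: float = 60.0,
    n_pulses: int = 20,
    seed: int = 0,
    ensemble=None,
) -> tuple[list, float]:
    """Shaped unit-energy pulse kernels and the self-calibrated gain.

    Returns ``(kernels, gain_mv_per_kev)``; each kernel is the shaped
    waveform of one simulated interaction divided by its deposit, so a
    photon of energy E contributes ``E * kernel``.  The gain is the mean
    kernel peak (mV per keV), which calibrates thresholds to keV.
    """
    if ensemble is None:
        ensemble = standard_pulse_ensemble(
            [energy_kev], geometry=geometry, n_pulses=n_pulses, seed=seed
        )[energy_kev]
    shaped = [shape_pulse(p, config) for p in ensemble]
    kernels = [v.samples_mV / v.source_energy_kev for v in shaped]
    gain = float(np.mean([k.max() for k in kernels]))
    return kernels, gain


def build_pulse_train(
    flux_per_s: float,
    frame_us: float,
    deposit_sampler: Callable[[np.random.Generator, int], np.ndarray],
    kernels: Sequence[np.ndarray],
    dt_ns: float,
    rng: np.random.Generator,
    noise_kev: np.ndarray | None = None,
) -> PulseTrain:
    """Superimpose Poisson-arriving shaped pulses (plus noise) into a frame.

    The number of interacting photons is Poisson with mean flux*T, arrival
    times are uniform on [0, T] and deposits come from ``deposit_sampler``.
    ``kernels`` must be in keV-calibrated units (peak = 1 per keV deposited).
    """
    n_samp = int(round(frame_us * 1e3 / dt_ns))
    n_photons = rng.poisson(flux_per_s * frame_us * 1e-6)
    times = np.sort(rng.uniform(0.0, frame_us * 1e3, n_photons))
    deposits = deposit_sampler(rng, n_photons)
    wf = np.zeros(n_samp)
    if noise_kev is not None:
        wf += noise_kev[:n_samp]
    for t, e in zip(times, deposits):
        k = kernels[rng.integers(len(kernels))]
        i0 = int(round(t / dt_ns))
        seg = min(len(k), n_samp - i0)
        if seg > 0:
            wf[i0:i0 + seg] += e * k[:seg]
    return PulseTrain(wf, dt_ns, frame_us, times, deposits, flux_per_s)


def simulate_threshold_scan(
    beam_energy_kev: float,
    deadtimes_ns: Sequence[float],
    config: ShaperConfig,
    sources: noise_mod.NoiseSources | None = None,
    n_pulses: int = 1000,
    seed: int = 0,
    thresholds_kev: np.ndarray | None = None,
    spacing_us: float = 2.0,
    clock_ns: float = 10.0,
    include_noise: bool = True,
    geometry: DetectorGeometry | None = None,
    ensemble=None,
) -> list[ThresholdScan]:
    """Scan the lowest threshold across a monochromatic pulse record.

    Well-separated full-deposit pulses (one every ``spacing_us``) are summed
    with an electronic-noise realisation; for every deadtime setting the
    record is counted at each threshold with a fresh random clock phase.
    The waveform is keV-calibrated with the configuration's own simulated
    gain, so thresholds are in keV throughout.
    """
    sources = sources if sources is not None else noise_mod.NoiseSources()
    rng = np.random.default_rng(seed)
    if thresholds_kev is None:
        thresholds_kev = np.arange(2.0, beam_energy_kev + 8.0, 0.5)
    dt_ns = 2.0
    kernels, gain = shaped_kernels(
        config, geometry, energy_kev=beam_energy_kev, seed=0, ensemble=ensemble
    )
    n_samp = int(round(n_pulses * spacing_us * 1e3 / dt_ns))
    wf = np.zeros(n_samp)
    offset = int(round(0.3 * spacing_us * 1e3 / dt_ns))
    stride = int(round(spacing_us * 1e3 / dt_ns))
    jitter_max = max(int(round(clock_ns / dt_ns)), 1)
    for m in range(n_pulses):
        k = kernels[rng.integers(len(kernels))]
        # per-pulse arrival jitter over one clock cycle: beam arrivals are
        # asynchronous to the comparator clock, giving the tau_c/2 average delay
        i0 = offset + m * stride + int(rng.integers(0, jitter_max))
        seg = min(len(k), n_samp - i0)
        wf[i0:i0 + seg] += beam_energy_kev * k[:seg] / gain
    if include_noise and n_pulses > 0:
        wf += noise_mod.noise_realization(
            config, sources, duration_us=n_samp * dt_ns * 1e-3, dt_ns=dt_ns, rng=rng,
        ) / gain
    scans = []
    for td in deadtimes_ns:
        counts = np.empty(thresholds_kev.size)
        for i, thr in enumerate(thresholds_kev):
            bank = ComparatorBank((float(thr),), deadtime_ns=td, clock_ns=clock_ns)
            counts[i] = count_frame(wf, dt_ns, bank, rng).sum()
        scans.append(
            ThresholdScan(thresholds_kev.copy(), counts, n_pulses,
                          beam_energy_kev, td)
        )
    return scans


def extract_e_half(
    scan: ThresholdScan,
    exclude_below_kev: float = NOISE_EXCLUSION_KEV,
) -> float:
    """Threshold (keV) where the normalised counts cross 1.5.

    At this point half of the pulses are double counted: the pulse length
    equals deadtime + clock/2.  Thresholds below ``exclude_below_kev`` are
    ignored (noise and triple-count region).
    """
    mask = scan.thresholds_kev > exclude_below_kev
    x = scan.thresholds_kev[mask]
    y = scan.normalized[mask]
    for i in range(x.size - 1):
        if y[i] >= 1.5 > y[i + 1]:
            return float(x[i] + (y[i] - 1.5) / (y[i] - y[i + 1]) * (x[i + 1] - x[i]))
    raise ExtractionError(
        f"no 2->1 transition above {exclude_below_kev} keV "
        f"(beam {scan.beam_energy_kev} keV, deadtime {scan.deadtime_ns} ns)"
    )


class OperatingPoint(NamedTuple):
    threshold_kev: float
    deadtime_ns: float
    pulse_length_ns: float


def deadtime_for(
    shaping_time_ns: float,
    sources: noise_mod.NoiseSources | None = None,
    geometry: DetectorGeometry | None = None,
    clock_ns: float = 10.0,
    seed: int = 0,
) -> OperatingPoint:
    """Operating point of the ideal channel at one shaping time.

    The lowest threshold is 4*sigma(tau) (one noise count on average per
    150-us frame); the deadtime is the length of a 100-keV pulse at that
    threshold, rounded up to a clock multiple.
    """
    sources = sources if sources is not None else noise_mod.NoiseSources()
    sigma = noise_mod.sigma_ideal_kev(shaping_time_ns, sources)
    threshold = 4.0 * sigma
    config = ShaperConfig.ideal(shaping_time_ns / 2)
    kernels, gain = shaped_kernels(config, geometry, energy_kev=100.0, seed=seed)
    mean_kernel = np.mean(np.array(kernels), axis=0)
    # keV-calibrated waveform: peak of the mean 100-keV pulse sits at 100
    pulse = _kernel_pulse(mean_kernel * 100.0 / gain, dt_ns=2.0, energy=100.0)
    length = pulse_length(pulse, threshold)
    deadtime = float(np.ceil(length / clock_ns) * clock_ns)
    return OperatingPoint(threshold, deadtime, length)


def _kernel_pulse(samples, dt_ns, energy):
    from .readout import VoltagePulse

    return VoltagePulse(samples, dt_ns=dt_ns, source_energy_kev=energy)


def count_rate_curve(
    flux_grid_per_s: Sequence[float],
    shaping_time_ns: float,
    deposit_sampler: Callable[[np.random.Generator, int], np.ndarray],
    n_frames: int = 1000,
    frame_us: float = 150.0,
    sources: noise_mod.NoiseSources | None = None,
    geometry: DetectorGeometry | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Registered output count rate versus input (interaction) count rate.

    The lowest threshold is 4*sigma and the deadtime the 100-keV pulse
    length for the given shaping time; deposits are drawn per photon from
    ``deposit_sampler`` (typically a deposited-energy spectrum sampler).
    Returns ``(input_rates, output_rates)`` in counts/s.
    """
    sources = sources if sources is not None else noise_mod.NoiseSources()
    op = deadtime_for(shaping_time_ns, sources, geometry)
    config = ShaperConfig.ideal(shaping_time_ns / 2)
    kernels, gain = shaped_kernels(config, geometry, energy_kev=60.0, seed=seed)
    kevk = [k / gain for k in kernels]
    bank = ComparatorBank((op.threshold_kev,), deadtime_ns=op.deadtime_ns)
    rng = np.random.default_rng(seed)
    out = []
    for flux in flux_grid_per_s:
        total = 0
        for _ in range(n_frames):
            noise_kev = noise_mod.noise_realization(
                config, sources, duration_us=frame_us, rng=rng
            ) / gain
            train = build_pulse_train(
                flux, frame_us, deposit_sampler, kevk, 2.0, rng, noise_kev=noise_kev
            )
            total += count_frame(train.waveform, 2.0, bank, rng).sum()
        out.append(total / (n_frames * frame_us * 1e-6))
    return np.asarray(flux_grid_per_s, dtype=float), np.asarray(out)
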