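"""X-ray tube spectra, silicon detector response and dose efficiency.

The tube spectrum is a semi-empirical model: Kramers bremsstrahlung
filtered by the tungsten target itself (Thomson-Whiddington production
depth, takeoff-angle path), plus the tungsten K fluorescence lines, then
Beer-Lambert filtration through beryllium, aluminium and soft tissue.

The detector response applies the simplified interaction physics of the
transport module photon by photon: attenuation in the 0.6-mm dead layer,
interaction probability over the 30-mm active depth (edge-on geometry),
photoelectric full deposits and Klein-Nishina Compton deposits.  Deposited
spectra are histogrammed on the standard 0.5-keV grid from 1 to 120 keV;
the dose efficiency at a threshold is the fraction of that histogram above
the threshold (unity at zero threshold), representing the registered
fraction of interacting photons for a purely photon-counting detector.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import xraydata
from .constants import MM_CM
from .transport import DetectorGeometry

__all__ = [
    "EmptySpectrumError",
    "EnergySpectrum",
    "BeamConfig",
    "default_energy_edges",
    "tube_spectrum",
    "attenuate",
    "detector_response",
    "dose_efficiency",
    "spectrum_sampler",
]


class EmptySpectrumError(ValueError):
    """Operation on a spectrum with no counts."""


#: tungsten K lines: energy (keV) and relative intensity (K-alpha1 = 100)
W_K_LINES = ((59.318, 100.0), (57.982, 58.0), (67.244, 33.0))
#: K-line share of total fluence after inherent filtration (semi-empirical)
K_LINE_FLUENCE_FRACTION = 0.08
#: Thomson-Whiddington constant for tungsten, keV^2 cm^2/g
THOMSON_WHIDDINGTON_KEV2_CM2_G = 1.1e6


def default_energy_edges() -> np.ndarray:
    """Standard 0.5-keV bin edges from 1 to 120 keV."""
    return np.arange(1.0, 120.0 + 0.25, 0.5)


@dataclass
class EnergySpectrum:
    """Histogram of photon fluence or deposited energy on a keV grid."""

    bin_edges_kev: np.ndarray
    values: np.ndarray
    kind: str = "incident"

    def __post_init__(self) -> None:
        self.bin_edges_kev = np.asarray(self.bin_edges_kev, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.bin_edges_kev.size - 1:
            raise ValueError("values must have one entry per bin")
        if np.any(self.values < 0):
            raise ValueError("spectrum values must be non-negative")

    @property
    def centers_kev(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_kev[:-1] + self.bin_edges_kev[1:])

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def mean_energy_kev(self) -> float:
        if self.total == 0:
            raise EmptySpectrumError("empty spectrum has no mean energy")
        return float((self.values * self.centers_kev).sum() / self.total)

    def normalized(self) -> "EnergySpectrum":
        if self.total == 0:
            raise EmptySpectrumError("cannot normalise an empty spectrum")
        return replace(self, values=self.values / self.total)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"energy_keV": self.centers_kev, "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "incident") -> "EnergySpectrum":
        df = pd.read_csv(path)
        centers = df["energy_keV"].to_numpy(dtype=float)
        width = centers[1] - centers[0]
        edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
        return cls(edges, df["value"].to_numpy(dtype=float), kind=kind)


@dataclass(frozen=True)
class BeamConfig:
    """X-ray tube and filtration settings."""

    kvp: float = 120.0
    anode_angle_deg: float = 10.5
    filtration_al_mm: float = 8.38
    filtration_be_mm: float = 0.8
    tissue_cm: float = 20.0

    def __post_init__(self) -> None:
        if self.kvp <= 0:
            raise ValueError("tube voltage must be positive")
        if min(self.filtration_al_mm, self.filtration_be_mm, self.tissue_cm) < 0:
            raise ValueError("filtration thicknesses must be non-negative")


def tube_spectrum(
    beam: BeamConfig,
    bin_edges_kev: np.ndarray | None = None,
    include_tissue: bool = True,
) -> EnergySpectrum:
    """Filtered tube fluence spectrum (relative units).

    Bremsstrahlung follows Kramers' law attenuated by the mean tungsten
    production depth along the takeoff angle; K lines are added (above the
    69.5-keV K edge) at a fixed share of the inherently filtered fluence.
    Fluence is identically zero above the tube voltage (Duane-Hunt limit).
    """
    edges = bin_edges_kev if bin_edges_kev is not None else default_energy_edges()
    e = 0.5 * (edges[:-1] + edges[1:])
    e0 = beam.kvp
    brems = np.where(e < e0, np.maximum(e0 / e - 1.0, 0.0), 0.0)
    # tungsten self-filtration at the mean production depth
    depth_g_cm2 = (e0**2 - np.minimum(e, e0) ** 2) / (2 * THOMSON_WHIDDINGTON_KEV2_CM2_G)
    sin_takeoff = np.sin(np.deg2rad(beam.anode_angle_deg))
    brems *= np.exp(-xraydata.mu_over_rho("W", e) * depth_g_cm2 / sin_takeoff)
    lines = np.zeros_like(e)
    if e0 > 69.525:
        for line_e, weight in W_K_LINES:
            lines[np.argmin(np.abs(e - line_e))] += weight
    inherent = (
        np.exp(-xraydata.mu_linear("Be", e) * beam.filtration_be_mm * MM_CM)
        * np.exp(-xraydata.mu_linear("Al", e) * beam.filtration_al_mm * MM_CM)
    )
    if lines.any():
        brems_fluence = float((brems * inherent).sum())
        line_fluence = float((lines * inherent).sum())
        target = K_LINE_FLUENCE_FRACTION / (1 - K_LINE_FLUENCE_FRACTION)
        lines *= target * brems_fluence / line_fluence
    spec = EnergySpectrum(edges, (brems + lines) * inherent, kind="incident")
    if include_tissue and beam.tissue_cm > 0:
        spec = attenuate(spec, "soft_tissue", beam.tissue_cm)
    return spec


def attenuate(spectrum: EnergySpectrum, material: str, thickness_cm: float) -> EnergySpectrum:
    """Beer-Lambert filtration of a fluence spectrum (per-bin scaling)."""
    if thickness_cm < 0:
        raise ValueError("thickness must be non-negative")
    factor = np.exp(-xraydata.mu_linear(material, spectrum.centers_kev) * thickness_cm)
    return replace(spectrum, values=spectrum.values * factor)


def detector_response(
    incident: EnergySpectrum,
    geometry: DetectorGeometry | None = None,
    n_photons: int = 10**6,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EnergySpectrum:
    """Monte-Carlo deposited-energy spectrum of the edge-on silicon detector.

    Per photon: survive the dead layer, interact (or not) over the active
    depth, deposit the full energy (photoelectric) or a Klein-Nishina
    Compton electron energy.  Photons that pass through undetected are
    excluded; deposits are histogrammed on the incident spectrum's grid, so
    deposits below the lowest bin edge fall outside the spectrum.
    """
    geometry = geometry if geometry is not None else DetectorGeometry()
    rng = rng if rng is not None else np.random.default_rng(seed)
    if incident.total == 0:
        raise EmptySpectrumError("incident spectrum is empty")
    edges = incident.bin_edges_kev
    p = incident.values / incident.total
    idx = rng.choice(incident.values.size, size=n_photons, p=p)
    e = edges[idx] + rng.random(n_photons) * np.diff(edges)[idx]
    mu = xraydata.si_interaction_mu_linear(e)
    dead_cm = geometry.dead_layer_mm * MM_CM
    active_cm = geometry.strip_length_mm * MM_CM
    survives = rng.random(n_photons) < np.exp(-mu * dead_cm)
    interacts = rng.random(n_photons) < -np.expm1(-mu * active_cm)
    e = e[survives & interacts]
    photo = rng.random(e.size) < xraydata.si_photo_fraction(e)
    deposits = np.where(photo, e, 0.0)
    compton = ~photo
    deposits[compton] = xraydata.sample_compton_deposit(e[compton], rng)
    hist, _ = np.histogram(deposits, bins=edges)
    return EnergySpectrum(edges, hist.astype(float), kind="deposited")


def dose_efficiency(deposited: EnergySpectrum, threshold_kev: float) -> float:
    """Fraction of the deposited-energy histogram above ``threshold_kev``.

    Monotone non-increasing in the threshold, equal to 1 at threshold 0;
    thresholds inside a bin are resolved assuming uniform density in the bin.
    """
    if threshold_kev < 0:
        raise ValueError("threshold must be non-negative")
    total = deposited.total
    if total == 0:
        raise EmptySpectrumError("deposited spectrum is empty")
    edges = deposited.bin_edges_kev
    if threshold_kev <= edges[0]:
        return 1.0
    if threshold_kev >= edges[-1]:
        return 0.0
    i = np.searchsorted(edges, threshold_kev, side="right") - 1
    frac_of_bin = (edges[i + 1] - threshold_kev) / (edges[i + 1] - edges[i])
    above = deposited.values[i + 1:].sum() + deposited.values[i] * frac_of_bin
    return float(above / total)


def spectrum_sampler(spectrum: EnergySpectrum):
    """Energy sampler ``f(rng, n) -> keV array`` over a spectrum's bins."""
    if spectrum.total == 0:
        raise EmptySpectrumError("cannot sample from an empty spectrum")
    p = spectrum.values / spectrum.total
    edges = spectrum.bin_edges_kev
    widths = np.diff(edges)

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        idx = rng.choice(p.size, size=n, p=p)
        return edges[idx] + rng.random(n) * widths[idx]

    return sample
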