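"""Photon interaction data for the materials in the beam path and detector.

Internal tabulations of total mass-attenuation coefficients (NIST-style
energy grid, cm^2/g, log-log interpolated) for the handful of materials the
simulator needs: silicon (detector), aluminium/beryllium (inherent tube
filtration), ICRU-44 soft tissue (patient filtration) and tungsten (anode
self-filtration).  Absorption-edge discontinuities are represented by grid
point pairs immediately below/above the edge.

The incoherent (Compton) component for silicon is computed from the exact
Klein-Nishina total cross section (free-electron approximation; the
incoherent-scattering-function correction is a few percent below ~30 keV,
where photoabsorption dominates anyway).  The photoelectric component is
obtained by subtracting the incoherent and a small tabulated coherent
estimate from the total.  Coherent scattering deposits no energy and is
excluded from the interaction cross section used for energy deposition.
"""

from __future__ import annotations

import numpy as np

from .constants import ELECTRON_REST_KEV, SI_A, SI_DENSITY_G_CM3, SI_Z

__all__ = [
    "MaterialError",
    "mu_over_rho",
    "mu_linear",
    "klein_nishina_total_barns",
    "si_incoherent_mu_rho",
    "si_photoelectric_mu_rho",
    "si_interaction_mu_linear",
    "si_photo_fraction",
    "compton_edge_kev",
    "sample_compton_deposit",
    "DENSITY_G_CM3",
]


class MaterialError(KeyError):
    """Unknown material requested from the attenuation tables."""


AVOGADRO = 6.02214076e23
_RE2_BARN = 0.0794080  # classical electron radius squared, barn

# total mass attenuation (with coherent), cm^2/g -------------------------------
_TABLES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "Si": (
        (1.0, 1.5, 1.8389, 1.8390, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0,
         20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0),
        (1570.0, 535.5, 309.2, 3192.0, 2777.0, 978.4, 452.9, 245.0, 147.0,
         64.68, 33.89, 10.34, 4.464, 1.436, 0.7012, 0.4385, 0.3207, 0.2228,
         0.1835, 0.1448),
    ),
    "Al": (
        (1.0, 1.5, 1.5596, 1.5597, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0,
         20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0),
        (1185.0, 402.2, 362.1, 3957.0, 2263.0, 788.0, 360.5, 193.4, 115.3,
         50.33, 26.23, 7.955, 3.441, 1.128, 0.5685, 0.3681, 0.2778, 0.2018,
         0.1704, 0.1378),
    ),
    "Be": (
        (1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0,
         40.0, 50.0, 60.0, 80.0, 100.0, 150.0),
        (604.1, 179.7, 74.69, 21.27, 8.685, 4.369, 2.527, 1.124, 0.6466,
         0.307, 0.2251, 0.1792, 0.1640, 0.1554, 0.1493, 0.1401, 0.1328,
         0.1190),
    ),
    "soft_tissue": (
        (1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0,
         40.0, 50.0, 60.0, 80.0, 100.0, 150.0),
        (3774.0, 1301.0, 579.6, 192.3, 82.70, 42.41, 24.62, 10.37, 5.367,
         1.693, 0.8205, 0.3783, 0.2685, 0.2262, 0.2048, 0.1823, 0.1693,
         0.1492),
    ),
    "W": (
        (1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 10.20, 10.21, 11.53,
         11.54, 12.09, 12.10, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 69.52,
         69.53, 80.0, 100.0, 150.0),
        (3683.0, 1643.0, 3170.0, 2273.0, 1252.0, 720.6, 456.5, 216.0, 96.91,
         91.5, 212.0, 168.0, 226.0, 204.0, 237.0, 139.3, 65.73, 22.73, 10.67,
         5.949, 3.713, 2.552, 11.23, 7.810, 4.438, 1.581),
    ),
    # small coherent-scattering estimate for silicon, used only to split the
    # total into interaction components; errors here shift the photoelectric
    # component by at most a few percent
    "_Si_coherent": (
        (1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0,
         40.0, 50.0, 60.0, 80.0, 100.0, 150.0),
        (1.90, 1.80, 1.70, 1.50, 1.30, 1.15, 1.00, 0.78, 0.62, 0.40, 0.28,
         0.152, 0.094, 0.063, 0.0455, 0.0266, 0.0173, 0.0081),
    ),
}

DENSITY_G_CM3 = {
    "Si": SI_DENSITY_G_CM3,
    "Al": 2.699,
    "Be": 1.848,
    "soft_tissue": 1.06,
    "W": 19.30,
}


def _interp_loglog(energy_kev, grid, values):
    e = np.asarray(energy_kev, dtype=float)
    return np.exp(np.interp(np.log(e), np.log(grid), np.log(values)))


def mu_over_rho(material: str, energy_kev) -> np.ndarray:
    """Total mass-attenuation coefficient (cm^2/g) at ``energy_kev``."""
    if material not in _TABLES or material.startswith("_"):
        raise MaterialError(
            f"no attenuation table for {material!r}; "
            f"known: {sorted(k for k in _TABLES if not k.startswith('_'))}"
        )
    grid, values = _TABLES[material]
    return _interp_loglog(energy_kev, grid, values)


def mu_linear(material: str, energy_kev) -> np.ndarray:
    """Linear attenuation coefficient (1/cm)."""
    return mu_over_rho(material, energy_kev) * DENSITY_G_CM3[material]


def klein_nishina_total_barns(energy_kev) -> np.ndarray:
    """Total Klein-Nishina cross section per electron, in barn."""
    a = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log1p(2 * a) / a)
    t2 = np.log1p(2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * _RE2_BARN * (t1 + t2 - t3)


def si_incoherent_mu_rho(energy_kev) -> np.ndarray:
    """Incoherent (Compton) mass attenuation for silicon, cm^2/g."""
    per_electron_cm2 = klein_nishina_total_barns(energy_kev) * 1e-24
    return per_electron_cm2 * AVOGADRO * SI_Z / SI_A


def si_photoelectric_mu_rho(energy_kev) -> np.ndarray:
    """Photoelectric mass attenuation for silicon, cm^2/g (by subtraction)."""
    total = mu_over_rho("Si", energy_kev)
    coherent = _interp_loglog(energy_kev, *_TABLES["_Si_coherent"])
    photo = total - coherent - si_incoherent_mu_rho(energy_kev)
    return np.maximum(photo, 1e-8)


def si_interaction_mu_linear(energy_kev) -> np.ndarray:
    """Energy-depositing linear attenuation (photo + incoherent), 1/cm."""
    mu_rho = si_photoelectric_mu_rho(energy_kev) + si_incoherent_mu_rho(energy_kev)
    return mu_rho * SI_DENSITY_G_CM3


def si_photo_fraction(energy_kev) -> np.ndarray:
    """Probability that an energy-depositing interaction is photoelectric."""
    photo = si_photoelectric_mu_rho(energy_kev)
    return photo / (photo + si_incoherent_mu_rho(energy_kev))


def compton_edge_kev(energy_kev) -> np.ndarray:
    """Maximum Compton electron energy 2E^2/(m_e c^2 + 2E)."""
    e = np.asarray(energy_kev, dtype=float)
    return 2 * e**2 / (ELECTRON_REST_KEV + 2 * e)


def sample_compton_cos_theta(energy_kev: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample photon scattering angles from the Klein-Nishina distribution.

    Rejection sampling against a uniform envelope in cos(theta); the
    differential cross section per unit cos(theta) is bounded by its forward
    value of 2 (in units of pi*re^2*(E'/E)^2... prefactors cancel).
    """
    e = np.asarray(energy_kev, dtype=float)
    a = e / ELECTRON_REST_KEV
    out = np.empty(e.shape, dtype=float)
    todo = np.arange(e.size)
    while todo.size:
        c = rng.uniform(-1.0, 1.0, todo.size)
        r = 1.0 / (1.0 + a[todo] * (1.0 - c))  # E'/E
        f = r**2 * (r + 1.0 / r - (1.0 - c**2))
        accept = rng.random(todo.size) * 2.0 < f
        out[todo[accept]] = c[accept]
        todo = todo[~accept]
    return out


def sample_compton_deposit(energy_kev: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample Compton electron (deposited) energies in keV."""
    e = np.asarray(energy_kev, dtype=float)
    c = sample_compton_cos_theta(e, rng)
    scattered = e / (1.0 + e / ELECTRON_REST_KEV * (1.0 - c))
    return e - scattered
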