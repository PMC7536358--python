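"""Charge transport in an edge-on silicon strip detector.

Photon interactions create electron-hole clouds in the depleted bulk; the
carriers drift in the solved 1-D electric field (v = mu*E), diffuse in two
dimensions, and induce a current on the collecting strip through the
Shockley-Ramo theorem with a planar weighting field E_w = 1/d (appropriate
for a beam confined to the centre of one pixel, where charge sharing is
absent).  Time stepping is on the package-wide 2-ns grid.

Geometry convention: x is the drift axis with the collecting strip (the
junction) at x = 0 and the backside at x = d (wafer thickness); y is the
lateral in-pixel coordinate; the beam axis (strip length, depth segments)
is orthogonal to both and does not enter the planar signal model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import xraydata
from .constants import (
    BOLTZMANN_J_PER_K,
    ELECTRON_CHARGE_C,
    EPS_SI_F_PER_CM,
    MM_CM,
    MU_ELECTRON_CM2_VS,
    MU_HOLE_CM2_VS,
    NS,
    UA,
    UM_CM,
    pairs_from_kev,
)

__all__ = [
    "DepletionError",
    "DetectorGeometry",
    "ElectricField",
    "CarrierCloud",
    "Trajectory",
    "solve_field",
    "transport_step",
    "induced_current",
    "sample_interaction",
    "simulate_current_pulse",
    "standard_pulse_ensemble",
]


class DepletionError(ValueError):
    """Bias voltage below the depletion voltage of the configured wafer."""


@dataclass(frozen=True)
class DetectorGeometry:
    """Geometry and operating point of the silicon strip detector."""

    pixel_pitch_x_mm: float = 0.4
    pixel_pitch_y_mm: float = 0.5
    wafer_thickness_um: float = 500.0
    bias_voltage_v: float = 400.0
    doping_cm3: float = 4.6e11
    temperature_k: float = 300.0
    strip_length_mm: float = 30.0
    n_segments: int = 9
    dead_layer_mm: float = 0.6

    def __post_init__(self) -> None:
        positive = (
            self.pixel_pitch_x_mm, self.pixel_pitch_y_mm, self.wafer_thickness_um,
            self.bias_voltage_v, self.doping_cm3, self.temperature_k,
            self.strip_length_mm,
        )
        if min(positive) <= 0 or self.n_segments < 1 or self.dead_layer_mm < 0:
            raise ValueError("geometry dimensions must be positive")

    @property
    def thickness_cm(self) -> float:
        return self.wafer_thickness_um * UM_CM

    @property
    def depletion_voltage_v(self) -> float:
        """Full-depletion voltage e*N*d^2/(2*eps) of the uniformly doped wafer."""
        rho = ELECTRON_CHARGE_C * self.doping_cm3
        return rho * self.thickness_cm**2 / (2 * EPS_SI_F_PER_CM)


@dataclass
class ElectricField:
    """Electric field magnitude along the drift axis, from the Poisson solve."""

    x_um: np.ndarray
    strength_v_per_cm: np.ndarray
    potential_v: np.ndarray

    def __call__(self, x_um) -> np.ndarray:
        return np.interp(x_um, self.x_um, self.strength_v_per_cm)

    @staticmethod
    def closed_form(geometry: DetectorGeometry, x_um) -> np.ndarray:
        """Analytic over-depleted planar field E(x) = V/d + (rho/eps)(d/2 - x)."""
        d = geometry.thickness_cm
        rho = ELECTRON_CHARGE_C * geometry.doping_cm3
        x = np.asarray(x_um, dtype=float) * UM_CM
        return geometry.bias_voltage_v / d + rho / EPS_SI_F_PER_CM * (d / 2 - x)


def solve_field(geometry: DetectorGeometry, n_points: int = 2001) -> ElectricField:
    """Solve the 1-D Poisson equation phi'' = -rho/eps by finite differences.

    Boundary conditions: phi(0) = 0 at the collecting strip, phi(d) = bias
    at the backside.  Raises :class:`DepletionError` when the wafer is not
    fully depleted at the configured bias.
    """
    if geometry.depletion_voltage_v > geometry.bias_voltage_v:
        raise DepletionError(
            f"depletion voltage {geometry.depletion_voltage_v:.1f} V exceeds "
            f"bias {geometry.bias_voltage_v:.1f} V"
        )
    d = geometry.thickness_cm
    rho = ELECTRON_CHARGE_C * geometry.doping_cm3
    x = np.linspace(0.0, d, n_points)
    h = x[1] - x[0]
    # tridiagonal Dirichlet solve via Thomas algorithm in vectorised form
    rhs = np.full(n_points - 2, -rho / EPS_SI_F_PER_CM * h**2)
    rhs[-1] -= geometry.bias_voltage_v
    diag = np.full(n_points - 2, -2.0)
    off = np.ones(n_points - 3)
    ab = np.zeros((3, n_points - 2))
    ab[0, 1:] = off
    ab[1] = diag
    ab[2, :-1] = off
    from scipy.linalg import solve_banded

    phi = np.empty(n_points)
    phi[0] = 0.0
    phi[-1] = geometry.bias_voltage_v
    phi[1:-1] = solve_banded((1, 1), ab, rhs)
    strength = np.gradient(phi, x)  # dphi/dx > 0 everywhere when over-depleted
    return ElectricField(x / UM_CM, strength, phi)


@dataclass
class CarrierCloud:
    """Macro-carrier ensemble: positions, species sign and charge weights.

    ``sign`` is +1 for holes and -1 for electrons; ``weight_pairs`` is the
    number of elementary charges each macro-carrier represents.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    sign: np.ndarray
    weight_pairs: np.ndarray
    active: np.ndarray
    creation_time_ns: float = 0.0

    @classmethod
    def from_deposit(
        cls,
        energy_kev: float,
        x0_um: float,
        y0_um: float = 0.0,
        n_carriers: int = 1000,
        spread_um: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> "CarrierCloud":
        """Point-like (optionally Gaussian-spread) cloud for a deposit."""
        n_pairs = pairs_from_kev(energy_kev)
        w = np.full(2 * n_carriers, n_pairs / n_carriers)
        sign = np.concatenate([np.ones(n_carriers), -np.ones(n_carriers)])
        x = np.full(2 * n_carriers, float(x0_um))
        y = np.full(2 * n_carriers, float(y0_um))
        if spread_um > 0:
            rng = rng if rng is not None else np.random.default_rng(0)
            x = x + rng.normal(0.0, spread_um, 2 * n_carriers)
            y = y + rng.normal(0.0, spread_um, 2 * n_carriers)
        return cls(x, y, sign, w, np.ones(2 * n_carriers, dtype=bool))

    @property
    def total_pairs(self) -> float:
        holes = self.weight_pairs[self.sign > 0].sum()
        return float(holes)


def _mobility(sign: np.ndarray) -> np.ndarray:
    return np.where(sign > 0, MU_HOLE_CM2_VS, MU_ELECTRON_CM2_VS)


_VSAT_CM_S = {1: 8.37e6, -1: 1.02e7}  # optional velocity-saturation limits


def transport_step(
    cloud: CarrierCloud,
    fieldmap: ElectricField,
    geometry: DetectorGeometry,
    dt_ns: float = 2.0,
    rng: np.random.Generator | None = None,
    velocity_saturation: bool = False,
) -> np.ndarray:
    """Advance the cloud one time step in place; return signed x-displacements.

    Each active carrier moves by mu*E*dt along its collection direction
    (holes toward the strip at x=0, electrons toward the backside) plus
    independent Gaussian diffusion displacements in x and y with variance
    2*D*dt, D = kT*mu/e.  Carriers reaching an electrode are absorbed
    (clipped to the boundary and deactivated); lateral positions are
    reflected at the pixel boundaries.  The returned displacement array
    (cm, signed, zero for inactive carriers) feeds the Ramo current.
    """
    if dt_ns <= 0:
        raise ValueError("dt must be positive")
    rng = rng if rng is not None else np.random.default_rng(0)
    dt = dt_ns * NS
    d_cm = geometry.thickness_cm
    act = cloud.active
    dx = np.zeros(cloud.x_um.size)
    if not act.any():
        return dx
    mu = _mobility(cloud.sign[act])
    e_field = fieldmap(cloud.x_um[act])
    v_drift = mu * e_field
    if velocity_saturation:
        vsat = np.where(cloud.sign[act] > 0, _VSAT_CM_S[1], _VSAT_CM_S[-1])
        v_drift = v_drift / (1.0 + v_drift / vsat)
    direction = -cloud.sign[act]  # holes -> -x (strip), electrons -> +x
    diffusion = BOLTZMANN_J_PER_K * geometry.temperature_k * mu / ELECTRON_CHARGE_C
    sigma_cm = np.sqrt(2.0 * diffusion * dt)
    x_old = cloud.x_um[act] * UM_CM
    x_new = x_old + direction * v_drift * dt + rng.normal(0.0, 1.0, mu.size) * sigma_cm
    collected = (x_new <= 0.0) | (x_new >= d_cm)
    x_new = np.clip(x_new, 0.0, d_cm)
    dx[act] = x_new - x_old
    # lateral diffusion with reflection at the pixel boundary
    half_pitch = geometry.pixel_pitch_y_mm * MM_CM / 2
    y_new = cloud.y_um[act] * UM_CM + rng.normal(0.0, 1.0, mu.size) * sigma_cm
    y_new = half_pitch - np.abs(np.abs(y_new + half_pitch) % (4 * half_pitch) - 2 * half_pitch)
    cloud.x_um[act] = x_new / UM_CM
    cloud.y_um[act] = y_new / UM_CM
    idx = np.nonzero(act)[0]
    cloud.active[idx[collected]] = False
    return dx


@dataclass
class Trajectory:
    """Per-step signed x-displacements of every macro-carrier (cm)."""

    displacements_cm: np.ndarray  # (n_steps, n_carriers)
    sign: np.ndarray
    weight_pairs: np.ndarray
    dt_ns: float
    energy_kev: float = 0.0
    metadata: dict = field(default_factory=dict)


def induced_current(trajectory: Trajectory, geometry: DetectorGeometry):
    """Shockley-Ramo induced current on the collecting strip.

    With the planar weighting field E_w = 1/d the current is
    i(t) = sum_k q_k * v_k / d; integrating a fully collected trajectory
    yields the total generated charge exactly.
    """
    from .readout import CurrentPulse

    dt = trajectory.dt_ns * NS
    d_cm = geometry.thickness_cm
    q = -trajectory.sign * trajectory.weight_pairs * ELECTRON_CHARGE_C
    # hole (+1) moving -x and electron (-1) moving +x both induce positive current
    amps = trajectory.displacements_cm @ q / (dt * d_cm)
    return CurrentPulse(
        amps / UA,
        dt_ns=trajectory.dt_ns,
        energy_kev=trajectory.energy_kev,
        metadata=dict(trajectory.metadata),
    )


def sample_interaction(
    energy_kev: float,
    geometry: DetectorGeometry,
    rng: np.random.Generator,
    n_carriers: int = 1000,
    x0_um: float | None = None,
    spread_um: float = 0.0,
):
    """Sample one photon interaction: type, deposited energy, carrier cloud.

    The interaction is photoelectric (full deposit) or Compton (deposit from
    the Klein-Nishina electron-energy distribution) with probabilities from
    the silicon cross sections; the depth along the strip is drawn from
    exponential attenuation over the active length and stored as metadata.
    Returns ``(cloud, deposited_kev, kind)``; the cloud is point-like at the
    wafer mid-plane unless ``x0_um`` is given.
    """
    if not (1.0 <= energy_kev <= 150.0):
        raise ValueError("photon energy must lie in [1, 150] keV")
    mu = float(xraydata.si_interaction_mu_linear(energy_kev))
    length_cm = geometry.strip_length_mm * MM_CM
    u = rng.random()
    depth_cm = -np.log1p(-u * (1 - np.exp(-mu * length_cm))) / mu
    if rng.random() < float(xraydata.si_photo_fraction(energy_kev)):
        deposited = float(energy_kev)
        kind = "photoelectric"
    else:
        deposited = float(xraydata.sample_compton_deposit(np.array([energy_kev]), rng)[0])
        kind = "compton"
    x0 = geometry.wafer_thickness_um / 2 if x0_um is None else x0_um
    cloud = CarrierCloud.from_deposit(
        deposited, x0, n_carriers=n_carriers, spread_um=spread_um, rng=rng
    )
    cloud.creation_time_ns = 0.0
    meta = {"kind": kind, "depth_mm": depth_cm / MM_CM, "x0_um": x0}
    return cloud, deposited, meta


def simulate_current_pulse(
    energy_kev: float,
    geometry: DetectorGeometry,
    x0_um: float | None = None,
    rng: np.random.Generator | None = None,
    n_carriers: int = 1000,
    dt_ns: float = 2.0,
    max_steps: int = 500,
    fieldmap: ElectricField | None = None,
    velocity_saturation: bool = False,
):
    """Full-deposit induced-current pulse for an interaction at ``x0_um``.

    Composes cloud creation, drift-diffusion stepping and the Ramo sum on
    the 2-ns grid; the pulse ends when every carrier has been collected.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    fieldmap = fieldmap if fieldmap is not None else solve_field(geometry)
    x0 = geometry.wafer_thickness_um / 2 if x0_um is None else x0_um
    cloud = CarrierCloud.from_deposit(energy_kev, x0, n_carriers=n_carriers, rng=rng)
    steps = []
    for _ in range(max_steps):
        steps.append(
            transport_step(cloud, fieldmap, geometry, dt_ns, rng,
                           velocity_saturation=velocity_saturation)
        )
        if not cloud.active.any():
            break
    traj = Trajectory(
        np.array(steps), cloud.sign, cloud.weight_pairs, dt_ns,
        energy_kev=energy_kev, metadata={"x0_um": x0},
    )
    return induced_current(traj, geometry)


def standard_pulse_ensemble(
    energies_kev: Sequence[float],
    geometry: DetectorGeometry | None = None,
    n_pulses: int = 20,
    seed: int = 0,
    n_carriers: int = 1000,
    beam_sigma_um: float = 50.0,
) -> Mapping[float, list]:
    """Seeded full-deposit pulse ensembles for gain and pulse-shape studies.

    Emulates a monochromatic beam centred on one pixel: interaction
    positions are normally distributed about the wafer mid-plane with the
    beam width ``beam_sigma_um``, clipped away from the electrodes.
    """
    geometry = geometry if geometry is not None else DetectorGeometry()
    rng = np.random.default_rng(seed)
    fieldmap = solve_field(geometry)
    d = geometry.wafer_thickness_um
    out: dict[float, list] = {}
    for e in energies_kev:
        pulses = []
        for _ in range(n_pulses):
            x0 = float(np.clip(rng.normal(d / 2, beam_sigma_um), 0.05 * d, 0.95 * d))
            pulses.append(
                simulate_current_pulse(
                    e, geometry, x0_um=x0, rng=rng, n_carriers=n_carriers,
                    fieldmap=fieldmap,
                )
            )
        out[float(e)] = pulses
    return out
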