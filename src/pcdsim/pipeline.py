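"""Run configuration, synthetic measurement-campaign fixtures and the
end-to-end pipeline (simulate -> scan -> fit -> report).

The fixture generator emulates the structure of the synchrotron
characterisation campaign: per detector module, threshold scans at a set of
beam energies and deadtime settings for both shaping-time settings, with
Poisson counting statistics, written in the ThresholdScan CSV dialect.
The module profiles carry the fitted time constants (tau_long, tau_short)
of the four measured detector modules.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import counting, noise as noise_mod, power, spectrum as spectrum_mod
from .calibration import PulseLengthMeasurement, fit_shape_params
from .readout import ShaperConfig, gain as channel_gain
from .spectrum import BeamConfig
from .transport import DetectorGeometry, standard_pulse_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "PipelineError",
    "RunConfig",
    "MODULE_PROFILES",
    "generate_fixture_scans",
    "run_pipeline",
]


class ConfigurationError(ValueError):
    """Invalid or missing run configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in ``stage``."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class ModuleProfile:
    """Fitted time constants and scan campaign of one detector module."""

    tau0_ns: float
    b_short: float
    # (setting, energy_keV, deadtimes_ns)
    campaign: tuple

    @property
    def tau_long_ns(self) -> float:
        return 2 * self.tau0_ns

    @property
    def tau_short_ns(self) -> float:
        return 2 * self.b_short * self.tau0_ns


MODULE_PROFILES: dict[int, ModuleProfile] = {
    1: ModuleProfile(19.6, 27.8 / 39.2, (
        ("long", 40.0, (70.0, 80.0)),
        ("long", 60.0, (70.0, 80.0, 90.0, 100.0)),
        ("long", 70.0, (70.0, 80.0, 90.0, 100.0)),
        ("short", 60.0, (70.0, 80.0)),
        ("short", 70.0, (70.0, 80.0)),
    )),
    2: ModuleProfile(20.7, 28.6 / 41.4, (
        ("long", 40.0, (70.0, 80.0, 90.0)),
        ("long", 60.0, (70.0, 80.0, 90.0, 100.0)),
        ("long", 80.0, (70.0, 80.0, 90.0, 100.0)),
        ("short", 40.0, (70.0, 80.0)),
        ("short", 60.0, (70.0, 80.0, 90.0)),
    )),
    3: ModuleProfile(19.2, 27.6 / 38.4, (
        ("long", 40.0, (40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)),
        ("short", 40.0, (40.0, 50.0, 60.0, 70.0)),
    )),
    4: ModuleProfile(19.3, 28.2 / 38.6, (
        ("long", 40.0, (40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)),
        ("short", 40.0, (40.0, 50.0, 60.0, 70.0)),
    )),
}


@dataclass
class RunConfig:
    """Validated configuration of one end-to-end pipeline run.

    Defaults are the printed operating values of the measured system.
    """

    module: int = 1
    seed: int = 1
    n_pulses: int = 600
    n_photons: int = 200_000
    output_dir: str = "results"
    geometry: DetectorGeometry = field(default_factory=DetectorGeometry)
    sources: noise_mod.NoiseSources = field(default_factory=noise_mod.NoiseSources)
    beam: BeamConfig = field(default_factory=BeamConfig)
    shaping_times_ns: tuple = (40.0, 100.0, 200.0)
    power_factors: tuple = (0.5,)

    def __post_init__(self) -> None:
        if self.module not in MODULE_PROFILES:
            raise ConfigurationError(f"module must be one of {sorted(MODULE_PROFILES)}")
        if self.n_pulses < 0 or self.n_photons <= 0:
            raise ConfigurationError("n_pulses must be >= 0 and n_photons > 0")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key, typ in (("geometry", DetectorGeometry),
                         ("sources", noise_mod.NoiseSources),
                         ("beam", BeamConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                try:
                    kwargs[key] = typ(**kwargs[key])
                except (TypeError, ValueError) as exc:
                    raise ConfigurationError(f"invalid {key} block: {exc}") from exc
        for key in ("shaping_times_ns", "power_factors"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"configuration file not found: {path}")
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise ConfigurationError("configuration file must contain a mapping")
        return cls.from_dict(data)


def generate_fixture_scans(
    config: RunConfig,
    out_dir=None,
    n_pulses: int | None = None,
) -> list[Path]:
    """Write the synthetic threshold-scan campaign for one module profile.

    Output is deterministic in (config, seed): one CSV per (setting,
    energy, deadtime) in the ThresholdScan dialect.  ``n_pulses = 0``
    produces header-only scans.
    """
    profile = MODULE_PROFILES[config.module]
    n_pulses = config.n_pulses if n_pulses is None else n_pulses
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    energies = sorted({e for _, e, _ in profile.campaign})
    ensembles = standard_pulse_ensemble(energies, geometry=config.geometry, seed=0)
    paths = []
    for i, (setting, energy, deadtimes) in enumerate(profile.campaign):
        b = 1.0 if setting == "long" else profile.b_short
        cfg = ShaperConfig.prototype(profile.tau0_ns, b)
        if n_pulses == 0:
            scans = [
                counting.ThresholdScan(np.empty(0), np.empty(0), 0, energy, td)
                for td in deadtimes
            ]
        else:
            scans = counting.simulate_threshold_scan(
                energy, deadtimes, cfg, config.sources, n_pulses=n_pulses,
                seed=config.seed * 1000 + i, geometry=config.geometry,
                ensemble=ensembles[energy],
            )
        for scan in scans:
            name = (f"scan_module{config.module}_{setting}"
                    f"_e={energy:g}_td={scan.deadtime_ns:g}.csv")
            scan.to_csv(out / name)
            paths.append(out / name)
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain: fixtures -> E1/2 -> shape fit -> noise/gain
    ratios -> spectra and dose efficiency -> power tradeoff.

    Returns the results bundle (also written as ``results.json``); every
    stage failure is re-raised as :class:`PipelineError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"seed": config.seed, "module": config.module}
    profile = MODULE_PROFILES[config.module]

    def stage(name):
        def wrap(fn):
            try:
                logger.info("pipeline stage: %s", name)
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, str(exc)) from exc
        return wrap

    @stage("calibration")
    def _cal():
        cal = noise_mod.reference_calibration(config.sources)
        results["calibration"] = cal._asdict()
        return cal

    @stage("fixtures")
    def _scans():
        return generate_fixture_scans(config, out / "scans")

    @stage("pulse-shape-fit")
    def _fit():
        energies = sorted({e for _, e, _ in profile.campaign})
        ensembles = standard_pulse_ensemble(energies, geometry=config.geometry, seed=0)
        measurements = []
        for path in _scans:
            scan = counting.ThresholdScan.from_csv(path)
            setting = "long" if "_long_" in path.name else "short"
            try:
                e_half = counting.extract_e_half(scan)
            except counting.ExtractionError:
                continue
            measurements.append(PulseLengthMeasurement(
                setting, scan.beam_energy_kev, scan.deadtime_ns, e_half))
        fit = fit_shape_params(measurements, ensembles)
        results["shape_fit"] = {
            "tau0_ns": fit.tau0_ns, "b_short": fit.b_short,
            "tau_long_ns": fit.tau_long_ns, "tau_short_ns": fit.tau_short_ns,
            "mse_ns2": fit.mse_ns2, "n_measurements": len(measurements),
        }
        return fit

    @stage("noise-gain-ratios")
    def _ratios():
        ens = standard_pulse_ensemble([40.0, 60.0, 70.0, 80.0],
                                      geometry=config.geometry, seed=0)
        long_cfg = ShaperConfig.prototype(_fit.tau0_ns, 1.0)
        short_cfg = ShaperConfig.prototype(_fit.tau0_ns, _fit.b_short)
        g_long = channel_gain(long_cfg, ens)
        g_short = channel_gain(short_cfg, ens)
        s_long, _ = noise_mod.sigma_total(long_cfg, config.sources)
        s_short, _ = noise_mod.sigma_total(short_cfg, config.sources)
        results["ratios"] = {
            "gain_long_mv_per_kev": g_long, "gain_short_mv_per_kev": g_short,
            "gain_ratio": g_long / g_short,
            "sigma_kev_ratio": (s_long / g_long) / (s_short / g_short),
        }

    @stage("spectrum")
    def _spec():
        incident = spectrum_mod.tube_spectrum(config.beam)
        deposited = spectrum_mod.detector_response(
            incident, config.geometry, n_photons=config.n_photons,
            seed=config.seed,
        )
        deposited.to_csv(out / "deposited_spectrum.csv")
        ops = {}
        for tau in config.shaping_times_ns:
            op = counting.deadtime_for(tau, config.sources, config.geometry)
            ops[tau] = {
                "threshold_kev": op.threshold_kev,
                "deadtime_ns": op.deadtime_ns,
                "pulse_length_ns": op.pulse_length_ns,
                "dose_efficiency_pct":
                    100 * spectrum_mod.dose_efficiency(deposited, op.threshold_kev),
            }
        results["operating_points"] = ops

    @stage("power")
    def _power():
        results["power_tradeoff"] = {
            str(p): {
                scope: power.compensation_factor(p, 40.0, config.sources, scope)
                for scope in power.SCOPES
            }
            for p in config.power_factors
        }

    (out / "results.json").write_text(json.dumps(results, indent=1, default=float))
    logger.info("pipeline results written to %s", out / "results.json")
    return results
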