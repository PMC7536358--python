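"""CSV dialects for waveforms and spectra, with JSON metadata sidecars.

Waveforms travel as two-column CSV (time_ns, value) plus a ``.json``
sidecar carrying units and provenance; threshold scans and spectra have
their own dialects on :class:`~pcdsim.counting.ThresholdScan` and
:class:`~pcdsim.spectrum.EnergySpectrum`.  All dialects round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .readout import CurrentPulse, VoltagePulse

__all__ = ["write_waveform_csv", "read_waveform_csv"]


def write_waveform_csv(path, pulse: "CurrentPulse | VoltagePulse") -> None:
    """Write a waveform as (time_ns, value) CSV with a JSON sidecar."""
    path = Path(path)
    if isinstance(pulse, CurrentPulse):
        values, unit = pulse.samples_uA, "uA"
        meta = {
            "kind": "current", "unit": unit, "dt_ns": pulse.dt_ns,
            "energy_kev": pulse.energy_kev, "metadata": _jsonable(pulse.metadata),
        }
    elif isinstance(pulse, VoltagePulse):
        values, unit = pulse.samples_mV, "mV"
        meta = {
            "kind": "voltage", "unit": unit, "dt_ns": pulse.dt_ns,
            "energy_kev": pulse.source_energy_kev,
        }
    else:
        raise TypeError(f"unsupported waveform type {type(pulse).__name__}")
    pd.DataFrame({"time_ns": pulse.times_ns, "value": values}).to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_waveform_csv(path) -> "CurrentPulse | VoltagePulse":
    """Read a waveform CSV written by :func:`write_waveform_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = df["value"].to_numpy(dtype=float)
    if meta["kind"] == "current":
        return CurrentPulse(
            values, dt_ns=meta["dt_ns"], energy_kev=meta["energy_kev"],
            metadata=meta.get("metadata", {}),
        )
    return VoltagePulse(values, dt_ns=meta["dt_ns"], source_energy_kev=meta["energy_kev"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
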