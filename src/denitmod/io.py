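"""Delimited-text I/O for measurements, trajectories and parameter configs.

Measurement files are comma-separated with a header row and the columns
``time_h, species, value, unit`` (long format, one observation per row).
Gas observations may be given in ``M`` (gas-phase molar) or ``%`` (v/v,
converted with the experiment's temperature and pressure); liquid species
in ``M`` or ``uM``.  The writer emits the same dialect, so write/read is a
round trip.

Parameter configs are a single YAML file with sections mirroring the model
parameter blocks (``microbial_conversions``, ``enzyme_synthesis``,
``physical``, ``experiment``); values are given in each parameter's
tabulated unit (micromolar for affinity constants) and converted to the
internal molar unit system at load.  Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .estimation import GAS_SPECIES, MeasurementSet
from .kinetics import EnzymeSynthesisParams, KineticParams, PhysicalParams
from .reactor import ExperimentConfig, Trajectory

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_trajectory",
    "read_params",
    "write_params",
]

_REQUIRED_COLUMNS = ("time_h", "species", "value", "unit")
_KNOWN_SPECIES = set(GAS_SPECIES) | {"NO2_liquid", "NO3_liquid", "E_NIR", "E_NOR", "E_NAP"}

#: Parameters stored in micromolar in config files (internal unit is M).
_UM_FIELDS_KIN = {
    "K_O2", "K_I_NO_O2", "K_NO3", "K_I_O2_NAP", "K_NO2", "K_I_O2_NIR",
    "K_NO", "K_I_O2_NOR", "K_I_NO",
}
_UM_FIELDS_SYN = {"K_NO3_NAP", "K_I_O2_NAP", "K_NO2_NIR", "K_NO_NOR", "K_O2_NOR"}


def read_timeseries(
    path: str | Path, config: Optional[ExperimentConfig] = None
) -> MeasurementSet:
    """Parse a measurement file into a unit-normalized MeasurementSet.

    Percentage gas values convert to M via the ideal gas law at the config
    temperature and pressure (defaults if no config is given).  Errors name
    the offending column or file line.
    """
    path = Path(path)
    config = config or ExperimentConfig()
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")

    series: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    units: Dict[str, str] = {}
    for sp, grp in df.groupby("species", sort=False):
        if sp not in _KNOWN_SPECIES:
            line = int(grp.index[0]) + 2  # header is line 1
            raise ValueError(f"{path}, line {line}: unknown species {sp!r}")
        t = grp["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            bad = int(grp.index[np.flatnonzero(np.diff(t) < 0)[0] + 1]) + 2
            raise ValueError(f"{path}, line {bad}: non-monotone time for {sp!r}")
        unit_vals = grp["unit"].unique()
        if len(unit_vals) != 1:
            raise ValueError(f"{path}: mixed units for species {sp!r}")
        unit = str(unit_vals[0])
        v = grp["value"].to_numpy(dtype=float)
        if unit == "M" or unit == "dimensionless":
            pass
        elif unit == "uM":
            v = v * 1e-6
        elif unit == "%":
            if sp not in GAS_SPECIES:
                raise ValueError(f"{path}: '%' unit only valid for gas species, not {sp!r}")
            v = np.array([config.pct_to_molar(x) for x in v])
        else:
            line = int(grp.index[0]) + 2
            raise ValueError(f"{path}, line {line}: unknown unit {unit!r}")
        series[sp] = (t, v)
        units[sp] = unit
    return MeasurementSet(series=series, units=units, provenance=str(path))


def write_timeseries(obs: MeasurementSet, path: str | Path) -> None:
    """Write a MeasurementSet in the long CSV dialect (values in M)."""
    rows = []
    for sp, (t, v) in obs.series.items():
        unit = "dimensionless" if sp.startswith("E_") else "M"
        for ti, vi in zip(t, v):
            rows.append({"time_h": ti, "species": sp, "value": vi, "unit": unit})
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(path, index=False)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Export a trajectory as CSV plus a sidecar column dictionary."""
    path = Path(path)
    frame = traj.to_frame()
    frame.to_csv(path, index=False)
    meta = path.with_suffix(path.suffix + ".meta.txt")
    lines = [
        "column dictionary",
        "time_h: simulation time, h",
        "C_*: liquid concentration, M (biomass C_X in C-mol/L)",
        "c_*: headspace concentration, M of gas phase",
        "E_*: dimensionless enzyme saturation in [0,1]",
        "c_*_pct: headspace concentration, % v/v",
        "C_*_uM: liquid concentration, uM",
        "succinate_*: cumulative succinate consumed by pathway, mol/L liquid",
        f"diagnostics: {traj.diagnostics}",
    ]
    meta.write_text("\n".join(lines) + "\n")


def _load_block(section: Dict, cls, um_fields: set, label: str):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown keys in {label!r}: {sorted(unknown)}")
    kwargs = {}
    for key, val in section.items():
        kwargs[key] = val * 1e-6 if key in um_fields else val
    return cls(**kwargs)


def read_params(path: str | Path):
    """Load (KineticParams, EnzymeSynthesisParams, PhysicalParams,
    ExperimentConfig) from a YAML config; absent sections use defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known_sections = {
        "microbial_conversions", "enzyme_synthesis", "physical", "experiment",
    }
    unknown = set(raw) - known_sections
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kin = _load_block(raw.get("microbial_conversions", {}), KineticParams,
                      _UM_FIELDS_KIN, "microbial_conversions")
    syn = _load_block(raw.get("enzyme_synthesis", {}), EnzymeSynthesisParams,
                      _UM_FIELDS_SYN, "enzyme_synthesis")
    phys = _load_block(raw.get("physical", {}), PhysicalParams, set(), "physical")
    exp_raw = dict(raw.get("experiment", {}))
    for key in ("nitrite_mM", "nitrate_mM"):
        if key in exp_raw:
            exp_raw[key.replace("_mM", "_M")] = exp_raw.pop(key) * 1e-3
    exp = _load_block(exp_raw, ExperimentConfig, set(), "experiment")
    return kin, syn, phys, exp


def write_params(
    path: str | Path,
    kin: KineticParams,
    syn: EnzymeSynthesisParams,
    phys: PhysicalParams,
    exp: ExperimentConfig,
) -> None:
    """Serialize parameter blocks back to the YAML dialect (uM where tabulated)."""
    def block(obj, um_fields):
        out = {}
        for f in dc_fields(type(obj)):
            v = getattr(obj, f.name)
            out[f.name] = v * 1e6 if f.name in um_fields else v
        return out

    doc = {
        "microbial_conversions": block(kin, _UM_FIELDS_KIN),
        "enzyme_synthesis": block(syn, _UM_FIELDS_SYN),
        "physical": block(phys, set()),
        "experiment": block(exp, set()),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
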