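"""Synthetic flask experiments: scenario presets and noisy measurement sets.

The experimental design being emulated is a 2 x 2 x 3 factorial of sealed
120-ml serum flasks (50 ml culture / 70 ml headspace): initial headspace
oxygen of 1% or 7%, nitrite or nitrate as the N-oxide, at 0.2, 1 or 2 mM.
The reference condition is 1% O2 with 1 mM nitrite.  Headspace O2, NO, N2O
and CO2 are sampled on a fixed grid (default every 0.5 h over 50 h) and
corrupted with configurable noise — by default proportional Gaussian with
standard deviation 5% of the per-species mean, truncated at zero, which
visually resembles the scatter of published flask data without claiming an
instrument error model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .estimation import GAS_SPECIES, MeasurementSet
from .kinetics import EnzymeSynthesisParams, KineticParams, PhysicalParams
from .reactor import ExperimentConfig, Trajectory, simulate

__all__ = ["NoiseModel", "scenario", "scenario_names", "generate_measurements",
            "REFERENCE_SCENARIO"]

REFERENCE_SCENARIO = "nitrite_1mM_o2_1pct"


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description.

    ``scheme`` is ``"proportional-gaussian"`` (sigma is a fraction of the
    per-species mean signal) or ``"additive-gaussian"`` (sigma is an
    absolute concentration in M, applied to every species).  Draws are
    truncated at zero.
    """

    scheme: str = "proportional-gaussian"
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("proportional-gaussian", "additive-gaussian"):
            raise ValueError(f"unknown noise scheme {self.scheme!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return values.copy()
        if self.scheme == "proportional-gaussian":
            sd = self.sigma * float(values.mean())
        else:
            sd = self.sigma
        return np.clip(values + rng.normal(0.0, sd, size=values.shape), 0.0, None)


def _build_library() -> Dict[str, ExperimentConfig]:
    lib: Dict[str, ExperimentConfig] = {}
    for species in ("nitrite", "nitrate"):
        for mM in (0.2, 1.0, 2.0):
            for o2 in (1.0, 7.0):
                mm_label = f"{mM:g}".replace(".", "p")
                name = f"{species}_{mm_label}mM_o2_{o2:g}pct"
                lib[name] = ExperimentConfig(
                    o2_pct=o2,
                    nitrite_M=mM * 1e-3 if species == "nitrite" else 0.0,
                    nitrate_M=mM * 1e-3 if species == "nitrate" else 0.0,
                    name=name,
                )
    return lib


_LIBRARY = _build_library()


def scenario_names() -> Sequence[str]:
    """Names of the twelve factorial flask presets."""
    return tuple(_LIBRARY)


def scenario(name: str) -> ExperimentConfig:
    """Look up one of the factorial presets by name.

    Raises ``KeyError`` listing the available presets for unknown names.
    """
    try:
        return _LIBRARY[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(_LIBRARY)}"
        ) from None


def generate_measurements(
    config: ExperimentConfig,
    kin: Optional[KineticParams] = None,
    syn: Optional[EnzymeSynthesisParams] = None,
    phys: Optional[PhysicalParams] = None,
    sample_times: Optional[np.ndarray] = None,
    noise: Optional[NoiseModel] = None,
    include_liquid_nitrite: bool = False,
    include_enzymes: bool = False,
    trajectory: Optional[Trajectory] = None,
) -> MeasurementSet:
    """Simulate a flask and sample noise-corrupted headspace observations.

    ``sample_times`` defaults to the trajectory output grid and must lie
    within the simulation horizon.  Passing a precomputed ``trajectory``
    skips re-simulation (it must match ``config``).  Optional channels add
    liquid nitrite and the enzyme saturations (an mRNA-level proxy, since
    synthesis rate is modeled as proportional to transcript level).
    """
    noise = noise or NoiseModel()
    traj = trajectory if trajectory is not None else simulate(
        config, kin, syn, phys
    )
    if sample_times is None:
        sample_times = traj.time
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.size == 0:
        raise ValueError("no sample times given")
    if sample_times.min() < traj.time[0] - 1e-9 or sample_times.max() > traj.time[-1] + 1e-9:
        raise ValueError("sample times outside the simulation horizon")

    rng = np.random.default_rng(noise.seed)
    series: Dict[str, tuple] = {}
    units: Dict[str, str] = {}
    for sp in GAS_SPECIES:
        clean = np.interp(sample_times, traj.time, traj.headspace(sp, unit="M"))
        series[sp] = (sample_times.copy(), noise.apply(clean, rng))
        units[sp] = "M"
    if include_liquid_nitrite:
        clean = np.interp(sample_times, traj.time, traj.states["C_NO2"].to_numpy())
        series["NO2_liquid"] = (sample_times.copy(), noise.apply(clean, rng))
        units["NO2_liquid"] = "M"
    if include_enzymes:
        for col in ("E_NIR", "E_NOR"):
            clean = np.interp(sample_times, traj.time, traj.states[col].to_numpy())
            series[col] = (sample_times.copy(), noise.apply(clean, rng))
            units[col] = "dimensionless"

    provenance = (
        f"synthetic scenario={config.name or 'custom'} "
        f"noise={noise.scheme} sigma={noise.sigma} seed={noise.seed}"
    )
    return MeasurementSet(series=series, units=units, provenance=provenance)
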