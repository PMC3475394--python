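"""One-at-a-time local sensitivity of the normalized SSE to the parameters.

Each parameter is scaled by (1 - delta) and (1 + delta) — default ±10%, in
its own units, one parameter at a time — the flask is re-simulated, and the
percent change of the mean-normalized SSE relative to the baseline fit is
reported per headspace species and in total:

    change(%) = 100 (SSE_perturbed - SSE_fit) / SSE_fit

Large entries mark identifiable parameters (the data constrain them);
near-zero entries mark parameters the experiment carries no information
about.  Entries are signed: a perturbation can improve a per-species SSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .estimation import MeasurementSet, apply_parameters, parameter_value, sse_normalized
from .kinetics import EnzymeSynthesisParams, KineticParams, PhysicalParams
from .reactor import ExperimentConfig, simulate

__all__ = ["SensitivityTable", "sensitivity_table", "DEFAULT_PARAMETERS"]

#: Parameters screened by default: the microbial-conversion and
#: enzyme-synthesis constants active in nitrite-fed reference flasks.
DEFAULT_PARAMETERS = (
    "q_m", "K_O2", "K_I_NO_O2",
    "K_NO2", "K_I_O2_NIR", "n_NIR",
    "K_NO", "K_I_O2_NOR", "K_I_NO",
    "v_m_NIR", "v_m_NOR", "K_NO2_NIR", "K_NO_NOR",
)

_COLUMNS = ["total", "O2", "NO", "N2O", "CO2"]


@dataclass
class SensitivityTable:
    """Signed percent SSE changes, parameters x (species, ±delta)."""

    delta: float
    baseline_sse: float
    table: pd.DataFrame  # MultiIndex columns (species, sign)
    failed: List[str] = field(default_factory=list)

    def total_change(self, sign: str = "-") -> pd.Series:
        return self.table[("total", sign)]

    def ranking(self) -> pd.Series:
        """Parameters ordered by max |total change| over both signs."""
        mag = self.table["total"].abs().max(axis=1)
        return mag.sort_values(ascending=False)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.columns = [f"{sp}_{sign}10pct" for sp, sign in out.columns]
        return out


def sensitivity_table(
    obs: MeasurementSet,
    config: ExperimentConfig,
    names: Sequence[str] = DEFAULT_PARAMETERS,
    delta: float = 0.10,
    kin: Optional[KineticParams] = None,
    syn: Optional[EnzymeSynthesisParams] = None,
    phys: Optional[PhysicalParams] = None,
) -> SensitivityTable:
    """Build the ±delta one-at-a-time sensitivity table.

    The baseline simulation is run once and reused for every row.  A
    perturbed simulation that fails flags its entries as missing (NaN) and
    the run continues.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    kin = kin or KineticParams()
    syn = syn or EnzymeSynthesisParams()
    phys = phys or PhysicalParams()

    base_traj = simulate(config, kin, syn, phys)
    base_per, base_total = sse_normalized(base_traj, obs)
    if base_total <= 0:
        raise ValueError("baseline SSE must be positive for normalized changes")
    base = {"total": base_total, **base_per}

    signs = {"-": 1.0 - delta, "+": 1.0 + delta}
    columns = pd.MultiIndex.from_product([_COLUMNS, signs.keys()])
    table = pd.DataFrame(index=list(names), columns=columns, dtype=float)
    failed: List[str] = []

    for name in names:
        value = parameter_value(name, kin, syn, phys)
        for sign, factor in signs.items():
            k, s, p = apply_parameters({name: value * factor}, kin, syn, phys)
            try:
                traj = simulate(config, k, s, p)
                per, total = sse_normalized(traj, obs)
            except (RuntimeError, FloatingPointError, ValueError):
                failed.append(f"{name}{sign}")
                for sp in _COLUMNS:
                    table.loc[name, (sp, sign)] = np.nan
                continue
            entry = {"total": total, **per}
            for sp in _COLUMNS:
                b = base[sp]
                table.loc[name, (sp, sign)] = (
                    100.0 * (entry[sp] - b) / b if b > 0 else 0.0
                )

    return SensitivityTable(
        delta=delta, baseline_sse=base_total, table=table, failed=failed
    )
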