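"""Closed-flask batch mass balances and their integration.

The experimental system is a sealed 120-ml serum flask: 50 ml liquid
culture under 70 ml headspace.  Dissolved O2, NO, N2O and CO2 exchange with
the headspace at rate r_tr,i = k_L a (c_i/H_i - C_i); the headspace sees
only that exchange (dc_i/dt = -r_tr,i V_L/V_G).  The liquid balances sum
the four succinate-oxidation pathways weighted by their stoichiometric
coefficients, the carbonate interconversion, and gas transfer.  The three
enzyme-saturation ODEs ride along.  Succinate itself is in excess and not a
state, but its cumulative consumption per pathway is integrated for carbon
audits.

Carbonate handling: the hydration rate constant only enforces equilibrium,
so the default ``carbonate="algebraic"`` mode replaces the stiff CO2/HCO3-
pair by its fast-equilibrium reduction (the pair moves in the fixed ratio
K_a/C_H set by the buffered pH).  ``carbonate="kinetic"`` integrates the
literal rate law and exists as a cross-validation mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import (
    EnzymeSynthesisParams,
    KineticParams,
    PhysicalParams,
    SystemState,
    carbonate_rate,
    enzyme_synthesis_rates,
    pathway_rates,
    transfer_rates,
)

__all__ = [
    "GAS_CONSTANT",
    "ReactionCoefficients",
    "ExperimentConfig",
    "Trajectory",
    "equilibrate_initial",
    "derivatives",
    "simulate",
]

#: Ideal gas constant, L atm mol^-1 K^-1.
GAS_CONSTANT = 0.082057366


@dataclass(frozen=True)
class ReactionCoefficients:
    """Stoichiometric coefficients wiring the four pathways into the balances.

    The canonical values are the two-decimal coefficients of the closed
    reaction equations (yield 2.2 aerobic / 1.8 anoxic; 1.2 O2, 3.23 NO3-,
    6.45 NO2-, 6.45 NO).  The N2O coefficient is tied to half the NO
    coefficient rather than rounded independently, so that N-oxide nitrogen
    is conserved exactly; rounding it separately to 3.23 would fabricate
    0.15% nitrogen over a complete nitrite-to-N2O conversion.
    """

    o2: float = 1.2        # mol O2 per mol succinate, aerobic
    no3: float = 3.23      # mol NO3- per mol succinate, nap
    no2: float = 6.45      # mol NO2- per mol succinate, nir
    no: float = 6.45       # mol NO per mol succinate, nor
    y_aerobic: float = 2.2  # C-mol biomass per mol succinate
    y_anoxic: float = 1.8

    @property
    def n2o(self) -> float:
        """mol N2O produced per mol succinate by NorB (2 NO -> 1 N2O)."""
        return self.no / 2.0

    @property
    def co2_aerobic(self) -> float:
        return 4.0 - self.y_aerobic

    @property
    def co2_anoxic(self) -> float:
        return 4.0 - self.y_anoxic

    @classmethod
    def from_derivation(cls) -> "ReactionCoefficients":
        """Unrounded coefficients from the bioenergetic derivation."""
        from .stoichiometry import BioenergeticParams, biomass_yield, derive_all

        p = BioenergeticParams()
        st = derive_all(p)
        return cls(
            o2=-st["aerobic"].coefficients["O2"],
            no3=-st["nap"].coefficients["NO3-"],
            no2=-st["nir"].coefficients["NO2-"],
            no=-st["nor"].coefficients["NO"],
            y_aerobic=biomass_yield("aerobic", p),
            y_anoxic=biomass_yield("anoxic", p),
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """Flask geometry, initial conditions and integration horizon."""

    V_L: float = 0.05            # L liquid
    V_G: float = 0.07            # L headspace
    o2_pct: float = 1.0          # initial headspace O2, % v/v
    co2_pct: float = 0.0
    no_pct: float = 0.0
    n2o_pct: float = 0.0
    nitrate_M: float = 0.0
    nitrite_M: float = 1e-3
    biomass_CmolL: float = 0.25e-3
    E_NAP0: float = 0.0
    E_NIR0: float = 0.0
    E_NOR0: float = 0.0
    pressure_atm: float = 1.0
    temperature_K: float = 293.15
    t_end: float = 50.0          # h
    dt_out: float = 0.5          # h, output grid spacing
    name: str = ""

    def __post_init__(self) -> None:
        if self.V_L <= 0 or self.V_G <= 0:
            raise ValueError("flask volumes must be positive")
        for f in ("o2_pct", "co2_pct", "no_pct", "n2o_pct"):
            if not 0.0 <= getattr(self, f) <= 100.0:
                raise ValueError(f"{f} must be a percentage in [0, 100]")
        if self.t_end <= 0:
            raise ValueError("simulation horizon must be positive")
        if self.temperature_K <= 0 or self.pressure_atm <= 0:
            raise ValueError("temperature and pressure must be positive")

    @property
    def gas_molar_density(self) -> float:
        """Total mol/L of ideal gas in the headspace."""
        return self.pressure_atm / (GAS_CONSTANT * self.temperature_K)

    def pct_to_molar(self, pct: float) -> float:
        """Headspace volume-% -> gas-phase molar concentration (M)."""
        return pct / 100.0 * self.gas_molar_density

    def output_grid(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + 0.5 * self.dt_out, self.dt_out)


@dataclass
class Trajectory:
    """Time-resolved solution of one flask simulation."""

    time: np.ndarray                 # h
    states: pd.DataFrame             # one row per time, columns = state names
    succinate: pd.DataFrame          # cumulative mol/L consumed per pathway
    config: ExperimentConfig
    diagnostics: Dict[str, object] = field(default_factory=dict)

    _GAS = ("c_O2", "c_NO", "c_N2O", "c_CO2")

    def state_at(self, index: int) -> SystemState:
        row = self.states.iloc[index]
        return SystemState(**{k: float(row[k]) for k in STATE_ORDER})

    def headspace(self, species: str, unit: str = "M") -> np.ndarray:
        """Headspace series for one of O2, NO, N2O, CO2 in M or %."""
        col = f"c_{species}"
        if col not in self._GAS:
            raise KeyError(f"unknown headspace species {species!r}")
        vals = self.states[col].to_numpy()
        if unit == "M":
            return vals
        if unit == "%":
            return vals / self.config.gas_molar_density * 100.0
        raise ValueError("unit must be 'M' or '%'")

    def n_oxide_total(self) -> np.ndarray:
        """Total N-oxide nitrogen (mol) in liquid plus gas at each time."""
        s, c = self.states, self.config
        liquid = s.C_NO3 + s.C_NO2 + s.C_NO + 2.0 * s.C_N2O
        gas = s.c_NO + 2.0 * s.c_N2O
        return (c.V_L * liquid + c.V_G * gas).to_numpy()

    def carbon_closure_error(self) -> float:
        """Relative error of the carbon balance over the whole run.

        4 x (succinate consumed) should equal biomass-C formed plus
        inorganic carbon accumulated (liquid CO2 + HCO3- and headspace CO2).
        """
        c = self.config
        consumed = float(self.succinate.iloc[-1].sum())
        if consumed <= 0:
            return 0.0
        s0, s1 = self.states.iloc[0], self.states.iloc[-1]
        d = s1 - s0
        carbon = (
            d.C_X + d.C_CO2 + d.C_HCO3 + d.c_CO2 * c.V_G / c.V_L
        )
        return abs(carbon - 4.0 * consumed) / (4.0 * consumed)

    def to_frame(self) -> pd.DataFrame:
        """Flat export table with both molar and presentation units."""
        c = self.config
        out = self.states.copy()
        out.insert(0, "time_h", self.time)
        for sp in ("O2", "NO", "N2O", "CO2"):
            out[f"c_{sp}_pct"] = out[f"c_{sp}"] / c.gas_molar_density * 100.0
        for sp in ("O2", "NO3", "NO2", "NO", "N2O"):
            out[f"C_{sp}_uM"] = out[f"C_{sp}"] * 1e6
        for pw in self.succinate.columns:
            out[f"succinate_{pw}"] = self.succinate[pw].to_numpy()
        return out


#: Order of the integrated state vector.
STATE_ORDER = (
    "C_O2", "C_NO3", "C_NO2", "C_NO", "C_N2O", "C_CO2", "C_HCO3", "C_X",
    "c_O2", "c_NO", "c_N2O", "c_CO2", "E_NAP", "E_NIR", "E_NOR",
)
_N_STATE = len(STATE_ORDER)
_PATHWAYS = ("aerobic", "nap", "nir", "nor")


def equilibrate_initial(
    config: ExperimentConfig, phys: Optional[PhysicalParams] = None
) -> SystemState:
    """Initial state with liquid gas species at Henry equilibrium.

    Headspace percentages convert to molar via the ideal gas law; the
    dissolved concentration of each gas species is c_i/H_i; dissolved
    CO2 additionally equilibrates with bicarbonate at the buffered pH.
    """
    phys = phys or PhysicalParams()
    c_O2 = config.pct_to_molar(config.o2_pct)
    c_NO = config.pct_to_molar(config.no_pct)
    c_N2O = config.pct_to_molar(config.n2o_pct)
    c_CO2 = config.pct_to_molar(config.co2_pct)
    C_CO2 = c_CO2 / phys.H_CO2
    return SystemState(
        C_O2=c_O2 / phys.H_O2,
        C_NO3=config.nitrate_M,
        C_NO2=config.nitrite_M,
        C_NO=c_NO / phys.H_NO,
        C_N2O=c_N2O / phys.H_N2O,
        C_CO2=C_CO2,
        C_HCO3=C_CO2 * phys.bicarbonate_ratio,
        C_X=config.biomass_CmolL,
        c_O2=c_O2,
        c_NO=c_NO,
        c_N2O=c_N2O,
        c_CO2=c_CO2,
        E_NAP=config.E_NAP0,
        E_NIR=config.E_NIR0,
        E_NOR=config.E_NOR0,
    )


def _state_from_vector(y: np.ndarray) -> SystemState:
    s = SystemState()
    for name, val in zip(STATE_ORDER, y):
        setattr(s, name, float(val))
    # clip tiny negatives and E_sat overshoot from solver round-off
    for name in STATE_ORDER[:12]:
        v = getattr(s, name)
        if v < 0:
            setattr(s, name, 0.0)
    for name in ("E_NAP", "E_NIR", "E_NOR"):
        setattr(s, name, min(max(getattr(s, name), 0.0), 1.0))
    return s


def derivatives(
    t: float,
    y: np.ndarray,
    kin: KineticParams,
    syn: EnzymeSynthesisParams,
    phys: PhysicalParams,
    config: ExperimentConfig,
    coefs: ReactionCoefficients,
    carbonate: str = "algebraic",
) -> np.ndarray:
    """Right-hand side of the flask ODE system.

    The state vector is ``STATE_ORDER`` followed by four cumulative
    succinate-consumption integrals (one per pathway).
    """
    state = _state_from_vector(y[:_N_STATE])
    r = pathway_rates(state, kin)
    de = enzyme_synthesis_rates(state, syn)
    tr = transfer_rates(state, phys)

    d = np.zeros_like(y)
    s = coefs
    d[0] = -s.o2 * r["aerobic"] + tr["O2"]                          # C_O2
    d[1] = -s.no3 * r["nap"]                                        # C_NO3
    d[2] = s.no3 * r["nap"] - s.no2 * r["nir"]                      # C_NO2
    d[3] = s.no2 * r["nir"] - s.no * r["nor"] + tr["NO"]            # C_NO
    d[4] = s.n2o * r["nor"] + tr["N2O"]                             # C_N2O

    co2_prod = s.co2_aerobic * r["aerobic"] + s.co2_anoxic * (
        r["nap"] + r["nir"] + r["nor"]
    )
    if carbonate == "kinetic":
        r_car = carbonate_rate(state, phys)
        d[5] = co2_prod - r_car + tr["CO2"]                         # C_CO2
        d[6] = r_car                                                # C_HCO3
    elif carbonate == "algebraic":
        # fast-equilibrium reduction: the pair moves at the fixed ratio
        ratio = phys.bicarbonate_ratio
        d_total = co2_prod + tr["CO2"]
        d[5] = d_total / (1.0 + ratio)
        d[6] = d_total * ratio / (1.0 + ratio)
    else:
        raise ValueError("carbonate mode must be 'algebraic' or 'kinetic'")

    d[7] = s.y_aerobic * r["aerobic"] + s.y_anoxic * (
        r["nap"] + r["nir"] + r["nor"]
    )                                                               # C_X

    vr = config.V_L / config.V_G
    d[8] = -tr["O2"] * vr
    d[9] = -tr["NO"] * vr
    d[10] = -tr["N2O"] * vr
    d[11] = -tr["CO2"] * vr

    d[12] = de["nap"]
    d[13] = de["nir"]
    d[14] = de["nor"]

    for i, pw in enumerate(_PATHWAYS):
        d[_N_STATE + i] = r[pw]

    if not np.all(np.isfinite(d)):
        bad = [STATE_ORDER[i] if i < _N_STATE else f"succinate_{_PATHWAYS[i - _N_STATE]}"
               for i in np.flatnonzero(~np.isfinite(d))]
        raise FloatingPointError(f"non-finite derivative for {bad} at t={t}")
    return d


def simulate(
    config: ExperimentConfig,
    kin: Optional[KineticParams] = None,
    syn: Optional[EnzymeSynthesisParams] = None,
    phys: Optional[PhysicalParams] = None,
    coefs: Optional[ReactionCoefficients] = None,
    carbonate: str = "algebraic",
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate one flask experiment from equilibrated initial conditions.

    Raises ``RuntimeError`` carrying the solver message (and the last good
    state in ``exc.args``) if integration fails.
    """
    kin = kin or KineticParams()
    syn = syn or EnzymeSynthesisParams()
    phys = phys or PhysicalParams()
    coefs = coefs or ReactionCoefficients()

    state0 = equilibrate_initial(config, phys)
    y0 = np.zeros(_N_STATE + len(_PATHWAYS))
    for i, name in enumerate(STATE_ORDER):
        y0[i] = getattr(state0, name)

    t_eval = config.output_grid()
    if carbonate == "kinetic" and phys.k_car > 1e10 and method == "LSODA":
        method = "BDF"  # extreme stiffness ratio; BDF copes better here

    sol = solve_ivp(
        derivatives,
        (0.0, config.t_end),
        y0,
        t_eval=t_eval,
        args=(kin, syn, phys, config, coefs, carbonate),
        method=method,
        rtol=rtol,
        atol=atol,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed: {sol.message}", sol.t[-1] if sol.t.size else 0.0,
            sol.y[:, -1] if sol.y.size else y0,
        )

    states = pd.DataFrame(sol.y[:_N_STATE].T, columns=list(STATE_ORDER))
    # present clipped values: round-off negatives are not physical
    num = states.columns[:12]
    states[num] = states[num].clip(lower=0.0)
    succ = pd.DataFrame(sol.y[_N_STATE:].T, columns=list(_PATHWAYS))
    return Trajectory(
        time=sol.t,
        states=states,
        succinate=succ,
        config=config,
        diagnostics={
            "method": method,
            "carbonate": carbonate,
            "rtol": rtol,
            "atol": atol,
            "nfev": int(sol.nfev),
            "njev": int(getattr(sol, "njev", 0) or 0),
            "status": int(sol.status),
        },
    )
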