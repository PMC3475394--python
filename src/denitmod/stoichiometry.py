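"""Growth stoichiometry of succinate oxidation from bioenergetic first principles.

*Agrobacterium tumefaciens* oxidizes succinate with one of four terminal
electron acceptors: O2 (aerobic respiration) or, during denitrification,
nitrate (Nap), nitrite (NirK) and nitric oxide (NorB).  N2O is the terminal
product because the organism lacks N2O reductase.  For each pathway this
module derives the full molar reaction stoichiometry (per mol succinate)
from

* an electron balance built on degrees of reduction (succinate dianion
  gamma = 14, biomass CH1.8O0.5N0.2 with ammonium-N gamma = 4.2 per C-mol),
* a chemiosmotic ATP bookkeeping: electron pairs translocate protons at
  cofactor-specific ratios (aerobic 10 H+/NADH and 8 H+/FADH2; anoxic 6 and
  4), ATP synthesis costs ``h_per_atp`` protons, and growth yields
  ``y_atp`` grams dry weight per mol ATP,
* element (C, H, O, N) and charge balances that close the equation.

The resulting aerobic yield is 2.2 C-mol biomass per mol succinate and the
anoxic (denitrifying) yield 1.8, with acceptor coefficients 1.2 O2,
3.23 NO3-, 6.47 NO2- and 6.47 NO (printed to two decimals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

import pandas as pd

__all__ = [
    "ATOMIC_WEIGHTS",
    "BioenergeticParams",
    "Compound",
    "PathwayStoichiometry",
    "biomass_molar_mass",
    "biomass_yield",
    "close_stoichiometry",
    "degree_of_reduction",
    "derive_all",
    "stoichiometry_table",
]

#: IUPAC 2021 standard atomic weights, truncated to the elements used here.
ATOMIC_WEIGHTS: Dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
}

#: Electrons transferred to the acceptor, per mole of acceptor.
#: O2 -> 2 H2O: 4; NO3- -> NO2-: 2; NO2- -> NO: 1; NO -> 1/2 N2O: 1.
ACCEPTOR_ELECTRONS: Dict[str, float] = {
    "aerobic": 4.0,
    "nap": 2.0,
    "nir": 1.0,
    "nor": 1.0,
}

PATHWAYS = ("aerobic", "nap", "nir", "nor")

#: Default biomass elemental composition per C-mol.
BIOMASS_FORMULA: Dict[str, float] = {"C": 1.0, "H": 1.8, "O": 0.5, "N": 0.2}


def biomass_molar_mass(formula: Mapping[str, float]) -> float:
    """Molar mass (g per C-mol) of a biomass elemental formula.

    Parameters
    ----------
    formula
        Map element symbol -> subscript.  Subscripts may be fractional
        (C-mol convention, carbon subscript 1).

    Raises
    ------
    ValueError
        If a subscript is negative, the carbon subscript is not 1, or an
        element is unknown.
    """
    if any(v < 0 for v in formula.values()):
        raise ValueError("negative subscript in biomass formula")
    unknown = set(formula) - set(ATOMIC_WEIGHTS)
    if unknown:
        raise ValueError(f"unknown elements in biomass formula: {sorted(unknown)}")
    if abs(formula.get("C", 0.0) - 1.0) > 1e-12:
        raise ValueError("biomass formula must be on a C-mol basis (C subscript 1)")
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in formula.items())


def degree_of_reduction(composition: Mapping[str, float], charge: float = 0.0) -> float:
    """Electrons available per mole relative to CO2/H2O/NH4+ reference states.

    gamma = 4 C + H - 2 O - 3 N - charge.  Nitrogen is counted at the
    ammonium reference (-3), the convention used when biomass N derives
    from NH4+.  An anion's extra electrons add to gamma (hence ``- charge``):
    succinate C4H4O4^2- gives 14, biomass CH1.8O0.5N0.2 gives 4.2.
    """
    return (
        4.0 * composition.get("C", 0.0)
        + composition.get("H", 0.0)
        - 2.0 * composition.get("O", 0.0)
        - 3.0 * composition.get("N", 0.0)
        - charge
    )


@dataclass(frozen=True)
class Compound:
    """A chemical species with elemental composition and charge."""

    name: str
    composition: Mapping[str, float]
    charge: float = 0.0

    @property
    def gamma(self) -> float:
        """Degree of reduction (electrons per mole)."""
        return degree_of_reduction(self.composition, self.charge)


SUCCINATE = Compound("succinate", {"C": 4, "H": 4, "O": 4}, charge=-2.0)
BIOMASS = Compound("biomass", BIOMASS_FORMULA, charge=0.0)

#: Acceptor/product pair per pathway.
_ACCEPTORS: Dict[str, Compound] = {
    "aerobic": Compound("O2", {"O": 2}),
    "nap": Compound("NO3-", {"N": 1, "O": 3}, charge=-1.0),
    "nir": Compound("NO2-", {"N": 1, "O": 2}, charge=-1.0),
    "nor": Compound("NO", {"N": 1, "O": 1}),
}
_PRODUCTS: Dict[str, Compound] = {
    "aerobic": Compound("H2O", {"H": 2, "O": 1}),  # reduced O2 ends up in water
    "nap": Compound("NO2-", {"N": 1, "O": 2}, charge=-1.0),
    "nir": Compound("NO", {"N": 1, "O": 1}),
    "nor": Compound("N2O", {"N": 2, "O": 1}),
}


@dataclass(frozen=True)
class BioenergeticParams:
    """Constants of the chemiosmotic yield calculation.

    ``nadh_fadh2_split`` is the fraction of catabolic electron pairs that
    enter the respiratory chain at the FADH2 level (succinate dehydrogenase);
    the remainder enters at the NADH level.  The default routes all pairs at
    NADH level, which reproduces the canonical yields (2.2 aerobic, 1.8
    anoxic) after rounding; a 1-in-7 FADH2 split also rounds to the same
    values.
    """

    h_per_atp: float = 4.0
    y_atp: float = 9.1  # g dry weight per mol ATP
    h_per_nadh_aerobic: float = 10.0
    h_per_fadh2_aerobic: float = 8.0
    h_per_nadh_anoxic: float = 6.0
    h_per_fadh2_anoxic: float = 4.0
    biomass_formula: Mapping[str, float] = field(
        default_factory=lambda: dict(BIOMASS_FORMULA)
    )
    biomass_mw: float = 24.6  # g dry weight per C-mol
    nadh_fadh2_split: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "h_per_atp",
            "y_atp",
            "h_per_nadh_aerobic",
            "h_per_fadh2_aerobic",
            "h_per_nadh_anoxic",
            "h_per_fadh2_anoxic",
            "biomass_mw",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.h_per_atp == 0:
            raise ValueError("h_per_atp must be strictly positive")
        if not 0.0 <= self.nadh_fadh2_split <= 1.0:
            raise ValueError("nadh_fadh2_split must lie in [0, 1]")
        recomputed = biomass_molar_mass(self.biomass_formula)
        if abs(recomputed - self.biomass_mw) > 0.05:
            raise ValueError(
                f"biomass_mw {self.biomass_mw} inconsistent with formula "
                f"({recomputed:.3f} g/C-mol)"
            )

    def protons_per_pair(self, regime: str) -> float:
        """Average protons translocated per catabolic electron pair."""
        if regime == "aerobic":
            nadh, fadh2 = self.h_per_nadh_aerobic, self.h_per_fadh2_aerobic
        elif regime == "anoxic":
            nadh, fadh2 = self.h_per_nadh_anoxic, self.h_per_fadh2_anoxic
        else:
            raise ValueError(f"unknown regime {regime!r}; use 'aerobic' or 'anoxic'")
        f = self.nadh_fadh2_split
        return (1.0 - f) * nadh + f * fadh2


def biomass_yield(regime: str, params: BioenergeticParams | None = None) -> float:
    """C-mol biomass formed per mol succinate under a respiratory regime.

    Solves the self-consistent linear yield equation: with yield x, the
    catabolic electrons are gamma_succ - gamma_X * x; they flow as pairs that
    each translocate ``protons_per_pair(regime)`` protons; ATP synthesis
    divides by ``h_per_atp``; and growth converts ATP to biomass at
    ``y_atp / biomass_mw`` C-mol per mol ATP:

        x = (gamma_succ - gamma_X x) / 2 * H_pair / h_per_atp * y_atp / mw
    """
    params = params or BioenergeticParams()
    gamma_s = SUCCINATE.gamma
    gamma_x = BIOMASS.gamma
    k = (
        params.protons_per_pair(regime)
        / 2.0
        / params.h_per_atp
        * params.y_atp
        / params.biomass_mw
    )
    return k * gamma_s / (1.0 + k * gamma_x)


@dataclass(frozen=True)
class PathwayStoichiometry:
    """Signed molar coefficients per mol succinate (negative = consumed)."""

    pathway: str
    coefficients: Mapping[str, float]

    def balance_residuals(self) -> Dict[str, float]:
        """Residual of each element and charge balance (should be ~0)."""
        species = _species_registry()
        res = {el: 0.0 for el in ("C", "H", "O", "N")}
        res["charge"] = 0.0
        for name, coef in self.coefficients.items():
            comp = species[name]
            for el in ("C", "H", "O", "N"):
                res[el] += coef * comp.composition.get(el, 0.0)
            res["charge"] += coef * comp.charge
        return res

    def electron_residual(self) -> float:
        """Donor electrons minus biomass plus acceptor electrons."""
        species = _species_registry()
        total = 0.0
        for name, coef in self.coefficients.items():
            total += coef * species[name].gamma
        return total


def _species_registry() -> Dict[str, Compound]:
    reg = {
        "succinate": SUCCINATE,
        "biomass": BIOMASS,
        "O2": _ACCEPTORS["aerobic"],
        "NO3-": _ACCEPTORS["nap"],
        "NO2-": _ACCEPTORS["nir"],
        "NO": _ACCEPTORS["nor"],
        "N2O": _PRODUCTS["nor"],
        "H2O": _PRODUCTS["aerobic"],
        "H+": Compound("H+", {"H": 1}, charge=1.0),
        "NH4+": Compound("NH4+", {"N": 1, "H": 4}, charge=1.0),
        "CO2": Compound("CO2", {"C": 1, "O": 2}),
    }
    return reg


def close_stoichiometry(yield_x: float, pathway: str) -> PathwayStoichiometry:
    """Close the reaction equation of one pathway at a given biomass yield.

    The acceptor coefficient follows from the electron balance, NH4+ from
    the N balance, CO2 from the C balance, H+ from the charge balance and
    H2O from the H balance; the O balance then closes identically.

    Parameters
    ----------
    yield_x
        C-mol biomass per mol succinate, in (0, 4).
    pathway
        One of ``aerobic``, ``nap``, ``nir``, ``nor``.
    """
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}; choose from {PATHWAYS}")
    if not 0.0 < yield_x < 4.0:
        raise ValueError("yield must lie in (0, 4) C-mol per mol succinate")

    acceptor = _ACCEPTORS[pathway]
    product = _PRODUCTS[pathway]

    e_residual = SUCCINATE.gamma - BIOMASS.gamma * yield_x
    if e_residual <= 0:
        raise ValueError("yield leaves no electrons for the acceptor")
    a = e_residual / ACCEPTOR_ELECTRONS[pathway]

    nh4 = BIOMASS_FORMULA["N"] * yield_x  # all biomass N from ammonium
    co2 = 4.0 - yield_x  # succinate has 4 C

    coefs: Dict[str, float] = {
        "succinate": -1.0,
        acceptor.name: -a,
        "NH4+": -nh4,
        "biomass": yield_x,
        "CO2": co2,
    }
    # N-oxide product: aerobic O2 goes to water; nor pairs 2 NO -> 1 N2O.
    if pathway == "nap":
        coefs["NO2-"] = coefs.get("NO2-", 0.0) + a
    elif pathway == "nir":
        coefs["NO"] = coefs.get("NO", 0.0) + a
    elif pathway == "nor":
        coefs["N2O"] = a / 2.0

    registry = _species_registry()

    # charge balance -> H+; net signed charge so far must be cancelled
    charge = sum(c * registry[n].charge for n, c in coefs.items())
    coefs["H+"] = -charge

    # hydrogen balance -> H2O
    hydrogen = sum(
        c * registry[n].composition.get("H", 0.0) for n, c in coefs.items()
    )
    coefs["H2O"] = -hydrogen / 2.0

    st = PathwayStoichiometry(pathway, coefs)
    res = st.balance_residuals()
    for key, val in res.items():
        if abs(val) > 0.02:
            raise AssertionError(f"{key} balance fails to close ({val:+.4f})")
    return st


def derive_all(params: BioenergeticParams | None = None) -> Dict[str, PathwayStoichiometry]:
    """Derive closed stoichiometries for all four pathways."""
    params = params or BioenergeticParams()
    y_aer = biomass_yield("aerobic", params)
    y_anx = biomass_yield("anoxic", params)
    return {
        "aerobic": close_stoichiometry(y_aer, "aerobic"),
        "nap": close_stoichiometry(y_anx, "nap"),
        "nir": close_stoichiometry(y_anx, "nir"),
        "nor": close_stoichiometry(y_anx, "nor"),
    }


def stoichiometry_table(params: BioenergeticParams | None = None) -> pd.DataFrame:
    """Compound x pathway coefficient matrix (mol per mol succinate)."""
    stoichs = derive_all(params)
    order = [
        "succinate", "O2", "NO3-", "NO2-", "NO", "N2O",
        "H+", "NH4+", "biomass", "CO2", "H2O",
    ]
    data = {
        pw: {cpd: st.coefficients.get(cpd, 0.0) for cpd in order}
        for pw, st in stoichs.items()
    }
    return pd.DataFrame(data).loc[order]
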