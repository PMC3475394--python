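"""Rate laws: succinate oxidation, enzyme synthesis, carbonate and gas transfer.

All quantities use a single internal unit system — concentrations in mol/L
(M) for both liquid and gas phase, time in hours — because the species span
nanomolar (NO) to millimolar (nitrate) and mixed units invite bugs.  The
canonical parameter values are tabulated in micromolar where that is the
natural scale; converters on the dataclasses do the scaling once, at load.

Four succinate-consumption rates (mol succinate L^-1 h^-1), all capped by
the same maximum specific succinate oxidation rate q_m and linear in
biomass:

* aerobic respiration: Monod in O2 with competitive NO inhibition of the
  terminal oxidase,
* nitrate reduction (Nap): Monod in NO3- times a steep power-law O2
  inhibition term, scaled by enzyme level E_sat,NAP,
* nitrite reduction (NirK): same structure in NO2-,
* NO reduction (NorB): squared Haldane form — second order in NO because
  two NO condense to one N2O — with substrate inhibition above ~micromolar
  NO and a first-order O2 inhibition term.

Enzyme synthesis is substrate-activated Michaelis-Menten transcription
(lumped with translation) with a (1 - E_sat) ceiling; nap synthesis is
additionally O2-inhibited.  No enzyme decay is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict


__all__ = [
    "KineticParams",
    "EnzymeSynthesisParams",
    "PhysicalParams",
    "SystemState",
    "pathway_rates",
    "enzyme_synthesis_rates",
    "carbonate_rate",
    "transfer_rates",
]

_UM = 1e-6  # micromolar -> molar

#: Concentrations this far below zero are treated as solver round-off.
NEGATIVE_TOL = 1e-15


def _clip(value: float) -> float:
    """Clip solver round-off below zero; reject genuinely negative input."""
    if value < -NEGATIVE_TOL * 1e3:
        raise ValueError(f"negative concentration {value!r}")
    return max(value, 0.0)


@dataclass(frozen=True)
class KineticParams:
    """Microbial conversion parameters (internal units: M, h).

    Defaults are the calibrated values for the reference flask experiment.
    """

    q_m: float = 0.066          # mol succinate (C-mol biomass)^-1 h^-1
    K_O2: float = 8.28 * _UM    # Monod saturation, O2 respiration
    K_I_NO_O2: float = 0.0174 * _UM  # competitive NO inhibition of oxidase
    K_NO3: float = 13000 * _UM
    K_I_O2_NAP: float = 4.0 * _UM
    n_NAP: float = 4.0
    K_NO2: float = 880 * _UM
    K_I_O2_NIR: float = 3.58 * _UM
    n_NIR: float = 3.7
    K_NO: float = 0.0081 * _UM
    K_I_O2_NOR: float = 1.0 * _UM
    K_I_NO: float = 20.0 * _UM  # Haldane substrate inhibition of NorB

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_NAP < 1 or self.n_NIR < 1:
            raise ValueError("inhibition exponents must be >= 1")

    def perturbed(self, name: str, factor: float) -> "KineticParams":
        """Copy with one parameter multiplied by ``factor``."""
        return replace(self, **{name: getattr(self, name) * factor})


@dataclass(frozen=True)
class EnzymeSynthesisParams:
    """Transcription-level regulation parameters (internal units: M, h).

    ``K_O2_NOR`` parameterizes an optional extra O2 factor on NorB
    synthesis used only for nitrate scenarios; it is off by default and its
    functional form is selectable (``o2_nor_mode``: "saturation" gives
    C_O2/(K+C_O2), "inhibition" gives K/(K+C_O2)) because only its constant
    is tabulated, not its shape.
    """

    v_m_NAP: float = 1.0 / 15.0  # h^-1
    v_m_NIR: float = 1.0 / 15.0
    v_m_NOR: float = 1.0
    K_NO3_NAP: float = 0.00001 * _UM  # effectively always saturated; kept as tabulated
    K_I_O2_NAP: float = 1.0 * _UM     # distinct from the conversion-level constant
    K_NO2_NIR: float = 50.0 * _UM
    K_NO_NOR: float = 0.054 * _UM
    K_O2_NOR: float = 400.0 * _UM
    use_o2_nor_term: bool = False
    o2_nor_mode: str = "saturation"

    def __post_init__(self) -> None:
        for name in (
            "v_m_NAP", "v_m_NIR", "v_m_NOR", "K_NO3_NAP",
            "K_I_O2_NAP", "K_NO2_NIR", "K_NO_NOR", "K_O2_NOR",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.o2_nor_mode not in ("saturation", "inhibition"):
            raise ValueError("o2_nor_mode must be 'saturation' or 'inhibition'")

    def perturbed(self, name: str, factor: float) -> "EnzymeSynthesisParams":
        return replace(self, **{name: getattr(self, name) * factor})


@dataclass(frozen=True)
class PhysicalParams:
    """Gas-liquid transfer, carbonate chemistry and the fixed pH."""

    k_L_a: float = 19.8           # h^-1, volumetric mass transfer coefficient
    H_O2: float = 33.0            # dimensionless Henry ratios M_gas/M_aq
    H_NO: float = 21.0
    H_N2O: float = 1.74
    H_CO2: float = 1.2
    k_car: float = 1e14           # h^-1; enforces CO2/HCO3- equilibrium
    K_a_car: float = 10 ** -6.36  # M
    pH: float = 7.5

    def __post_init__(self) -> None:
        for name in ("k_L_a", "H_O2", "H_NO", "H_N2O", "H_CO2", "k_car", "K_a_car"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def C_H(self) -> float:
        """Proton concentration (M) fixed by the buffered pH."""
        return 10.0 ** (-self.pH)

    @property
    def bicarbonate_ratio(self) -> float:
        """Equilibrium C_HCO3/C_CO2 ratio at the fixed pH."""
        return self.K_a_car / self.C_H

    def henry(self, species: str) -> float:
        return {"O2": self.H_O2, "NO": self.H_NO,
                "N2O": self.H_N2O, "CO2": self.H_CO2}[species]

    def perturbed(self, name: str, factor: float) -> "PhysicalParams":
        return replace(self, **{name: getattr(self, name) * factor})


@dataclass
class SystemState:
    """Instantaneous state of one flask (all concentrations in M).

    Liquid: seven chemical species plus biomass; gas: four species;
    enzymes: three dimensionless saturations in [0, 1].
    """

    C_O2: float = 0.0
    C_NO3: float = 0.0
    C_NO2: float = 0.0
    C_NO: float = 0.0
    C_N2O: float = 0.0
    C_CO2: float = 0.0
    C_HCO3: float = 0.0
    C_X: float = 0.0       # C-mol/L
    c_O2: float = 0.0
    c_NO: float = 0.0
    c_N2O: float = 0.0
    c_CO2: float = 0.0
    E_NAP: float = 0.0
    E_NIR: float = 0.0
    E_NOR: float = 0.0

    def validate(self) -> None:
        for name in ("C_O2", "C_NO3", "C_NO2", "C_NO", "C_N2O", "C_CO2",
                     "C_HCO3", "C_X", "c_O2", "c_NO", "c_N2O", "c_CO2"):
            if getattr(self, name) < -NEGATIVE_TOL * 1e3:
                raise ValueError(f"negative concentration {name}")
        for name in ("E_NAP", "E_NIR", "E_NOR"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")


def pathway_rates(state: SystemState, kin: KineticParams) -> Dict[str, float]:
    """Succinate consumption rate of each pathway (mol succinate L^-1 h^-1).

    Returns a dict with keys ``aerobic``, ``nap``, ``nir``, ``nor``.
    """
    C_O2 = _clip(state.C_O2)
    C_NO3 = _clip(state.C_NO3)
    C_NO2 = _clip(state.C_NO2)
    C_NO = _clip(state.C_NO)
    C_X = _clip(state.C_X)
    q = kin.q_m * C_X

    r_o2 = q * C_O2 / (kin.K_O2 * (1.0 + C_NO / kin.K_I_NO_O2) + C_O2)

    inh_nap = kin.K_I_O2_NAP ** kin.n_NAP / (
        kin.K_I_O2_NAP ** kin.n_NAP + C_O2 ** kin.n_NAP
    )
    r_nap = q * state.E_NAP * C_NO3 / (kin.K_NO3 + C_NO3) * inh_nap

    inh_nir = kin.K_I_O2_NIR ** kin.n_NIR / (
        kin.K_I_O2_NIR ** kin.n_NIR + C_O2 ** kin.n_NIR
    )
    r_nir = q * state.E_NIR * C_NO2 / (kin.K_NO2 + C_NO2) * inh_nir

    denom = C_NO * (1.0 + C_NO / kin.K_I_NO) + kin.K_NO
    r_nor = (
        q * state.E_NOR * C_NO ** 2 / denom ** 2
        * kin.K_I_O2_NOR / (kin.K_I_O2_NOR + C_O2)
    )

    return {"aerobic": r_o2, "nap": r_nap, "nir": r_nir, "nor": r_nor}


def enzyme_synthesis_rates(
    state: SystemState, syn: EnzymeSynthesisParams
) -> Dict[str, float]:
    """dE_sat/dt (h^-1) for the three denitrification reductases."""
    for name in ("E_NAP", "E_NIR", "E_NOR"):
        v = getattr(state, name)
        if not -1e-12 <= v <= 1.0 + 1e-12:
            raise ValueError(f"{name}={v} outside [0, 1]")
    C_O2 = _clip(state.C_O2)
    C_NO3 = _clip(state.C_NO3)
    C_NO2 = _clip(state.C_NO2)
    C_NO = _clip(state.C_NO)

    d_nap = (
        syn.v_m_NAP
        * C_NO3 / (syn.K_NO3_NAP + C_NO3)
        * syn.K_I_O2_NAP / (syn.K_I_O2_NAP + C_O2)
        * (1.0 - min(state.E_NAP, 1.0))
    )
    d_nir = (
        syn.v_m_NIR
        * C_NO2 / (syn.K_NO2_NIR + C_NO2)
        * (1.0 - min(state.E_NIR, 1.0))
    )
    d_nor = (
        syn.v_m_NOR
        * C_NO / (syn.K_NO_NOR + C_NO)
        * (1.0 - min(state.E_NOR, 1.0))
    )
    if syn.use_o2_nor_term:
        if syn.o2_nor_mode == "saturation":
            d_nor *= C_O2 / (syn.K_O2_NOR + C_O2)
        else:
            d_nor *= syn.K_O2_NOR / (syn.K_O2_NOR + C_O2)
    return {"nap": d_nap, "nir": d_nir, "nor": d_nor}


def carbonate_rate(state: SystemState, phys: PhysicalParams) -> float:
    """Net CO2 hydration rate r_car (M h^-1), positive toward bicarbonate.

    r_car = k_car (C_CO2 - C_HCO3 C_H / K_a); at the buffered pH the pair
    relaxes to C_HCO3/C_CO2 = K_a/C_H.
    """
    return phys.k_car * (state.C_CO2 - state.C_HCO3 * phys.C_H / phys.K_a_car)


def transfer_rates(state: SystemState, phys: PhysicalParams) -> Dict[str, float]:
    """Gas->liquid transfer r_tr,i = k_L a (c_i/H_i - C_i), liquid basis (M h^-1)."""
    pairs = {
        "O2": (state.c_O2, state.C_O2),
        "NO": (state.c_NO, state.C_NO),
        "N2O": (state.c_N2O, state.C_N2O),
        "CO2": (state.c_CO2, state.C_CO2),
    }
    return {
        sp: phys.k_L_a * (c / phys.henry(sp) - C) for sp, (c, C) in pairs.items()
    }
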