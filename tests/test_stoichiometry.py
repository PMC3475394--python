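"""Stoichiometry: molar masses, bioenergetic yields and balance closure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from denitmod.stoichiometry import (
    BIOMASS,
    BIOMASS_FORMULA,
    SUCCINATE,
    BioenergeticParams,
    _species_registry,
    biomass_molar_mass,
    biomass_yield,
    close_stoichiometry,
    derive_all,
    stoichiometry_table,
)


class TestBiomassMolarMass:
    @pytest.mark.parametrize(
        "formula, expected, decimals",
        [
            (BIOMASS_FORMULA, 24.6, 1),                      # CH1.8O0.5N0.2
            ({"C": 1}, 12.011, 3),                           # bare carbon
            ({"C": 1, "H": 2, "O": 1}, 30.03, 2),            # formaldehyde-level C
        ],
    )
    def test_known_formulas(self, formula, expected, decimals):
        assert round(biomass_molar_mass(formula), decimals) == pytest.approx(expected)

    def test_negative_subscript_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            biomass_molar_mass({"C": 1, "H": -0.5})

    def test_requires_cmol_basis(self):
        with pytest.raises(ValueError, match="C-mol"):
            biomass_molar_mass({"C": 2, "H": 4})


class TestDegreesOfReduction:
    def test_succinate_dianion(self):
        assert SUCCINATE.gamma == pytest.approx(14.0)

    def test_biomass_with_ammonium_nitrogen(self):
        assert BIOMASS.gamma == pytest.approx(4.2)


class TestBiomassYield:
    def test_aerobic_matches_reaction_equation(self):
        assert biomass_yield("aerobic") == pytest.approx(2.2, abs=0.05)

    def test_anoxic_matches_reaction_equation(self):
        assert biomass_yield("anoxic") == pytest.approx(1.8, abs=0.05)

    def test_no_atp_no_growth(self):
        p = BioenergeticParams(y_atp=0.0)
        assert biomass_yield("aerobic", p) == 0.0

    def test_unknown_regime(self):
        with pytest.raises(ValueError, match="regime"):
            biomass_yield("fermentative")

    def test_fadh2_split_one_in_seven_still_rounds(self):
        """Routing 1 of 7 electron pairs at FADH2 level keeps 2.2 / 1.8."""
        p = BioenergeticParams(nadh_fadh2_split=1.0 / 7.0)
        assert round(biomass_yield("aerobic", p), 1) == 2.2
        assert round(biomass_yield("anoxic", p), 1) == 1.8

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError, match="split"):
            BioenergeticParams(nadh_fadh2_split=1.5)

    def test_inconsistent_molar_mass_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            BioenergeticParams(biomass_mw=25.0)


class TestCloseStoichiometry:
    def test_nap_nitrate_coefficient(self):
        st_ = close_stoichiometry(biomass_yield("anoxic"), "nap")
        assert -st_.coefficients["NO3-"] == pytest.approx(3.23, abs=0.02)

    def test_nir_nitrite_and_proton_coefficients(self):
        st_ = close_stoichiometry(biomass_yield("anoxic"), "nir")
        assert -st_.coefficients["NO2-"] == pytest.approx(6.45, abs=0.02)
        assert -st_.coefficients["H+"] == pytest.approx(8.09, abs=0.02)

    def test_aerobic_printed_equation(self):
        st_ = close_stoichiometry(biomass_yield("aerobic"), "aerobic")
        c = st_.coefficients
        assert -c["O2"] == pytest.approx(1.2, abs=0.02)
        assert -c["H+"] == pytest.approx(1.56, abs=0.02)
        assert -c["NH4+"] == pytest.approx(0.44, abs=0.01)
        assert c["CO2"] == pytest.approx(1.8, abs=0.01)
        assert c["H2O"] == pytest.approx(1.68, abs=0.02)

    def test_electron_boundary_yield(self):
        """Biomass (4.2 e-/C-mol) is more reduced than succinate carbon
        (14/4 e-), so the acceptor demand vanishes at yield 14/4.2 — the
        electron boundary — while CO2 is still positive there."""
        y_max = 14.0 / 4.2
        st_ = close_stoichiometry(y_max * (1 - 1e-9), "aerobic")
        assert -st_.coefficients["O2"] == pytest.approx(0.0, abs=1e-6)
        assert st_.coefficients["CO2"] == pytest.approx(4.0 - y_max, rel=1e-6)

    def test_infeasible_yield(self):
        with pytest.raises(ValueError):
            close_stoichiometry(4.5, "aerobic")
        with pytest.raises(ValueError):
            close_stoichiometry(-0.1, "nir")
        with pytest.raises(ValueError, match="electrons"):
            close_stoichiometry(3.5, "aerobic")  # beyond the electron boundary

    def test_unknown_pathway(self):
        with pytest.raises(ValueError, match="pathway"):
            close_stoichiometry(1.8, "nos")


@settings(derandomize=True, max_examples=60)
@given(
    yield_x=st.floats(min_value=0.05, max_value=3.2),
    pathway=st.sampled_from(["aerobic", "nap", "nir", "nor"]),
)
def test_balances_close_for_any_feasible_yield(yield_x, pathway):
    """Element, charge and electron balances close for any feasible yield."""
    st_ = close_stoichiometry(yield_x, pathway)
    for key, res in st_.balance_residuals().items():
        assert abs(res) < 0.02, f"{key} balance off by {res}"
    assert abs(st_.electron_residual()) < 0.05


def test_linear_solver_oracle():
    """An independent linear solve over the five balance equations
    reproduces the sequential closure coefficients exactly."""
    reg = _species_registry()
    for pathway, acceptor, product, y in [
        ("aerobic", "O2", None, biomass_yield("aerobic")),
        ("nap", "NO3-", "NO2-", biomass_yield("anoxic")),
        ("nir", "NO2-", "NO", biomass_yield("anoxic")),
        ("nor", "NO", "N2O", biomass_yield("anoxic")),
    ]:
        # unknowns: acceptor, H+, NH4+, CO2, H2O (product tied to acceptor)
        unknowns = [acceptor, "H+", "NH4+", "CO2", "H2O"]
        tie = {"nap": 1.0, "nir": 1.0, "nor": 0.5}.get(pathway, 0.0)
        rows, rhs = [], []
        for bal in ("C", "H", "O", "N", "charge"):
            def attr(name):
                cpd = reg[name]
                return cpd.charge if bal == "charge" else cpd.composition.get(bal, 0.0)

            row = []
            for u in unknowns:
                coef = attr(u)
                if u == acceptor and product is not None:
                    # product appears at +tie per mol acceptor consumed
                    coef = attr(u) - tie * attr(product)
                row.append(coef)
            rows.append(row)
            # knowns: succinate consumed (-1), biomass +y
            rhs.append(-(-1.0 * attr("succinate") + y * attr("biomass")))
        x = np.linalg.solve(np.array(rows), np.array(rhs))
        solved = dict(zip(unknowns, x))

        st_ = close_stoichiometry(y, pathway)
        assert solved[acceptor] == pytest.approx(st_.coefficients[acceptor], rel=1e-9)
        assert solved["H+"] == pytest.approx(st_.coefficients["H+"], rel=1e-9)
        assert solved["H2O"] == pytest.approx(st_.coefficients["H2O"], rel=1e-9)
        assert solved["CO2"] == pytest.approx(st_.coefficients["CO2"], rel=1e-9)


def test_pathway_coefficient_ratios():
    """NirK consumes twice the nitrite Nap consumes nitrate; NorB makes one
    N2O per two NO (all at the shared anoxic yield)."""
    sts = derive_all()
    nap = -sts["nap"].coefficients["NO3-"]
    nir = -sts["nir"].coefficients["NO2-"]
    nor_no = -sts["nor"].coefficients["NO"]
    nor_n2o = sts["nor"].coefficients["N2O"]
    assert nir == pytest.approx(2.0 * nap, rel=1e-12)
    assert nor_n2o == pytest.approx(0.5 * nor_no, rel=1e-12)


def test_export_table_shape_and_content():
    tab = stoichiometry_table()
    assert set(tab.columns) == {"aerobic", "nap", "nir", "nor"}
    assert tab.loc["succinate"].eq(-1.0).all()
    assert tab.loc["biomass", "aerobic"] == pytest.approx(2.2, abs=0.01)
    assert tab.loc["O2", ["nap", "nir", "nor"]].eq(0.0).all()
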