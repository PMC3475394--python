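"""Flask assembly: equilibration, derivative structure, conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from denitmod.kinetics import (
    EnzymeSynthesisParams,
    KineticParams,
    PhysicalParams,
)
from denitmod.reactor import (
    STATE_ORDER,
    ExperimentConfig,
    ReactionCoefficients,
    derivatives,
    equilibrate_initial,
    simulate,
)

KIN = KineticParams()
SYN = EnzymeSynthesisParams()
PHYS = PhysicalParams()
COEFS = ReactionCoefficients()


class TestEquilibrateInitial:
    def test_zero_headspace_oxygen(self):
        cfg = ExperimentConfig(o2_pct=0.0)
        assert equilibrate_initial(cfg).C_O2 == 0.0

    def test_one_percent_oxygen(self):
        """1% O2 at 293.15 K / 1 atm dissolves to ~12.6 uM (about the
        '10 uM' liquid level of the low-oxygen flasks)."""
        s = equilibrate_initial(ExperimentConfig(o2_pct=1.0))
        assert s.c_O2 == pytest.approx(4.157e-4, rel=1e-3)
        assert s.C_O2 == pytest.approx(1.26e-5, rel=1e-2)

    def test_no_initial_nitric_oxides_in_gas(self):
        s = equilibrate_initial(ExperimentConfig())
        assert s.c_NO == 0.0 and s.c_N2O == 0.0
        assert s.C_NO == 0.0 and s.C_N2O == 0.0

    def test_carbonate_equilibrium(self):
        s = equilibrate_initial(ExperimentConfig(co2_pct=0.5))
        assert s.C_HCO3 / s.C_CO2 == pytest.approx(PHYS.bicarbonate_ratio)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            ExperimentConfig(temperature_K=-1.0)


def _rhs(y, carbonate="algebraic"):
    cfg = ExperimentConfig()
    return derivatives(0.0, y, KIN, SYN, PHYS, cfg, COEFS, carbonate)


def _vector(**kw):
    y = np.zeros(len(STATE_ORDER) + 4)
    for name, val in kw.items():
        y[STATE_ORDER.index(name)] = val
    return y


class TestDerivatives:
    def test_dormant_state_is_stationary(self):
        """No electron acceptors and no enzymes: nothing moves (with an
        inducer such as nitrite present, enzyme synthesis would still run)."""
        y = _vector(C_X=0.25e-3)
        assert np.allclose(_rhs(y), 0.0)

    def test_conversions_halt_without_oxygen_and_enzymes(self):
        """All E_sat = 0 and C_O2 = 0: every chemical conversion stops;
        only the synthesis of the induced enzymes proceeds."""
        y = _vector(C_NO3=1e-3, C_NO2=1e-3, C_X=0.25e-3)
        d = _rhs(y)
        i_nap, i_nir = STATE_ORDER.index("E_NAP"), STATE_ORDER.index("E_NIR")
        chem = np.delete(d, [i_nap, i_nir])
        assert np.allclose(chem, 0.0)
        assert d[i_nap] > 0 and d[i_nir] > 0

    def test_oxygen_never_produced(self):
        cfg = ExperimentConfig()
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = _vector(
                C_O2=rng.uniform(0, 3e-5), C_NO3=rng.uniform(0, 2e-3),
                C_NO2=rng.uniform(0, 2e-3), C_NO=rng.uniform(0, 1e-6),
                C_N2O=rng.uniform(0, 1e-4), C_X=rng.uniform(1e-4, 1e-3),
                c_O2=rng.uniform(0, 4e-4), E_NAP=rng.uniform(0, 1),
                E_NIR=rng.uniform(0, 1), E_NOR=rng.uniform(0, 1),
            )
            d = _rhs(y)
            i_C, i_c = STATE_ORDER.index("C_O2"), STATE_ORDER.index("c_O2")
            total_o2_rate = cfg.V_L * d[i_C] + cfg.V_G * d[i_c]
            assert total_o2_rate <= 1e-20

    def test_nan_diagnostics(self):
        y = _vector(C_O2=1e-5, C_X=np.inf)
        with pytest.raises(FloatingPointError, match="non-finite"):
            _rhs(y)


@settings(derandomize=True, max_examples=60)
@given(
    c_no3=st.floats(0, 2e-3), c_no2=st.floats(0, 2e-3),
    c_no=st.floats(0, 1e-5), c_n2o=st.floats(0, 5e-4),
    g_no=st.floats(0, 1e-5), g_n2o=st.floats(0, 5e-4),
    c_o2=st.floats(0, 3e-5), e_nir=st.floats(0, 1), e_nor=st.floats(0, 1),
)
def test_n_oxide_conservation_is_analytic(
    c_no3, c_no2, c_no, c_n2o, g_no, g_n2o, c_o2, e_nir, e_nor
):
    """The instantaneous N-oxide balance closes for any state: pathway
    terms telescope and transfer terms cancel between the phases."""
    cfg = ExperimentConfig()
    y = _vector(
        C_NO3=c_no3, C_NO2=c_no2, C_NO=c_no, C_N2O=c_n2o,
        c_NO=g_no, c_N2O=g_n2o, C_O2=c_o2, C_X=0.25e-3,
        E_NAP=1.0, E_NIR=e_nir, E_NOR=e_nor,
    )
    d = _rhs(y)
    i = {n: STATE_ORDER.index(n) for n in STATE_ORDER}
    liquid = d[i["C_NO3"]] + d[i["C_NO2"]] + d[i["C_NO"]] + 2 * d[i["C_N2O"]]
    gas = d[i["c_NO"]] + 2 * d[i["c_N2O"]]
    total = cfg.V_L * liquid + cfg.V_G * gas
    scale = max(abs(cfg.V_L * liquid), abs(cfg.V_G * gas), 1e-12)
    assert abs(total) <= 1e-10 * scale + 1e-24


class TestSimulate:
    def test_zero_biomass_inert(self):
        cfg = ExperimentConfig(biomass_CmolL=0.0, t_end=10.0)
        traj = simulate(cfg)
        assert np.allclose(traj.headspace("O2"), traj.headspace("O2")[0],
                           rtol=1e-6)
        assert traj.succinate.iloc[-1].sum() == pytest.approx(0.0, abs=1e-15)

    def test_reference_scenario_course(self, reference_trajectory):
        """Headspace O2 declines to depletion, N2O accumulates, and the
        final N2O-N approaches the initial nitrite-N."""
        traj = reference_trajectory
        o2 = traj.headspace("O2", unit="%")
        assert o2[0] == pytest.approx(1.0, rel=1e-6)
        assert o2[-1] < 0.02 * o2[0]
        n2o = traj.headspace("N2O")
        assert np.all(np.diff(n2o) > -1e-12)
        cfg = traj.config
        final = traj.states.iloc[-1]
        n2o_n = 2 * (cfg.V_L * final.C_N2O + cfg.V_G * final.c_N2O)
        nitrite_n = cfg.V_L * cfg.nitrite_M
        assert n2o_n == pytest.approx(nitrite_n, rel=0.01)

    def test_n_oxide_conservation_along_trajectory(self, reference_trajectory):
        n = reference_trajectory.n_oxide_total()
        assert np.max(np.abs(n - n[0])) / n[0] < 1e-3

    def test_carbon_closure(self, reference_trajectory):
        assert reference_trajectory.carbon_closure_error() < 5e-3

    def test_enzyme_saturations_nondecreasing_and_bounded(
        self, reference_trajectory
    ):
        for col in ("E_NAP", "E_NIR", "E_NOR"):
            e = reference_trajectory.states[col].to_numpy()
            assert np.all(np.diff(e) >= -1e-10)
            assert e.max() <= 1.0 + 1e-9

    def test_concentrations_nonnegative(self, reference_trajectory):
        assert (reference_trajectory.states.iloc[:, :12] >= 0).all().all()

    def test_carbonate_modes_agree(self, reference_config):
        """Fast-equilibrium reduction vs literal stiff hydration ODE:
        headspace CO2 within 0.1%."""
        alg = simulate(reference_config, carbonate="algebraic")
        kin_mode = simulate(reference_config, carbonate="kinetic")
        a, k = alg.headspace("CO2"), kin_mode.headspace("CO2")
        mask = a > a.max() * 1e-3
        assert np.max(np.abs(a[mask] - k[mask]) / a[mask]) < 1e-3

    def test_tolerance_refinement(self, reference_config, reference_trajectory):
        """Halving rtol and atol moves every headspace output by <0.01%
        of its trajectory maximum."""
        fine = simulate(reference_config, rtol=0.5e-8, atol=0.5e-12)
        for sp in ("O2", "NO", "N2O", "CO2"):
            a = reference_trajectory.headspace(sp)
            b = fine.headspace(sp)
            assert np.max(np.abs(a - b)) / np.max(np.abs(b)) < 1e-4

    def test_derived_coefficients_close_to_printed(self):
        derived = ReactionCoefficients.from_derivation()
        printed = ReactionCoefficients()
        assert derived.o2 == pytest.approx(printed.o2, abs=0.02)
        assert derived.no3 == pytest.approx(printed.no3, abs=0.02)
        assert derived.no2 == pytest.approx(printed.no2, abs=0.02)
        assert derived.y_aerobic == pytest.approx(printed.y_aerobic, abs=0.01)
        assert derived.y_anoxic == pytest.approx(printed.y_anoxic, abs=0.01)

    def test_simulation_with_derived_coefficients(self, reference_config):
        """The unrounded derivation-based coefficient set also conserves."""
        traj = simulate(reference_config, coefs=ReactionCoefficients.from_derivation())
        n = traj.n_oxide_total()
        assert np.max(np.abs(n - n[0])) / n[0] < 1e-3
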