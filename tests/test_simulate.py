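import numpy as np
import pytest

from coagxa import (
    FACTOR_NAMES,
    PlasmaComposition,
    SimulationConfig,
    build_initial_state,
    derivative,
    simulate,
    simulate_fixed_step,
)
from coagxa.metrics import analyte_series
from coagxa.network import SPECIES_INDEX, moiety_matrix
from coagxa.simulate import jacobian

from conftest import random_composition


def brute_force_derivative(y, network):
    """Independent flux summation, one reaction at a time, from the
    declared reaction tuples (not the compiled index arrays)."""
    dy = np.zeros(len(network.species))
    idx = {s: i for i, s in enumerate(network.species)}
    for (reactants, products, key), k in zip(network.reactions, network.rates):
        flux = k
        for r in reactants:
            flux *= y[idx[r]]
        for r in reactants:
            dy[idx[r]] -= flux
        for p in products:
            dy[idx[p]] += flux
    return dy


class TestInitialState:
    def test_nominal_defaults(self, nominal, network, means):
        state = build_initial_state(nominal, means, SimulationConfig(), network)
        assert state["TF"] == pytest.approx(5e-12)
        assert state["VIIa"] == pytest.approx(0.01 * means["fVII"])
        assert state["II"] == pytest.approx(1.4e-6)
        assert state["Xa"] == 0.0 and state["IIa"] == 0.0
        assert state.time == 0.0

    def test_products_and_complexes_start_at_zero(self, nominal, network, means):
        state = build_initial_state(nominal, means, SimulationConfig(), network)
        zymogens = {"TF", "VII", "VIIa", "X", "IX", "II", "VIII", "V", "TFPI", "AT"}
        for name in network.species:
            if name not in zymogens:
                assert state[name] == 0.0, name

    def test_viia_scales_with_fvii(self, network, means):
        comp = PlasmaComposition(
            "s", {**{f: 100.0 for f in FACTOR_NAMES}, "fVII": 50.0}
        )
        state = build_initial_state(comp, means, SimulationConfig(), network)
        assert state["VIIa"] == pytest.approx(0.005 * means["fVII"])


class TestDerivative:
    def test_zero_state_zero_rates(self, network):
        assert np.all(derivative(np.zeros(network.n_species), network) == 0.0)

    def test_only_tf_and_vii_react(self, network):
        y = np.zeros(network.n_species)
        y[SPECIES_INDEX["TF"]] = 5e-12
        y[SPECIES_INDEX["VII"]] = 1e-8
        dy = derivative(y, network)
        nonzero = {network.species[i] for i in np.nonzero(dy)[0]}
        assert nonzero == {"TF", "VII", "TF:VII"}

    def test_matches_brute_force_enumeration(self, network, rng):
        y = rng.uniform(0, 1e-7, size=network.n_species)
        dy = derivative(y, network)
        ref = brute_force_derivative(y, network)
        np.testing.assert_allclose(dy, ref, rtol=1e-12)

    def test_rate_vector_conserves_moieties(self, network, rng):
        _, M = moiety_matrix()
        y = rng.uniform(0, 1e-6, size=network.n_species)
        dy = derivative(y, network)
        # zero up to float cancellation relative to the rate magnitudes
        assert np.abs(M @ dy).max() < 1e-12 * np.abs(dy).max()

    def test_jacobian_matches_finite_differences(self, network, rng):
        y = rng.uniform(1e-10, 1e-7, size=network.n_species)
        J = jacobian(y, network)
        eps = 1e-14
        for i in rng.choice(network.n_species, size=6, replace=False):
            yp = y.copy(); yp[i] += eps
            col = (derivative(yp, network) - derivative(y, network)) / eps
            np.testing.assert_allclose(J[:, i], col, rtol=5e-4, atol=1e-12)


class TestSimulate:
    def test_no_factors_no_fxa(self, network, means):
        comp = PlasmaComposition("empty", {f: 0.0 for f in FACTOR_NAMES})
        traj = simulate(comp, network=network, means=means)
        assert np.all(analyte_series(traj, "fXa") == 0.0)

    def test_no_tissue_factor_no_activation(self, nominal, network, means):
        cfg = SimulationConfig(tf_concentration=0.0)
        traj = simulate(nominal, network=network, means=means, config=cfg)
        assert np.all(analyte_series(traj, "fXa") == 0.0)

    def test_output_grid(self, nominal_trajectory):
        assert len(nominal_trajectory.times) == 3601
        assert nominal_trajectory.times[0] == 0.0
        assert nominal_trajectory.times[-1] == 3600.0
        assert nominal_trajectory.step == 1.0

    def test_non_negative_after_clamping(self, nominal_trajectory):
        assert nominal_trajectory.concentrations.min() >= 0.0

    def test_moiety_conservation_along_trajectory(self, nominal_trajectory):
        names, M = moiety_matrix()
        totals = nominal_trajectory.raw_concentrations @ M.T
        drift = np.abs(totals - totals[0]).max(axis=0)
        # within 10x solver tolerance of the initial totals
        tol = 10 * (1e-8 * totals[0] + 1e-14)
        assert np.all(drift <= tol), dict(zip(names, drift))

    def test_deterministic_bit_identical(self, nominal, network, means):
        a = simulate(nominal, network=network, means=means)
        b = simulate(nominal, network=network, means=means)
        assert np.array_equal(a.concentrations, b.concentrations)

    def test_adaptive_matches_fixed_step_oracle(self, nominal, network, means):
        adaptive = simulate(nominal, network=network, means=means)
        oracle = simulate_fixed_step(nominal, network=network, means=means, dt=1e-3)
        fa = analyte_series(adaptive, "fXa")
        fo = analyte_series(oracle, "fXa")
        for t in (600, 1800, 3600):
            assert abs(fa[t] - fo[t]) / fo[t] < 0.005

    def test_inhibitor_and_procoagulant_monotonicity(self, nominal, network, means):
        """+20% TFPI or AT must not raise total-fXa AUC; +20% fVIII or
        fIX must not lower it."""
        def auc(comp):
            traj = simulate(comp, network=network, means=means)
            return analyte_series(traj, "fXa").sum()

        base = auc(nominal)
        assert auc(nominal.replace_levels(TFPI=120.0)) <= base
        assert auc(nominal.replace_levels(AT=120.0)) <= base
        assert auc(nominal.replace_levels(fVIII=120.0)) >= base
        assert auc(nominal.replace_levels(fIX=120.0)) >= base

    def test_random_compositions_stay_conservative(self, network, means, rng, table1_spec):
        names, M = moiety_matrix()
        for i in range(3):
            comp = random_composition(rng, table1_spec, subject_id=f"r{i}")
            traj = simulate(comp, network=network, means=means)
            totals = traj.raw_concentrations @ M.T
            drift = np.abs(totals - totals[0]).max(axis=0)
            assert np.all(drift <= 10 * (1e-8 * totals[0] + 1e-14))


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(t_end=-1)
    with pytest.raises(ValueError):
        SimulationConfig(output_grid_step=0)
    with pytest.raises(ValueError):
        SimulationConfig(rtol=0)
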