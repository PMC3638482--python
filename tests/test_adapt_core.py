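"""The step-wise regularized estimator: objectives, steps, ensembles."""

import numpy as np
import pytest

from adaptkit.adapt_core import (
    AdaptConfig,
    estimate_step,
    flux_trajectories,
    init_trajectory,
    objective_data,
    objective_reg,
    run_ensemble,
    run_trajectory,
)
from adaptkit.interpolants import Interpolant, PhenotypeDataset, sigma_envelope
from adaptkit.synthetic_data import NoiseConfig, generate_snapshots


@pytest.fixture(scope="module")
def flat_dataset(true_model):
    """Time-constant data: the reference steady state at every stage."""
    y = true_model.outputs(true_model.x0)
    return PhenotypeDataset(
        stage_times=np.arange(5.0),
        observable_names=true_model.output_names,
        means=np.tile(y, (5, 1)),
        sds=np.zeros((5, 4)),
    )


class TestObjectives:
    def test_data_misfit_zero_at_match(self):
        y = np.array([1.0, 2.0])
        bd = objective_data(y, y, np.array([0.1, 0.1]))
        assert bd.X_d == 0.0 and bd.N_meas == 2

    def test_two_sigma_residual(self):
        bd = objective_data(np.array([1.2]), np.array([1.0]), np.array([0.1]))
        assert bd.X_d == pytest.approx(4.0)
        assert bd.sse == pytest.approx(4.0)

    def test_data_misfit_matches_hand_summation(self):
        rng = np.random.default_rng(1)
        y, d, s = rng.normal(size=4), rng.normal(size=4), rng.uniform(0.1, 1, 4)
        expect = sum(((yi - di) / si) ** 2 for yi, di, si in zip(y, d, s)) / 4
        assert objective_data(y, d, s).X_d == pytest.approx(expect, abs=1e-12)

    def test_reg_zero_when_constant(self):
        th = np.array([1.0, 2.0])
        assert objective_reg(th, th, 0.1, th).X_r == 0.0

    def test_reg_unit_case(self):
        # one parameter doubling over dt=0.1 with ref 1: ((2-1)/(1*0.1))^2 = 100
        bd = objective_reg(np.array([1.0]), np.array([2.0]), 0.1, np.array([1.0]))
        assert bd.X_r == pytest.approx(100.0)

    def test_reg_matches_hand_summation(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(1, 2, 3), rng.uniform(1, 2, 3)
        ref, dt = rng.uniform(0.5, 1.5, 3), 0.25
        expect = sum(((bi - ai) / (ri * dt)) ** 2
                     for ai, bi, ri in zip(a, b, ref)) / 3
        assert objective_reg(a, b, dt, ref).X_r == pytest.approx(expect, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            objective_data(np.ones(2), np.ones(2), np.array([0.1, 0.0]))
        with pytest.raises(ValueError):
            objective_reg(np.ones(1), np.ones(1), 0.1, np.zeros(1))


class TestEstimateStep:
    def test_huge_regularization_freezes_parameters(
        self, reduced_model, zero_noise_data
    ):
        ds, _ = zero_noise_data
        itp, env = Interpolant.fit(ds), sigma_envelope(ds)
        cfg = AdaptConfig(free_parameters=("k1",), lambda_r=1e6)
        theta = reduced_model.theta0.copy()
        th2, _, _ = estimate_step(
            reduced_model, reduced_model.x0, theta, itp, env, 0.0, cfg
        )
        assert abs(th2[0] / theta[0] - 1) < 1e-3


class TestInitTrajectory:
    def test_loguniform_median_is_geometric_mean(self):
        rng = np.random.default_rng(0)
        lr, ur = 0.1, 10.0
        draws = np.exp(rng.uniform(np.log(lr), np.log(ur), 100_000))
        assert np.median(draws) == pytest.approx(1.0, rel=0.02)

    def test_zero_noise_start_recovers_stage1_parameter(
        self, reduced_model, zero_noise_data
    ):
        """The stage-1 fit equals the value reproducing the stage-1 steady
        state, cross-checked against a fine grid search."""
        from adaptkit.kinetic_model import steady_state

        ds, _ = zero_noise_data
        itp = Interpolant.fit(ds, smoothing=1.0)  # interpolating: exact at t0
        env = sigma_envelope(ds)
        m = reduced_model
        cfg = AdaptConfig(free_parameters=("k1",))
        theta, x0 = init_trajectory(m, itp, env, 0.0, cfg,
                                    np.random.default_rng(4))
        d0, sig0 = ds.means[0], env(0.0)
        grid = np.exp(np.linspace(np.log(0.1 * m.theta0[0]),
                                  np.log(10 * m.theta0[0]), 4000))
        costs = []
        for k1 in grid:
            th = m.theta0.copy()
            th[0] = k1
            x_ss = steady_state(m, th, m.u0, m.x0, tol=1e-10)
            costs.append(float(np.sum(((m.outputs(x_ss) - d0) / sig0) ** 2)))
        best = grid[int(np.argmin(costs))]
        assert theta[0] == pytest.approx(best, rel=2e-3)
        # returned state is the steady state for the fitted parameters
        x_check = steady_state(m, theta, m.u0, m.x0, tol=1e-10)
        np.testing.assert_allclose(x0, x_check, rtol=1e-8)


class TestRunTrajectory:
    def test_constant_data_gives_constant_parameters(
        self, reduced_model, flat_dataset
    ):
        itp, env = Interpolant.fit(flat_dataset), sigma_envelope(flat_dataset)
        cfg = AdaptConfig(free_parameters=("k1",))
        tr = run_trajectory(reduced_model, itp, env, cfg,
                            np.random.default_rng(1))
        k1 = tr.parameter("k1")
        assert np.max(np.abs(k1 / k1[0] - 1)) < 1e-3
        assert all(b.X_r < 1e-4 for b in tr.breakdowns)
        assert tr.accepted

    def test_step_count_and_grid(self, reduced_model, flat_dataset):
        itp, env = Interpolant.fit(flat_dataset), sigma_envelope(flat_dataset)
        cfg = AdaptConfig(free_parameters=("k1",), dt=0.5)
        tr = run_trajectory(reduced_model, itp, env, cfg,
                            np.random.default_rng(1))
        assert len(tr.times) == round((4.0 - 0.0) / 0.5) + 1
        np.testing.assert_allclose(np.diff(tr.times), 0.5)

    def test_zero_noise_trajectory_is_nondecreasing(
        self, reduced_model, zero_noise_data
    ):
        """The staged intervention relieves inhibition, so the lumped k1
        must rise; small solver wiggle is tolerated."""
        ds, _ = zero_noise_data
        itp, env = Interpolant.fit(ds), sigma_envelope(ds)
        cfg = AdaptConfig(free_parameters=("k1",))
        tr = run_trajectory(reduced_model, itp, env, cfg,
                            np.random.default_rng(2))
        k1 = tr.parameter("k1")
        assert np.all(np.diff(k1) > -1e-3 * k1[:-1])
        assert k1[-1] > 5 * k1[0]


class TestRunEnsemble:
    def test_acceptance_filter_definition(self, reduced_model, noisy_data):
        ds, _ = noisy_data
        cfg = AdaptConfig(free_parameters=("k1",), nr=4, seed=5)
        ens = run_ensemble(reduced_model, ds, cfg)
        assert len(ens) == 4
        for tr in ens.trajectories:
            assert tr.accepted == (tr.total_sse < cfg.sse_thres)

    def test_bit_identical_rerun_from_seed(self, reduced_model, noisy_data):
        ds, _ = noisy_data
        cfg = AdaptConfig(free_parameters=("k1",), nr=3, seed=11)
        e1 = run_ensemble(reduced_model, ds, cfg)
        e2 = run_ensemble(reduced_model, ds, cfg)
        for a, b in zip(e1.trajectories, e2.trajectories):
            np.testing.assert_array_equal(a.theta_hat, b.theta_hat)
            np.testing.assert_array_equal(a.states, b.states)
            assert a.total_sse == b.total_sse

    def test_flux_recomputation_is_consistent(self, reduced_model, noisy_data):
        ds, _ = noisy_data
        cfg = AdaptConfig(free_parameters=("k1",), nr=2, seed=3)
        ens = run_ensemble(reduced_model, ds, cfg)
        recomputed = flux_trajectories(ens, reduced_model)
        for tr, fl in zip(ens.trajectories, recomputed):
            np.testing.assert_allclose(fl, tr.fluxes, rtol=0, atol=1e-12)

    def test_reduced_flux1_is_mass_action_product(self, reduced_model, noisy_data):
        ds, _ = noisy_data
        cfg = AdaptConfig(free_parameters=("k1",), nr=1, seed=3)
        ens = run_ensemble(reduced_model, ds, cfg)
        tr = ens.trajectories[0]
        k1 = tr.parameter("k1")
        expect = k1 * tr.states[:, 0] * tr.states[:, 2]
        np.testing.assert_allclose(tr.fluxes[:, 0], expect, rtol=1e-12)

    def test_quasi_steady_tracking_balance(self, reduced_model, zero_noise_data):
        """At every grid time the stoichiometric balance closes: the state
        tracks the quasi-steady state of the current parameters."""
        ds, _ = zero_noise_data
        cfg = AdaptConfig(free_parameters=("k1",), nr=1, seed=3)
        ens = run_ensemble(reduced_model, ds, cfg)
        tr = ens.trajectories[0]
        m = reduced_model
        for k in range(len(tr.times)):
            residual = m.stoichiometry @ tr.fluxes[k] + m.input_matrix @ m.u0
            assert np.max(np.abs(residual)) < 1e-4

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AdaptConfig(dt=0.0)
        with pytest.raises(ValueError):
            AdaptConfig(lr=2.0, ur=1.0)
        with pytest.raises(ValueError):
            AdaptConfig(nr=0)
        with pytest.raises(ValueError):
            AdaptConfig(lambda_r=-0.1)
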