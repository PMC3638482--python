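"""Bootstrap replicates, smoothing splines, SD envelopes and 2-D densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptkit.interpolants import (
    Interpolant,
    PhenotypeDataset,
    bootstrap_sample,
    build_interpolant_ensemble,
    default_smoothing,
    density_histogram,
    fit_spline,
    sigma_envelope,
)


class TestPhenotypeDataset:
    def test_shape_and_monotonicity_validation(self):
        with pytest.raises(ValueError):
            PhenotypeDataset(np.array([0.0, 0.0]), ["A"],
                             np.ones((2, 1)), np.ones((2, 1)))
        with pytest.raises(ValueError):
            PhenotypeDataset(np.array([0.0, 1.0]), ["A"],
                             np.ones((2, 2)), np.ones((2, 2)))
        with pytest.raises(ValueError):
            PhenotypeDataset(np.array([0.0, 1.0]), ["A"],
                             np.ones((2, 1)), -np.ones((2, 1)))

    def test_csv_round_trip_bit_exact(self, tiny_dataset, tmp_path):
        path = tmp_path / "ds.csv"
        tiny_dataset.to_csv(path)
        back = PhenotypeDataset.from_csv(path)
        np.testing.assert_array_equal(back.means, tiny_dataset.means)
        np.testing.assert_array_equal(back.sds, tiny_dataset.sds)
        assert back.observable_names == tiny_dataset.observable_names


class TestBootstrapSample:
    def test_zero_sd_returns_identical_dataset(self, tiny_dataset):
        ds = tiny_dataset.with_sds(np.zeros_like(tiny_dataset.sds))
        rep = bootstrap_sample(ds, np.random.default_rng(0))
        np.testing.assert_array_equal(rep.means, ds.means)

    def test_seed_determinism(self, tiny_dataset):
        r1 = bootstrap_sample(tiny_dataset, np.random.default_rng(5))
        r2 = bootstrap_sample(tiny_dataset, np.random.default_rng(5))
        np.testing.assert_array_equal(r1.means, r2.means)

    def test_replicate_moments_converge(self, tiny_dataset):
        """Elementwise sample mean/SD over 1e4 replicates match (d, sigma)."""
        rng = np.random.default_rng(2024)
        n = 10_000
        draws = np.stack(
            [bootstrap_sample(tiny_dataset, rng).means for _ in range(n)]
        )
        sample_sd = draws.std(axis=0)
        assert np.all(
            np.abs(sample_sd / tiny_dataset.sds - 1) < 0.03
        )
        se = tiny_dataset.sds / np.sqrt(n)
        assert np.all(np.abs(draws.mean(axis=0) - tiny_dataset.means) < 3 * se)


class TestFitSpline:
    def test_smoothing_one_interpolates(self):
        t = np.array([1.0, 2.0, 3.0])
        v = np.array([2.0, 3.0, 5.0])
        s = fit_spline(t, v, smoothing=1.0)
        assert np.max(np.abs(s(t) - v)) < 1e-10

    def test_smoothing_zero_limit_is_ols_line(self):
        """p -> 0 approaches the least-squares straight line (oracle: polyfit)."""
        rng = np.random.default_rng(3)
        t = np.linspace(0, 4, 5)
        v = 1.5 * t + 0.3 + rng.normal(0, 0.2, 5)
        s = fit_spline(t, v, smoothing=1e-9)
        slope, icept = np.polyfit(t, v, 1)
        assert np.max(np.abs(s(t) - (slope * t + icept))) < 1e-3

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_spline(np.array([1.0]), np.array([1.0]), 0.5)
        with pytest.raises(ValueError):
            fit_spline(np.array([1.0, 1.0]), np.array([1.0, 2.0]), 0.5)
        with pytest.raises(ValueError):
            fit_spline(np.array([1.0, 2.0]), np.array([1.0, 2.0]), 0.0)

    def test_matches_scipy_penalized_spline(self):
        """Independent oracle: scipy's penalized smoothing spline with the
        equivalent penalty lam = (1-p)/p agrees to machine precision."""
        from scipy.interpolate import make_smoothing_spline

        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 10, 9))
        v = np.sin(t) + rng.normal(0, 0.2, 9)
        tt = np.linspace(t[0], t[-1], 200)
        for p in (0.99, 6 / 7, 0.5, 0.1):
            ours = fit_spline(t, v, p)
            ref = make_smoothing_spline(t, v, lam=(1 - p) / p)
            assert np.max(np.abs(ours(tt) - ref(tt))) < 1e-10

    @given(p1=st.floats(0.05, 0.95), p2=st.floats(0.05, 0.95))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_fidelity_monotone_in_smoothing(self, p1, p2):
        """Summed squared residuals at the data are non-increasing in p."""
        rng = np.random.default_rng(11)
        t = np.linspace(0, 4, 6)
        v = np.sin(t) + rng.normal(0, 0.3, t.size)
        lo, hi = sorted((p1, p2))
        res = {
            p: float(np.sum((fit_spline(t, v, p)(t) - v) ** 2))
            for p in (lo, hi)
        }
        assert res[hi] <= res[lo] + 1e-12


class TestInterpolantEnsemble:
    def test_zero_sd_gives_identical_interpolants(self, tiny_dataset):
        ds = tiny_dataset.with_sds(np.zeros_like(tiny_dataset.sds))
        ens = build_interpolant_ensemble(ds, n=5, rng=0)
        tt = np.linspace(0, 1, 7)
        vals = [[itp(t) for t in tt] for itp in ens.interpolants]
        for v in vals[1:]:
            np.testing.assert_array_equal(v, vals[0])

    def test_seed_reproducibility_bit_exact(self, tiny_dataset):
        e1 = build_interpolant_ensemble(tiny_dataset, n=4, rng=9)
        e2 = build_interpolant_ensemble(tiny_dataset, n=4, rng=9)
        for a, b in zip(e1.replicates, e2.replicates):
            np.testing.assert_array_equal(a.means, b.means)

    def test_ensemble_mean_at_stages_tracks_data(self, tiny_dataset):
        n = 400
        ens = build_interpolant_ensemble(tiny_dataset, n=n, smoothing=1.0, rng=1)
        for i, t in enumerate(tiny_dataset.stage_times):
            vals = np.array([itp(t) for itp in ens.interpolants])
            se = tiny_dataset.sds[i] / np.sqrt(n)
            assert np.all(
                np.abs(vals.mean(axis=0) - tiny_dataset.means[i]) < 4 * se
            )

    def test_default_smoothing_heuristic(self):
        # h = 1 -> p = 1/(1 + 1/6) = 6/7
        assert default_smoothing(np.arange(5.0)) == pytest.approx(6 / 7)


class TestSigmaEnvelope:
    def test_stage_values_and_midpoint_linearity(self, tiny_dataset):
        env = sigma_envelope(tiny_dataset, floor_rel=1e-9)
        np.testing.assert_allclose(env(0.0), tiny_dataset.sds[0])
        np.testing.assert_allclose(
            env(0.5), 0.5 * (tiny_dataset.sds[0] + tiny_dataset.sds[1])
        )

    def test_zero_sd_floors_everywhere(self, tiny_dataset):
        ds = tiny_dataset.with_sds(np.zeros_like(tiny_dataset.sds))
        env = sigma_envelope(ds, floor_rel=0.01)
        expected = 0.01 * np.maximum(np.max(np.abs(ds.means), axis=0), 1.0)
        for t in (0.0, 0.3, 1.0):
            np.testing.assert_allclose(env(t), expected)


class TestDensityHistogram:
    def test_single_curve_one_entry_per_column(self):
        t_grid = np.linspace(0, 1, 5)
        bins = np.linspace(-2, 2, 9)
        counts = density_histogram([np.sin], t_grid, bins)
        assert np.all(counts.sum(axis=0) == 1)
        assert np.all((counts == 0) | (counts == 1))

    def test_matches_brute_force_binning(self):
        rng = np.random.default_rng(8)
        coeffs = rng.normal(size=(50, 3))
        curves = [np.poly1d(c) for c in coeffs]
        t_grid = np.linspace(-1, 1, 11)
        bins = np.linspace(-6, 6, 25)
        counts = density_histogram(curves, t_grid, bins)
        for k, t in enumerate(t_grid):
            vals = np.array([c(t) for c in curves])
            for b in range(bins.size - 1):
                closed = b == bins.size - 2
                hi_ok = vals <= bins[b + 1] if closed else vals < bins[b + 1]
                expect = int(np.sum((vals >= bins[b]) & hi_ok))
                assert counts[b, k] == expect
        assert np.all(counts.sum(axis=0) == 50)  # bins cover the range

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            density_histogram([np.sin], np.array([]), np.array([0.0, 1.0]))
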