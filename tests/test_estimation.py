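"""EM estimator: likelihood, E/M steps, metric standardization, full fits."""

import numpy as np
import pytest

from ehirt.estimation import (
    ConvergenceSettings,
    ExpectedCounts,
    HAVE_NUMBA,
    LatentGrid,
    e_step,
    em_cycles,
    fit,
    fit_path,
    m_step_items,
    m_step_weights,
    make_grid_points,
    marginal_log_likelihood,
    normal_grid,
    response_probability,
    standardize_metric,
)
from ehirt.simulate import AbilitySpec, default_item_bank, generate_responses, sample_abilities

from _oracles import brute_force_loglik


class TestResponseProbability:
    @pytest.mark.parametrize(
        "a,b,z,expected",
        [
            (1.0, 0.0, 0.0, 0.5),
            (2.7, 1.3, 1.3, 0.5),  # z = b is the 50% point for any a
            (1.7, 0.0, 1.0, 0.8455),
        ],
    )
    def test_values(self, a, b, z, expected):
        assert response_probability(a, b, z) == pytest.approx(expected, abs=1e-4)

    def test_monotone_in_ability_and_overflow_safe(self):
        z = np.linspace(-800, 800, 101)
        p = response_probability(2.0, 0.5, z)
        assert np.all(np.diff(p) >= 0)
        assert np.isfinite(p).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            response_probability(-1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            response_probability(1.0, np.nan, 0.0)


class TestMarginalLogLikelihood:
    def test_point_mass_grid_reduces_to_bernoulli(self):
        grid = LatentGrid([0.7], [1.0])
        a, b = np.array([1.2, 0.8]), np.array([-0.3, 0.5])
        x = np.array([[1, 0]])
        p = response_probability(a, b, 0.7)
        expected = np.log(p[0]) + np.log(1 - p[1])
        assert marginal_log_likelihood(a, b, grid, x) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_two_point_grid(self):
        # sigma(-1) + sigma(1) = 1, so the mixture likelihood is exactly 1/2
        grid = LatentGrid([-1.0, 1.0], [0.5, 0.5])
        ll = marginal_log_likelihood([1.0], [0.0], grid, [[1]])
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n, k, q = rng.integers(2, 21), rng.integers(1, 6), rng.integers(2, 6)
            a = rng.uniform(0.4, 2.5, k)
            b = rng.uniform(-2, 2, k)
            w = rng.dirichlet(np.ones(q))
            grid = LatentGrid(np.linspace(-3, 3, q), w)
            x = rng.integers(0, 2, (n, k))
            assert marginal_log_likelihood(a, b, grid, x) == pytest.approx(
                brute_force_loglik(a, b, grid, x), abs=1e-10
            )

    def test_invalid_weights_rejected(self):
        grid = normal_grid()
        bad = grid.weights * 2
        with pytest.raises(ValueError):
            LatentGrid(grid.points, bad)


class TestESTep:
    def test_degenerate_grid_posterior(self):
        grid = LatentGrid([0.0], [1.0])
        x = np.array([[1, 0], [1, 1], [0, 0]])
        counts, post = e_step([1.0, 1.0], [0.0, 0.0], grid, x)
        np.testing.assert_allclose(post, 1.0)
        assert counts.m[0] == pytest.approx(3.0)

    def test_testee_count_conserved(self, bank, grid_points, normal_weights, small_responses):
        x, _ = small_responses
        counts, post = e_step(bank.a, bank.b, LatentGrid(grid_points, normal_weights), x)
        assert counts.m.sum() == pytest.approx(x.shape[0], abs=1e-8)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(counts.r >= -1e-12)
        assert np.all(counts.r <= counts.m[None, :] + 1e-12)

    def test_two_point_hand_computed_posteriors(self):
        # 2 testees x 1 item, grid {-1, +1}, equal prior weights
        grid = LatentGrid([-1.0, 1.0], [0.5, 0.5])
        a, b = [1.0], [0.0]
        p_lo = response_probability(1.0, 0.0, -1.0)
        p_hi = response_probability(1.0, 0.0, 1.0)
        x = np.array([[1], [0]])
        _, post = e_step(a, b, grid, x)
        np.testing.assert_allclose(
            post[0], [p_lo / (p_lo + p_hi), p_hi / (p_lo + p_hi)], atol=1e-12
        )
        np.testing.assert_allclose(
            post[1], [(1 - p_lo) / (2 - p_lo - p_hi), (1 - p_hi) / (2 - p_lo - p_hi)],
            atol=1e-12,
        )


class TestMStep:
    def test_self_consistency_fixed_point(self, grid_points):
        # counts generated exactly from (a0, b0) are reproduced
        a0 = np.array([0.8, 1.5, 2.5])
        b0 = np.array([-1.2, 0.3, 1.8])
        m = 100.0 * normal_grid().weights
        p = response_probability(a0[:, None], b0[:, None], grid_points[None, :])
        counts = ExpectedCounts(r=m[None, :] * p, m=m)
        a_hat, b_hat, clamped = m_step_items(counts, grid_points, np.ones(3), np.zeros(3))
        np.testing.assert_allclose(a_hat, a0, atol=1e-6)
        np.testing.assert_allclose(b_hat, b0, atol=1e-6)
        assert not clamped.any()

    def test_symmetric_counts_give_zero_difficulty(self, grid_points):
        m = np.full(grid_points.size, 10.0)
        p = response_probability(1.0, 0.0, grid_points)
        counts = ExpectedCounts(r=(10.0 * p)[None, :], m=m)
        _, b_hat, _ = m_step_items(counts, grid_points, np.array([0.7]), np.array([0.5]))
        assert b_hat[0] == pytest.approx(0.0, abs=1e-8)

    def test_all_correct_counts_clamped_and_flagged(self, grid_points):
        m = np.full(grid_points.size, 5.0)
        counts = ExpectedCounts(r=m[None, :].copy(), m=m)  # every response correct
        a_hat, b_hat, clamped = m_step_items(counts, grid_points, np.ones(1), np.zeros(1))
        assert clamped[0]
        assert 0.05 <= a_hat[0] <= 10.0 and -10.0 <= b_hat[0] <= 10.0

    def test_weight_update_is_posterior_column_mean(self):
        post = np.array([[0.2, 0.8], [0.6, 0.4], [1.0, 0.0]])
        w = m_step_weights(post)
        np.testing.assert_allclose(w, post.mean(axis=0), atol=1e-15)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_shared_posterior_row_returned_as_weights(self):
        row = np.array([0.1, 0.3, 0.6])
        w = m_step_weights(np.tile(row, (7, 1)))
        np.testing.assert_allclose(w, row, atol=1e-12)


class TestStandardizeMetric:
    def test_identity_when_already_standard(self):
        grid = LatentGrid([-1.0, 0.0, 1.0], [0.5, 0.0, 0.5])  # mean 0, SD 1
        a, b, new = standardize_metric([1.3], [0.4], grid)
        np.testing.assert_allclose(a, [1.3], atol=1e-12)
        np.testing.assert_allclose(b, [0.4], atol=1e-12)
        np.testing.assert_allclose(new.weights, grid.weights, atol=1e-12)

    def test_probability_invariance_at_matched_quantiles(self):
        grid = normal_grid()
        w = grid.weights * np.linspace(0.5, 2.0, grid.points.size)
        grid = LatentGrid(grid.points, w / w.sum())
        a, b = np.array([1.4]), np.array([0.8])
        a2, b2, _ = standardize_metric(a, b, grid)
        mu, s = grid.mean(), grid.sd()
        z = np.linspace(-3, 3, 13)
        zp = (z - mu) / s
        np.testing.assert_allclose(a2 * (zp - b2), a * (z - b), atol=1e-10)

    def test_affine_relocation_of_mass(self):
        # a distribution with mean mu and SD s maps to one whose CDF matches
        # direct relocation of the point masses, within one grid spacing
        pts = make_grid_points()
        w = np.zeros(10)
        w[[2, 7]] = 0.5
        grid = LatentGrid(pts, w)
        mu, s = grid.mean(), grid.sd()
        _, _, new = standardize_metric(np.array([1.0]), np.array([0.0]), grid)
        relocated = (pts[[2, 7]] - mu) / s
        cdf = np.cumsum(new.weights)
        for target, level in zip(relocated, [0.5, 1.0]):
            crossing = pts[np.searchsorted(cdf, level - 1e-9)]
            assert abs(crossing - target) <= grid.spacing + 1e-9
        assert abs(new.mean()) < 0.2 and abs(new.sd() - 1.0) < 0.2

    def test_degenerate_distribution_rejected(self):
        w = np.zeros(10)
        w[4] = 1.0
        with pytest.raises(ValueError):
            standardize_metric([1.0], [0.0], LatentGrid(make_grid_points(), w))


class TestFit:
    @pytest.mark.parametrize("method", ["mml", "eh"])
    def test_loglik_trace_monotone(self, small_responses, normal_weights, method):
        x, _ = small_responses
        k = x.shape[1]
        res = fit(
            x, np.ones(k), np.zeros(k), normal_weights,
            ConvergenceSettings(criterion=1e-4, method=method),
        )
        assert np.all(np.diff(res.loglik_trace) >= -1e-8)
        assert res.converged

    def test_nested_criteria_cycle_counts(self, small_responses, normal_weights):
        x, _ = small_responses
        k = x.shape[1]
        res = fit_path(x, np.ones(k), np.zeros(k), normal_weights, [1e-2, 1e-3, 1e-4])
        cyc = [res[c].n_cycles for c in (1e-2, 1e-3, 1e-4)]
        assert cyc[0] <= cyc[1] <= cyc[2]

    def test_snapshot_equals_standalone_run(self, small_responses, normal_weights):
        # one pass with snapshots must equal a separate run per criterion
        x, _ = small_responses
        k = x.shape[1]
        path = fit_path(x, np.ones(k), np.zeros(k), normal_weights, [1e-2, 1e-3])
        solo = fit(
            x, np.ones(k), np.zeros(k), normal_weights,
            ConvergenceSettings(criterion=1e-2, method="eh"),
        )
        np.testing.assert_allclose(path[1e-2].a_hat, solo.a_hat, atol=1e-12)
        np.testing.assert_allclose(path[1e-2].b_hat, solo.b_hat, atol=1e-12)
        assert path[1e-2].n_cycles == solo.n_cycles

    @pytest.mark.skipif(not HAVE_NUMBA, reason="compiled kernel unavailable")
    def test_engines_agree(self, small_responses, normal_weights):
        x, _ = small_responses
        k = x.shape[1]
        out = {}
        for engine in ("numpy", "numba"):
            out[engine] = fit_path(
                x, np.ones(k), np.zeros(k), normal_weights, [1e-3],
                method="eh", engine=engine,
            )[1e-3]
        assert out["numpy"].n_cycles == out["numba"].n_cycles
        np.testing.assert_allclose(out["numpy"].a_hat, out["numba"].a_hat, atol=1e-8)
        np.testing.assert_allclose(out["numpy"].b_hat, out["numba"].b_hat, atol=1e-8)
        np.testing.assert_allclose(
            out["numpy"].loglik_trace, out["numba"].loglik_trace, atol=1e-6
        )

    def test_nonconvergence_returns_flagged_result(self, small_responses, normal_weights):
        x, _ = small_responses
        k = x.shape[1]
        res = fit(
            x, np.ones(k), np.zeros(k), normal_weights,
            ConvergenceSettings(criterion=1e-8, max_em_cycles=3, method="eh"),
        )
        assert not res.converged
        assert res.n_cycles == 3

    def test_parameter_recovery_large_sample(self, bank, normal_weights):
        # n = 5000, normal abilities, standard MML: mean absolute error of
        # both parameters should be well under 0.1 (averaged over seeds)
        errs_a, errs_b = [], []
        for seed in (1, 2, 3):
            ab = sample_abilities(5000, AbilitySpec("normal"), seed)
            x = generate_responses(bank, ab, seed + 100).x.astype(float)
            res = fit(
                x, np.ones(bank.k), np.zeros(bank.k), normal_weights,
                ConvergenceSettings(criterion=1e-4, method="mml"),
            )
            errs_a.append(np.abs(res.a_hat - bank.a).mean())
            errs_b.append(np.abs(res.b_hat - bank.b).mean())
        assert np.mean(errs_a) < 0.1
        assert np.mean(errs_b) < 0.1

    def test_eh_recovers_normal_latent_shape(self, bank, grid_points, normal_weights):
        # EMD between estimated weights and the binned generating sample
        # shrinks as n grows (on average over seeds)
        from ehirt.metrics import emd, sample_to_grid

        means = []
        for n in (250, 2000):
            vals = []
            for seed in (1, 2, 3):
                ab = sample_abilities(n, AbilitySpec("normal"), seed)
                x = generate_responses(bank, ab, seed + 50).x.astype(float)
                res = fit(
                    x, np.ones(bank.k), np.zeros(bank.k), normal_weights,
                    ConvergenceSettings(criterion=1e-3, method="eh"),
                )
                vals.append(emd(res.grid.weights, sample_to_grid(ab.z, grid_points), grid_points))
            means.append(np.mean(vals))
        assert means[1] < means[0]

    def test_em_cycles_runs_exact_count(self, small_responses, normal_weights):
        x, _ = small_responses
        k = x.shape[1]
        a, b, w, ll = em_cycles(x, np.ones(k), np.zeros(k), normal_weights, make_grid_points())
        assert np.isfinite(ll)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)
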