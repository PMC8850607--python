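"""Bayesian filter: kernel, likelihood, recursion, prediction, metrics."""

import numpy as np
import pytest
from scipy import stats as spstats

from perclos import (
    FeatureMatrix,
    ObservationEntry,
    PerclosSeries,
    Posterior,
    StateModel,
    bayes_filter,
    evaluate,
    likelihood,
    make_grid,
    predict_ahead,
    simulate_states,
    transition_kernel,
)
from perclos.exceptions import DomainError


def _entry(fid, alpha, beta=0.0, sigma2=0.04, selected=True):
    return ObservationEntry(
        feature_id=fid, alpha=alpha, beta=beta, sigma2=sigma2,
        p_slope=0.0, r2=0.5, selected=selected, n=50,
    )


def _oracle_filter(Y, entries, model, n_grid=4001):
    """Brute-force reference filter: direct products on a fine grid."""
    grid = np.linspace(1e-4, 1 - 1e-4, n_grid)
    h = np.arctanh(2 * grid - 1)
    jac = 2.0 / (1.0 - (2 * grid - 1) ** 2)
    sd = np.sqrt(model.sigma_eps2)
    K = spstats.norm.pdf(
        h[None, :], loc=(model.a * grid + model.b)[:, None], scale=sd
    ) * jac[None, :]
    K /= K.sum(axis=1, keepdims=True)
    p = np.full(n_grid, 1.0 / n_grid)
    out = np.empty((len(Y), n_grid))
    for t in range(len(Y)):
        pred = p @ K
        lik = np.ones(n_grid)
        for y, e in zip(Y[t], entries):
            lik *= spstats.norm.pdf(y, loc=e.alpha * grid + e.beta,
                                    scale=np.sqrt(e.sigma2))
        p = pred * lik
        p /= p.sum()
        out[t] = p
    return grid, out


def _at_coincident_points(fine_pmf, coarse_size=201, fine_size=4001):
    """Fine pmf restricted to the coarse grid points (exact subset) and
    renormalized, so both filters are compared as point-density masses."""
    stride = (fine_size - 1) // (coarse_size - 1)
    sub = fine_pmf[:, ::stride]
    return sub / sub.sum(axis=1, keepdims=True)


class TestKernel:
    def test_rows_are_distributions(self):
        K = transition_kernel(StateModel(2.0, -1.0, 0.05), make_grid(101))
        assert np.allclose(K.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(K >= 0)

    def test_zero_slope_forgets_the_past(self):
        K = transition_kernel(StateModel(0.0, 0.3, 0.02), make_grid(101))
        assert np.allclose(K, K[0][None, :])

    def test_degenerate_noise_is_nearest_point_delta(self):
        grid = make_grid(101)
        K = transition_kernel(StateModel(1.0, 0.0, 0.0), grid)
        assert np.allclose(K.sum(axis=1), 1.0)
        assert np.all((K == 0) | (K == 1))

    def test_row_matches_monte_carlo_histogram(self, table_state):
        """Kernel row vs 10^6 direct draws of the recursion, TV < 0.02."""
        grid = make_grid(201)
        K = transition_kernel(table_state, grid)
        g0 = 60  # a grid point in the populated low region
        rng = np.random.default_rng(12345)
        draws = 0.5 * (
            1 + np.tanh(table_state.a * grid[g0] + table_state.b
                        + rng.normal(0, np.sqrt(table_state.sigma_eps2), 1_000_000))
        )
        h = grid[1] - grid[0]
        edges = np.concatenate(([0.0], grid[:-1] + h / 2, [1.0]))
        hist, _ = np.histogram(draws, bins=edges)
        emp = hist / hist.sum()
        tv = 0.5 * np.abs(emp - K[g0]).sum()
        assert tv < 0.02

    def test_grid_outside_unit_interval_rejected(self, table_state):
        with pytest.raises(DomainError):
            transition_kernel(table_state, np.linspace(0.0, 1.0, 11))


class TestLikelihood:
    def test_no_features_is_flat(self):
        grid = make_grid(51)
        w = likelihood([], [], grid)
        assert np.allclose(w, 1.0)

    def test_tight_feature_concentrates_at_inverse_image(self):
        grid = make_grid(201)
        e = _entry("f", alpha=2.0, beta=0.1, sigma2=1e-8)
        y = 2.0 * 0.42 + 0.1
        w = likelihood([y], [e], grid)
        assert grid[np.argmax(w)] == pytest.approx(0.42, abs=0.005)

    def test_log_space_equals_direct_product(self):
        grid = make_grid(101)
        entries = [_entry(f"f{i}", a, b, s) for i, (a, b, s) in
                   enumerate([(1.0, 0.0, 0.04), (-0.5, 0.2, 0.09), (2.0, -0.1, 0.25)])]
        y = [0.3, 0.1, 0.5]
        w = likelihood(y, entries, grid)
        direct = np.ones(grid.size)
        for yi, e in zip(y, entries):
            direct *= spstats.norm.pdf(yi, loc=e.alpha * grid + e.beta,
                                       scale=np.sqrt(e.sigma2))
        direct /= direct.max()
        assert np.allclose(w, direct, rtol=1e-8)

    def test_missing_value_skipped(self):
        grid = make_grid(51)
        e = _entry("f", 1.0)
        assert np.allclose(likelihood([np.nan], [e], grid), 1.0)


class TestFilter:
    def test_flat_likelihood_reduces_to_chapman_kolmogorov(self, table_state):
        """With no informative features the posterior is the propagated prior."""
        L, G = 10, 101
        fm = FeatureMatrix(np.full((L, 1), np.nan), ["f"])
        post = bayes_filter(fm, [_entry("f", 1.0)], table_state, grid_size=G)
        grid = make_grid(G)
        K = transition_kernel(table_state, grid)
        p = np.full(G, 1.0 / G)
        for t in range(L):
            p = p @ K
            p /= p.sum()
            assert np.allclose(post.pmf[t], p, atol=1e-12)

    def test_matches_fine_grid_oracle(self):
        """20-step 2-feature toy vs a 4001-point brute-force filter.

        The toy state model keeps the posterior in the mid-range, several
        grid cells wide, so the comparison isolates the correctness of the
        recursion rather than grid resolution."""
        toy = StateModel(0.9, 0.05, 0.1)
        x = simulate_states(toy, 20, x0=0.5, seed=3)
        rng = np.random.default_rng(99)
        entries = [_entry("f1", 1.0, 0.0, 0.04), _entry("f2", -0.8, 0.5, 0.09)]
        Y = np.column_stack(
            [e.alpha * x.values + e.beta + rng.normal(0, np.sqrt(e.sigma2), 20)
             for e in entries]
        )
        fm = FeatureMatrix(Y, ["f1", "f2"])
        post = bayes_filter(fm, entries, toy, grid_size=201)
        _, fine = _oracle_filter(Y, entries, toy)
        sub = _at_coincident_points(fine)
        tv = 0.5 * np.abs(sub - post.pmf).sum(axis=1)
        assert tv.max() < 1e-3

    def test_causality(self, table_state):
        """Truncating the stream leaves earlier posteriors bit-identical."""
        rng = np.random.default_rng(7)
        Y = rng.normal(0.3, 0.2, size=(15, 1))
        fm_full = FeatureMatrix(Y, ["f"])
        fm_cut = FeatureMatrix(Y[:8], ["f"])
        e = [_entry("f", 1.0)]
        full = bayes_filter(fm_full, e, table_state)
        cut = bayes_filter(fm_cut, e, table_state)
        assert np.array_equal(full.pmf[:8], cut.pmf)

    def test_noise_scaling_never_shrinks_intervals(self, table_state):
        """4x observation variance keeps or widens the median interval."""
        x = simulate_states(table_state, 40, x0=0.2, seed=11)
        rng = np.random.default_rng(13)
        entries = [_entry("f1", 1.0, 0.0, 4e-4), _entry("f2", 0.5, 0.1, 4e-4)]
        Y = np.column_stack(
            [e.alpha * x.values + e.beta + rng.normal(0, np.sqrt(e.sigma2), 40)
             for e in entries]
        )
        fm = FeatureMatrix(Y, ["f1", "f2"])
        post1 = bayes_filter(fm, entries, table_state)
        wide = [
            ObservationEntry(
                feature_id=e.feature_id, alpha=e.alpha, beta=e.beta,
                sigma2=4 * e.sigma2, p_slope=0.0, r2=0.5, selected=True, n=40,
            )
            for e in entries
        ]
        post4 = bayes_filter(fm, wide, table_state)
        w1 = np.median(post1.ci_high - post1.ci_low)
        w4 = np.median(post4.ci_high - post4.ci_low)
        assert w4 >= w1

    def test_decoding_beats_constant_baseline(self, small_sessions):
        spec, sessions = small_sessions
        for s in sessions:
            sel = [e for e in s.true_entries if e.selected]
            fm = s.features.select([e.feature_id for e in sel])
            post = bayes_filter(fm, sel, spec.state)
            rmse = evaluate(post, s.perclos)["rmse"]
            baseline = np.sqrt(np.mean((0.5 - s.perclos.values) ** 2))
            assert rmse < baseline


class TestPredictAhead:
    def test_zero_steps_is_identity(self, table_state):
        grid = make_grid(51)
        K = transition_kernel(table_state, grid)
        row = np.full(51, 1.0 / 51)
        out = predict_ahead(row, K, 0)
        assert out.shape == (0, 51)
        assert np.allclose(row, 1.0 / 51)  # input untouched

    def test_zero_slope_converges_to_common_row(self):
        grid = make_grid(101)
        m = StateModel(0.0, 0.2, 0.05)
        K = transition_kernel(m, grid)
        row = np.zeros(101)
        row[3] = 1.0
        out = predict_ahead(row, K, 30)
        assert np.allclose(out[-1], K[0], atol=1e-12)

    def test_matches_monte_carlo_forward_simulation(self, table_state):
        grid = make_grid(201)
        K = transition_kernel(table_state, grid)
        row = np.zeros(201)
        row[50] = 0.7
        row[80] = 0.3
        n_ahead = 3
        out = predict_ahead(row, K, n_ahead)
        rng = np.random.default_rng(5)
        starts = rng.choice(grid, size=500_000, p=row)
        sd = np.sqrt(table_state.sigma_eps2)
        cur = starts
        for _ in range(n_ahead):
            cur = 0.5 * (1 + np.tanh(table_state.a * cur + table_state.b
                                     + rng.normal(0, sd, cur.size)))
        h = grid[1] - grid[0]
        edges = np.concatenate(([0.0], grid[:-1] + h / 2, [1.0]))
        hist, _ = np.histogram(cur, bins=edges)
        tv = 0.5 * np.abs(hist / hist.sum() - out[-1]).sum()
        assert tv < 0.02


class TestEvaluate:
    def _post(self, mean, lo, hi):
        n = len(mean)
        return Posterior(
            grid=np.array([0.5]), pmf=np.ones((n, 1)),
            mean=np.asarray(mean), ci_low=np.asarray(lo), ci_high=np.asarray(hi),
        )

    def test_perfect_estimate(self):
        truth = PerclosSeries(np.linspace(0.1, 0.9, 20))
        v = truth.values
        m = evaluate(self._post(v, v - 1e-6, v + 1e-6), truth)
        assert m["rmse"] == pytest.approx(0.0, abs=1e-12)
        assert m["hpd_pct"] == 100.0

    def test_full_interval_always_covers(self):
        truth = PerclosSeries(np.linspace(0.1, 0.9, 20))
        n = len(truth)
        m = evaluate(self._post(np.zeros(n), np.zeros(n), np.ones(n)), truth)
        assert m["hpd_pct"] == 100.0
        assert m["rmse"] > 0

    def test_binned_metrics_partition_the_data(self):
        truth = PerclosSeries(np.array([0.1, 0.3, 0.6, 0.9, 0.2]))
        n = len(truth)
        m = evaluate(self._post(truth.values, np.zeros(n), np.ones(n)), truth)
        assert sum(b["n"] for b in m["bins"]) == n
        assert m["bins"][0]["n"] == 2 and m["bins"][3]["n"] == 1

    def test_nan_truth_excluded_pairwise(self):
        truth = PerclosSeries(np.array([0.2, np.nan, 0.4]))
        m = evaluate(self._post([0.2, 0.9, 0.4], [0, 0, 0], [1, 1, 1]), truth)
        assert m["n"] == 2
        assert m["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_interval_calibration_on_well_specified_sessions(self):
        """Mean 95%-interval coverage over 50 generated sessions is 95 +/- 2."""
        from perclos import SyntheticSpec, generate_feature_sessions

        spec = SyntheticSpec(n_sessions=50, seed=11)
        hpds = []
        for s in generate_feature_sessions(spec):
            sel = [e for e in s.true_entries if e.selected]
            fm = s.features.select([e.feature_id for e in sel])
            post = bayes_filter(fm, sel, spec.state)
            hpds.append(evaluate(post, s.perclos)["hpd_pct"])
        assert np.mean(hpds) == pytest.approx(95.0, abs=2.0)
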