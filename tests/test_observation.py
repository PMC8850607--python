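"""Linear-Gaussian encoder fits, transform search, slope-test selection."""

import numpy as np
import pytest
from scipy import stats as spstats

from perclos import (
    ObservationEntry,
    PerclosSeries,
    fit_observation_model,
    pool_entries,
    search_transform,
    select_features,
)
from perclos.exceptions import DomainError, SingularFitError


@pytest.fixture(scope="module")
def x_series():
    rng = np.random.default_rng(2)
    return PerclosSeries(rng.uniform(0.1, 0.9, 120))


class TestFit:
    def test_exact_line(self, x_series):
        y = 2.0 * x_series.values + 1.0
        e = fit_observation_model(y, x_series)
        assert e.alpha == pytest.approx(2.0, abs=1e-12)
        assert e.beta == pytest.approx(1.0, abs=1e-12)
        assert e.sigma2 == pytest.approx(0.0, abs=1e-20)
        assert e.r2 == pytest.approx(1.0)
        assert e.p_slope == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_textbook_regression_oracle(self, x_series, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0.5 * x_series.values - 0.2, 0.3)
        e = fit_observation_model(y, x_series)
        ref = spstats.linregress(x_series.values, y)
        assert e.alpha == pytest.approx(ref.slope, rel=1e-10)
        assert e.beta == pytest.approx(ref.intercept, rel=1e-10)
        assert e.p_slope == pytest.approx(ref.pvalue, rel=1e-8)
        assert e.r2 == pytest.approx(ref.rvalue**2, rel=1e-10)

    def test_type_one_error_rate(self):
        """Independent noise features are flagged ~5% of the time."""
        rng = np.random.default_rng(77)
        x = PerclosSeries(rng.uniform(0.1, 0.9, 60))
        hits = sum(
            fit_observation_model(rng.standard_normal(60), x).p_slope < 0.05
            for _ in range(2000)
        )
        rate = hits / 2000
        assert rate == pytest.approx(0.05, abs=0.015)  # ~3 binomial sd

    def test_constant_x_singular(self):
        x = PerclosSeries(np.full(20, 0.3))
        with pytest.raises(SingularFitError):
            fit_observation_model(np.arange(20.0), x)

    def test_constant_y_degenerate_convention(self, x_series):
        e = fit_observation_model(np.full(len(x_series), 4.2), x_series)
        assert (e.alpha, e.p_slope, e.r2) == (0.0, 1.0, 0.0)

    def test_r2_invariant_alpha_equivariant_under_scaling(self, x_series):
        rng = np.random.default_rng(5)
        y = rng.normal(1.2 * x_series.values, 0.4)
        e1 = fit_observation_model(y, x_series)
        e2 = fit_observation_model(7.0 * y + 3.0, x_series)
        assert e2.r2 == pytest.approx(e1.r2, rel=1e-10)
        assert e2.alpha == pytest.approx(7.0 * e1.alpha, rel=1e-10)

    def test_residual_acf1_detects_autocorrelation(self, x_series):
        rng = np.random.default_rng(8)
        n = len(x_series)
        ar = np.zeros(n)
        for i in range(1, n):
            ar[i] = 0.9 * ar[i - 1] + rng.standard_normal()
        e = fit_observation_model(ar, x_series)
        assert e.resid_acf1 > 0.5
        e_white = fit_observation_model(rng.standard_normal(n), x_series)
        assert abs(e_white.resid_acf1) < 0.3


class TestTransformSearch:
    def test_log_recovers_exponential_relation(self, x_series):
        y = np.exp(3.0 * x_series.values + 0.5)
        e = search_transform(y, x_series)
        assert e.transform == "log"
        assert e.alpha == pytest.approx(3.0, abs=1e-10)
        assert e.beta == pytest.approx(0.5, abs=1e-10)

    def test_identity_kept_for_linear_feature(self, x_series):
        y = 2.0 * x_series.values - 0.3
        e = search_transform(y, x_series)
        assert e.transform == "identity"

    def test_log_skipped_for_nonpositive_feature(self, x_series):
        y = x_series.values - 0.5  # crosses zero
        e = search_transform(y, x_series)
        assert e.transform in ("identity", "exp")

    def test_log_beats_identity_on_noisy_exponential(self):
        rng = np.random.default_rng(21)
        wins = 0
        for _ in range(500):
            x = PerclosSeries(rng.uniform(0.05, 0.95, 50))
            y = np.exp(rng.normal(2.0 * x.values + 0.2, 0.3))
            ident = fit_observation_model(y, x)
            logged = fit_observation_model(y, x, transform="log")
            wins += logged.r2 > ident.r2
        assert wins / 500 >= 0.95


class TestSelection:
    def test_perfect_feature_selected(self, x_series):
        e = fit_observation_model(x_series.values.copy(), x_series)
        mask = select_features([e])
        assert mask[0] and e.selected

    def test_zero_threshold_selects_nothing(self, x_series):
        rng = np.random.default_rng(3)
        entries = [
            fit_observation_model(rng.standard_normal(len(x_series)), x_series)
            for _ in range(20)
        ]
        assert not select_features(entries, threshold=0.0).any()

    def test_noise_selection_rate_near_threshold(self):
        rng = np.random.default_rng(13)
        x = PerclosSeries(rng.uniform(0.1, 0.9, 59))
        entries = [
            fit_observation_model(rng.standard_normal(59), x) for _ in range(2000)
        ]
        rate = select_features(entries, threshold=0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.015)

    def test_bh_is_more_conservative_on_nulls(self):
        rng = np.random.default_rng(4)
        x = PerclosSeries(rng.uniform(0.1, 0.9, 60))
        entries = [
            fit_observation_model(rng.standard_normal(60), x) for _ in range(300)
        ]
        raw = select_features(entries, threshold=0.05, method="none").sum()
        bh = select_features(entries, threshold=0.05, method="bh").sum()
        assert bh <= raw

    def test_power_monotone_in_effect_size(self):
        """Selection power increases with |alpha|/sigma at fixed length."""
        rng = np.random.default_rng(17)
        power = []
        for alpha in (0.05, 0.15, 0.45):
            hits = 0
            for _ in range(300):
                x = PerclosSeries(rng.uniform(0.1, 0.9, 40))
                y = rng.normal(alpha * x.values, 0.3)
                hits += fit_observation_model(y, x).p_slope < 0.05
            power.append(hits / 300)
        assert power[0] < power[1] < power[2]


class TestPooling:
    def test_consistent_sessions_pool_to_themselves(self):
        rng = np.random.default_rng(9)
        series = {
            d: PerclosSeries(rng.uniform(0.1, 0.9, 50), session_id=d) for d in (1, 2)
        }
        tables = {
            d: [
                ObservationEntry(
                    "f", alpha=1.5, beta=0.2, sigma2=0.04, p_slope=0.0, r2=0.9,
                    selected=True, n=50, session_id=d,
                )
            ]
            for d in (1, 2)
        }
        pooled = pool_entries(tables, ["f"], series)[0]
        assert pooled.alpha == pytest.approx(1.5)
        assert pooled.sigma2 == pytest.approx(0.04)

    def test_sign_inconsistency_inflates_pooled_variance(self):
        rng = np.random.default_rng(10)
        series = {
            d: PerclosSeries(rng.uniform(0.1, 0.9, 50), session_id=d) for d in (1, 2)
        }
        tables = {
            d: [
                ObservationEntry(
                    "f", alpha=s, beta=0.0, sigma2=0.04, p_slope=0.0, r2=0.9,
                    selected=True, n=50, session_id=d,
                )
            ]
            for d, s in ((1, 1.0), (2, -1.0))
        }
        pooled = pool_entries(tables, ["f"], series)[0]
        assert pooled.alpha == pytest.approx(0.0)
        assert pooled.sigma2 > 0.04 + 0.1  # inflated by slope spread
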