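import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cotrans import (
    ColorCountTable,
    DoseSeries,
    ExpressionModel,
    SaturatedTableError,
    bootstrap_ci,
    color_count_pmf,
    estimate_lambda,
    expected_counts,
    expression_probability,
    lambda_lower_bound,
)
from cotrans.model import point_estimate

from conftest import VITRO_PRINTED, VITRO_ROWS, VIVO_PRINTED, VIVO_ROWS


def enumeration_pmf_bruteforce(lam: float, k: int = 3, m_max: int = 60) -> np.ndarray:
    """Plain O(m_max^k) enumeration over (m_1..m_k) count vectors."""
    per_color = stats.poisson.pmf(np.arange(m_max + 1), lam / k)
    assert per_color.sum() > 1 - 1e-12
    grids = np.meshgrid(*([np.arange(m_max + 1)] * k), indexing="ij")
    prob = np.ones_like(grids[0], dtype=float)
    for g in grids:
        prob = prob * per_color[g]
    n_expressed = sum((g >= 1).astype(int) for g in grids)
    return np.array([prob[n_expressed == i].sum() for i in range(k + 1)])


class TestExpressionProbability:
    def test_zero_lambda(self):
        assert expression_probability(0.0, 3) == 0.0

    def test_half(self):
        assert expression_probability(3 * math.log(2), 3) == pytest.approx(0.5, abs=1e-12)

    def test_monte_carlo_oracle(self):
        lam = 7.9
        rng = np.random.default_rng(42)
        draws = rng.poisson(lam / 3, size=1_000_000)
        freq = (draws >= 1).mean()
        p = expression_probability(lam, 3)
        se = math.sqrt(p * (1 - p) / 1_000_000)
        assert abs(p - freq) < 4 * se

    @given(
        st.floats(min_value=0, max_value=60, allow_subnormal=False),
        st.integers(min_value=2, max_value=8),
    )
    def test_range(self, lam, k):
        p = expression_probability(lam, k)
        assert 0 <= p < 1
        assert (p == 0) == (lam == 0)

    @given(st.floats(min_value=0.01, max_value=50))
    def test_strictly_increasing(self, lam):
        assert expression_probability(lam * 1.01, 3) > expression_probability(lam, 3)

    @pytest.mark.parametrize("lam,k", [(-0.1, 3), (1.0, 1), (math.nan, 3)])
    def test_invalid(self, lam, k):
        with pytest.raises(ValueError):
            expression_probability(lam, k)


class TestColorCountPmf:
    def test_zero_lambda(self):
        np.testing.assert_allclose(color_count_pmf(ExpressionModel(0.0)), [1, 0, 0, 0])

    def test_symmetric_binomial(self):
        lam = -3 * math.log(0.5)  # p = 0.5
        np.testing.assert_allclose(
            color_count_pmf(ExpressionModel(lam)), [1 / 8, 3 / 8, 3 / 8, 1 / 8], atol=1e-12
        )

    def test_enumeration_oracle_lam5(self):
        np.testing.assert_allclose(
            color_count_pmf(ExpressionModel(5.0)), enumeration_pmf_bruteforce(5.0), atol=1e-10
        )

    @pytest.mark.parametrize("lam", [0.5, 2.0, 5.0, 10.0, 20.0])
    def test_enumeration_oracle_grid(self, lam):
        np.testing.assert_allclose(
            color_count_pmf(ExpressionModel(lam)), enumeration_pmf_bruteforce(lam), atol=1e-10
        )

    @given(st.floats(min_value=0, max_value=40), st.integers(min_value=2, max_value=6))
    def test_sums_to_one(self, lam, k):
        assert color_count_pmf(ExpressionModel(lam, k)).sum() == pytest.approx(1.0, abs=1e-9)


class TestEstimateLambda:
    @pytest.mark.parametrize(
        "counts,printed",
        [(VITRO_ROWS[l], v) for l, v in VITRO_PRINTED.items()]
        + [(VIVO_ROWS[l], v) for l, v in VIVO_PRINTED.items()],
    )
    def test_reference_tables(self, counts, printed):
        est = estimate_lambda(ColorCountTable(counts))
        assert round(est.lambda_hat, 1) == printed

    def test_all_zero(self):
        est = estimate_lambda(ColorCountTable((100, 0, 0, 0)))
        assert est.lambda_hat == 0.0
        assert not est.saturated

    def test_saturated(self):
        est = estimate_lambda(ColorCountTable((0, 0, 0, 1791)))
        assert est.saturated
        assert math.isinf(est.lambda_hat)

    def test_empty_table(self):
        with pytest.raises(ValueError, match="N must be > 0"):
            estimate_lambda(ColorCountTable((0, 0, 0, 0)))

    def test_forward_inverse_identity(self):
        for lam in np.linspace(0.4, 40.0, 100):
            ec = expected_counts(ExpressionModel(lam), 1000)
            assert point_estimate(ec) == pytest.approx(lam, rel=1e-9)

    def test_forward_inverse_k4(self):
        ec = expected_counts(ExpressionModel(7.0, k=4), 500)
        assert point_estimate(ec) == pytest.approx(7.0, rel=1e-9)

    @given(
        st.lists(st.integers(min_value=0, max_value=500), min_size=4, max_size=4).filter(
            lambda r: sum(r) > 0
        )
    )
    def test_monotone_in_s(self, r):
        table = ColorCountTable(tuple(r))
        est = estimate_lambda(table)
        # bump one cell up a class -> S increases by 1 at fixed N
        if r[0] > 0:
            bumped = (r[0] - 1, r[1] + 1, r[2], r[3])
            est2 = estimate_lambda(ColorCountTable(bumped))
            if math.isfinite(est.lambda_hat) and math.isfinite(est2.lambda_hat):
                assert est2.lambda_hat > est.lambda_hat


class TestExpectedCounts:
    def test_zero_lambda(self):
        np.testing.assert_allclose(expected_counts(ExpressionModel(0.0), 100), [100, 0, 0, 0])

    def test_zero_cells(self):
        np.testing.assert_allclose(expected_counts(ExpressionModel(3.0), 0), [0, 0, 0, 0])

    def test_matches_reference_within_sampling_error(self, vitro_mid):
        n = vitro_mid.n_cells
        expected = expected_counts(ExpressionModel(12.41), n)
        observed = np.asarray(vitro_mid.counts, dtype=float)
        pmf = expected / n
        se = np.sqrt(n * pmf * (1 - pmf))
        # 4 SE with a small-count floor: classes are correlated and lambda was
        # itself fit from these counts, so 3 SE per class is slightly too tight
        assert np.all(np.abs(observed - expected) <= 4 * np.maximum(se, 3.0))


class TestBootstrapCI:
    def test_contains_point_estimate(self, vitro_low):
        est = bootstrap_ci(vitro_low, n_boot=5000, seed=123)
        assert est.ci_low <= 7.877 <= est.ci_high
        assert est.ci_low == pytest.approx(7.88, abs=0.5)

    def test_deterministic_given_seed(self, vitro_low):
        a = bootstrap_ci(vitro_low, n_boot=1000, seed=5)
        b = bootstrap_ci(vitro_low, n_boot=1000, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_degenerate_table(self):
        est = bootstrap_ci(ColorCountTable((50, 0, 0, 0)), n_boot=200, seed=0)
        assert (est.ci_low, est.ci_high) == (0.0, 0.0)

    def test_saturated_rejected(self, vitro_saturated):
        with pytest.raises(SaturatedTableError):
            bootstrap_ci(vitro_saturated, n_boot=100, seed=0)

    def test_coverage_smoke(self):
        # small-scale coverage check; the full 500-replicate version is an
        # acceptance criterion
        lam_true, n = 10.0, 2000
        rng = np.random.default_rng(2024)
        pmf = color_count_pmf(ExpressionModel(lam_true))
        hits = 0
        reps = 60
        for i in range(reps):
            counts = rng.multinomial(n, pmf)
            est = bootstrap_ci(ColorCountTable(tuple(counts)), n_boot=2000, seed=i)
            hits += est.ci_low <= lam_true <= est.ci_high
        assert hits / reps > 0.85


class TestLambdaLowerBound:
    def test_zero_event_closed_form(self, vitro_saturated):
        # for m = 0 the bound solves (p^k)^N = alpha
        est = lambda_lower_bound(vitro_saturated, alpha=0.05)
        n = vitro_saturated.n_cells
        p = expression_probability(est.lambda_hat, 3)
        assert (p**3) ** n == pytest.approx(0.05, rel=1e-6)
        assert est.method == "lower_bound_binomial"
        assert est.saturated

    def test_monte_carlo_oracle(self, vitro_saturated):
        est = lambda_lower_bound(vitro_saturated, alpha=0.05)
        rng = np.random.default_rng(77)
        n = vitro_saturated.n_cells
        p3 = expression_probability(est.lambda_hat, 3) ** 3
        # 10^4 simulated experiments: >= 1 non-three-color cell in ~95% of runs
        non_all = rng.binomial(n, 1 - p3, size=10_000)
        frac = (non_all >= 1).mean()
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_conservative_at_smaller_alpha(self, vitro_saturated):
        # a stricter (smaller alpha) bound must be lower, i.e. more conservative:
        # the solved CDF is increasing in lambda, so the root increases with alpha
        lb05 = lambda_lower_bound(vitro_saturated, alpha=0.05).lambda_hat
        lb20 = lambda_lower_bound(vitro_saturated, alpha=0.20).lambda_hat
        assert lb05 < lb20

    def test_increasing_in_n(self):
        lb_small = lambda_lower_bound(ColorCountTable((0, 0, 0, 500)), alpha=0.05).lambda_hat
        lb_large = lambda_lower_bound(ColorCountTable((0, 0, 0, 5000)), alpha=0.05).lambda_hat
        assert lb_large > lb_small

    def test_no_all_color_cells(self):
        with pytest.raises(ValueError, match="no all-color cells"):
            lambda_lower_bound(ColorCountTable((100, 0, 0, 0)), alpha=0.05)

    def test_extrapolation(self, vitro_low, vitro_mid):
        series = DoseSeries(((1e10, vitro_low), (5e10, vitro_mid)))
        est = lambda_lower_bound(series, method="extrapolation", target_dose=5e11)
        assert est.method == "lower_bound_extrapolation"
        assert math.isfinite(est.lambda_hat)
        assert est.lambda_hat > 0
        # two-point fit is closed-form: slope from the two log-log points
        f2a, f2b = 184 / 1750, 52 / 1773
        slope = math.log(f2b / f2a) / math.log(5e10 / 1e10)
        f2_pred = math.exp(math.log(f2b) + slope * math.log(5e11 / 5e10))
        p = expression_probability(est.lambda_hat, 3)
        assert 3 * p**2 * (1 - p) == pytest.approx(f2_pred, rel=1e-6)
        assert p > 2 / 3  # high-lambda branch

    def test_extrapolation_needs_two_doses(self, vitro_low):
        with pytest.raises(ValueError):
            lambda_lower_bound(
                DoseSeries(((1e10, vitro_low),)), method="extrapolation", target_dose=5e11
            )


class TestParameterRecovery:
    @pytest.mark.parametrize("lam", [1.0, 5.0, 10.0, 20.0])
    def test_recovery_at_large_n(self, lam):
        from conftest import asymptotic_sd

        n = 100_000
        rng = np.random.default_rng(int(lam * 100))
        m = rng.poisson(lam / 3, size=(n, 3))
        n_colors = (m >= 1).sum(axis=1)
        counts = np.bincount(n_colors, minlength=4)
        est = estimate_lambda(ColorCountTable(tuple(counts)))
        assert abs(est.lambda_hat - lam) <= 3 * asymptotic_sd(lam, n)


class TestColorCountTable:
    def test_invariants(self):
        t = ColorCountTable((1, 2, 3, 4))
        assert t.k == 3
        assert t.n_cells == 10
        assert t.expressed_color_total == 2 + 6 + 12

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ColorCountTable((-1, 0, 0, 2))

    def test_k_too_small(self):
        with pytest.raises(ValueError):
            ColorCountTable((1, 2))

    def test_dose_series_ordering(self, vitro_low, vitro_mid):
        with pytest.raises(ValueError, match="strictly increasing"):
            DoseSeries(((5e10, vitro_mid), (1e10, vitro_low)))
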