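"""Weighted κ, band classification, paired t-tests, sample-size search."""

import numpy as np
import pytest
from scipy import special

from ductcpr.grid import DegenerateInputError
from ductcpr.stats import (
    InfeasibleError,
    RatingTable,
    classify_kappa,
    disagreement_weights,
    kappa_from_counts,
    kappa_sample_size,
    paired_t_test,
    simulate_rating_pairs,
    summarize_scores,
    weighted_kappa,
)


def _table_from_counts(counts, categories):
    a, b = [], []
    for i, ci in enumerate(categories):
        for j, cj in enumerate(categories):
            a += [ci] * int(counts[i][j])
            b += [cj] * int(counts[i][j])
    return RatingTable.from_scores(a, b, categories)


class TestWeightedKappa:
    def test_perfect_agreement_is_one(self):
        t = RatingTable.from_scores([1, 2, 3, 4, 4, 3], [1, 2, 3, 4, 4, 3])
        for scheme in ("linear", "quadratic"):
            assert weighted_kappa(t, scheme).kappa == pytest.approx(1.0)

    def test_two_by_two_matches_hand_expanded_formula(self):
        # counts [[20, 5], [10, 15]] over 50 cases, 2 categories.
        # po_w = (5 + 10)/50 = 0.3 ; pe_w = 0.5*0.4 + 0.5*0.6 = 0.5
        # kappa = 1 - 0.3/0.5 = 0.4 (same for linear and quadratic at k=2)
        t = _table_from_counts([[20, 5], [10, 15]], (1, 2))
        assert abs(weighted_kappa(t, "linear").kappa - 0.4) < 1e-12
        assert abs(weighted_kappa(t, "quadratic").kappa - 0.4) < 1e-12

    def test_case_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 5, 60)
        b = np.clip(a + rng.integers(-1, 2, 60), 1, 4)
        t1 = RatingTable.from_scores(a, b)
        perm = rng.permutation(60)
        t2 = RatingTable.from_scores(a[perm], b[perm])
        assert weighted_kappa(t1).kappa == pytest.approx(weighted_kappa(t2).kappa)

    def test_category_reversal_invariance(self):
        rng = np.random.default_rng(9)
        a = rng.integers(1, 5, 80)
        b = np.clip(a + rng.integers(-1, 2, 80), 1, 4)
        k1 = weighted_kappa(RatingTable.from_scores(a, b), "linear").kappa
        k2 = weighted_kappa(RatingTable.from_scores(5 - a, 5 - b), "linear").kappa
        assert k1 == pytest.approx(k2)

    def test_ci_brackets_kappa_and_is_seeded(self):
        rng = np.random.default_rng(5)
        a = rng.integers(1, 5, 100)
        b = np.where(rng.random(100) < 0.7, a, rng.integers(1, 5, 100))
        r1 = weighted_kappa(RatingTable.from_scores(a, b), seed=7)
        r2 = weighted_kappa(RatingTable.from_scores(a, b), seed=7)
        assert r1.ci_low <= r1.kappa <= r1.ci_high
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_degenerate_identical_pair_table_raises(self):
        t = RatingTable.from_scores([2] * 10, [2] * 10)
        with pytest.raises(DegenerateInputError):
            weighted_kappa(t)

    def test_independent_raters_give_kappa_near_zero(self):
        # 1000 simulated independent cohorts: mean kappa within ±0.02 of 0
        rng = np.random.default_rng(17)
        m = np.array([0.1, 0.2, 0.3, 0.4])
        a, b = simulate_rating_pairs(100, m, 0.0, rng, size=1000)
        w = disagreement_weights(4, "linear")
        flat = a * 4 + b
        counts = np.stack(
            [np.bincount(row, minlength=16).reshape(4, 4) for row in flat]
        )
        kappas = kappa_from_counts(counts, w)
        assert abs(np.nanmean(kappas)) < 0.02


class TestClassifyKappa:
    @pytest.mark.parametrize(
        "kappa,band",
        [
            (0.796, "good"),
            (0.758, "good"),
            (0.8, "good"),
            (0.800001, "excellent"),
            (0.2, "poor"),
            (0.200001, "fair"),
            (0.4, "fair"),
            (0.6, "moderate"),
            (0.0, "poor"),
            (1.0, "excellent"),
            (-0.3, "poor"),
        ],
    )
    def test_band_boundaries(self, kappa, band):
        assert classify_kappa(kappa) == band

    def test_out_of_range_rejected(self):
        for bad in (-1.5, 1.5):
            with pytest.raises(ValueError):
                classify_kappa(bad)

    def test_below_chance_flag_on_result(self):
        t = RatingTable.from_scores([1, 2, 1, 2, 1, 2], [2, 1, 2, 1, 2, 1], (1, 2))
        r = weighted_kappa(t)
        assert r.kappa < 0 and r.below_chance and r.band == "poor"


class TestPairedT:
    def test_matches_closed_form(self):
        a, b = [1.0, 2, 3, 4, 5], [0.0, 0, 0, 0, 0]
        r = paired_t_test(a, b)
        d = np.array(a) - np.array(b)
        t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_exp = 2 * (1 - special.stdtr(len(d) - 1, abs(t_exp)))
        assert r.t_statistic == pytest.approx(t_exp, rel=1e-12)
        assert r.p_value == pytest.approx(p_exp, rel=1e-10)
        assert r.n == 5 and r.mean_difference == pytest.approx(3.0)

    def test_swapping_sides_negates_t_preserves_p(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 2, 20)
        b = a + rng.normal(0.5, 1, 20)
        r1, r2 = paired_t_test(a, b), paired_t_test(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_constant_shift_is_degenerate(self):
        a = np.arange(10.0)
        with pytest.raises(DegenerateInputError):
            paired_t_test(a + 3.0, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1, 2, 3], [1, 2])


class TestSampleSize:
    M = np.array([0.05, 0.1, 0.25, 0.6])

    def test_threshold_at_or_above_assumed_kappa_infeasible(self):
        with pytest.raises(InfeasibleError):
            kappa_sample_size(0.5, self.M, threshold=0.6)

    def test_deterministic_given_seed(self):
        kw = dict(
            marginal_probs=self.M, threshold=0.6, seed=3,
            n_grid=(20, 40, 80), n_cohorts=40, n_boot=200,
        )
        assert kappa_sample_size(0.9, **kw) == kappa_sample_size(0.9, **kw)

    def test_stronger_agreement_needs_no_more_cases(self):
        kw = dict(
            marginal_probs=self.M, threshold=0.6, seed=3,
            n_grid=(20, 30, 50, 80, 120, 200), n_cohorts=40, n_boot=200,
        )
        n_hi = kappa_sample_size(0.95, **kw)
        n_lo = kappa_sample_size(0.80, **kw)
        assert n_hi <= n_lo

    def test_simulated_pairs_hit_requested_kappa(self):
        rng = np.random.default_rng(8)
        a, b = simulate_rating_pairs(200, self.M, 0.75, rng, size=400)
        w = disagreement_weights(4, "linear")
        flat = a * 4 + b
        counts = np.stack(
            [np.bincount(row, minlength=16).reshape(4, 4) for row in flat]
        )
        assert np.nanmean(kappa_from_counts(counts, w)) == pytest.approx(0.75, abs=0.02)


class TestSummarize:
    def test_all_good_scores(self):
        t = RatingTable.from_scores([4] * 10, [4] * 10)
        s = summarize_scores(t)
        assert s["method_a"]["mean"] == 4.0

    def test_counts_imply_mean(self):
        # grade counts (0, 2, 22, 76) over 100 cases -> mean 3.74
        scores = [2] * 2 + [3] * 22 + [4] * 76
        t = RatingTable.from_scores(scores, scores)
        s = summarize_scores(t)
        assert s["method_a"]["counts"] == {1: 0, 2: 2, 3: 22, 4: 76}
        assert s["method_a"]["mean"] == pytest.approx(3.74)

    def test_counts_sum_to_case_count(self):
        rng = np.random.default_rng(1)
        t = RatingTable.from_scores(rng.integers(1, 5, 57), rng.integers(1, 5, 57))
        s = summarize_scores(t)
        assert sum(s["method_b"]["counts"].values()) == 57


def test_rating_table_rejects_out_of_scale_scores():
    with pytest.raises(ValueError, match="outside"):
        RatingTable.from_scores([1, 5], [2, 2])


def test_rating_table_csv_round_trip(tmp_path):
    t = RatingTable.from_scores([1, 2, 3, 4], [4, 3, 2, 1])
    f = tmp_path / "ratings.csv"
    t.to_csv(f)
    back = RatingTable.from_csv(f)
    assert np.array_equal(back.score_a, t.score_a)
    assert np.array_equal(back.score_b, t.score_b)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st  # noqa: E402

_scores = st.lists(st.integers(1, 4), min_size=4, max_size=60)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(a=_scores, b=_scores, perm_seed=st.integers(0, 2**16))
def test_kappa_bounded_and_permutation_invariant(a, b, perm_seed):
    n = min(len(a), len(b))
    a, b = np.asarray(a[:n]), np.asarray(b[:n])
    t = RatingTable.from_scores(a, b)
    try:
        k1 = weighted_kappa(t, n_boot=10).kappa
    except DegenerateInputError:
        return
    assert k1 <= 1.0 + 1e-12
    perm = np.random.default_rng(perm_seed).permutation(n)
    k2 = weighted_kappa(RatingTable.from_scores(a[perm], b[perm]), n_boot=10).kappa
    assert k1 == pytest.approx(k2, abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(steps=st.lists(st.floats(0.01, 5.0), min_size=1, max_size=50))
def test_polyline_length_telescopes_over_arbitrary_steps(steps):
    from ductcpr.cpr import measure_mpd_length
    from ductcpr.path import CenterlinePath

    x = np.concatenate([[0.0], np.cumsum(steps)])
    pts = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    m = measure_mpd_length(CenterlinePath(pts))
    assert m.total_mm == pytest.approx(float(sum(steps)), rel=1e-9)
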