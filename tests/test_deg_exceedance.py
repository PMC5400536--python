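import itertools
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riskpath.deg_exceedance import (
    ReferenceInterval,
    call_degs,
    compute_reference_interval,
    deg_table,
    exceedance_score,
    fdr_correct,
    mean_difference_test,
    permutation_pvalues,
    reference_intervals,
)
from riskpath.io_preprocess import zscore_normalize
from .conftest import make_matrix


class TestReferenceInterval:
    def test_zero_sd_collapses_to_point(self):
        iv = compute_reference_interval([1.0, 1.0, 1.0])
        assert iv.xmin == iv.xmax == 1.0

    def test_standard_values_give_pm_196(self):
        # mean 0, population SD 1
        iv = compute_reference_interval([-1.0, 1.0])
        assert iv.xmin == pytest.approx(-1.96)
        assert iv.xmax == pytest.approx(1.96)

    def test_width_equals_2k_sd(self, rng):
        v = rng.standard_normal(200) * 3.1 + 0.7
        iv = compute_reference_interval(v)
        assert iv.xmax - iv.xmin == pytest.approx(2 * 1.96 * v.std(), abs=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            compute_reference_interval([1.0])


class TestExceedanceScore:
    INTERVAL = ReferenceInterval("g", 0.0, 1.0, -1.96, 1.96)

    def test_worked_arithmetic(self):
        score, signed = exceedance_score([2.5, 0.0, -3.0], self.INTERVAL)
        assert score == pytest.approx(0.54 + 1.04)
        assert signed == pytest.approx(0.54 - 1.04)

    def test_inside_interval_scores_zero(self):
        assert exceedance_score([0.0, 1.5, -1.9], self.INTERVAL) == (0.0, 0.0)

    def test_empty_case_vector(self):
        assert exceedance_score([], self.INTERVAL) == (0.0, 0.0)

    def test_matches_elementwise_loop(self, rng):
        cases = rng.standard_normal(1000) * 2
        score, signed = exceedance_score(cases, self.INTERVAL)
        s = sg = 0.0
        for x in cases:
            if x > 1.96:
                s += x - 1.96
                sg += x - 1.96
            elif x < -1.96:
                s += -1.96 - x
                sg += x - (-1.96)
        assert score == pytest.approx(s, abs=1e-9)
        assert signed == pytest.approx(sg, abs=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        st.floats(-10, 10),
    )
    def test_translation_equivariance(self, cases, shift):
        base = ReferenceInterval("g", 0.0, 1.0, -1.5, 1.5)
        moved = ReferenceInterval("g", shift, 1.0, -1.5 + shift, 1.5 + shift)
        s0, g0 = exceedance_score(cases, base)
        s1, g1 = exceedance_score([c + shift for c in cases], moved)
        assert s1 == pytest.approx(s0, rel=1e-9, abs=1e-9)
        assert g1 == pytest.approx(g0, rel=1e-9, abs=1e-9)

    def test_monotone_in_values_above_xmax(self):
        s0, _ = exceedance_score([2.5, 0.0], self.INTERVAL)
        s1, _ = exceedance_score([2.6, 0.0], self.INTERVAL)
        assert s1 > s0


def exhaustive_pvalue(values, n_good, k=1.96):
    """Independent oracle: enumerate every split of the samples into a
    control set of size n_good and a case set of the rest; p = fraction of
    splits whose exceedance score ties or beats the observed split's."""
    values = list(values)
    n = len(values)

    def split_score(good_idx):
        good = [values[i] for i in good_idx]
        case = [values[i] for i in range(n) if i not in good_idx]
        mu = statistics.fmean(good)
        sd = (sum((x - mu) ** 2 for x in good) / len(good)) ** 0.5
        lo, hi = mu - k * sd, mu + k * sd
        return sum(hi_ex(x, lo, hi) for x in case)

    def hi_ex(x, lo, hi):
        if x > hi:
            return x - hi
        if x < lo:
            return lo - x
        return 0.0

    observed = split_score(tuple(range(n_good)))
    splits = list(itertools.combinations(range(n), n_good))
    hits = sum(split_score(s) >= observed - 1e-12 for s in splits)
    return hits / len(splits)


class TestPermutationPvalues:
    def test_constant_gene_gets_p_one(self):
        m = make_matrix([[2.0] * 8], ["good"] * 5 + ["poor"] * 3)
        p = permutation_pvalues(m, n_perm=200, seed=1)
        assert p.iloc[0] == 1.0

    def test_dominant_gene_hits_add_one_floor(self, rng):
        # 10 tight controls, 10 far outliers: any shuffle that moves an
        # outlier into the control set blows up the interval, so the observed
        # score is the strict maximum and p hits the add-one floor
        good = rng.normal(0.0, 0.1, size=10)
        poor = rng.normal(50.0, 2.0, size=10)
        m = make_matrix([np.concatenate([good, poor])], ["good"] * 10 + ["poor"] * 10)
        p = permutation_pvalues(m, n_perm=500, seed=2)
        assert p.iloc[0] == pytest.approx(1 / 501)

    def test_agrees_with_exhaustive_enumeration(self, rng):
        vals = rng.standard_normal((6, 5)) * [[1], [2], [1], [3], [1], [2]]
        m = make_matrix(vals, ["good", "good", "good", "poor", "poor"])
        p = permutation_pvalues(m, n_perm=10000, seed=3)
        for i in range(6):
            oracle = exhaustive_pvalue(list(vals[i]), n_good=3)
            assert p.iloc[i] == pytest.approx(oracle, abs=0.02)

    def test_seed_reproducibility(self, small_cohort_matrix):
        p1 = permutation_pvalues(small_cohort_matrix, n_perm=100, seed=9)
        p2 = permutation_pvalues(small_cohort_matrix, n_perm=100, seed=9)
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())

    def test_empty_poor_group_rejected(self, rng):
        m = make_matrix(rng.standard_normal((3, 4)), ["good"] * 4)
        with pytest.raises(ValueError):
            permutation_pvalues(m, n_perm=10, seed=0)


class TestFdrCorrect:
    def test_bh_closed_form(self):
        assert np.allclose(fdr_correct([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_correct([0.2])[0] == pytest.approx(0.2)

    def test_matches_independent_step_up_loop(self, rng):
        p = rng.uniform(size=500)
        q = fdr_correct(p)
        # independent BH: q_(i) = min_{j>=i} p_(j) * m / j
        order = np.argsort(p)
        m = len(p)
        q_oracle = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            q_oracle[idx] = running
        assert np.allclose(q, q_oracle, atol=1e-12)


class TestCallDegs:
    def test_null_matrix_yields_no_calls(self, rng):
        m = make_matrix(rng.standard_normal((300, 25)), ["good"] * 18 + ["poor"] * 7)
        degs = call_degs(zscore_normalize(m), n_perm=300, seed=5)
        assert len(degs) <= 3  # FDR keeps the null clean

    def test_subgroup_shift_power_run(self, rng):
        # 10 genes shifted +4z in 5 of 15 poor samples; the planted cohort
        # lifts the BH threshold clear of the B=1000 add-one floor
        vals = rng.standard_normal((40, 53))
        for g in range(10):
            carriers = rng.choice(np.arange(38, 53), size=5, replace=False)
            vals[g, carriers] += 4.0
        m = make_matrix(vals, ["good"] * 38 + ["poor"] * 15)
        degs = call_degs(zscore_normalize(m), n_perm=1000, seed=6)
        called_up = [f"g{i}" for i in range(10) if f"g{i}" in degs.index
                     and degs.loc[f"g{i}", "direction"] == "up"]
        assert len(called_up) >= 8

    def test_within_interval_mean_shift_not_called(self, rng):
        vals = rng.standard_normal((200, 53))
        vals[0, 38:] += 0.5  # all poor samples, stays inside the interval
        m = make_matrix(vals, ["good"] * 38 + ["poor"] * 15)
        degs = call_degs(zscore_normalize(m), n_perm=1000, seed=7)
        assert "g0" not in degs.index
        # ... while the mean-difference comparator sees it
        t = mean_difference_test(zscore_normalize(m))
        assert t.loc["g0", "p_value"] < 0.2

    def test_direction_column_consistency(self, rng):
        m = make_matrix(rng.standard_normal((50, 20)), ["good"] * 14 + ["poor"] * 6)
        table = deg_table(zscore_normalize(m), n_perm=200, seed=8)
        sig = table["q_value"] < 0.05
        assert (table.loc[~sig, "direction"] == "none").all()
        up = table["direction"] == "up"
        assert (table.loc[up, "signed_score"] > 0).all()


def test_reference_intervals_match_per_gene_calls(small_cohort_matrix):
    frame = reference_intervals(small_cohort_matrix)
    good = small_cohort_matrix.values[
        small_cohort_matrix.samples_in_group("good")
    ]
    for g in list(frame.index)[:5]:
        iv = compute_reference_interval(good.loc[g].to_numpy(), g)
        assert frame.loc[g, "xmin"] == pytest.approx(iv.xmin, abs=1e-12)
        assert frame.loc[g, "xmax"] == pytest.approx(iv.xmax, abs=1e-12)
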