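import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score

from diffpairct import (DiffPairRule, compute_diffpairs, roc_auc, screen_all,
                        select_cutoff, unique_mirnas, welch_t_test)
from diffpairct.screen import ScreenRecord, screen_table

from conftest import make_ct, make_meta


# ---------------------------------------------------------------- oracles
def welch_oracle(x, y):
    """Textbook Welch formula: t = (x̄−ȳ)/√(s²x/nx + s²y/ny), df by
    Welch–Satterthwaite, two-sided p from the t distribution."""
    from scipy.stats import t as tdist
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (vx**2 / (nx**2 * (nx - 1)) + vy**2 / (ny**2 * (ny - 1)))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def auc_oracle(values, labels):
    """Brute-force double loop over all (cancer, control) outcome pairs."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    ca, co = values[labels], values[~labels]
    wins = ties = 0
    for u in ca:
        for v in co:
            if u > v:
                wins += 1
            elif u == v:
                ties += 1
    return (wins + 0.5 * ties) / (len(ca) * len(co))


def cutoff_oracle(values, labels):
    """Exhaustive search over all midpoints (±inf sentinels), both
    directions; returns the best achievable sens+spec."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    uniq = np.unique(values)
    cuts = [-np.inf, np.inf] + [(uniq[i] + uniq[i + 1]) / 2
                                for i in range(len(uniq) - 1)]
    best = -1.0
    for c in cuts:
        for above in (True, False):
            pred = values > c if above else values < c
            sens = (pred & labels).sum() / labels.sum()
            spec = (~pred & ~labels).sum() / (~labels).sum()
            best = max(best, sens + spec)
    return best


# ---------------------------------------------------------------- Welch t
class TestWelchTTest:
    def test_matches_textbook_formula(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0, 5.0]
        got = welch_t_test(x, y)
        exp = welch_oracle(x, y)
        np.testing.assert_allclose(got, exp, rtol=1e-12)

    def test_identical_groups_t_zero_p_one(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_swap_negates_t_keeps_df_p(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0, 5.0]
        t1, df1, p1 = welch_t_test(x, y)
        t2, df2, p2 = welch_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_equal_means_convention(self):
        t, df, p = welch_t_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_t_test([1.0], [1.0, 2.0])

    @given(st.lists(st.integers(-500, 500), min_size=3, max_size=8,
                    unique=True).map(lambda L: [v / 100 for v in L]),
           st.lists(st.integers(-500, 500), min_size=3, max_size=8,
                    unique=True).map(lambda L: [v / 100 for v in L]))
    def test_property_matches_oracle(self, x, y):
        got = welch_t_test(x, y)
        exp = welch_oracle(x, y)
        np.testing.assert_allclose(got, exp, rtol=1e-9)


# ---------------------------------------------------------------- ROC AUC
class TestRocAuc:
    def test_perfect_separation(self):
        auc, orient = roc_auc([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert auc == 1.0 and orient == "cancer_above"

    def test_all_ties_is_half(self):
        auc, _ = roc_auc([2.0] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_inverted_signal_reported_above_half(self):
        auc, orient = roc_auc([1, 2, 3, 5, 6, 7], [1, 1, 1, 0, 0, 0])
        assert auc == 1.0 and orient == "cancer_below"

    def test_random_instance_matches_brute_force(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=12)
        labels = np.array([1] * 6 + [0] * 6, bool)
        auc, orient = roc_auc(values, labels)
        exp = auc_oracle(values, labels)
        assert auc == pytest.approx(max(exp, 1 - exp), abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=30) + np.r_[np.ones(12), np.zeros(18)]
        labels = np.array([1] * 12 + [0] * 18, bool)
        auc, orient = roc_auc(values, labels)
        sk = roc_auc_score(labels, values)
        assert auc == pytest.approx(max(sk, 1 - sk), abs=1e-12)

    @given(st.lists(st.integers(0, 5), min_size=2, max_size=12),
           st.data())
    def test_exhaustive_small_instances_match_oracle(self, vals, data):
        n = len(vals)
        n_ca = data.draw(st.integers(1, n - 1))
        labels = np.array([1] * n_ca + [0] * (n - n_ca), bool)
        values = np.asarray(vals, float)
        auc, _ = roc_auc(values, labels)
        exp = auc_oracle(values, labels)
        assert auc == pytest.approx(max(exp, 1 - exp), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], [1, 1])


# ------------------------------------------------------------ select_cutoff
class TestSelectCutoff:
    def test_perfect_separation_midpoint(self):
        cut, direction, sens, spec = select_cutoff(
            [5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert cut == 4.0 and direction == "cancer_above"
        assert sens == spec == 1.0

    def test_no_information_attains_one(self):
        cut, direction, sens, spec = select_cutoff(
            [2.0, 2.0, 2.0, 2.0], [1, 0, 1, 0])
        assert sens + spec == pytest.approx(1.0)

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(17)
        for trial in range(25):
            n = 20
            values = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            cut, direction, sens, spec = select_cutoff(values, labels)
            assert sens + spec == pytest.approx(
                cutoff_oracle(values, labels), abs=1e-12)
            # the returned rule reproduces the returned sens/spec
            pred = values > cut if direction == "cancer_above" else values < cut
            assert (pred & labels).sum() / labels.sum() == pytest.approx(sens)

    @given(st.lists(st.integers(-4, 4), min_size=4, max_size=14), st.data())
    def test_achieved_sum_at_least_one(self, vals, data):
        n = len(vals)
        n_ca = data.draw(st.integers(1, n - 1))
        labels = np.array([1] * n_ca + [0] * (n - n_ca), bool)
        _, _, sens, spec = select_cutoff(np.asarray(vals, float), labels)
        assert sens + spec >= 1.0 - 1e-12

    def test_monotone_transform_preserves_auc_and_best_sum(self):
        rng = np.random.default_rng(23)
        values = rng.normal(size=16)
        labels = np.array([1] * 7 + [0] * 9, bool)
        a1, _ = roc_auc(values, labels)
        _, _, s1, p1 = select_cutoff(values, labels)
        trans = np.exp(values / 2)  # strictly increasing
        a2, _ = roc_auc(trans, labels)
        _, _, s2, p2 = select_cutoff(trans, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)
        assert s1 + p1 == pytest.approx(s2 + p2, abs=1e-12)


# ------------------------------------------------------------ DiffPairRule
class TestDiffPairRule:
    def test_boundary_classifies_control(self):
        rule = DiffPairRule(("A", "B"), 0.0, "cancer_above")
        pred = rule.classify([-1.0, 0.0, 1.0])
        assert list(pred) == [False, False, True]

    def test_flip_is_identical_classifier(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        rule = DiffPairRule(("A", "B"), 0.7, "cancer_above")
        assert np.array_equal(rule.classify(x), rule.flipped().classify(-x))

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            DiffPairRule(("A", "B"), 0.0, "up")


# ---------------------------------------------------------------- screen_all
class TestScreenAll:
    @staticmethod
    def _planted_cohort():
        """Noiseless cohort where exactly one pair separates classes."""
        rng = np.random.default_rng(31)
        n_ca, n_co, n_mir = 8, 8, 6
        ct = rng.uniform(24, 32, size=(1, n_mir)).repeat(n_ca + n_co, axis=0)
        shifts = rng.normal(0, 2.0, size=n_ca + n_co)
        ct = ct + shifts[:, None]
        ct[:n_ca, 0] += 5.0  # planted disease effect on miRNA 0
        samples = [f"s{i}" for i in range(n_ca + n_co)]
        m = make_ct(ct, samples=samples)
        meta = make_meta(samples, ["cancer"] * n_ca + ["control"] * n_co,
                         ["train"] * (n_ca + n_co))
        return m, meta

    def test_planted_pair_ranks_first_with_perfect_scores(self):
        m, meta = self._planted_cohort()
        records = screen_all(compute_diffpairs(m), meta)
        top = records[0]
        assert "miR-0" in top.rule.pair
        assert top.sens == top.spec == 1.0
        assert top.auc == 1.0

    def test_vacuous_gate_marks_all_candidates(self):
        m, meta = self._planted_cohort()
        records = screen_all(compute_diffpairs(m), meta,
                             sens_min=0.0, spec_min=0.0)
        assert all(r.is_candidate for r in records)
        assert len(records) == 6 * 5 // 2

    def test_gate_consults_sens_spec_only(self):
        m, meta = self._planted_cohort()
        records = screen_all(compute_diffpairs(m), meta)
        for r in records:
            assert r.is_candidate == (r.sens >= 0.80 and r.spec >= 0.80)

    def test_ordering_descending_sum_then_p(self):
        m, meta = self._planted_cohort()
        records = screen_all(compute_diffpairs(m), meta)
        sums = [r.sens + r.spec for r in records]
        assert sums == sorted(sums, reverse=True)

    def test_181_mirnas_yield_16290_records(self, paper_screen):
        _, _, _, records = paper_screen
        assert len(records) == 16290

    def test_planted_effect_recovered_in_paper_cohort(self, paper_screen):
        _, _, truth, records = paper_screen
        planted = set(truth.effect_mirnas)
        assert planted & set(records[0].rule.pair)

    def test_requires_both_classes_in_train(self):
        m, _ = self._planted_cohort()
        meta = make_meta(m.sample_ids, ["cancer"] * 16, ["train"] * 16)
        with pytest.raises(ValueError, match="both"):
            screen_all(compute_diffpairs(m), meta)


class TestUniqueMirnas:
    @staticmethod
    def _rec(pair):
        rule = DiffPairRule(pair, 0.0, "cancer_above")
        return ScreenRecord(rule, 0.0, 1.0, 1.0, 0.5, 1.0, 1.0, 1.0, 1.0, True)

    def test_union(self):
        recs = [self._rec(("A", "B")), self._rec(("A", "C"))]
        assert unique_mirnas(recs) == ["A", "B", "C"]

    def test_empty(self):
        assert unique_mirnas([]) == []

    def test_140_candidates_from_26_names(self):
        """140 pairs drawn from a pool of 26 names yield exactly those 26."""
        names = [f"miR-x{i}" for i in range(26)]
        all_pairs = [(names[i], names[j]) for i in range(26)
                     for j in range(i + 1, 26)]
        rng = np.random.default_rng(26)
        # force every name to appear, then fill up to 140 pairs
        chosen = [all_pairs[i * 25] for i in range(13)]
        rest = [p for p in all_pairs if p not in chosen]
        idx = rng.choice(len(rest), size=140 - len(chosen), replace=False)
        chosen += [rest[i] for i in idx]
        recs = [self._rec(p) for p in chosen]
        got = unique_mirnas(recs)
        assert len(recs) == 140
        assert got == sorted(names)


class TestScreenTable:
    def test_percentage_columns_rounded_half_away(self):
        rec = ScreenRecord(DiffPairRule(("A", "B"), 1.0, "cancer_above"),
                           2.0, 10.0, 0.01, 0.9, 0.8209, 0.845, 0.5, 0.5, True)
        table = screen_table([rec])
        assert table.loc[0, "SENS"] == 82
        assert table.loc[0, "SPEC"] == 85  # 0.845 rounds half away from zero

    def test_bh_column_is_optional_extra(self):
        recs = [ScreenRecord(DiffPairRule(("A", f"B{i}"), 0.0, "cancer_above"),
                             1.0, 5.0, p, 0.6, 0.5, 0.5, 0.5, 0.5, False)
                for i, p in enumerate([0.01, 0.02, 0.5])]
        plain = screen_table(recs)
        with_bh = screen_table(recs, add_bh=True)
        assert "p_bh" not in plain.columns
        assert "p_bh" in with_bh.columns
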