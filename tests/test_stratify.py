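import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tescope.io_core import GeneSet, ValidationError
from tescope.stratify import (
    compare_four_groups,
    compare_two_groups,
    overrepresentation,
    preranked_gsea,
    rbp_enrichment,
)


def series(values):
    return pd.Series(values, index=[f"g{i}" for i in range(len(values))], dtype=float)


class TestCompareTwoGroups:
    def test_identical_groups_not_significant(self):
        v = series(list(range(10)) * 2)
        flag = pd.Series([False] * 10 + [True] * 10, index=v.index)
        s = compare_two_groups(v, flag)
        assert s.p_value > 0.99
        assert s.mean_per_group["flag_true"] == pytest.approx(s.mean_per_group["flag_false"])

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(42)
        vals = np.concatenate([rng.normal(0, 0.1, 200), rng.normal(-1, 0.1, 200)])
        v = series(vals)
        flag = pd.Series([False] * 200 + [True] * 200, index=v.index)
        s = compare_two_groups(v, flag)
        assert s.p_value < 1e-6
        diff = s.mean_per_group["flag_true"] - s.mean_per_group["flag_false"]
        assert diff == pytest.approx(-1.0, abs=0.05)

    def test_m6a_group_te_drop_on_cohort(self, default_cohort, aged_analysis):
        """On the aged-vs-young cohort the m6A group's TE change is lower."""
        vals = aged_analysis["change"].records["log2_te_fc"]
        vals = vals[np.isfinite(vals)]
        flag = default_cohort.truth.loc[vals.index, "m6a"]
        s = compare_two_groups(vals, flag, labels=("non_m6a", "m6a"))
        assert s.mean_per_group["m6a"] < s.mean_per_group["non_m6a"]
        assert s.p_value < 0.01

    def test_small_group_rejected(self):
        v = series([1, 2, 3])
        flag = pd.Series([False, False, True], index=v.index)
        with pytest.raises(ValidationError):
            compare_two_groups(v, flag)


class TestCompareFourGroups:
    def make(self, shifts, n=150, seed=0):
        rng = np.random.default_rng(seed)
        vals, f1, f2 = [], [], []
        for (a, b), shift in shifts.items():
            vals.append(rng.normal(shift, 1.0, n))
            f1 += [a] * n
            f2 += [b] * n
        v = series(np.concatenate(vals))
        return (
            v,
            pd.Series(f1, index=v.index),
            pd.Series(f2, index=v.index),
        )

    def test_null_behaviour_and_adjustment(self):
        v, f1, f2 = self.make({(a, b): 0.0 for a in (False, True) for b in (False, True)})
        s = compare_four_groups(v, f1, f2)
        assert len(s.grouping) == 4
        assert (s.pairwise["p_bonferroni"] >= s.pairwise["p_raw"] - 1e-15).all()
        assert (s.pairwise["p_bonferroni"] <= 1.0).all()

    def test_planted_cell_shift_detected(self):
        shifts = {(False, False): 0.0, (False, True): 0.0, (True, False): 0.0,
                  (True, True): -1.0}
        v, f1, f2 = self.make(shifts, seed=1)
        s = compare_four_groups(v, f1, f2, names=("m6a", "papcpe"))
        target = "m6a+/papcpe+"
        involving = s.pairwise[
            (s.pairwise["group_a"] == target) | (s.pairwise["group_b"] == target)
        ]
        others = s.pairwise[
            (s.pairwise["group_a"] != target) & (s.pairwise["group_b"] != target)
        ]
        assert (involving["p_bonferroni"] < 0.01).all()
        assert (others["p_bonferroni"] > 0.05).all()
        assert s.p_value < 1e-10

    def test_empty_cell_listed_in_error(self):
        v = series([0.0, 1.0, 2.0, 3.0])
        f1 = pd.Series([False, False, True, True], index=v.index)
        f2 = pd.Series([False, False, False, False], index=v.index)
        with pytest.raises(ValidationError, match=r"\+"):
            compare_four_groups(v, f1, f2)

    def test_anova_reduces_to_t_test(self):
        """With two groups, F equals t^2."""
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 30)
        v = series(np.concatenate([a, b]))
        flag = pd.Series([False] * 30 + [True] * 30, index=v.index)
        t_res = compare_two_groups(v, flag)
        # pooled-variance t matches classic one-way ANOVA
        f_stat, _ = stats.f_oneway(a, b)
        t_pooled, _ = stats.ttest_ind(b, a, equal_var=True)
        assert f_stat == pytest.approx(t_pooled**2, abs=1e-9)
        # and the Welch route agrees in direction/significance
        assert np.sign(t_res.statistic) == np.sign(t_pooled)


# ---------------------------------------------------------------------------
# GSEA with exhaustive oracle
# ---------------------------------------------------------------------------

def brute_force_es(scores: pd.Series, members: set, weight: float) -> float:
    """Independent running-sum evaluation on an already-ranked series."""
    n = len(scores)
    hits = [g in members for g in scores.index]
    n_hit = sum(hits)
    total = sum(abs(s) ** weight for g, s in scores.items() if g in members)
    run, best = 0.0, 0.0
    for (g, s), is_hit in zip(scores.items(), hits):
        if is_hit:
            run += (abs(s) ** weight) / total
        else:
            run -= 1.0 / (n - n_hit)
        if abs(run) > abs(best):
            best = run
    return best


def ranked(scores):
    s = pd.Series(scores, dtype=float)
    return s[sorted(s.index, key=lambda g: (-s[g], g))]


class TestPrerankedGSEA:
    def test_single_top_hit_carries_all_weight(self):
        res = preranked_gsea({"a": 1.0, "b": 0.0}, GeneSet.from_iterable("s", ["a"]),
                             weight=1.0, n_perm=50, seed=0)
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["a"]

    def test_bottom_set_has_negative_es(self):
        scores = {f"g{i}": 10 - i for i in range(10)}
        res = preranked_gsea(scores, GeneSet.from_iterable("s", ["g8", "g9"]),
                             weight=0.0, n_perm=100, seed=0)
        assert res.es < 0
        assert set(res.leading_edge) == {"g8", "g9"}

    def test_es_matches_brute_force_five_gene_ranking(self):
        scores = {"a": 5.0, "b": 3.0, "c": 1.0, "d": -2.0, "e": -4.0}
        gs = GeneSet.from_iterable("s", ["a", "c"])
        res = preranked_gsea(scores, gs, weight=0.0, n_perm=500, seed=1)
        oracle = brute_force_es(ranked(scores), gs.members, 0.0)
        assert res.es == pytest.approx(oracle, abs=1e-12)

    def test_p_within_three_binomial_se_of_enumeration(self):
        """Permutation p vs exact enumeration over all C(5,2)=10 placements."""
        scores = {"a": 5.0, "b": 3.0, "c": 1.0, "d": -2.0, "e": -4.0}
        gs = GeneSet.from_iterable("s", ["a", "c"])
        r = ranked(scores)
        es_obs = brute_force_es(r, gs.members, 0.0)
        null = [
            brute_force_es(r, set(combo), 0.0)
            for combo in itertools.combinations(r.index, 2)
        ]
        same_sign = [e for e in null if (e >= 0) == (es_obs >= 0)]
        p_exact = sum(abs(e) >= abs(es_obs) for e in same_sign) / len(same_sign)
        n_perm = 2000
        res = preranked_gsea(scores, gs, weight=0.0, n_perm=n_perm, seed=3)
        se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
        # the +1-corrected estimator adds at most ~1/n_perm of bias
        assert abs(res.p - p_exact) <= 3 * se + 2 / n_perm

    def test_weighted_es_matches_brute_force(self):
        rng = np.random.default_rng(4)
        scores = {f"g{i}": float(v) for i, v in enumerate(rng.normal(0, 2, 30))}
        gs = GeneSet.from_iterable("s", [f"g{i}" for i in (0, 3, 7, 11, 19)])
        res = preranked_gsea(scores, gs, weight=1.0, n_perm=10, seed=0)
        oracle = brute_force_es(ranked(scores), gs.members, 1.0)
        assert res.es == pytest.approx(oracle, abs=1e-12)
        assert abs(res.es) <= 1.0

    def test_scores_outside_set_do_not_change_weighted_es(self):
        """Permuting values among non-members leaves ES unchanged."""
        rng = np.random.default_rng(8)
        base = {f"g{i}": float(i) for i in range(12)}
        gs = GeneSet.from_iterable("s", ["g2", "g5", "g9"])
        res1 = preranked_gsea(base, gs, weight=1.0, n_perm=10, seed=0)
        # swap scores between two non-members: ranking positions swap but the
        # hit/miss profile and hit weights are unchanged
        swapped = dict(base)
        swapped["g3"], swapped["g4"] = base["g4"], base["g3"]
        res2 = preranked_gsea(swapped, gs, weight=1.0, n_perm=10, seed=0)
        assert res1.es == pytest.approx(res2.es, abs=1e-12)

    def test_scaling_scores_leaves_weight0_es_unchanged(self):
        rng = np.random.default_rng(12)
        scores = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=20))}
        gs = GeneSet.from_iterable("s", ["g1", "g4", "g5"])
        r1 = preranked_gsea(scores, gs, weight=0.0, n_perm=10, seed=0)
        r2 = preranked_gsea({g: 3.7 * v for g, v in scores.items()}, gs,
                            weight=0.0, n_perm=10, seed=0)
        assert r1.es == pytest.approx(r2.es, abs=1e-12)

    def test_set_covering_all_genes_rejected(self):
        with pytest.raises(ValidationError):
            preranked_gsea({"a": 1.0, "b": 0.5},
                           GeneSet.from_iterable("s", ["a", "b"]), n_perm=10, seed=0)

    def test_deterministic_given_seed(self):
        scores = {f"g{i}": float(i % 7) for i in range(20)}
        gs = GeneSet.from_iterable("s", ["g3", "g11"])
        r1 = preranked_gsea(scores, gs, n_perm=200, seed=5)
        r2 = preranked_gsea(scores, gs, n_perm=200, seed=5)
        assert (r1.es, r1.nes, r1.p) == (r2.es, r2.nes, r2.p)


class TestOverrepresentation:
    def test_matches_hypergeometric_enumeration(self):
        """Perfectly aligned 10/10 split of a 20-gene universe."""
        universe = [f"g{i}" for i in range(20)]
        fg = universe[:10]
        gs = GeneSet.from_iterable("s", universe[:10])
        out = overrepresentation(fg, universe, [gs])
        # exact Fisher by hypergeometric enumeration: P(X >= 10) plus
        # equally-or-less-likely tables on the other side
        p_oracle = sum(
            stats.hypergeom.pmf(k, 20, 10, 10)
            for k in range(0, 11)
            if stats.hypergeom.pmf(k, 20, 10, 10)
            <= stats.hypergeom.pmf(10, 20, 10, 10) + 1e-12
        )
        assert out.loc["s", "p"] == pytest.approx(p_oracle, rel=1e-9)
        assert out.loc["s", "overlap_count"] == 10

    def test_empty_overlap_has_odds_ratio_below_one(self):
        universe = [f"g{i}" for i in range(20)]
        fg = universe[:10]
        gs = GeneSet.from_iterable("s", universe[10:])
        out = overrepresentation(fg, universe, [gs])
        assert out.loc["s", "odds_ratio"] < 1.0

    def test_single_set_fdr_equals_p(self):
        universe = [f"g{i}" for i in range(12)]
        gs = GeneSet.from_iterable("s", universe[:4])
        out = overrepresentation(universe[:6], universe, [gs])
        assert out.loc["s", "fdr"] == pytest.approx(out.loc["s", "p"])

    def test_foreground_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            overrepresentation(["x"], ["a", "b"], [GeneSet.from_iterable("s", ["a"])])

    def test_overlap_bounded(self):
        universe = [f"g{i}" for i in range(30)]
        fg = universe[:7]
        gs = GeneSet.from_iterable("s", universe[5:15])
        out = overrepresentation(fg, universe, [gs])
        assert out.loc["s", "overlap_count"] <= min(len(fg), out.loc["s", "set_in_universe"])


class TestRBPEnrichment:
    def test_planted_rbp_ranks_first(self):
        rng = np.random.default_rng(77)
        genes = [f"g{i}" for i in range(200)]
        fg = genes[:50]
        occ = pd.DataFrame(index=genes)
        occ["planted"] = [rng.random() < (0.8 if g in fg else 0.1) for g in genes]
        for j in range(5):
            occ[f"noise{j}"] = rng.random(200) < 0.3
        out = rbp_enrichment(occ, fg, genes)
        assert out.index[0] == "planted"
        assert out.iloc[0]["fdr"] < 0.01

    def test_ubiquitous_motif_not_significant(self):
        genes = [f"g{i}" for i in range(40)]
        occ = pd.DataFrame({"everywhere": [True] * 40}, index=genes)
        out = rbp_enrichment(occ, genes[:10], genes)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_zero_occurrence_motif_no_crash(self):
        genes = [f"g{i}" for i in range(40)]
        occ = pd.DataFrame({"absent": [False] * 40}, index=genes)
        out = rbp_enrichment(occ, genes[:10], genes)
        assert np.isfinite(out.iloc[0]["odds_ratio"])
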