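import numpy as np
import pandas as pd
import pytest

from tescope.efficiency import TEChange
from tescope.io_core import GeneSet, Thresholds, ValidationError
from tescope.prioritize import candidate_cascade, concordance_scatter, overlap_analysis


def te_change_from(directions: dict) -> TEChange:
    """Build a TEChange whose records carry the given direction per gene."""
    fc = {"down": -1.0, "up": 1.0, "unchanged": 0.0}
    df = pd.DataFrame(
        {
            "te_a": 1.0,
            "te_b": [2.0 ** fc[d] for d in directions.values()],
            "log2_te_fc": [fc[d] for d in directions.values()],
            "bin_a": "mid",
            "bin_b": "mid",
            "direction": list(directions.values()),
        },
        index=list(directions.keys()),
    )
    return TEChange(records=df, specific_a=[], specific_b=[])


class TestCandidateCascade:
    @pytest.fixture()
    def fixture_12(self, thresholds):
        """Twelve genes covering the flag combinations; hand enumeration:

        stage 1 (diff TE both + m6a + rip): g01 g02 g03 g04 g05 g06 -> 6
        stage 2 (down in both):             g01 g02 g03 g04         -> 4
        stage 3 (log2fc < -0.58 in both):   g01 g02                 -> 2
        """
        d1 = {
            "g01": "down", "g02": "down", "g03": "down", "g04": "down",
            "g05": "down", "g06": "up",
            "g07": "down", "g08": "down",   # not in rip / not in m6a
            "g09": "unchanged", "g10": "down", "g11": "up", "g12": "unchanged",
        }
        d2 = dict(d1)
        d2.update({"g05": "up", "g10": "unchanged", "g09": "down"})
        m6a = GeneSet.from_iterable("m6a", [f"g{i:02d}" for i in range(1, 8)] + ["g09", "g10", "g12"])
        rip = GeneSet.from_iterable("rip", [f"g{i:02d}" for i in range(1, 7)] + ["g08", "g09", "g10", "g11", "g12"])
        fc1 = {"g01": -1.0, "g02": -0.9, "g03": -0.5, "g04": -1.2, "g05": -1.0,
               "g06": 0.4, "g07": -1.0, "g08": -1.0, "g09": 0.0, "g10": -1.0,
               "g11": 0.9, "g12": 0.1}
        fc2 = {"g01": -0.8, "g02": -0.7, "g03": -0.9, "g04": -0.3, "g05": 0.5,
               "g06": 0.6, "g07": -1.0, "g08": -1.0, "g09": -0.9, "g10": 0.0,
               "g11": 0.8, "g12": 0.0}
        return te_change_from(d1), te_change_from(d2), m6a, rip, fc1, fc2

    def test_hand_enumerated_stages(self, fixture_12, thresholds):
        ch1, ch2, m6a, rip, fc1, fc2 = fixture_12
        report = candidate_cascade(ch1, ch2, m6a, rip, fc1, fc2, thresholds)
        assert report.counts() == [6, 4, 2]
        assert report.stages[0].members == ["g01", "g02", "g03", "g04", "g05", "g06"]
        assert report.stages[1].members == ["g01", "g02", "g03", "g04"]
        assert report.final_candidates == ["g01", "g02"]
        assert report.concordance_fraction == pytest.approx(4 / 6)

    def test_direction_flip_eliminated_at_stage_two(self, thresholds):
        ch1 = te_change_from({"g": "down", "h": "down", "pad": "unchanged"})
        ch2 = te_change_from({"g": "up", "h": "down", "pad": "unchanged"})
        allg = GeneSet.from_iterable("all", ["g", "h", "pad"])
        report = candidate_cascade(
            ch1, ch2, allg, allg, {"g": -1.0, "h": -1.0}, {"g": -1.0, "h": -1.0},
            thresholds,
        )
        assert "g" in report.stages[0].members
        assert "g" not in report.stages[1].members
        assert report.stages[1].members == ["h"]

    def test_stage_nesting_invariant(self, fixture_12, thresholds):
        ch1, ch2, m6a, rip, fc1, fc2 = fixture_12
        report = candidate_cascade(ch1, ch2, m6a, rip, fc1, fc2, thresholds)
        s1, s2, s3 = (set(s.members) for s in report.stages)
        assert s3 <= s2 <= s1

    def test_threshold_monotonicity(self, fixture_12):
        """Relaxing the final log2 FC cut toward 0 never shrinks the output."""
        ch1, ch2, m6a, rip, fc1, fc2 = fixture_12
        prev: set = set()
        for cut in (-1.5, -1.0, -0.58, -0.3, -0.05):
            th = Thresholds(concordant_log2fc=cut)
            rep = candidate_cascade(ch1, ch2, m6a, rip, fc1, fc2, th)
            cur = set(rep.final_candidates)
            assert prev <= cur
            prev = cur

    def test_empty_stage_one_warns_not_raises(self, thresholds, caplog):
        ch1 = te_change_from({"g": "unchanged", "h": "unchanged"})
        ch2 = te_change_from({"g": "unchanged", "h": "unchanged"})
        empty = GeneSet.from_iterable("none", [])
        with caplog.at_level("WARNING", logger="tescope"):
            report = candidate_cascade(ch1, ch2, empty, empty, {}, {}, thresholds)
        assert report.counts() == [0, 0, 0]
        assert report.concordance_fraction is None

    def test_recovers_planted_targets_on_cohorts(
        self, default_cohort, aged_analysis, kd_analysis, rip_set, thresholds
    ):
        """Final candidates are dominated by truly affected genes."""
        report = candidate_cascade(
            aged_analysis["change"], kd_analysis["change"],
            default_cohort.m6a_set, rip_set,
            aged_analysis["de_tl"]["log2fc"], kd_analysis["de_tl"]["log2fc"],
            thresholds,
        )
        final = set(report.final_candidates)
        assert final, "cascade produced no candidates"
        affected = set(default_cohort.truth.index[default_cohort.truth.affected])
        precision = len(final & affected) / len(final)
        assert precision >= 0.7


class TestOverlapAnalysis:
    def test_shared_fraction_arithmetic(self):
        s1 = GeneSet.from_iterable("first", ["a", "b", "c"])
        s2 = GeneSet.from_iterable("second", ["b", "c", "d"])
        out = overlap_analysis([s1, s2], reference="first")
        assert out.shared_fraction == pytest.approx(2 / 3)
        assert out.region_counts[frozenset({"first", "second"})] == 2
        assert out.region_counts[frozenset({"first"})] == 1
        assert out.region_counts[frozenset({"second"})] == 1

    def test_identical_sets(self):
        s1 = GeneSet.from_iterable("a", ["x", "y"])
        s2 = GeneSet.from_iterable("b", ["x", "y"])
        assert overlap_analysis([s1, s2], reference="a").shared_fraction == 1.0

    def test_region_counts_marginalize_to_set_sizes(self):
        rng = np.random.default_rng(6)
        pool = [f"g{i}" for i in range(100)]
        sets = [
            GeneSet.from_iterable(f"s{j}", rng.choice(pool, size=40, replace=False))
            for j in range(3)
        ]
        out = overlap_analysis(sets, reference="s0")
        assert sum(out.region_counts.values()) == len(
            set().union(*(s.members for s in sets))
        )
        for s in sets:
            marginal = sum(
                n for sig, n in out.region_counts.items() if s.name in sig
            )
            assert marginal == len(s.members)

    def test_case_insensitive_symbol_mode(self):
        mouse = GeneSet.from_iterable("mouse", ["Hells", "Brca1"])
        human = GeneSet.from_iterable("human", ["HELLS", "DNMT1"])
        exact = overlap_analysis([mouse, human], reference="human")
        assert exact.shared_fraction == 0.0
        ci = overlap_analysis(
            [mouse, human], reference="human", match_mode="case_insensitive_symbol"
        )
        assert ci.shared_fraction == pytest.approx(1 / 2)

    def test_unknown_reference_rejected(self):
        s1 = GeneSet.from_iterable("a", ["x"])
        s2 = GeneSet.from_iterable("b", ["y"])
        with pytest.raises(ValidationError):
            overlap_analysis([s1, s2], reference="c")


class TestConcordanceScatter:
    def test_equal_vectors(self):
        v = {"g1": -1.0, "g2": 2.0, "g3": 0.5}
        r, _, quad = concordance_scatter(v, v)
        assert r == pytest.approx(1.0)
        assert quad["both_down"] == 1 and quad["both_up"] == 2
        assert quad["discordant_1up_2down"] == 0

    def test_negated_vectors(self):
        v = {"g1": -1.0, "g2": 2.0, "g3": 0.5}
        neg = {g: -x for g, x in v.items()}
        r, _, quad = concordance_scatter(v, neg)
        assert r == pytest.approx(-1.0)
        assert quad["both_down"] == 0 and quad["both_up"] == 0

    def test_matches_covariance_formula_eight_points(self):
        x = np.array([-1.2, -0.8, -0.5, -0.1, 0.2, 0.6, 1.1, 1.5])
        y = np.array([-0.9, -1.1, 0.3, -0.2, -0.4, 0.8, 0.2, 1.9])
        genes = [f"g{i}" for i in range(8)]
        r, _, _ = concordance_scatter(dict(zip(genes, x)), dict(zip(genes, y)))
        r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(r_oracle, abs=1e-12)
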