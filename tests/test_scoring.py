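import numpy as np
import pandas as pd
import pytest

from sigsearch import (
    ReferencePanel,
    ScoringError,
    TaggedSignature,
    ValidationError,
    extreme_set,
    ks_statistic,
    rank_profile,
    scale_scores,
    score_cmap,
    score_gsea,
    score_panel,
    score_xcos,
    score_xsum,
    score_zhang,
)

from .conftest import random_panel, random_tagged
from .oracles import cmap_brute, gsea_brute, ks_brute, xcos_brute, xsum_brute, zhang_brute


class TestRankProfile:
    def test_order_and_signed_ranks(self, four_gene_panel):
        rp = rank_profile(four_gene_panel, "d1")
        assert rp.gene_order == ("g1", "g3", "g4", "g2")
        assert rp.signed_rank == {"g1": 4.0, "g2": -3.0, "g3": 2.0, "g4": -1.0}
        assert rp.position == {"g1": 1, "g3": 2, "g4": 3, "g2": 4}

    def test_order_invariant_under_shift(self):
        base = [3.0, -2.0, 1.0, -0.5]
        p1 = ReferencePanel(pd.DataFrame({"d": base}, index=list("abcd")))
        p2 = ReferencePanel(pd.DataFrame({"d": [x + 10 for x in base]}, index=list("abcd")))
        assert rank_profile(p1, "d").gene_order == rank_profile(p2, "d").gene_order

    def test_stat_ties_broken_by_gene_id(self):
        p = ReferencePanel(pd.DataFrame({"d": [1.0, 1.0, 0.0]}, index=["g2", "g1", "g3"]))
        assert rank_profile(p, "d").gene_order == ("g1", "g2", "g3")

    def test_unknown_drug(self, four_gene_panel):
        with pytest.raises(ValidationError, match="not in panel"):
            rank_profile(four_gene_panel, "nope")


class TestKsStatistic:
    def test_tags_at_top(self):
        assert ks_statistic([1, 2], 10) == pytest.approx(0.8)

    def test_tags_at_bottom(self):
        assert ks_statistic([9, 10], 10) == pytest.approx(-0.9)

    def test_uniform_fill_is_near_zero(self):
        n = 10
        assert abs(ks_statistic(list(range(1, n + 1)), n)) <= 1 / n + 1e-12

    def test_empty_errors(self):
        with pytest.raises(ScoringError):
            ks_statistic([], 10)

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 30))
            t = int(rng.integers(1, n + 1))
            pos = sorted(rng.choice(np.arange(1, n + 1), size=t, replace=False))
            assert ks_statistic(pos, n) == pytest.approx(ks_brute(pos, n))


class TestCmap:
    def test_mimic_and_reversal_compose_ks(self):
        # 10-gene profile with descending order g01..g10
        stats = list(range(10, 0, -1))
        genes = [f"g{i:02d}" for i in range(1, 11)]
        panel = ReferencePanel(pd.DataFrame({"d": stats}, index=genes))
        rp = rank_profile(panel, "d")
        mimic = TaggedSignature(("g01", "g02"), ("g09", "g10"), 2)
        assert score_cmap(mimic, rp) == pytest.approx(0.8 - (-0.9))
        reverse = TaggedSignature(("g09", "g10"), ("g01", "g02"), 2)
        assert score_cmap(reverse, rp) == pytest.approx(-0.9 - 0.8)

    def test_same_sign_deviations_zero(self):
        genes = [f"g{i:02d}" for i in range(1, 11)]
        panel = ReferencePanel(pd.DataFrame({"d": list(range(10, 0, -1))}, index=genes))
        rp = rank_profile(panel, "d")
        both_top = TaggedSignature(("g01", "g02"), ("g03", "g04"), 2)
        assert score_cmap(both_top, rp) == 0.0

    def test_missing_side_errors(self, four_gene_panel):
        rp = rank_profile(four_gene_panel, "d1")
        ts = TaggedSignature(("g1",), ("zz",), 1)
        with pytest.raises(ScoringError, match="down tags"):
            score_cmap(ts, rp)


class TestScaleScores:
    def test_two_sided_scaling(self):
        out = scale_scores({"A": 2.0, "B": 1.0, "C": -4.0})
        assert out.to_dict() == {"A": 1.0, "B": 0.5, "C": -1.0}

    def test_all_zero_unchanged(self):
        assert scale_scores({"A": 0.0, "B": 0.0}).to_dict() == {"A": 0.0, "B": 0.0}

    def test_single_negative_self_normalizes(self):
        assert scale_scores({"A": -1.7}).to_dict() == {"A": -1.0}


class TestGsea:
    def test_unweighted_extremes(self, descending_panel):
        rp = rank_profile(descending_panel, "d1")
        ts = TaggedSignature(("g1",), ("g4",), 1)
        assert score_gsea(ts, rp, weight_p=0.0) == pytest.approx(1.0)
        swapped = TaggedSignature(("g4",), ("g1",), 1)
        assert score_gsea(swapped, rp, weight_p=0.0) == pytest.approx(-1.0)

    def test_same_sign_null_rule(self, descending_panel):
        rp = rank_profile(descending_panel, "d1")
        ts = TaggedSignature(("g1",), ("g2",), 1)
        assert score_gsea(ts, rp, weight_p=0.0) == 0.0


class TestZhang:
    def _panel(self, s1, s2):
        return ReferencePanel(pd.DataFrame({"d": [s1, s2, 0.1]}, index=["g1", "g2", "g3"]))

    def test_perfect_concordance(self):
        ts = TaggedSignature(("g1",), ("g2",), 1, up_stats=(2.0,), down_stats=(-1.0,))
        rp = rank_profile(self._panel(5.0, -3.0), "d")
        assert score_zhang(ts, rp) == pytest.approx(1.0)

    def test_perfect_discordance(self):
        ts = TaggedSignature(("g1",), ("g2",), 1, up_stats=(2.0,), down_stats=(-1.0,))
        rp = rank_profile(self._panel(-5.0, 3.0), "d")
        assert score_zhang(ts, rp) == pytest.approx(-1.0)

    def test_absent_gene_shrinks_denominator(self):
        ts = TaggedSignature(
            ("g1",), ("gX",), 1, up_stats=(2.0,), down_stats=(-1.0,)
        )
        rp = rank_profile(self._panel(5.0, -3.0), "d")
        score = score_zhang(ts, rp)
        assert score == pytest.approx(1.0)  # single matched tag, concordant
        assert -1.0 <= score <= 1.0


class TestExtremes:
    def test_extreme_partition(self, four_gene_panel):
        rp = rank_profile(four_gene_panel, "d1")
        top, bottom = extreme_set(rp, 1)
        assert top == ("g1",) and bottom == ("g2",)
        top2, bottom2 = extreme_set(rp, 2)
        assert set(top2) | set(bottom2) == {"g1", "g2", "g3", "g4"}

    def test_extreme_too_large(self, four_gene_panel):
        rp = rank_profile(four_gene_panel, "d1")
        with pytest.raises(ValidationError, match="too large"):
            extreme_set(rp, 3)


class TestXsum:
    def test_mimic_sign(self, four_gene_panel):
        rp = rank_profile(four_gene_panel, "d1")
        ts = TaggedSignature(("g1",), ("g2",), 1)
        assert score_xsum(ts, rp, 1) == pytest.approx(5.0)

    def test_reversal_sign(self, four_gene_panel):
        rp = rank_profile(four_gene_panel, "d1")
        ts = TaggedSignature(("g2",), ("g1",), 1)
        assert score_xsum(ts, rp, 1) == pytest.approx(-5.0)

    def test_non_extreme_tags_contribute_zero(self, four_gene_panel):
        rp = rank_profile(four_gene_panel, "d1")
        ts = TaggedSignature(("g3",), ("g4",), 1)
        assert score_xsum(ts, rp, 1) == 0.0


class TestXcos:
    def _two_gene_profile(self, a, b):
        return rank_profile(
            ReferencePanel(pd.DataFrame({"d": [a, b]}, index=["g1", "g2"])), "d"
        )

    def test_collinear(self):
        ts = TaggedSignature(("g1",), ("g2",), 1, up_stats=(1.0,), down_stats=(-1.0,))
        assert score_xcos(ts, self._two_gene_profile(2.0, -2.0), 1) == pytest.approx(1.0)

    def test_oblique(self):
        ts = TaggedSignature(("g1",), ("g2",), 1, up_stats=(1.0,), down_stats=(-1.0,))
        expected = 3.5 / (np.sqrt(2) * np.sqrt(9.25))
        assert score_xcos(ts, self._two_gene_profile(3.0, -0.5), 1) == pytest.approx(
            expected
        )

    def test_no_extreme_tags_warns_and_zeroes(self, four_gene_panel):
        rp = rank_profile(four_gene_panel, "d1")
        ts = TaggedSignature(("g3",), ("g4",), 1, up_stats=(1.0,), down_stats=(-1.0,))
        with pytest.warns(UserWarning, match="extremes"):
            assert score_xcos(ts, rp, 1) == 0.0


class TestScorePanel:
    def test_single_drug_cmap_self_scales(self, rng):
        panel = random_panel(rng, 8, 1)
        ts = random_tagged(rng, panel, 2, 2)
        st = score_panel(ts, panel, "CMap")
        assert st.scores.iloc[0] in (-1.0, 0.0, 1.0)

    def test_column_permutation_invariance(self, rng):
        panel = random_panel(rng, 8, 4)
        ts = random_tagged(rng, panel, 2, 2)
        shuffled = ReferencePanel(panel.data[["d3", "d1", "d4", "d2"]])
        for method in ("XSum", "CMap", "GSEA", "ZhangScore", "XCos"):
            a = score_panel(ts, panel, method).scores
            b = score_panel(ts, shuffled, method).scores
            for d in panel.drug_ids:
                assert a[d] == pytest.approx(b[d])

    def test_to_frame_ranks_most_negative_first(self, rng):
        panel = random_panel(rng, 8, 4)
        ts = random_tagged(rng, panel, 2, 2)
        df = score_panel(ts, panel, "XSum").to_frame()
        assert list(df.columns) == ["drug", "method", "topn", "score", "rank"]
        assert df["score"].is_monotonic_increasing


class TestOracleEquivalence:
    """Each method matches its brute-force enumeration on random instances."""

    @pytest.mark.parametrize("method", ["XSum", "CMap", "GSEA", "ZhangScore", "XCos"])
    def test_matches_brute_force(self, method, rng):
        for _ in range(100):
            n_genes = int(rng.integers(5, 9))
            n_drugs = int(rng.integers(1, 5))
            panel = random_panel(rng, n_genes, n_drugs)
            topn = int(rng.integers(1, 3))
            ts = random_tagged(rng, panel, topn, topn)
            extreme_n = int(rng.integers(1, n_genes // 2 + 1))
            weight_p = float(rng.choice([0.0, 1.0, 2.0]))
            for drug in panel.drug_ids:
                rp = rank_profile(panel, drug)
                stats_desc = [rp.stats[g] for g in rp.gene_order]
                up_pos = sorted(rp.position[g] for g in ts.up_tags)
                dn_pos = sorted(rp.position[g] for g in ts.down_tags)
                top, bottom = rp.gene_order[:extreme_n], rp.gene_order[-extreme_n:]
                if method == "XSum":
                    got = score_xsum(ts, rp, extreme_n)
                    want = xsum_brute(ts.up_tags, ts.down_tags, rp.stats, top, bottom)
                elif method == "CMap":
                    got = score_cmap(ts, rp)
                    want = cmap_brute(up_pos, dn_pos, n_genes)
                elif method == "GSEA":
                    got = score_gsea(ts, rp, weight_p)
                    want = gsea_brute(up_pos, dn_pos, stats_desc, n_genes, weight_p)
                elif method == "ZhangScore":
                    got = score_zhang(ts, rp)
                    want = zhang_brute(
                        ts.stat_map, {g: rp.stats[g] for g in ts.all_tags}
                    )
                else:
                    got = score_xcos(ts, rp, extreme_n)
                    want = xcos_brute(ts.stat_map, rp.stats, ts.all_tags, top, bottom)
                assert got == pytest.approx(want, abs=1e-12), (method, drug)
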