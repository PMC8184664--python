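"""Running-sum enrichment score, permutation null, BH adjustment, GMT/RNK I/O."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletconn.enrichment import (
    GeneSet,
    RankedGeneList,
    bh_adjust,
    enrichment_score,
    permutation_significance,
    read_gmt,
    score_gene_sets,
    write_gmt,
)

from .conftest import running_sum_oracle

# hand-checkable 6-gene fixture: stats 3,2,1,-1,-2,-3 and the set {g1, g3}
SIX = RankedGeneList(("g1", "g2", "g3", "g4", "g5", "g6"),
                     np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0]))
SIX_SET = GeneSet("emt_demo", frozenset({"g1", "g3"}))


class TestRankedGeneList:
    def test_sorting_with_gene_id_tie_break(self):
        r = RankedGeneList.from_unsorted(["b", "c", "a"], [1.0, 2.0, 1.0])
        assert r.genes == ("c", "a", "b")

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            RankedGeneList(("a", "b"), np.array([1.0, 2.0]))

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            RankedGeneList(("a", "a"), np.array([2.0, 1.0]))

    def test_rnk_roundtrip(self, tmp_path):
        path = tmp_path / "x.rnk"
        SIX.write_rnk(path)
        back = RankedGeneList.read_rnk(path)
        assert back.genes == SIX.genes
        assert np.array_equal(back.stats, SIX.stats)


class TestGmtIO:
    def test_roundtrip(self, tmp_path):
        sets = [GeneSet("s1", frozenset({"a", "b"}), "first"),
                GeneSet("s2", frozenset({"c"}), "second")]
        path = tmp_path / "x.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert [(s.name, s.members) for s in back] == [(s.name, s.members) for s in sets]

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\tdesc\n")
        with pytest.raises(ValueError, match="line"):
            read_gmt(path)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSet("void", frozenset())


class TestEnrichmentScore:
    def test_single_top_gene_unweighted_scores_one(self):
        ranked = RankedGeneList(tuple(f"g{i}" for i in range(1, 11)),
                                np.arange(10, 0, -1).astype(float))
        es, _, lead = enrichment_score(ranked, GeneSet("s", frozenset({"g1"})), weight=0)
        assert es == pytest.approx(1.0)
        assert lead == ("g1",)

    def test_single_bottom_gene_unweighted_scores_minus_one(self):
        ranked = RankedGeneList(tuple(f"g{i}" for i in range(1, 11)),
                                np.arange(10, 0, -1).astype(float))
        es, _, lead = enrichment_score(ranked, GeneSet("s", frozenset({"g10"})), weight=0)
        assert es == pytest.approx(-1.0)
        assert lead == ("g10",)

    def test_hand_executed_worked_example(self):
        es, running, lead = enrichment_score(SIX, SIX_SET, weight=1)
        # hits +3/4 and +1/4, misses -1/4 each; extremum 0.75 at ranks 1 and 3
        assert es == pytest.approx(0.75)
        assert np.allclose(running, [0.75, 0.5, 0.75, 0.5, 0.25, 0.0])
        assert set(lead) == {"g1"} or set(lead) == {"g1", "g3"}

    def test_matches_loop_oracle_on_random_input(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            stats = np.sort(rng.normal(size=30))[::-1]
            genes = tuple(f"g{i:02d}" for i in range(30))
            members = frozenset(rng.choice(genes, size=6, replace=False))
            ranked = RankedGeneList(genes, stats)
            es, running, _ = enrichment_score(ranked, GeneSet("s", members), weight=1)
            es_ref, running_ref = running_sum_oracle(genes, stats, members, 1)
            assert es == pytest.approx(es_ref, abs=1e-12)
            assert np.allclose(running, running_ref)

    def test_running_sum_ends_at_zero(self):
        _, running, _ = enrichment_score(SIX, SIX_SET, weight=1)
        assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_absent_members_dropped_not_missed(self):
        gs = GeneSet("s", frozenset({"g1", "g3", "not_in_list"}))
        es, _, _ = enrichment_score(SIX, gs, weight=1)
        assert es == pytest.approx(0.75)

    def test_zero_overlap_rejected(self):
        with pytest.raises(ValueError, match="no overlap"):
            enrichment_score(SIX, GeneSet("s", frozenset({"zz"})))

    def test_full_coverage_rejected(self):
        with pytest.raises(ValueError, match="whole"):
            enrichment_score(SIX, GeneSet("s", frozenset(SIX.genes)))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), scale=st.floats(0.1, 50.0))
    def test_weight_one_invariant_to_positive_scaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        stats = np.sort(rng.normal(size=20))[::-1]
        genes = tuple(f"g{i:02d}" for i in range(20))
        gs = GeneSet("s", frozenset(rng.choice(genes, size=4, replace=False)))
        es1, _, _ = enrichment_score(RankedGeneList(genes, stats), gs, weight=1)
        es2, _, _ = enrichment_score(RankedGeneList(genes, stats * scale), gs, weight=1)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_weight_zero_invariant_to_monotone_rescale(self):
        rng = np.random.default_rng(4)
        stats = np.sort(rng.normal(size=20))[::-1]
        genes = tuple(f"g{i:02d}" for i in range(20))
        gs = GeneSet("s", frozenset(rng.choice(genes, size=4, replace=False)))
        es1, _, _ = enrichment_score(RankedGeneList(genes, stats), gs, weight=0)
        warped = np.exp(stats)  # strictly monotone, preserves ranking
        es2, _, _ = enrichment_score(RankedGeneList(genes, warped), gs, weight=0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_agrees_with_gseapy_reference(self):
        """Independent cross-check of the weighted ES against gseapy."""
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        rng = np.random.default_rng(12)
        stats = np.sort(rng.normal(size=40))[::-1]
        genes = [f"g{i:02d}" for i in range(40)]
        members = list(rng.choice(genes, size=8, replace=False))
        rnk = pd.Series(stats, index=genes)
        res = gseapy.prerank(rnk=rnk, gene_sets={"s": members}, permutation_num=10,
                             min_size=1, max_size=50, weight=1, seed=0,
                             outdir=None, no_plot=True)
        es_ref = float(res.res2d.loc[res.res2d["Term"] == "s", "ES"].iloc[0])
        es, _, _ = enrichment_score(
            RankedGeneList(tuple(genes), stats), GeneSet("s", frozenset(members)), weight=1
        )
        assert es == pytest.approx(es_ref, abs=1e-6)


class TestPermutationSignificance:
    def test_exact_mode_enumerates_all_placements(self):
        res = permutation_significance(SIX, SIX_SET, n_perm=1000, exact=True)
        # brute force over all C(6,2)=15 two-member sets, sign-stratified
        null = []
        for combo in itertools.combinations(SIX.genes, 2):
            es, _, _ = enrichment_score(SIX, GeneSet("n", frozenset(combo)), weight=1)
            null.append(es)
        positive = [e for e in null if e >= 0]
        expected_p = sum(e >= res.es for e in positive) / len(positive)
        assert len(null) == 15
        assert res.exact
        assert res.p_perm == pytest.approx(expected_p)

    def test_exact_matches_monte_carlo_within_binomial_error(self):
        exact = permutation_significance(SIX, SIX_SET, exact=True)
        mc = permutation_significance(SIX, SIX_SET, n_perm=4000, seed=1, exact=False)
        se = math.sqrt(exact.p_perm * (1 - exact.p_perm) / 4000)
        assert abs(mc.p_perm - exact.p_perm) < 4 * se + 2 / 4000

    def test_dominant_set_hits_minimum_p(self):
        ranked, gs = __import__("isletconn").simulate_ranked_list(200, 5, shift=10.0, seed=0)
        res = permutation_significance(ranked, gs, n_perm=500, seed=0, exact=False)
        # no null placement can match: p is the minimum attainable
        assert res.p_perm == pytest.approx(1 / (res.n_null_same_sign + 1), abs=1e-12)
        assert res.p_perm < 0.05
        assert res.nes > 1.0

    def test_null_pvalues_approximately_uniform(self):
        """Calibration: shift=0 lists give p < 0.05 about 5% of the time."""
        from isletconn import simulate_ranked_list

        hits = 0
        n_lists = 150
        for seed in range(n_lists):
            ranked, gs = simulate_ranked_list(300, 8, shift=0.0, seed=seed)
            res = permutation_significance(ranked, gs, n_perm=199, seed=seed, exact=False)
            hits += res.p_perm < 0.05
        # 95% binomial band around 0.05 with 150 trials
        se = math.sqrt(0.05 * 0.95 / n_lists)
        assert abs(hits / n_lists - 0.05) < 2.5 * se

    def test_deterministic_per_seed(self):
        from isletconn import simulate_ranked_list

        ranked, gs = simulate_ranked_list(300, 10, shift=0.5, seed=3)
        a = permutation_significance(ranked, gs, n_perm=300, seed=7, exact=False)
        b = permutation_significance(ranked, gs, n_perm=300, seed=7, exact=False)
        assert (a.es, a.nes, a.p_perm) == (b.es, b.nes, b.p_perm)

    def test_low_n_perm_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_significance(SIX, SIX_SET, n_perm=50)


class TestBHAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_step_up_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_order_preserved(self):
        p = [0.04, 0.01, 0.03, 0.02]
        q = bh_adjust(p)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_monotone(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.5], [-0.1], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestScoreGeneSets:
    def test_family_table_with_bh_column(self):
        from isletconn import simulate_ranked_list

        ranked, planted = simulate_ranked_list(300, 10, shift=3.0, seed=0)
        decoy = GeneSet("decoy", frozenset(list(ranked.genes)[::37]))
        table = score_gene_sets(ranked, [planted, decoy], n_perm=200, seed=0, exact=False)
        assert list(table["set"]) == ["planted", "decoy"]
        assert np.all(table["q"] >= table["p"] - 1e-12)
        planted_row = table.set_index("set").loc["planted"]
        assert planted_row["es"] > 0.5
        assert planted_row["p"] < 0.05
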