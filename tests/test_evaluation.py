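"""Enrichment, ranking AUC, precision, Welch test, redundancy, diversity."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from atmkit.atm import ATM
from atmkit.evaluation import (
    GeneSetCollection,
    atm_precision,
    diversity_coefficient,
    gba_predictions,
    hypergeom_enrich,
    jaccard,
    matched_control_sets,
    random_control_sets,
    read_gmt,
    term_auc,
    term_mapping_predictions,
    welch_right_tailed,
)


def _enumeration_tail(N, M, n, x):
    """P(|draw ∩ category| >= x) by exhaustive enumeration of all C(N, n) draws."""
    universe = range(N)
    category = set(range(M))
    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(category.intersection(draw)) >= x:
            hits += 1
    return hits / total


def _atm(genes, tfs=(), terms=(), idx=0, k=2):
    return ATM(
        component_index=idx,
        k_of_run=k,
        weight=1.0,
        terms=[(t, 1.0) for t in terms],
        genes=[(g, 1.0) for g in genes],
        tfs=[(t, 1.0) for t in tfs],
    )


class TestHypergeomEnrich:
    def test_zero_overlap_is_certain(self):
        res = hypergeom_enrich({"a"}, {"b"}, {"a", "b", "c"})
        assert res.p_value == pytest.approx(1.0)

    def test_hand_enumerated_example(self):
        # N=10, M=4, n=3, x=2 -> (C(4,2)C(6,1)+C(4,3))/C(10,3) = 40/120
        universe = {f"u{i}" for i in range(10)}
        category = {f"u{i}" for i in range(4)}
        atm = {"u0", "u1", "u9"}
        res = hypergeom_enrich(atm, category, universe)
        assert res.overlap == 2
        assert res.p_value == pytest.approx(1 / 3)

    def test_full_overlap_has_pvalue_one(self):
        universe = {"a", "b", "c"}
        res = hypergeom_enrich(universe, universe, universe)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_atm_rejected(self):
        with pytest.raises(ValueError, match="empty ATM"):
            hypergeom_enrich(set(), {"a"}, {"a"})

    @pytest.mark.parametrize("N", [4, 7, 10, 12])
    def test_matches_exhaustive_enumeration(self, N):
        rng = np.random.default_rng(N)
        universe = {f"u{i}" for i in range(N)}
        for _ in range(6):
            M = int(rng.integers(1, N))
            n = int(rng.integers(1, N + 1))
            category = {f"u{i}" for i in range(M)}
            atm = set(rng.choice(sorted(universe), size=n, replace=False))
            res = hypergeom_enrich(atm, category, universe)
            expected = _enumeration_tail(N, M, n, res.overlap)
            assert res.p_value == pytest.approx(expected, abs=1e-12)


class TestEnrichAtms:
    def test_bh_correction_is_optional_and_monotone(self):
        from atmkit.evaluation import enrich_atms

        atm = _atm([f"g{i}" for i in range(4)], ["t1"])
        coll = GeneSetCollection.from_dict(
            {
                "hit": ("hit", "", {"g0", "g1", "g2", "g3", "t1"}),
                "miss": ("miss", "", {"g9"}),
            },
            universe={f"g{i}" for i in range(10)} | {"t1"},
        )
        raw = enrich_atms([atm], coll)
        adjusted = enrich_atms([atm], coll, correction="bh")
        assert len(raw) == len(adjusted) == 2
        for r, a in zip(raw, adjusted):
            assert a.p_value >= r.p_value  # BH never shrinks a p-value
        with pytest.raises(ValueError):
            enrich_atms([atm], coll, correction="bonferroni")


class TestTermAuc:
    def test_perfect_ranking(self):
        assert term_auc(["r1", "r2", "n1", "n2"], {"r1", "r2"}) == 1.0

    def test_worst_ranking(self):
        assert term_auc(["n1", "n2", "r1", "r2"], {"r1", "r2"}) == 0.0

    def test_interleaved_ranking(self):
        assert term_auc(["r1", "n1", "r2", "n2"], {"r1", "r2"}) == pytest.approx(0.75)

    def test_undefined_without_both_classes(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert term_auc(["a", "b"], {"a", "b"}) is None
        with pytest.warns(UserWarning, match="undefined"):
            assert term_auc(["a", "b"], set()) is None

    def test_random_permutations_average_one_half(self):
        rng = np.random.default_rng(123)
        terms = [f"t{i}" for i in range(50)]
        relevant = set(terms[:10])
        aucs = []
        for _ in range(500):
            perm = list(rng.permutation(terms))
            aucs.append(term_auc(perm, relevant))
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 1e-3


class TestPrecisionAndJaccard:
    def test_precision_anchors(self):
        assert atm_precision({"a", "b"}, {"a", "b", "c"}) == 1.0
        assert atm_precision({"a"}, {"b"}) == 0.0
        members = {f"m{i}" for i in range(10)}
        gold = {f"m{i}" for i in range(5)} | {"x", "y"}
        assert atm_precision(members, gold) == 0.5

    def test_precision_empty_atm_rejected(self):
        with pytest.raises(ValueError):
            atm_precision(set(), {"a"})

    def test_jaccard_anchors(self):
        s = {f"e{i}" for i in range(8)}
        assert jaccard(s, set(s)) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_jaccard_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())

    @given(
        st.sets(st.integers(0, 20), min_size=1, max_size=10),
        st.sets(st.integers(0, 20), max_size=10),
    )
    @settings(deadline=None, derandomize=True)
    def test_jaccard_symmetric_and_relabel_invariant(self, a, b):
        assert jaccard(a, b) == jaccard(b, a)
        relabel = lambda s: {f"x{v}" for v in s}
        assert jaccard(relabel(a), relabel(b)) == jaccard(a, b)


class TestWelch:
    def test_identical_samples_give_t_zero_p_half(self):
        t, df, p = welch_right_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(0.5)

    def test_large_effect_tiny_pvalue(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 1, 50)
        b = rng.normal(0, 1, 50)
        _, _, p = welch_right_tailed(a, b)
        assert p < 1e-10

    def test_swapping_samples_negates_t_and_flips_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1, 1, 20)
        b = rng.normal(0, 1, 25)
        t1, _, p1 = welch_right_tailed(a, b)
        t2, _, p2 = welch_right_tailed(b, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(1 - p1)

    def test_df_is_welch_satterthwaite(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 3, 15)
        _, df, _ = welch_right_tailed(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        expected = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert df == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_right_tailed([1.0, 1.0], [1.0, 1.0])

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(10, 2000))
        b = rng.normal(size=(10, 2000))
        res = stats.ttest_ind(a, b, equal_var=False, alternative="greater", axis=0)
        ks = stats.kstest(res.pvalue, "uniform")
        assert ks.pvalue > 0.001


class TestRandomControls:
    def test_reproducible_by_seed(self):
        genes = [f"g{i}" for i in range(20)]
        tfs = [f"t{i}" for i in range(5)]
        one = random_control_sets(genes, tfs, reps=1, seed=9)
        two = random_control_sets(genes, tfs, reps=1, seed=9)
        assert one == two

    def test_default_sizes_match_median_module(self):
        genes = [f"g{i}" for i in range(50)]
        tfs = [f"t{i}" for i in range(10)]
        sets = random_control_sets(genes, tfs, reps=1000, seed=0)
        assert len(sets) == 1000
        assert all(len(s) == 10 for s in sets)  # 8 genes + 2 TFs

    def test_matched_variant_counts(self):
        atms = [_atm(["g1", "g2", "g3"], ["t1"]), _atm(["g1"], ["t1", "t2"])]
        genes = [f"g{i}" for i in range(20)]
        tfs = [f"t{i}" for i in range(6)]
        sets = matched_control_sets(atms, genes, tfs, reps_per_atm=200, seed=0)
        assert len(sets) == 400
        assert all(len(s) == 4 for s in sets[:200])
        assert all(len(s) == 3 for s in sets[200:])

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            random_control_sets(["g1"], ["t1"], n_genes=8, n_tfs=2, reps=1)

    def test_matched_null_precision_matches_base_rate(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(80)]
        tfs = [f"t{i}" for i in range(20)]
        universe = genes + tfs
        gold = set(rng.choice(universe, size=30, replace=False))
        sets = random_control_sets(genes, tfs, n_genes=8, n_tfs=2, reps=800, seed=1)
        precisions = [atm_precision(s, gold) for s in sets]
        base_rate = len(gold) / len(universe)
        se = np.std(precisions, ddof=1) / np.sqrt(len(precisions))
        assert abs(np.mean(precisions) - base_rate) < 3 * se + 0.01


class TestDiversity:
    def test_repeated_single_gene(self):
        atms = [_atm(["g1"], ["t1"], ["w1"]) for _ in range(3)]
        d = diversity_coefficient(atms, (50, 100, 10))
        assert d[0] == pytest.approx(0.01)

    def test_partition_covers_everything(self):
        atms = [
            _atm([f"g{i}" for i in range(5)], ["t0"], ["w0"]),
            _atm([f"g{i}" for i in range(5, 10)], ["t1"], ["w1"]),
        ]
        d = diversity_coefficient(atms, (2, 10, 2))
        assert d[0] == 1.0 and d[1] == 1.0 and d[2] == 1.0

    def test_undefined_for_rank_one_runs(self):
        assert diversity_coefficient([_atm(["g1"], k=1)], (5, 5, 5)) is None

    def test_matches_brute_force_union(self):
        rng = np.random.default_rng(3)
        atms = [
            _atm(
                [f"g{i}" for i in rng.choice(30, 6, replace=False)],
                [f"t{i}" for i in rng.choice(8, 2, replace=False)],
                [f"w{i}" for i in rng.choice(40, 10, replace=False)],
                idx=r,
                k=4,
            )
            for r in range(4)
        ]
        d = diversity_coefficient(atms, (40, 30, 8))
        genes = set().union(*(set(a.gene_labels) for a in atms))
        assert d[0] == pytest.approx(len(genes) / 30)


class TestPredictions:
    def test_fully_annotated_atm_yields_nothing(self):
        atm = _atm(["g1", "g2"], ["t1"])
        enr = [hypergeom_enrich(atm.members, {"g1", "g2", "t1"}, {"g1", "g2", "t1", "x"}, 0, "C1")]
        preds = gba_predictions([atm], enr, {"C1": {"g1", "g2", "t1"}})
        assert preds == []

    def test_candidate_count_is_members_minus_annotated(self):
        members = [f"g{i}" for i in range(104)]
        atm = _atm(members)
        annotated = set(members[:16])
        universe = set(members) | {f"bg{i}" for i in range(400)}
        enr = [hypergeom_enrich(atm.members, annotated, universe, 0, "axon")]
        assert enr[0].p_value <= 0.05
        preds = gba_predictions([atm], enr, {"axon": annotated})
        assert len(preds) == 104 - 16

    def test_small_set_difference(self):
        atm = _atm(["a", "b", "c", "d", "e"])
        universe = {f"u{i}" for i in range(50)} | atm.members
        annotated = {"a", "b"}
        enr = [hypergeom_enrich(atm.members, annotated, universe, 0, "C")]
        preds = gba_predictions([atm], enr, {"C": annotated})
        assert {p.entity for p in preds} == {"c", "d", "e"}

    def test_term_mapping_orders_by_overlap(self):
        atm = _atm(["g1"], ["t1"], terms=["wnt", "notch", "cochlea", "hair"])
        coll = GeneSetCollection.from_dict(
            {
                "C_none": ("C_none", "ribosome assembly", {"g9"}),
                "C_exact": ("C_exact", "wnt notch cochlea hair", {"g8"}),
                "C_partial": ("C_partial", "notch signaling pathway", {"g7"}),
            },
            universe={"g1", "g7", "g8", "g9", "t1"},
        )
        ranked = term_mapping_predictions(atm, coll, enriched_category_ids=set())
        assert [cid for cid, _ in ranked] == ["C_exact", "C_partial"]
        assert dict(ranked)["C_exact"] == 4

    def test_term_mapping_excludes_enriched_categories(self):
        atm = _atm(["g1"], terms=["wnt"])
        coll = GeneSetCollection.from_dict(
            {"C1": ("C1", "wnt pathway", {"g1"})}, universe={"g1", "g2"}
        )
        assert term_mapping_predictions(atm, coll, enriched_category_ids={"C1"}) == []


class TestGmtIO:
    def test_read_gmt_with_universe_restriction(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text(
            "S1\tfirst set\tg1\tg2\tg9\n"
            "S2\tsecond set\tg3\n"
            "S3\torphan\tzz\n"
        )
        coll = read_gmt(gmt, universe={"G1", "G2", "G3", "G4"})
        assert set(coll.sets) == {"S1", "S2"}
        assert coll.sets["S1"].members == {"G1", "G2"}

    def test_description_sidecar_overrides(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("S1\tshort\tg1\n")
        desc = tmp_path / "desc.tsv"
        desc.write_text("S1\ta longer free text description\n")
        coll = read_gmt(gmt, universe={"G1"}, descriptions=desc)
        assert coll.sets["S1"].description == "a longer free text description"
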