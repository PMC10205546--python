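"""MCN selection, transcriptome merge, Venn table, Spearman, ORA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse, stats as sps

from hnsomics.core_io import GeneSet, GeneSetCollection, SingleCellCounts, ValidationError
from hnsomics.integrate import (
    VENN_CATEGORIES,
    classify_functional,
    correlate_changes,
    mcn_top_genes,
    merge_transcriptomes,
    normalize_cells,
    ora,
    select_mcn_cells,
    venn_classify,
)
from hnsomics.simulate import generate_singlecell


class TestMcnSelection:
    def test_planted_cluster_recovered_exactly(self):
        sc, truth = generate_singlecell(300, n_cells=200, seed=5)
        assert select_mcn_cells(sc) == truth

    def test_infinite_threshold_empty(self):
        sc, _ = generate_singlecell(300, n_cells=100, seed=5)
        assert select_mcn_cells(sc, expr_threshold=math.inf) == set()

    def test_two_planted_clusters_unioned(self):
        sc, truth = generate_singlecell(300, n_cells=200, n_mcn_clusters=2, seed=5)
        assert len({sc.clusters[b] for b in truth}) == 2
        assert select_mcn_cells(sc) == truth

    def test_missing_marker_rejected(self):
        sc, _ = generate_singlecell(300, n_cells=50, seed=5)
        with pytest.raises(ValidationError, match="Nothere"):
            select_mcn_cells(sc, markers_primary=("Nothere",))


class TestMcnTopGenes:
    def test_strict_cutoff_behaviour(self):
        sc, truth = generate_singlecell(200, n_cells=100, seed=2)
        table = mcn_top_genes(sc, truth).set_index("gene_symbol")
        means = table["mean_normalized_count"]
        # independent recomputation of the means
        norm = normalize_cells(sc)
        cols = [j for j, b in enumerate(sc.barcodes) if b in truth]
        assert np.allclose(means.to_numpy(), norm[:, cols].mean(axis=1), atol=1e-12)
        # strictness: a cutoff equal to a gene's own mean must not select it
        some_gene = means.index[10]
        table2 = mcn_top_genes(sc, truth, cutoff=float(means[some_gene]))
        assert not table2.set_index("gene_symbol").loc[some_gene, "selected"]
        assert (table["selected"] == (means > 0.5)).all()

    def test_empty_mcn_cells_rejected(self):
        sc, _ = generate_singlecell(100, n_cells=50, seed=2)
        with pytest.raises(ValidationError):
            mcn_top_genes(sc, set())


class TestMergeTranscriptomes:
    def test_union_rule(self):
        a = pd.Series({"g1": 12.0, "g2": 10.0, "g3": 0.0})
        b = pd.Series({"g1": 0.0, "g2": 10.0, "g3": 5.0})
        assert merge_transcriptomes(a, b) == {"g1"}

    def test_threshold_strict(self):
        a = pd.Series({"g": 10.0})
        assert merge_transcriptomes(a, a) == set()
        assert merge_transcriptomes(pd.Series({"g": 10.0 + 1e-9}), a) == {"g"}

    def test_identical_inputs(self):
        a = pd.Series({"g1": 20.0, "g2": 1.0})
        assert merge_transcriptomes(a, a) == {"g1"}


class TestVenn:
    def test_decision_table(self):
        universe = {"g"}
        for key, category in VENN_CATEGORIES.items():
            t, s, n = key
            out = venn_classify(
                {"g"} if t else set(), {"g"} if s else set(), {"g"} if n else set(), universe
            )
            assert out.iloc[0]["category"] == category

    def test_transported_combination(self):
        out = venn_classify({"g"}, set(), {"g"}, {"g"})
        assert out.iloc[0]["category"] == "transported"

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_categories_partition_universe(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(60)]
        pick = lambda: {g for g in universe if rng.random() < 0.4}
        out = venn_classify(pick(), pick(), pick(), universe)
        assert len(out) == len(universe)
        assert out["category"].value_counts().sum() == len(universe)

    def test_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            venn_classify({"alien"}, set(), set(), {"g"})


def naive_spearman_perm_p(x, y):
    """Oracle: enumerate all pairings of tie-averaged ranks."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)

    def rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    obs = abs(rho(rx, ry))
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho(rx, np.array(perm))) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestSpearman:
    def test_monotone_gives_unit_rho(self):
        x = pd.Series({f"f{i}": float(i) for i in range(8)})
        y = x**3 + 2
        r = correlate_changes(x, y)
        assert r.spearman_r == pytest.approx(1.0, abs=1e-12)

    def test_hand_worked_example(self):
        r = correlate_changes(
            pd.Series({"a": 1, "b": 2, "c": 3, "d": 4}),
            pd.Series({"a": 1, "b": 3, "c": 2, "d": 4}),
        )
        assert r.spearman_r == pytest.approx(0.8, abs=1e-12)  # 1 - 6*2/(4*15)

    def test_reversal_antisymmetry(self):
        x = pd.Series({f"f{i}": float(i) for i in range(6)})
        r = correlate_changes(x, -x)
        assert r.spearman_r == pytest.approx(-1.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(size=20), index=[f"f{i}" for i in range(20)])
        y = pd.Series(rng.normal(size=20), index=x.index)
        a = correlate_changes(x, y)
        b = correlate_changes(np.exp(x), y**3)
        assert a.spearman_r == pytest.approx(b.spearman_r, abs=1e-12)

    def test_too_few_shared_features_rejected(self):
        with pytest.raises(ValidationError):
            correlate_changes(pd.Series({"a": 1, "b": 2}), pd.Series({"a": 1, "b": 2}))

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2)])
    def test_exact_permutation_p_matches_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        idx = [f"f{i}" for i in range(n)]
        got = correlate_changes(pd.Series(x, index=idx), pd.Series(y, index=idx))
        assert got.p_value == pytest.approx(naive_spearman_perm_p(x, y), abs=1e-12)

    def test_exact_permutation_p_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0])
        idx = [f"f{i}" for i in range(5)]
        got = correlate_changes(pd.Series(x, index=idx), pd.Series(y, index=idx))
        assert got.p_value == pytest.approx(naive_spearman_perm_p(x, y), abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(size=30), index=[f"f{i}" for i in range(30)])
        y = pd.Series(rng.normal(size=30), index=x.index)
        got = correlate_changes(x, y)
        ref_r, ref_p = sps.spearmanr(x.to_numpy(), y.to_numpy())
        assert got.spearman_r == pytest.approx(float(ref_r), abs=1e-12)
        assert got.p_value == pytest.approx(float(ref_p), abs=1e-12)


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by direct enumeration with exact integer combinatorics."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


class TestOra:
    def collection(self, *sets):
        return GeneSetCollection(
            [GeneSet(f"T{i}", f"term {i}", frozenset(s)) for i, s in enumerate(sets)]
        )

    def test_worked_example(self):
        bg = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        query = {f"g{i}" for i in range(3)} | {f"g{i}" for i in range(10, 17)}  # overlap 3
        res, _ = ora(query, bg, self.collection(term))
        assert res.iloc[0]["k_overlap"] == 3
        expect = hypergeom_tail_oracle(3, 20, 5, 10)
        assert res.iloc[0]["p_hyper"] == pytest.approx(expect, abs=1e-12)
        assert res.iloc[0]["p_hyper"] == pytest.approx(0.5, abs=5e-5)

    def test_zero_overlap_p_is_one(self):
        bg = {f"g{i}" for i in range(10)}
        res, _ = ora({"g0", "g1"}, bg, self.collection({"g5", "g6", "g7"}))
        assert res.iloc[0]["p_hyper"] == pytest.approx(1.0, abs=1e-12)

    def test_query_equals_background(self):
        bg = {f"g{i}" for i in range(12)}
        res, _ = ora(bg, bg, self.collection({"g0", "g1", "g2", "g3"}))
        assert res.iloc[0]["k_overlap"] == 4
        assert res.iloc[0]["p_hyper"] == pytest.approx(1.0, abs=1e-12)

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValidationError, match="alien"):
            ora({"alien"}, {"g0", "g1", "g2"}, self.collection({"g0", "g1", "g2"}))

    def test_size_bounds_skip_reported(self):
        bg = {f"g{i}" for i in range(10)}
        res, skipped = ora({"g0"}, bg, self.collection({"g0", "g1"}, {"g0", "g1", "g2"}))
        assert list(skipped["term_id"]) == ["T0"]  # size 2 < min_term 3
        assert list(res["term_id"]) == ["T1"]

    def test_bh_dominates_raw_p(self):
        rng = np.random.default_rng(1)
        bg = {f"g{i}" for i in range(25)}
        terms = [set(rng.choice(sorted(bg), size=6, replace=False)) for _ in range(8)]
        query = set(rng.choice(sorted(bg), size=10, replace=False))
        res, _ = ora(query, bg, self.collection(*terms))
        assert (res["p_adj"] >= res["p_hyper"] - 1e-15).all()

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_enumeration_oracle_small_backgrounds(self, seed):
        rng = np.random.default_rng(seed)
        n_bg = int(rng.integers(8, 26))
        bg = {f"g{i}" for i in range(n_bg)}
        term = set(rng.choice(sorted(bg), size=int(rng.integers(3, n_bg // 2 + 2)), replace=False))
        query = set(rng.choice(sorted(bg), size=int(rng.integers(1, n_bg)), replace=False))
        res, _ = ora(query, bg, self.collection(term))
        k = len(term & query)
        expect = hypergeom_tail_oracle(k, n_bg, len(term), len(query))
        assert res.iloc[0]["p_hyper"] == pytest.approx(expect, abs=1e-12)


class TestClassifyFunctional:
    def test_mapped_and_unmapped(self):
        mapping = pd.DataFrame({"gene": ["Avp"], "category": ["endogenous peptide"]})
        out = classify_functional({"Avp", "G1"}, mapping)
        assert out == {"Avp": "endogenous peptide", "G1": "unclassified"}

    def test_empty_mapping_all_unclassified(self):
        out = classify_functional({"a", "b"}, pd.DataFrame({"gene": [], "category": []}))
        assert set(out.values()) == {"unclassified"}

    def test_conflicting_duplicates_rejected(self):
        mapping = pd.DataFrame({"gene": ["Avp", "Avp"], "category": ["peptide", "enzyme"]})
        with pytest.raises(ValidationError, match="Avp"):
            classify_functional({"Avp"}, mapping)

    def test_consistent_duplicates_allowed(self):
        mapping = pd.DataFrame({"gene": ["Avp", "Avp"], "category": ["peptide", "peptide"]})
        assert classify_functional({"Avp"}, mapping) == {"Avp": "peptide"}
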