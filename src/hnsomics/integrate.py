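"""Multi-omic integration.

Builds the magnocellular-neurone (MCN) reference gene list from single-cell
counts (marker-based cluster selection with Avp/Oxt and Caprin2, then a
mean-normalized-count cutoff), merges two bulk transcriptomes, classifies
genes by transcript/protein presence across compartments (the Venn decision
table), correlates cross-compartment changes by Spearman rank correlation,
and runs background-aware hypergeometric over-representation analysis.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSetCollection, SingleCellCounts, ValidationError

__all__ = [
    "CorrelationResult",
    "normalize_cells",
    "select_mcn_cells",
    "mcn_top_genes",
    "merge_transcriptomes",
    "VENN_CATEGORIES",
    "venn_classify",
    "correlate_changes",
    "ora",
    "classify_functional",
]

DEFAULT_CELL_TARGET = 10_000.0  # per-cell scaling target before log1p


def normalize_cells(
    sc: SingleCellCounts, target: float = DEFAULT_CELL_TARGET, log1p: bool = True
) -> np.ndarray:
    """Per-cell normalized expression (genes x cells, dense).

    Counts are scaled so every cell sums to ``target``, then log1p
    transformed.  This is the conventional single-cell normalization for
    marker-mean comparisons.
    """
    mat = np.asarray(sc.matrix.todense(), dtype=float)
    totals = mat.sum(axis=0)
    if (totals == 0).any():
        empty = [sc.barcodes[i] for i in np.where(totals == 0)[0]]
        raise ValidationError(f"cells with zero total counts: {empty[:5]}")
    scaled = mat * (target / totals)[np.newaxis, :]
    return np.log1p(scaled) if log1p else scaled


def select_mcn_cells(
    sc: SingleCellCounts,
    cluster_labels: Mapping[str, str] | None = None,
    markers_primary: Sequence[str] = ("Avp", "Oxt"),
    marker_secondary: str = "Caprin2",
    expr_threshold: float = 1.0,
) -> set[str]:
    """Cells of every cluster that looks magnocellular by marker expression.

    A cluster qualifies when its mean normalized expression of Avp OR Oxt
    exceeds ``expr_threshold`` AND its mean Caprin2 does too.  Returns the
    union of cells of all qualifying clusters; an empty result is a
    legitimate outcome, not an error.  Labels default to ``sc.clusters``;
    unlabeled input falls back to a seeded k-means labeling.
    """
    labels = dict(cluster_labels) if cluster_labels is not None else sc.clusters
    if labels is None:
        labels = _kmeans_fallback_labels(sc)
    missing_markers = [m for m in [*markers_primary, marker_secondary] if m not in sc.genes]
    if missing_markers:
        raise ValidationError(f"marker gene(s) absent from matrix: {missing_markers}")
    norm = normalize_cells(sc)
    gene_idx = {g: i for i, g in enumerate(sc.genes)}
    cells_by_cluster: dict[str, list[int]] = {}
    for j, barcode in enumerate(sc.barcodes):
        cells_by_cluster.setdefault(labels[barcode], []).append(j)
    selected: set[str] = set()
    for cluster, cols in cells_by_cluster.items():
        sub = norm[:, cols]
        primary_ok = any(
            float(sub[gene_idx[m]].mean()) > expr_threshold for m in markers_primary
        )
        secondary_ok = float(sub[gene_idx[marker_secondary]].mean()) > expr_threshold
        if primary_ok and secondary_ok:
            selected.update(sc.barcodes[j] for j in cols)
    return selected


def _kmeans_fallback_labels(sc: SingleCellCounts, k: int = 4, seed: int = 0) -> dict[str, str]:
    """Deterministic k-means labeling for matrices delivered without clusters."""
    from scipy.cluster.vq import kmeans2

    norm = normalize_cells(sc).T  # cells x genes
    _, assignments = kmeans2(norm, k, seed=seed, minit="++")
    return {b: f"cluster_{a}" for b, a in zip(sc.barcodes, assignments)}


def mcn_top_genes(
    sc: SingleCellCounts, mcn_cells: Iterable[str], cutoff: float = 0.5
) -> pd.DataFrame:
    """Mean normalized expression per gene over the MCN cells.

    ``selected`` marks genes whose mean strictly exceeds ``cutoff`` —
    the abundance filter that, in the source data, retains roughly the top
    tenth of expressed genes.
    """
    mcn_cells = set(mcn_cells)
    if not mcn_cells:
        raise ValidationError("mcn_top_genes requires a non-empty MCN cell set")
    unknown = mcn_cells - set(sc.barcodes)
    if unknown:
        raise ValidationError(f"unknown barcodes: {sorted(unknown)[:5]}")
    norm = normalize_cells(sc)
    cols = [j for j, b in enumerate(sc.barcodes) if b in mcn_cells]
    means = norm[:, cols].mean(axis=1)
    return pd.DataFrame(
        {
            "gene_symbol": sc.genes,
            "mean_normalized_count": means,
            "selected": means > cutoff,
        }
    )


def merge_transcriptomes(
    strain_a: Mapping[str, float] | pd.Series,
    strain_b: Mapping[str, float] | pd.Series,
    threshold: float = 10.0,
) -> set[str]:
    """Union of genes with normalized counts strictly above threshold in either strain."""
    a = pd.Series(strain_a, dtype=float)
    b = pd.Series(strain_b, dtype=float)
    return set(a.index[a > threshold]) | set(b.index[b > threshold])


# Decision table over (transcript_in_son, protein_in_son, protein_in_nil)
VENN_CATEGORIES: dict[tuple[bool, bool, bool], str] = {
    (True, False, False): "transcript_only",
    (True, True, True): "both_compartments",
    (True, True, False): "son_only_protein",
    (True, False, True): "transported",
    (False, False, True): "nil_only_protein",
    (False, True, False): "protein_no_transcript_son",
    (False, True, True): "protein_no_transcript_both",
    (False, False, False): "absent",
}


def venn_classify(
    transcripts: Iterable[str],
    son_proteins: Iterable[str],
    nil_proteins: Iterable[str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Classify every gene of the universe by compartment presence.

    The eight categories partition the universe.  "transported" marks the
    biologically loaded combination: a cell-body transcript whose protein
    shows up only in the axonal-terminal compartment, consistent with
    somatic synthesis followed by axonal transport.
    """
    universe = set(universe)
    transcripts, son_proteins, nil_proteins = set(transcripts), set(son_proteins), set(nil_proteins)
    for name, s in [
        ("transcripts", transcripts),
        ("son_proteins", son_proteins),
        ("nil_proteins", nil_proteins),
    ]:
        outside = s - universe
        if outside:
            raise ValidationError(f"{name} outside universe: {sorted(outside)[:5]}")
    rows = []
    for gene in sorted(universe):
        key = (gene in transcripts, gene in son_proteins, gene in nil_proteins)
        rows.append(
            {
                "gene_symbol": gene,
                "transcript_in_son": key[0],
                "protein_in_son": key[1],
                "protein_in_nil": key[2],
                "category": VENN_CATEGORIES[key],
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    spearman_r: float
    p_value: float


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p for Spearman rho by full enumeration.

    Enumerates all n! pairings of the (tie-averaged) ranks; p is the
    fraction of permutations with |rho| >= |rho_obs| (up to float slack).
    """
    n = len(rx)
    rx_c = rx - rx.mean()
    denom_x = math.sqrt(float(rx_c @ rx_c))
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    ry_c = perms - perms.mean(axis=1, keepdims=True)
    denom_y = np.sqrt(np.einsum("ij,ij->i", ry_c, ry_c))
    rhos = (ry_c @ rx_c) / (denom_x * denom_y)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def correlate_changes(
    x: Mapping[str, float] | pd.Series, y: Mapping[str, float] | pd.Series
) -> CorrelationResult:
    """Spearman correlation of two per-feature change maps, joined on keys.

    Rho uses average ranks for ties.  The two-sided p-value comes from the
    exact permutation distribution for n <= 9 and from the usual
    t-approximation for larger n.
    """
    xs = pd.Series(x, dtype=float).dropna()
    ys = pd.Series(y, dtype=float).dropna()
    shared = xs.index.intersection(ys.index)
    n = len(shared)
    if n < 3:
        raise ValidationError(f"correlate_changes needs >= 3 shared features, got {n}")
    xv = xs.loc[shared].to_numpy()
    yv = ys.loc[shared].to_numpy()
    rho, p_approx = sps.spearmanr(xv, yv)
    rho = float(rho)
    if n <= 9:
        p = _exact_spearman_p(sps.rankdata(xv), sps.rankdata(yv), rho)
    else:
        p = float(p_approx)
    return CorrelationResult(n, rho, p)


def ora(
    query: Iterable[str],
    background: Iterable[str],
    collection: GeneSetCollection,
    min_term: int = 3,
    max_term: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hypergeometric over-representation against an explicit background.

    Every term is intersected with the background before testing; the
    upper-tail p is P(overlap >= observed) under sampling n_query genes
    from the background.  Benjamini-Hochberg adjustment runs across the
    tested terms of the collection.  Terms whose background-restricted
    size falls outside [min_term, max_term] are skipped and reported.
    Returns ``(results, skipped)``.
    """
    query = set(query)
    background = set(background)
    outside = query - background
    if outside:
        raise ValidationError(f"query genes outside background: {sorted(outside)[:10]}")
    n_bg = len(background)
    n_query = len(query)
    rows, skipped_rows = [], []
    for term in collection:
        members = term.members & background
        m = len(members)
        if m < min_term or m > max_term:
            skipped_rows.append(
                {"term_id": term.term_id, "size_in_background": m, "reason": "size_out_of_bounds"}
            )
            continue
        k = len(members & query)
        p = float(sps.hypergeom.sf(k - 1, n_bg, m, n_query))
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "k_overlap": k,
                "n_query": n_query,
                "m_term_in_background": m,
                "n_background": n_bg,
                "p_hyper": p,
            }
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "k_overlap",
            "n_query",
            "m_term_in_background",
            "n_background",
            "p_hyper",
        ],
    )
    if len(results):
        results["p_adj"] = multipletests(results["p_hyper"], method="fdr_bh")[1]
        results = results.sort_values("p_hyper", kind="stable").reset_index(drop=True)
    else:
        results["p_adj"] = pd.Series(dtype=float)
    skipped = pd.DataFrame(skipped_rows, columns=["term_id", "size_in_background", "reason"])
    return results, skipped


def classify_functional(
    genes: Iterable[str], mapping: Mapping[str, str] | pd.DataFrame
) -> dict[str, str]:
    """Label genes with a user-supplied functional category table.

    The table mirrors pharmacological classifications (endogenous peptide,
    enzyme, transporter, transcription factor, ...) supplied as a
    two-column mapping.  Genes absent from the table are labeled
    "unclassified"; conflicting duplicate entries are an error.
    """
    if isinstance(mapping, pd.DataFrame):
        if mapping.shape[1] < 2:
            raise ValidationError("functional mapping needs two columns (gene, category)")
        gcol, ccol = mapping.columns[:2]
        table: dict[str, str] = {}
        for g, c in zip(mapping[gcol], mapping[ccol]):
            if g in table and table[g] != c:
                raise ValidationError(f"conflicting categories for gene {g!r}: {table[g]!r} vs {c!r}")
            table[g] = c
    else:
        table = dict(mapping)
    return {g: table.get(g, "unclassified") for g in genes}
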