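"""Synthetic study generator with planted ground truth.

Emulates the statistical structure of a two-compartment (cell body vs
axonal terminal) TMT proteome/phosphoproteome study of osmotically
stimulated magnocellular neurones, so that every downstream stage is
testable without any external download:

* 6 control vs 6 water-deprived (WD) samples per tissue (SON, NIL);
* log-normal protein abundances with a planted fraction of differential
  proteins (count fixed by the rounding rule ``floor(frac * n)``, never
  sampled, so tests can assert it);
* phosphopeptides whose abundances ride on top of their parent protein's
  realized per-sample abundance, with planted occupancy effects — this is
  what makes the protein-level subtraction worth exercising;
* per-sample multiplicative loading factors shared between the proteome
  and phospho tables of a tissue, mirroring the reuse of total-protein
  normalization factors;
* a single-cell count matrix with one (or more) planted MCN-like clusters
  marked by elevated Avp/Oxt and Caprin2;
* two bulk transcriptomes with a controllable overlap and a log-normal
  count distribution around a stated median;
* cross-compartment coupling: a planted fraction of genes whose SON
  proteome change shares sign with their NIL phospho occupancy change
  (positive correlation target), and a disjoint fraction whose NIL
  hyperphosphorylation comes with a negative NIL proteome change
  (secretion-like negative correlation target).

All generators are deterministic under their seed.
"""

from __future__ import annotations

import json
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .abundance import PhosphopeptideRecord, group_key_to_str, write_phosphopeptide_table
from .core_io import (
    AbundanceMatrix,
    GeneSet,
    GeneSetCollection,
    SampleDesign,
    SingleCellCounts,
    ValidationError,
    default_design,
    design_samples,
    write_abundance_table,
    write_design,
    write_fasta,
    write_gene_mapping,
    write_gmt,
    write_singlecell,
    write_transcriptome,
)

__all__ = [
    "SimulationParams",
    "ProteomeSim",
    "StudyData",
    "generate_proteome",
    "generate_phosphoproteome",
    "generate_singlecell",
    "generate_transcriptomes",
    "simulate_study",
    "write_study",
]

# A few genes carry their real symbols so marker-based selection and the
# worked examples read naturally; the rest of the universe is G#####.
SPECIAL_GENES = (
    "Avp", "Oxt", "Caprin2", "Nos1", "Stmn1", "Syn1", "Syn2", "Map2", "Rps6",
    "Jund", "Pdyn", "Pam", "Chgb", "Snap25", "Stxbp1", "Cadps", "Vamp2",
    "Rab3a", "Dnm1", "Scg2",
)

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationParams:
    """Knobs of the synthetic study; defaults are the study conditions.

    Effects are on the log2 scale.  ``channel_loading_spread`` s draws the
    per-sample multiplicative loading factor as s**U(-1, 1).  The coupled
    fractions partition the NIL phospho-differential genes into disjoint
    coupling classes.
    """

    n_proteins: int = 1500
    n_per_group: int = 6
    frac_diff_proteome: float = 0.05
    proteome_effect_log2: float = 1.0
    peptides_per_protein: float = 2.0
    frac_diff_phospho: float = 0.08
    phospho_effect_log2: float = 0.8
    residual_sd_log2: float = 0.2
    channel_loading_spread: float = 1.5
    frac_coupled_son_nil: float = 0.3
    frac_secretion_coupled: float = 0.3
    frac_isoform: float = 0.02
    frac_low_confidence: float = 0.2
    frac_detected: float = 0.92
    baseline_log2_mean: float = 18.0
    baseline_log2_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_diff_proteome",
            "frac_diff_phospho",
            "frac_coupled_son_nil",
            "frac_secretion_coupled",
            "frac_isoform",
            "frac_low_confidence",
            "frac_detected",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be positive")
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2 (Welch test needs 2 per group)")
        if self.residual_sd_log2 < 0:
            raise ValidationError("residual_sd_log2 must be >= 0")
        if self.channel_loading_spread < 1.0:
            raise ValidationError("channel_loading_spread must be >= 1")
        if self.frac_coupled_son_nil + self.frac_secretion_coupled > 1.0:
            raise ValidationError("coupling fractions must sum to <= 1 (classes are disjoint)")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def planted_count(frac: float, n: int) -> int:
    """Deterministic differential count: floor(frac * n)."""
    return int(math.floor(frac * n))


# ---------------------------------------------------------------------------
# universe


def make_universe(params: SimulationParams, rng: np.random.Generator):
    """Accessions, gene mapping and protein sequences.

    One accession per protein; the first ``floor(frac_isoform * n)`` genes
    own a second (isoform) accession, so gene-level aggregation is
    exercised downstream.
    """
    n = params.n_proteins
    n_iso = planted_count(params.frac_isoform, n)
    n_genes = n - n_iso
    genes = list(SPECIAL_GENES[: min(len(SPECIAL_GENES), n_genes)])
    genes += [f"G{i:05d}" for i in range(len(genes), n_genes)]
    accessions = [f"P{i:05d}" for i in range(n_genes)]
    gene_of = dict(zip(accessions, genes))
    for i in range(n_iso):
        iso_acc = f"P{i:05d}B"
        accessions.append(iso_acc)
        gene_of[iso_acc] = genes[i]
    sequences = {}
    for acc in accessions:
        length = int(rng.integers(200, 401))
        sequences[acc] = "".join(rng.choice(AA_ALPHABET, size=length))
    return accessions, gene_of, sequences


# ---------------------------------------------------------------------------
# proteome


@dataclass
class ProteomeSim:
    """One tissue's simulated proteome plus the internals phospho needs."""

    matrix: AbundanceMatrix  # raw scale
    truth: pd.DataFrame
    realized_log2: pd.DataFrame  # pre-loading log2 values, used as phospho backbone
    loading: dict[str, float]
    effects: dict[str, float]


def _check_single_tissue(design: Sequence[SampleDesign]) -> str:
    tissues = {d.tissue for d in design}
    if len(tissues) != 1:
        raise ValidationError(f"design must cover one tissue, got {sorted(tissues)}")
    for cond in ("control", "WD"):
        if sum(d.condition == cond for d in design) < 2:
            raise ValidationError(f"design needs >= 2 samples in condition {cond!r}")
    return tissues.pop()


def generate_proteome(
    params: SimulationParams,
    design: Sequence[SampleDesign],
    accessions: Sequence[str] | None = None,
    effects: Mapping[str, float] | None = None,
    gene_of: Mapping[str, str] | None = None,
    coupling_class: Mapping[str, str] | None = None,
    rng: np.random.Generator | int | None = None,
) -> ProteomeSim:
    """Raw-scale proteome matrix with planted differential proteins.

    If ``effects`` is not supplied, ``floor(frac_diff_proteome * n)``
    proteins get an effect of magnitude ``proteome_effect_log2``, half up
    and half down.  Per-sample loading factors multiply the exported raw
    values; WD samples are shifted by the true log2 fold change.
    """
    rng = _rng(params.seed if rng is None else rng)
    tissue = _check_single_tissue(design)
    if accessions is None:
        accessions = [f"P{i:05d}" for i in range(params.n_proteins)]
    accessions = list(accessions)
    n = len(accessions)

    if effects is None:
        n_diff = planted_count(params.frac_diff_proteome, n)
        chosen = rng.permutation(n)[:n_diff]
        effects = {}
        for j, idx in enumerate(chosen):
            sign = 1.0 if j < (n_diff + 1) // 2 else -1.0
            effects[accessions[idx]] = sign * params.proteome_effect_log2
    effects = dict(effects)

    samples = design_samples(design)
    is_wd = np.array([d.condition == "WD" for d in design], dtype=float)
    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, size=n)
    eff = np.array([effects.get(a, 0.0) for a in accessions])
    noise = (
        rng.normal(0.0, params.residual_sd_log2, size=(n, len(samples)))
        if params.residual_sd_log2 > 0
        else np.zeros((n, len(samples)))
    )
    log2_vals = baseline[:, None] + eff[:, None] * is_wd[None, :] + noise
    spread = params.channel_loading_spread
    loading = spread ** rng.uniform(-1.0, 1.0, size=len(samples)) if spread > 1 else np.ones(len(samples))
    raw = np.exp2(log2_vals) * loading[None, :]

    matrix = AbundanceMatrix(
        pd.DataFrame(raw, index=pd.Index(accessions, name="accession"), columns=samples),
        scale="raw",
    )
    truth = pd.DataFrame(
        {
            "feature_id": accessions,
            "tissue": tissue,
            "layer": "proteome",
            "gene_symbol": [gene_of.get(a, a) if gene_of else a for a in accessions],
            "true_log2fc": eff,
            "is_differential": eff != 0.0,
            "coupling_class": [
                (coupling_class or {}).get(a, "none") for a in accessions
            ],
        }
    )
    realized = pd.DataFrame(log2_vals, index=matrix.data.index, columns=samples)
    return ProteomeSim(matrix, truth, realized, dict(zip(samples, loading)), effects)


# ---------------------------------------------------------------------------
# phosphoproteome


def _plan_phospho(
    accessions: Sequence[str],
    params: SimulationParams,
    rng: np.random.Generator,
) -> list[tuple[str, float]]:
    """Peptide slots (accession, occupancy effect).

    Peptide counts per protein are Poisson around the stated mean;
    ``floor(frac_diff_phospho * n_peptides)`` slots carry an occupancy
    effect of magnitude ``phospho_effect_log2`` with random sign.
    """
    slots: list[str] = []
    counts = rng.poisson(params.peptides_per_protein, size=len(accessions))
    for acc, c in zip(accessions, counts):
        slots.extend([acc] * int(c))
    n_pep = len(slots)
    n_diff = planted_count(params.frac_diff_phospho, n_pep)
    diff_idx = set(rng.permutation(n_pep)[:n_diff].tolist())
    signs = rng.choice([-1.0, 1.0], size=n_pep)
    return [
        (acc, signs[i] * params.phospho_effect_log2 if i in diff_idx else 0.0)
        for i, acc in enumerate(slots)
    ]


def _draw_peptide(seq: str, rng: np.random.Generator, used_keys: set) -> tuple[str, tuple]:
    """A substring with >= 1 phospho-acceptor residue and a fresh group key."""
    for _ in range(200):
        length = int(rng.integers(8, 16))
        if length >= len(seq):
            length = max(4, len(seq) - 1)
        start = int(rng.integers(0, len(seq) - length + 1))
        pep = seq[start : start + length]
        acceptors = [i + 1 for i, ch in enumerate(pep) if ch in "STY"]
        if not acceptors:
            continue
        n_sites = 1 if len(acceptors) == 1 or rng.random() < 0.7 else 2
        offsets = sorted(rng.choice(acceptors, size=n_sites, replace=False).tolist())
        sites = tuple((pep[o - 1], int(o)) for o in offsets)
        key_loc = (pep, sites)
        key_unloc = (pep, len(sites))
        if key_loc not in used_keys and key_unloc not in used_keys:
            used_keys.add(key_loc)
            used_keys.add(key_unloc)
            return pep, sites
    raise ValidationError("could not draw a phosphopeptide; sequence too short or exhausted")


def generate_phosphoproteome(
    proteome: ProteomeSim,
    params: SimulationParams,
    design: Sequence[SampleDesign],
    sequences: Mapping[str, str],
    plan: Sequence[tuple[str, float]] | None = None,
    gene_of: Mapping[str, str] | None = None,
    coupling_class: Mapping[str, str] | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[PhosphopeptideRecord], pd.DataFrame]:
    """Phosphopeptide PSMs riding on the realized proteome.

    Each peptide's per-sample log2 abundance is the parent protein's
    realized log2 value plus a peptide offset, plus the occupancy effect in
    WD samples, plus residual noise; the exported raw values share the
    proteome's loading factors.  After protein-level adjustment the
    expected log2 fold change of a peptide is therefore exactly its
    occupancy effect.  Some peptides get site confidences <= 70 to
    exercise the localization rule, and some are emitted as two PSMs to
    exercise grouping.
    """
    rng = _rng(params.seed + 1 if rng is None else rng)
    tissue = _check_single_tissue(design)
    samples = design_samples(design)
    if list(proteome.matrix.sample_ids) != samples:
        raise ValidationError("phospho design does not match the proteome's samples")
    if plan is None:
        plan = _plan_phospho(proteome.matrix.feature_ids, params, rng)
    unknown = [acc for acc, _ in plan if acc not in proteome.realized_log2.index]
    if unknown:
        raise ValidationError(f"plan references proteins absent from proteome: {unknown[:5]}")

    is_wd = np.array([d.condition == "WD" for d in design], dtype=float)
    loading = np.array([proteome.loading[s] for s in samples])
    used_keys: set = set()
    records: list[PhosphopeptideRecord] = []
    truth_rows = []
    counter = 0
    for acc, occ in plan:
        seq = sequences[acc]
        pep, sites = _draw_peptide(seq, rng, used_keys)
        low_conf = rng.random() < params.frac_low_confidence
        confidence = float(rng.uniform(30.0, 70.0)) if low_conf else float(rng.uniform(75.0, 100.0))
        offset = float(rng.uniform(-3.0, -1.0))
        noise = (
            rng.normal(0.0, params.residual_sd_log2, size=len(samples))
            if params.residual_sd_log2 > 0
            else np.zeros(len(samples))
        )
        log2_vals = (
            proteome.realized_log2.loc[acc].to_numpy() + offset + occ * is_wd + noise
        )
        n_psms = 2 if rng.random() < 0.15 else 1
        raw = np.exp2(log2_vals - math.log2(n_psms)) * loading
        for k in range(n_psms):
            counter += 1
            records.append(
                PhosphopeptideRecord(
                    psm_id=f"{tissue}_psm{counter:06d}",
                    peptide_sequence=pep,
                    parent_accession=acc,
                    sites=sites,
                    site_confidence=confidence,
                    abundances=pd.Series(raw, index=samples),
                )
            )
        localized = confidence > 70.0
        key = (pep, sites) if localized else (pep, len(sites))
        truth_rows.append(
            {
                "feature_id": group_key_to_str(key),
                "tissue": tissue,
                "layer": "phospho",
                "gene_symbol": gene_of.get(acc, acc) if gene_of else acc,
                "parent_accession": acc,
                "true_log2fc": occ,
                "is_differential": occ != 0.0,
                "coupling_class": (coupling_class or {}).get(acc, "none"),
            }
        )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# single cell


def generate_singlecell(
    genes: Sequence[str] | int,
    n_cells: int = 400,
    frac_mcn: float = 0.25,
    marker_genes: Sequence[str] = ("Avp", "Oxt", "Caprin2"),
    marker_ratio: float = 50.0,
    marker_base: float = 0.02,
    program_genes: Sequence[str] | None = None,
    program_ratio: float = 8.0,
    base_mean: float = 0.3,
    dispersion: float = 0.5,
    n_mcn_clusters: int = 1,
    n_other_clusters: int = 3,
    seed: int | np.random.Generator = 0,
) -> tuple[SingleCellCounts, set[str]]:
    """Negative-binomial counts with planted MCN-like cluster(s).

    ``floor(frac_mcn * n_cells)`` cells are MCN; in those cells the marker
    genes' means are multiplied by ``marker_ratio`` and an optional MCN
    expression program by ``program_ratio``.  Counts are Gamma-Poisson
    (negative binomial) with the stated dispersion.  Returns the matrix
    (with cluster labels attached) and the planted MCN barcodes.
    """
    rng = _rng(seed)
    if isinstance(genes, int):
        gene_list = list(marker_genes) + [f"G{i:05d}" for i in range(len(marker_genes), genes)]
    else:
        gene_list = list(genes)
    missing = [m for m in marker_genes if m not in gene_list]
    if missing:
        raise ValidationError(f"marker gene(s) missing from gene universe: {missing}")
    n_genes = len(gene_list)
    n_mcn = planted_count(frac_mcn, n_cells)

    base = rng.lognormal(mean=math.log(base_mean), sigma=1.0, size=n_genes)
    mcn_mult = np.ones(n_genes)
    gene_idx = {g: i for i, g in enumerate(gene_list)}
    # markers are cluster-specific: fixed low baseline outside MCN cells, so
    # the marker rule separates clusters for any seed
    for m in marker_genes:
        base[gene_idx[m]] = marker_base
        mcn_mult[gene_idx[m]] = marker_ratio
    if program_genes is not None:
        for g in program_genes:
            if g in gene_idx and g not in marker_genes:
                mcn_mult[gene_idx[g]] = program_ratio

    is_mcn = np.zeros(n_cells, dtype=bool)
    is_mcn[:n_mcn] = True
    means = np.where(is_mcn[None, :], (base * mcn_mult)[:, None], base[:, None])
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, means * dispersion, size=(n_genes, n_cells))
    counts = rng.poisson(lam).astype(np.int64)
    # no empty cells: give any zero-total cell one count of the first gene
    empty = counts.sum(axis=0) == 0
    counts[0, empty] = 1

    barcodes = [f"cell{i:04d}" for i in range(n_cells)]
    clusters: dict[str, str] = {}
    for i, b in enumerate(barcodes):
        if is_mcn[i]:
            clusters[b] = f"MCN_{i % max(1, n_mcn_clusters)}"
        else:
            clusters[b] = f"other_{int(rng.integers(0, max(1, n_other_clusters)))}"
    sc = SingleCellCounts(sparse.csr_matrix(counts), gene_list, barcodes, clusters)
    return sc, {b for i, b in enumerate(barcodes) if is_mcn[i]}


# ---------------------------------------------------------------------------
# transcriptomes


def generate_transcriptomes(
    gene_universe: Sequence[str],
    overlap_frac: float = 0.85,
    expression_scale: float = 50.0,
    frac_expressed: float = 0.85,
    sigma: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.Series, pd.Series]:
    """Two strain transcriptomes sharing ``overlap_frac`` of expressed genes.

    Expressed genes draw counts from LogNormal(ln(scale), sigma), whose
    median is exactly ``expression_scale`` — so a scale at the detection
    threshold puts half the expressed genes below it.  Non-expressed genes
    have zero counts (undetected).
    """
    if not 0.0 <= overlap_frac <= 1.0:
        raise ValidationError("overlap_frac must be in [0, 1]")
    rng = _rng(seed)
    genes = list(gene_universe)
    n = len(genes)
    order = rng.permutation(n)
    n_expr = planted_count(frac_expressed, n)
    n_shared = planted_count(overlap_frac, n_expr)
    expr_a = [genes[i] for i in order[:n_expr]]
    unique_b_pool = [genes[i] for i in order[n_expr:]]
    n_unique = n_expr - n_shared
    expr_b = expr_a[:n_shared] + unique_b_pool[:n_unique]
    if len(expr_b) < n_expr:  # small universe: reuse strain-a tail, raising overlap
        expr_b += expr_a[n_shared : n_shared + (n_expr - len(expr_b))]

    def table(expressed: list[str]) -> pd.Series:
        counts = pd.Series(0.0, index=genes)
        counts.loc[expressed] = rng.lognormal(math.log(expression_scale), sigma, size=len(expressed))
        counts.index.name = "gene_symbol"
        return counts

    return table(expr_a), table(expr_b)


# ---------------------------------------------------------------------------
# whole-study orchestration


@dataclass
class StudyData:
    """Everything the pipeline consumes, plus planted ground truth."""

    params: SimulationParams
    design_son: list[SampleDesign]
    design_nil: list[SampleDesign]
    son_proteome: ProteomeSim
    nil_proteome: ProteomeSim
    son_phospho: list[PhosphopeptideRecord]
    nil_phospho: list[PhosphopeptideRecord]
    gene_of: dict[str, str]
    sequences: dict[str, str]
    singlecell: SingleCellCounts
    mcn_barcodes: set[str]
    transcriptome_a: pd.Series
    transcriptome_b: pd.Series
    genesets: GeneSetCollection
    ground_truth: pd.DataFrame


def simulate_study(params: SimulationParams | None = None) -> StudyData:
    """Generate the full coupled two-tissue study.

    Coupling is planted gene-wise: NIL phospho occupancy effects are drawn
    first; a fraction of the genes carrying them get a same-sign SON
    proteome effect (transport-then-phosphorylate, positive correlation
    target) and a disjoint fraction get an opposite-sign NIL proteome
    effect (phosphorylate-then-secrete, negative correlation target).
    """
    params = params or SimulationParams()
    rng = _rng(params.seed)
    accessions, gene_of, sequences = make_universe(params, rng)
    n_acc = len(accessions)

    n_detected = planted_count(params.frac_detected, n_acc)
    son_detected = [accessions[i] for i in sorted(rng.permutation(n_acc)[:n_detected])]
    nil_detected = [accessions[i] for i in sorted(rng.permutation(n_acc)[:n_detected])]

    # 1. NIL phospho plan first: it anchors both coupling classes.
    nil_plan = _plan_phospho(nil_detected, params, rng)
    gene_occ: dict[str, float] = {}
    for acc, occ in nil_plan:
        if occ != 0.0:
            gene_occ[gene_of[acc]] = gene_occ.get(gene_of[acc], 0.0) + occ
    primary_acc = {}
    for acc in accessions:
        primary_acc.setdefault(gene_of[acc], acc)
    son_set, nil_set = set(son_detected), set(nil_detected)
    couplable = [
        g
        for g in gene_occ
        if gene_occ[g] != 0.0 and primary_acc[g] in son_set and primary_acc[g] in nil_set
    ]
    couplable = [couplable[i] for i in rng.permutation(len(couplable))]
    n_c1 = planted_count(params.frac_coupled_son_nil, len(couplable))
    n_c2 = planted_count(params.frac_secretion_coupled, len(couplable))
    son_coupled = couplable[:n_c1]
    secretion = couplable[n_c1 : n_c1 + n_c2]

    eff = params.proteome_effect_log2
    son_effects = {primary_acc[g]: math.copysign(eff, gene_occ[g]) for g in son_coupled}
    nil_effects = {primary_acc[g]: -math.copysign(eff, gene_occ[g]) for g in secretion}
    coupling_by_acc: dict[str, str] = {}
    for g in son_coupled:
        coupling_by_acc[primary_acc[g]] = "son_proteome->nil_phospho"
    for g in secretion:
        coupling_by_acc[primary_acc[g]] = "nil_phospho->nil_secretion"

    def fill_effects(detected: list[str], forced: dict[str, float]) -> dict[str, float]:
        n_diff = planted_count(params.frac_diff_proteome, len(detected))
        effects = dict(forced)
        pool = [a for a in detected if a not in effects]
        pool = [pool[i] for i in rng.permutation(len(pool))]
        extra = max(0, n_diff - len(effects))
        for j, acc in enumerate(pool[:extra]):
            effects[acc] = eff if j % 2 == 0 else -eff
        return effects

    design_son = default_design("SON", params.n_per_group)
    design_nil = default_design("NIL", params.n_per_group)
    son_proteome = generate_proteome(
        params, design_son, son_detected, fill_effects(son_detected, son_effects),
        gene_of, coupling_by_acc, rng,
    )
    nil_proteome = generate_proteome(
        params, design_nil, nil_detected, fill_effects(nil_detected, nil_effects),
        gene_of, coupling_by_acc, rng,
    )

    son_plan = _plan_phospho(son_detected, params, rng)
    son_phospho, son_ph_truth = generate_phosphoproteome(
        son_proteome, params, design_son, sequences, son_plan, gene_of, coupling_by_acc, rng
    )
    nil_phospho, nil_ph_truth = generate_phosphoproteome(
        nil_proteome, params, design_nil, sequences, nil_plan, gene_of, coupling_by_acc, rng
    )

    # 2. single-cell reference with an MCN program covering most planted
    #    differential genes plus random fill, ~12% of the universe.
    genes_all = sorted(set(gene_of.values()))
    diff_genes = {
        gene_of[a]
        for sim in (son_proteome, nil_proteome)
        for a in sim.effects
    } | set(gene_occ)
    program = {g for g in diff_genes if rng.random() < 0.7}
    target_program = planted_count(0.12, len(genes_all))
    fill_pool = [g for g in genes_all if g not in program]
    fill_pool = [fill_pool[i] for i in rng.permutation(len(fill_pool))]
    program.update(fill_pool[: max(0, target_program - len(program))])
    singlecell, mcn_barcodes = generate_singlecell(
        genes_all, program_genes=sorted(program), seed=rng
    )

    # 3. transcriptomes and gene sets
    tr_a, tr_b = generate_transcriptomes(genes_all, seed=rng)
    genesets = _make_genesets(genes_all, gene_occ, program, rng)

    truth = pd.concat(
        [son_proteome.truth, nil_proteome.truth, son_ph_truth, nil_ph_truth],
        ignore_index=True,
    )
    return StudyData(
        params=params,
        design_son=design_son,
        design_nil=design_nil,
        son_proteome=son_proteome,
        nil_proteome=nil_proteome,
        son_phospho=son_phospho,
        nil_phospho=nil_phospho,
        gene_of=gene_of,
        sequences=sequences,
        singlecell=singlecell,
        mcn_barcodes=mcn_barcodes,
        transcriptome_a=tr_a,
        transcriptome_b=tr_b,
        genesets=genesets,
        ground_truth=truth,
    )


def _make_genesets(
    genes_all: list[str],
    gene_occ: Mapping[str, float],
    program: set[str],
    rng: np.random.Generator,
    n_random_terms: int = 17,
) -> GeneSetCollection:
    """A small GMT-style collection: a few terms enriched in the planted
    phospho-differential genes, the rest random draws from the universe."""
    sets = []
    hyper = sorted(g for g, e in gene_occ.items() if e > 0 and g in program)
    hypo = sorted(g for g, e in gene_occ.items() if e < 0 and g in program)
    pool = np.array(genes_all)
    if len(hyper) >= 3:
        pad = rng.choice(pool, size=max(0, 15 - len(hyper)), replace=False).tolist()
        sets.append(GeneSet("T_HYPER", "planted hyperphosphorylation program", frozenset(hyper + pad)))
    if len(hypo) >= 3:
        pad = rng.choice(pool, size=max(0, 15 - len(hypo)), replace=False).tolist()
        sets.append(GeneSet("T_HYPO", "planted hypophosphorylation program", frozenset(hypo + pad)))
    for i in range(n_random_terms):
        size = int(rng.integers(10, 80))
        members = rng.choice(pool, size=min(size, len(pool)), replace=False)
        sets.append(GeneSet(f"T_RAND{i:02d}", f"random term {i}", frozenset(members.tolist())))
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# writers


def write_study(study: StudyData, outdir: str | Path) -> dict[str, str]:
    """Write every pipeline input (and the ground truth) as text files.

    Emits exactly the formats ``core_io`` reads: TSV abundance/design/
    mapping tables, FASTA, MTX + TSVs, GMT, plus ground_truth.tsv and the
    simulation parameters as JSON.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "design": str(outdir / "design.tsv"),
        "son_proteome": str(outdir / "son_proteome.tsv"),
        "nil_proteome": str(outdir / "nil_proteome.tsv"),
        "son_phospho": str(outdir / "son_phospho.tsv"),
        "nil_phospho": str(outdir / "nil_phospho.tsv"),
        "gene_mapping": str(outdir / "gene_mapping.tsv"),
        "fasta": str(outdir / "proteins.fasta"),
        "singlecell_dir": str(outdir / "singlecell"),
        "transcriptome_a": str(outdir / "transcriptome_wistar_like.tsv"),
        "transcriptome_b": str(outdir / "transcriptome_sprague_like.tsv"),
        "gmt": str(outdir / "genesets.gmt"),
        "ground_truth": str(outdir / "ground_truth.tsv"),
        "params": str(outdir / "simulation_params.json"),
    }
    write_design(paths["design"], study.design_son + study.design_nil)
    write_abundance_table(paths["son_proteome"], study.son_proteome.matrix)
    write_abundance_table(paths["nil_proteome"], study.nil_proteome.matrix)
    write_phosphopeptide_table(paths["son_phospho"], study.son_phospho, study.design_son)
    write_phosphopeptide_table(paths["nil_phospho"], study.nil_phospho, study.design_nil)
    write_gene_mapping(paths["gene_mapping"], study.gene_of)
    write_fasta(paths["fasta"], study.sequences)
    write_singlecell(paths["singlecell_dir"], study.singlecell)
    write_transcriptome(paths["transcriptome_a"], study.transcriptome_a)
    write_transcriptome(paths["transcriptome_b"], study.transcriptome_b)
    write_gmt(paths["gmt"], study.genesets)
    study.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False, float_format="%.17g")
    with open(paths["params"], "w") as fh:
        json.dump(asdict(study.params), fh, indent=2, sort_keys=True)
    return paths
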