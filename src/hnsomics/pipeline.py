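"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes: normalize -> group/adjust phospho ->
differential tables (proteome and phospho per tissue) -> cumulative
phosphorylation-state scores with the 2-SD cutoff -> MCN reference list ->
transcriptome merge and Venn classification -> cross-compartment Spearman
correlations -> over-representation analysis — writing every intermediate
table to the output directory, with a structured run report that doubles
as a methods audit (per-stage counts and every cutoff used).

Every output is deterministic for a given config + input set: rerunning
produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance, core_io, integrate, phospho, stats
from .core_io import AbundanceMatrix, ValidationError

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "analyze_study"]

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and the analysis constants, JSON-serializable.

    The defaults are the study's printed constants: uncorrected alpha 0.05,
    site-localization confidence threshold 70%, MCN mean-normalized-count
    cutoff 0.5, transcript count threshold 10, and a 2-SD multiplier for
    the phosphorylation-state cutoff.
    """

    design: str = ""
    son_proteome: str = ""
    nil_proteome: str = ""
    son_phospho: str = ""
    nil_phospho: str = ""
    gene_mapping: str = ""
    fasta: str = ""
    singlecell_dir: str = ""
    transcriptome_a: str = ""
    transcriptome_b: str = ""
    gmt: str = ""
    out_dir: str = "pipeline_out"
    alpha: float = 0.05
    site_confidence_threshold: float = 70.0
    mcn_count_cutoff: float = 0.5
    mcn_expr_threshold: float = 1.0
    transcript_count_threshold: float = 10.0
    delta_ps_sd_multiplier: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        for name in (
            "site_confidence_threshold",
            "mcn_count_cutoff",
            "transcript_count_threshold",
            "delta_ps_sd_multiplier",
            "mcn_expr_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def for_study_dir(cls, data_dir: str | Path, out_dir: str | Path, **overrides) -> "PipelineConfig":
        """Config pointing at the file layout ``simulate.write_study`` emits."""
        d = Path(data_dir)
        return cls(
            design=str(d / "design.tsv"),
            son_proteome=str(d / "son_proteome.tsv"),
            nil_proteome=str(d / "nil_proteome.tsv"),
            son_phospho=str(d / "son_phospho.tsv"),
            nil_phospho=str(d / "nil_phospho.tsv"),
            gene_mapping=str(d / "gene_mapping.tsv"),
            fasta=str(d / "proteins.fasta"),
            singlecell_dir=str(d / "singlecell"),
            transcriptome_a=str(d / "transcriptome_wistar_like.tsv"),
            transcriptome_b=str(d / "transcriptome_sprague_like.tsv"),
            gmt=str(d / "genesets.gmt"),
            out_dir=str(out_dir),
            **overrides,
        )


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the run report (also written as JSON).

    Any stage error aborts with :class:`PipelineError` naming the stage;
    outputs of completed stages are retained and listed in MANIFEST.txt.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    report: dict = {"stages": {}, "cutoffs": {
        "alpha": config.alpha,
        "site_confidence_threshold": config.site_confidence_threshold,
        "mcn_count_cutoff": config.mcn_count_cutoff,
        "mcn_expr_threshold": config.mcn_expr_threshold,
        "transcript_count_threshold": config.transcript_count_threshold,
        "delta_ps_sd_multiplier": config.delta_ps_sd_multiplier,
    }}

    def finish_stage(name: str, counts: dict) -> None:
        manifest.append(name)
        report["stages"][name] = counts
        (out / "MANIFEST.txt").write_text("\n".join(manifest) + "\n")

    state: dict = {}

    def stage(name: str, fn) -> None:
        try:
            counts = fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - abort carries stage name
            raise PipelineError(name, exc) from exc
        finish_stage(name, counts)

    stage("load", lambda: _stage_load(config, state))
    stage("normalize", lambda: _stage_normalize(config, state, out))
    stage("adjust", lambda: _stage_adjust(config, state, out))
    stage("differential", lambda: _stage_differential(config, state, out))
    stage("deltaps", lambda: _stage_deltaps(config, state, out))
    stage("mcn", lambda: _stage_mcn(config, state, out))
    stage("integrate", lambda: _stage_integrate(config, state, out))
    stage("enrich", lambda: _stage_enrich(config, state, out))

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest.append("report")
    (out / "MANIFEST.txt").write_text("\n".join(manifest) + "\n")
    return report


def analyze_study(study, alpha: float = 0.05, sd_multiplier: float = 2.0,
                  confidence_threshold: float = 70.0) -> dict:
    """In-memory analysis of a simulated study (no file round-trip).

    Runs normalization, phospho grouping/adjustment, differential tables,
    cumulative phosphorylation-state scoring and the two coupled
    cross-compartment correlations.  Used for replicate-heavy evaluations
    where writing intermediates would dominate the runtime; the file-based
    ``run_pipeline`` covers the same chain stage by stage.
    """
    from . import stats as _stats

    out: dict = {}
    for tissue, sim, records, design in [
        ("SON", study.son_proteome, study.son_phospho, study.design_son),
        ("NIL", study.nil_proteome, study.nil_phospho, study.design_nil),
    ]:
        factors = abundance.compute_normalization_factors(sim.matrix)
        prot_log2 = abundance.normalize_log2(sim.matrix, factors)
        groups = abundance.group_phosphopeptides(records, confidence_threshold)
        ph_raw = abundance.groups_to_matrix(groups, sim.matrix.sample_ids)
        ph_log2 = abundance.normalize_log2(ph_raw, factors)
        parent_of = {g.key_str: g.parent_accession for g in groups}
        adjusted, _ = abundance.adjust_phosphopeptides(ph_log2, prot_log2, parent_of)
        prot_diff, _ = _stats.differential_table(prot_log2, design, alpha)
        ph_diff, _ = _stats.differential_table(adjusted, design, alpha)
        cutoff = phospho.mean_peptide_sd(adjusted, sd_multiplier)
        parent_gene = {k: study.gene_of[a] for k, a in parent_of.items() if a in study.gene_of}
        dps, _ = phospho.delta_ps(ph_diff, parent_gene, alpha)
        out[f"{tissue}_proteome_diff"] = prot_diff
        out[f"{tissue}_phospho_diff"] = ph_diff
        out[f"{tissue}_adjusted"] = adjusted
        out[f"{tissue}_cutoff"] = cutoff
        out[f"{tissue}_deltaps"] = phospho.classify_delta_ps(dps, cutoff)

    def gene_fc(diff: pd.DataFrame) -> pd.Series:
        d = diff.copy()
        d["gene"] = d["feature_id"].map(study.gene_of)
        d = d.dropna(subset=["gene"]).drop_duplicates("gene", keep="first")
        return pd.Series(d["log2fc"].to_numpy(), index=d["gene"])

    son_fc, nil_fc = gene_fc(out["SON_proteome_diff"]), gene_fc(out["NIL_proteome_diff"])
    nil_dps = pd.Series(
        out["NIL_deltaps"]["delta_ps"].to_numpy(), index=out["NIL_deltaps"]["gene_symbol"]
    )
    out["r_nil_dps_vs_son_proteome"] = integrate.correlate_changes(nil_dps, son_fc)
    out["r_nil_dps_vs_nil_proteome"] = integrate.correlate_changes(nil_dps, nil_fc)
    return out


# -- stages -----------------------------------------------------------------


def _stage_load(config: PipelineConfig, state: dict) -> dict:
    design = core_io.read_design(config.design)
    state["design"] = {t: [d for d in design if d.tissue == t] for t in core_io.TISSUES}
    counts = {}
    for tissue, prot_path in [("SON", config.son_proteome), ("NIL", config.nil_proteome)]:
        des = state["design"][tissue]
        state[f"{tissue}_proteome_raw"] = core_io.read_abundance_table(prot_path, des)
        counts[f"{tissue}_proteins"] = len(state[f"{tissue}_proteome_raw"].data)
    state["gene_of"] = core_io.read_gene_mapping(config.gene_mapping)
    counts["gene_mappings"] = len(state["gene_of"])
    return counts


def _stage_normalize(config: PipelineConfig, state: dict, out: Path) -> dict:
    counts = {}
    factor_rows = []
    for tissue in core_io.TISSUES:
        raw = state[f"{tissue}_proteome_raw"]
        factors = abundance.compute_normalization_factors(raw)
        log2 = abundance.normalize_log2(raw, factors)
        state[f"{tissue}_factors"] = factors
        state[f"{tissue}_proteome_log2"] = log2
        core_io.write_abundance_table(out / f"{tissue.lower()}_proteome_log2.tsv", log2)
        for s, f in factors.factors.items():
            factor_rows.append({"tissue": tissue, "sample_id": s, "factor": f})
        counts[f"{tissue}_proteins_normalized"] = len(log2.data)
    _write_tsv(out / "normalization_factors.tsv", pd.DataFrame(factor_rows))
    return counts


def _stage_adjust(config: PipelineConfig, state: dict, out: Path) -> dict:
    counts = {}
    phospho_paths = {"SON": config.son_phospho, "NIL": config.nil_phospho}
    for tissue in core_io.TISSUES:
        records = abundance.read_phosphopeptide_table(
            phospho_paths[tissue], state["design"][tissue]
        )
        state[f"{tissue}_phospho_records"] = records
        if not records:
            raise ValidationError(f"no phosphopeptide records for {tissue}")
        groups = abundance.group_phosphopeptides(
            records, confidence_threshold=config.site_confidence_threshold
        )
        samples = core_io.design_samples(state["design"][tissue])
        raw = abundance.groups_to_matrix(groups, samples)
        # the total-protein loading factors are reused for the phospho table
        log2 = abundance.normalize_log2(raw, state[f"{tissue}_factors"])
        parent_of = {g.key_str: g.parent_accession for g in groups}
        adjusted, unadjusted = abundance.adjust_phosphopeptides(
            log2, state[f"{tissue}_proteome_log2"], parent_of
        )
        state[f"{tissue}_groups"] = groups
        state[f"{tissue}_parent_of"] = parent_of
        state[f"{tissue}_phospho_adjusted"] = adjusted
        core_io.write_abundance_table(out / f"{tissue.lower()}_phospho_adjusted.tsv", adjusted)
        counts[f"{tissue}_psms"] = len(records)
        counts[f"{tissue}_groups"] = len(groups)
        counts[f"{tissue}_localized_groups"] = sum(g.localized for g in groups)
        counts[f"{tissue}_unadjusted_groups"] = len(unadjusted)
    return counts


def _stage_differential(config: PipelineConfig, state: dict, out: Path) -> dict:
    counts = {}
    for tissue in core_io.TISSUES:
        design = state["design"][tissue]
        for layer, key in [("proteome", f"{tissue}_proteome_log2"), ("phospho", f"{tissue}_phospho_adjusted")]:
            table, skipped = stats.differential_table(state[key], design, alpha=config.alpha)
            state[f"{tissue}_{layer}_diff"] = table
            _write_tsv(out / f"{tissue.lower()}_{layer}_differential.tsv", table)
            if len(skipped):
                _write_tsv(out / f"{tissue.lower()}_{layer}_skipped.tsv", skipped)
            counts[f"{tissue}_{layer}_tested"] = len(table)
            counts[f"{tissue}_{layer}_skipped"] = len(skipped)
            counts[f"{tissue}_{layer}_up"] = int((table["class"] == "up").sum())
            counts[f"{tissue}_{layer}_down"] = int((table["class"] == "down").sum())
        pca = stats.pca_scores(state[f"{tissue}_proteome_log2"])
        scores = pca.scores.copy()
        scores.insert(0, "sample_id", scores.index)
        _write_tsv(out / f"{tissue.lower()}_proteome_pca.tsv", scores)
        counts[f"{tissue}_pca_var_pc1"] = float(pca.variance_explained[0])
    return counts


def _stage_deltaps(config: PipelineConfig, state: dict, out: Path) -> dict:
    counts = {}
    gene_of = state["gene_of"]
    for tissue in core_io.TISSUES:
        cutoff = phospho.mean_peptide_sd(
            state[f"{tissue}_phospho_adjusted"], sd_multiplier=config.delta_ps_sd_multiplier
        )
        parent_gene = {
            key: gene_of[acc]
            for key, acc in state[f"{tissue}_parent_of"].items()
            if acc in gene_of
        }
        records, unmapped = phospho.delta_ps(
            state[f"{tissue}_phospho_diff"], parent_gene, alpha=config.alpha
        )
        classified = phospho.classify_delta_ps(records, cutoff)
        state[f"{tissue}_deltaps"] = classified
        state[f"{tissue}_deltaps_cutoff"] = cutoff
        _write_tsv(out / f"{tissue.lower()}_deltaps.tsv", classified)
        counts[f"{tissue}_mean_peptide_sd"] = cutoff.mean_peptide_sd
        counts[f"{tissue}_cutoff"] = cutoff.cutoff
        counts[f"{tissue}_genes_scored"] = len(classified)
        counts[f"{tissue}_hyper"] = int((classified.get("ps_class", pd.Series(dtype=str)) == "hyper").sum())
        counts[f"{tissue}_hypo"] = int((classified.get("ps_class", pd.Series(dtype=str)) == "hypo").sum())
        counts[f"{tissue}_unmapped_groups"] = len(unmapped)
    return counts


def _stage_mcn(config: PipelineConfig, state: dict, out: Path) -> dict:
    sc = core_io.read_singlecell(config.singlecell_dir)
    mcn_cells = integrate.select_mcn_cells(sc, expr_threshold=config.mcn_expr_threshold)
    if mcn_cells:
        gene_list = integrate.mcn_top_genes(sc, mcn_cells, cutoff=config.mcn_count_cutoff)
    else:
        gene_list = pd.DataFrame(
            {"gene_symbol": sc.genes, "mean_normalized_count": np.nan, "selected": False}
        )
    state["mcn_gene_list"] = gene_list
    state["mcn_selected"] = set(gene_list.loc[gene_list["selected"], "gene_symbol"])
    _write_tsv(out / "mcn_gene_list.tsv", gene_list)
    return {
        "cells_total": len(sc.barcodes),
        "mcn_cells": len(mcn_cells),
        "genes_total": len(gene_list),
        "mcn_genes_selected": len(state["mcn_selected"]),
    }


def _stage_integrate(config: PipelineConfig, state: dict, out: Path) -> dict:
    gene_of = state["gene_of"]
    tr_a = core_io.read_transcriptome(config.transcriptome_a)
    tr_b = core_io.read_transcriptome(config.transcriptome_b)
    transcripts = integrate.merge_transcriptomes(
        tr_a, tr_b, threshold=config.transcript_count_threshold
    )
    son_prot_genes = {gene_of[a] for a in state["SON_proteome_log2"].feature_ids if a in gene_of}
    nil_prot_genes = {gene_of[a] for a in state["NIL_proteome_log2"].feature_ids if a in gene_of}
    universe = set(tr_a.index) | set(tr_b.index) | son_prot_genes | nil_prot_genes
    venn = integrate.venn_classify(transcripts, son_prot_genes, nil_prot_genes, universe)
    state["venn"] = venn
    _write_tsv(out / "venn_assignments.tsv", venn)

    # per-gene proteome log2fc maps (primary accession per gene: first seen)
    def gene_fc(diff: pd.DataFrame) -> pd.Series:
        d = diff.copy()
        d["gene"] = d["feature_id"].map(gene_of)
        d = d.dropna(subset=["gene"]).drop_duplicates("gene", keep="first")
        return pd.Series(d["log2fc"].to_numpy(), index=d["gene"])

    son_fc = gene_fc(state["SON_proteome_diff"])
    nil_fc = gene_fc(state["NIL_proteome_diff"])
    son_dps = pd.Series(
        state["SON_deltaps"]["delta_ps"].to_numpy(), index=state["SON_deltaps"]["gene_symbol"]
    )
    nil_dps = pd.Series(
        state["NIL_deltaps"]["delta_ps"].to_numpy(), index=state["NIL_deltaps"]["gene_symbol"]
    )
    pairs = [
        ("son_proteome_vs_nil_proteome", son_fc, nil_fc),
        ("son_deltaps_vs_nil_deltaps", son_dps, nil_dps),
        ("nil_deltaps_vs_son_proteome", nil_dps, son_fc),
        ("nil_deltaps_vs_nil_proteome", nil_dps, nil_fc),
    ]
    rows = []
    for name, x, y in pairs:
        try:
            res = integrate.correlate_changes(x, y)
            rows.append(
                {"comparison": name, "n": res.n, "spearman_r": res.spearman_r, "p": res.p_value}
            )
        except ValidationError:
            rows.append({"comparison": name, "n": 0, "spearman_r": np.nan, "p": np.nan})
    correlations = pd.DataFrame(rows)
    state["correlations"] = correlations
    _write_tsv(out / "correlations.tsv", correlations)
    counts = {
        "transcripts_expressed": len(transcripts),
        "venn_universe": len(venn),
    }
    counts.update(venn["category"].value_counts().to_dict())
    for row in rows:
        counts[f"r_{row['comparison']}"] = None if pd.isna(row["spearman_r"]) else float(row["spearman_r"])
    return counts


def _stage_enrich(config: PipelineConfig, state: dict, out: Path) -> dict:
    collection = core_io.read_gmt(config.gmt)
    background = state["mcn_selected"]
    dps = state["NIL_deltaps"]
    changed = set(dps.loc[dps["ps_class"] != "neutral", "gene_symbol"]) if len(dps) else set()
    query = changed & background
    if query and background:
        results, skipped = integrate.ora(query, background, collection)
    else:
        results = pd.DataFrame(
            columns=["term_id", "term_name", "k_overlap", "n_query",
                     "m_term_in_background", "n_background", "p_hyper", "p_adj"]
        )
        skipped = pd.DataFrame(columns=["term_id", "size_in_background", "reason"])
    state["enrichment"] = results
    _write_tsv(out / "enrichment.tsv", results)
    if len(skipped):
        _write_tsv(out / "enrichment_skipped.tsv", skipped)
    return {
        "query_genes": len(query),
        "background_genes": len(background),
        "terms_tested": len(results),
        "terms_skipped": len(skipped),
        "terms_significant": int((results["p_adj"] < 0.05).sum()) if len(results) else 0,
    }
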