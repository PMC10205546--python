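"""Cumulative phosphorylation-state score and phosphosite mapping.

The phosphorylation-state change of a gene (dPs) is the sum of log2 fold
changes over all of its significantly changing phosphopeptide groups,
pooled across protein isoforms of that gene.  A gene with no significant
peptide gets no record at all — "no evidence" is distinct from "neutral".

The classification cutoff is data-derived: twice the mean per-peptide
standard deviation of adjusted log2 abundances across all samples of the
tissue.  In the source study this works out to +/-0.34 for the cell-body
compartment (mean SD 0.17) and +/-0.40 for the terminal compartment
(mean SD 0.2).  Classification uses strict inequalities, so a score equal
to the cutoff stays neutral.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import PhosphositeGroup
from .core_io import AbundanceMatrix, ValidationError

__all__ = [
    "DeltaPsCutoff",
    "MappedPhosphosite",
    "mean_peptide_sd",
    "delta_ps",
    "classify_delta_ps",
    "map_phosphosites",
]


@dataclass(frozen=True)
class DeltaPsCutoff:
    """Data-derived classification cutoff: exactly 2 x mean peptide SD."""

    mean_peptide_sd: float
    cutoff: float
    n_peptides: int
    sd_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_peptide_sd <= 0:
            raise ValidationError("mean peptide SD must be positive")
        if self.cutoff != self.sd_multiplier * self.mean_peptide_sd:
            raise ValidationError("cutoff must equal sd_multiplier x mean_peptide_sd exactly")


def mean_peptide_sd(adjusted: AbundanceMatrix, sd_multiplier: float = 2.0) -> DeltaPsCutoff:
    """Average per-peptide sample SD of adjusted log2 abundances.

    SDs use the n-1 denominator and pool all samples of the tissue (both
    conditions); peptides with fewer than two non-missing values carry no
    SD and are excluded from the average.
    """
    if adjusted.scale != "log2_adjusted":
        raise ValidationError(
            f"mean_peptide_sd expects log2_adjusted scale, got {adjusted.scale!r}"
        )
    vals = adjusted.data.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(vals), axis=1)
    usable = n_obs >= 2
    if not usable.any():
        raise ValidationError("no peptide with >= 2 non-missing values")
    with np.errstate(invalid="ignore"):
        sds = np.nanstd(vals[usable], axis=1, ddof=1)
    mean_sd = float(np.mean(sds))
    if mean_sd <= 0:
        raise ValidationError("mean peptide SD is zero; cutoff undefined")
    return DeltaPsCutoff(mean_sd, sd_multiplier * mean_sd, int(usable.sum()), sd_multiplier)


def delta_ps(
    phospho_diff: pd.DataFrame,
    parent_gene: Mapping[str, str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene summed log2 fold change over significant phosphopeptides.

    ``phospho_diff`` is a differential table computed on ADJUSTED phospho
    abundances (feature_id, log2fc, p).  For every gene with at least one
    record at p < alpha, delta_ps is the sum of those records' log2fc,
    pooling isoform accessions of the same gene.  Genes without a
    significant peptide are absent.  Group keys without a gene mapping are
    returned in the unmapped report rather than silently dropped.
    """
    required = {"feature_id", "log2fc", "p"}
    missing = required - set(phospho_diff.columns)
    if missing:
        raise ValidationError(f"phospho_diff missing column(s): {sorted(missing)}")
    sig = phospho_diff[phospho_diff["p"] < alpha]
    unmapped = sorted(k for k in sig["feature_id"] if k not in parent_gene)
    sig = sig[sig["feature_id"].isin(parent_gene.keys())].copy()
    if sig.empty:
        cols = ["gene_symbol", "delta_ps", "n_significant", "member_groups"]
        return pd.DataFrame(columns=cols), unmapped
    sig["gene_symbol"] = sig["feature_id"].map(parent_gene)
    agg = (
        sig.groupby("gene_symbol", sort=True)
        .agg(
            delta_ps=("log2fc", "sum"),
            n_significant=("log2fc", "size"),
            member_groups=("feature_id", lambda s: ";".join(s)),
        )
        .reset_index()
    )
    return agg, unmapped


def classify_delta_ps(records: pd.DataFrame, cutoff: DeltaPsCutoff) -> pd.DataFrame:
    """Assign hyper / hypo / neutral by strict comparison with the cutoff."""
    out = records.copy()
    dps = out["delta_ps"].to_numpy(dtype=float)
    out["ps_class"] = np.where(
        dps > cutoff.cutoff, "hyper", np.where(dps < -cutoff.cutoff, "hypo", "neutral")
    )
    out["cutoff_used"] = cutoff.cutoff
    return out


@dataclass(frozen=True)
class MappedPhosphosite:
    """A phosphosite placed on the parent protein sequence (1-based)."""

    accession: str
    residue: str
    protein_position: int
    direction: str  # hyper | hypo | unchanged
    ambiguous: bool = False


def map_phosphosites(
    sequence: str,
    group: PhosphositeGroup,
    direction: str = "unchanged",
    accession: str | None = None,
) -> list[MappedPhosphosite]:
    """Place a localized group's sites on a protein sequence.

    protein_position = match_start + peptide_offset - 1 (both 1-based).
    If the peptide occurs at several positions, every placement is reported
    with the ambiguity flag set.  A peptide not found in the sequence, or a
    residue mismatch at a mapped position, is an error.
    """
    if not group.localized or group.sites is None:
        raise ValidationError(
            f"group {group.key_str} is not localized; cannot map its sites"
        )
    acc = accession if accession is not None else group.parent_accession
    peptide = group.peptide_sequence
    starts = []
    pos = sequence.find(peptide)
    while pos != -1:
        starts.append(pos)
        pos = sequence.find(peptide, pos + 1)
    if not starts:
        raise ValidationError(f"peptide {peptide!r} not found in sequence of {acc!r}")
    ambiguous = len(starts) > 1
    mapped = []
    for start in starts:
        for residue, offset in group.sites:
            protein_pos = start + offset  # start is 0-based; offset 1-based
            if sequence[protein_pos - 1] != residue:
                raise ValidationError(
                    f"{acc}: residue mismatch at position {protein_pos}: expected {residue}, "
                    f"sequence has {sequence[protein_pos - 1]!r}"
                )
            mapped.append(MappedPhosphosite(acc, residue, protein_pos, direction, ambiguous))
    return mapped
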