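"""Quantitation preprocessing.

Implements the processing chain that takes raw reporter-ion intensities to
analysis-ready log2 tables:

* total-peptide normalization (equalize per-sample column totals) and log2
  transform of the proteome;
* the same normalization factors re-applied to the phosphopeptide table —
  total phospho signal varies with the biology of interest, so the total
  protein loading is the better loading metric;
* master-protein selection by annotation quality;
* phosphosite localization at a confidence threshold and grouping of PSMs
  with identical sequence and predicted sites;
* protein-level correction: subtracting log2 parent-protein abundance from
  log2 phosphopeptide abundance so that phospho changes reflect occupancy,
  not protein amount.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AbundanceMatrix, ValidationError

__all__ = [
    "PhosphopeptideRecord",
    "PhosphositeGroup",
    "NormalizationFactors",
    "AnnotationScore",
    "compute_normalization_factors",
    "normalize_log2",
    "select_master_protein",
    "annotation_score",
    "group_phosphopeptides",
    "adjust_phosphopeptides",
    "groups_to_matrix",
    "read_phosphopeptide_table",
    "write_phosphopeptide_table",
]

PHOSPHO_RESIDUES = ("S", "T", "Y")


@dataclass(frozen=True)
class PhosphopeptideRecord:
    """One phosphopeptide spectral match with localized sites.

    ``sites`` are (residue, 1-based offset within the peptide) pairs;
    ``site_confidence`` is the localization confidence in percent (e.g. a
    PhosphoRS-style score consumed as input).
    """

    psm_id: str
    peptide_sequence: str
    parent_accession: str
    sites: tuple[tuple[str, int], ...]
    site_confidence: float
    abundances: pd.Series  # per-sample raw intensities

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValidationError(f"PSM {self.psm_id}: no phosphosites")
        if not 0 <= self.site_confidence <= 100:
            raise ValidationError(
                f"PSM {self.psm_id}: confidence {self.site_confidence} outside [0, 100]"
            )
        for residue, offset in self.sites:
            if residue not in PHOSPHO_RESIDUES:
                raise ValidationError(f"PSM {self.psm_id}: {residue} is not a phospho residue")
            if not 1 <= offset <= len(self.peptide_sequence):
                raise ValidationError(
                    f"PSM {self.psm_id}: site offset {offset} outside peptide of length "
                    f"{len(self.peptide_sequence)}"
                )
            if self.peptide_sequence[offset - 1] != residue:
                raise ValidationError(
                    f"PSM {self.psm_id}: residue {residue} at offset {offset} does not match "
                    f"peptide letter {self.peptide_sequence[offset - 1]!r}"
                )


@dataclass
class PhosphositeGroup:
    """PSMs with identical sequence and predicted sites, summed.

    Localized groups are keyed by (sequence, site list); records whose
    localization confidence did not pass the threshold are keyed by
    (sequence, number of phosphates) instead.
    """

    group_key: tuple
    parent_accession: str
    abundances: pd.Series
    n_psms: int
    localized: bool
    peptide_sequence: str
    sites: tuple[tuple[str, int], ...] | None  # None when unlocalized

    @property
    def key_str(self) -> str:
        return group_key_to_str(self.group_key)


def group_key_to_str(key: tuple) -> str:
    seq, tail = key
    if isinstance(tail, int):
        return f"{seq}|{tail}p"
    return f"{seq}|" + ";".join(f"{res}{off}" for res, off in tail)


@dataclass
class NormalizationFactors:
    """Per-sample multiplicative factors equalizing total raw abundance."""

    factors: dict[str, float]
    target_total: float

    def __getitem__(self, sample_id: str) -> float:
        return self.factors[sample_id]

    def as_series(self) -> pd.Series:
        return pd.Series(self.factors, name="factor")


@dataclass(frozen=True)
class AnnotationScore:
    accession: str
    score: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError("annotation score must be non-negative")


def annotation_score(accession: str, *fields: str | None) -> AnnotationScore:
    """Score an accession by the number of populated annotation fields."""
    return AnnotationScore(accession, sum(1 for f in fields if f))


def compute_normalization_factors(raw: AbundanceMatrix) -> NormalizationFactors:
    """Factors that bring every sample to the mean column total.

    factor_s = mean(column totals) / column_total_s.  Any positive target
    yields identical fold changes and p-values downstream; the mean keeps
    absolute log2 values near the input scale.  Missing cells do not
    contribute to totals.
    """
    if raw.scale != "raw":
        raise ValidationError(f"normalization factors need raw scale, got {raw.scale!r}")
    totals = raw.data.sum(axis=0, skipna=True)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(f"zero total abundance in sample(s): {list(zero.index)}")
    target = float(totals.mean())
    factors = {s: target / float(t) for s, t in totals.items()}
    return NormalizationFactors(factors, target)


def normalize_log2(raw: AbundanceMatrix, factors: NormalizationFactors) -> AbundanceMatrix:
    """Apply loading factors and log2-transform.

    Raw zeros become explicit missing — a zero intensity carries no log2
    information and must not masquerade as a measured value.
    """
    if raw.scale != "raw":
        raise ValidationError(f"normalize_log2 expects raw scale, got {raw.scale!r}")
    missing = [s for s in raw.sample_ids if s not in factors.factors]
    if missing:
        raise ValidationError(f"no normalization factor for sample(s): {missing}")
    fvec = np.array([factors[s] for s in raw.sample_ids])
    scaled = raw.data.to_numpy(dtype=float) * fvec[np.newaxis, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logged = np.log2(scaled)
    logged[~np.isfinite(logged)] = np.nan
    out = pd.DataFrame(logged, index=raw.data.index, columns=raw.data.columns)
    return AbundanceMatrix(out, scale="log2")


def select_master_protein(group: Sequence[AnnotationScore]) -> str:
    """Pick the best-annotated accession of a protein group.

    Highest annotation score wins; ties break to the lexicographically
    smallest accession so the choice is deterministic.
    """
    if not group:
        raise ValidationError("empty candidate-master group")
    return min(group, key=lambda a: (-a.score, a.accession)).accession


def group_phosphopeptides(
    records: Sequence[PhosphopeptideRecord],
    confidence_threshold: float = 70.0,
) -> list[PhosphositeGroup]:
    """Group PSMs by (sequence, predicted sites) and sum their abundances.

    Records with confidence strictly above the threshold are localized and
    keyed by their exact site list; records at or below it are kept but
    keyed by (sequence, phosphate count) and flagged unlocalized.  Grouping
    conserves signal: per-sample summed abundance over all groups equals
    the sum over all PSMs.
    """
    groups: dict[tuple, PhosphositeGroup] = {}
    order: list[tuple] = []
    for rec in records:
        localized = rec.site_confidence > confidence_threshold
        if localized:
            key = (rec.peptide_sequence, tuple(sorted(rec.sites, key=lambda s: s[1])))
        else:
            key = (rec.peptide_sequence, len(rec.sites))
        if key in groups:
            g = groups[key]
            if g.parent_accession != rec.parent_accession:
                raise ValidationError(
                    f"group {group_key_to_str(key)}: conflicting parent accessions "
                    f"{g.parent_accession!r} vs {rec.parent_accession!r}"
                )
            a = g.abundances.to_numpy(dtype=float)
            b = rec.abundances.reindex(g.abundances.index).to_numpy(dtype=float)
            summed = np.nansum(np.vstack([a, b]), axis=0)
            summed[np.isnan(a) & np.isnan(b)] = np.nan
            g.abundances = pd.Series(summed, index=g.abundances.index)
            g.n_psms += 1
        else:
            groups[key] = PhosphositeGroup(
                group_key=key,
                parent_accession=rec.parent_accession,
                abundances=rec.abundances.astype(float).copy(),
                n_psms=1,
                localized=localized,
                peptide_sequence=rec.peptide_sequence,
                sites=key[1] if localized else None,
            )
            order.append(key)
    return [groups[k] for k in order]


def groups_to_matrix(groups: Sequence[PhosphositeGroup], sample_ids: Sequence[str]) -> AbundanceMatrix:
    """Stack grouped abundances into a raw-scale matrix keyed by group string."""
    keys = [g.key_str for g in groups]
    if len(set(keys)) != len(keys):
        raise ValidationError("group key strings are not unique")
    sample_ids = list(sample_ids)
    rows = []
    for g in groups:
        s = g.abundances
        if list(s.index) != sample_ids:
            s = s.reindex(sample_ids)
        rows.append(s.to_numpy(dtype=float))
    data = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(sample_ids))),
        index=pd.Index(keys, name="group_key"),
        columns=sample_ids,
    )
    return AbundanceMatrix(data, scale="raw")


def adjust_phosphopeptides(
    phospho_log2: AbundanceMatrix,
    protein_log2: AbundanceMatrix,
    parent_of: Mapping[str, str],
) -> tuple[AbundanceMatrix, list[str]]:
    """Subtract log2 parent-protein abundance from log2 phosphopeptide abundance.

    The correction removes total-protein-level changes from the phospho
    signal, leaving occupancy changes.  Groups whose parent protein is
    absent from the protein table are passed through unadjusted and
    returned in the second element.  Missingness propagates: if the parent
    is missing in a sample, the adjusted value is missing there.
    """
    if phospho_log2.scale != "log2" or protein_log2.scale != "log2":
        raise ValidationError(
            "adjust_phosphopeptides expects both inputs on log2 scale "
            f"(got {phospho_log2.scale!r}, {protein_log2.scale!r})"
        )
    if set(phospho_log2.sample_ids) != set(protein_log2.sample_ids):
        raise ValidationError("phospho and protein tables cover different sample sets")
    prot = protein_log2.data.loc[:, phospho_log2.sample_ids]
    adjusted = phospho_log2.data.copy()
    parents = pd.Series([parent_of.get(k) for k in adjusted.index], index=adjusted.index)
    has_parent = parents.notna() & parents.isin(prot.index)
    unadjusted = list(adjusted.index[~has_parent])
    if has_parent.any():
        sub = prot.loc[parents[has_parent].to_numpy()].to_numpy(dtype=float)
        adjusted.loc[has_parent] = adjusted.loc[has_parent].to_numpy(dtype=float) - sub
    return AbundanceMatrix(adjusted, scale="log2_adjusted"), unadjusted


# -- phosphopeptide table I/O -------------------------------------------------
#
# TSV columns: psm_id, sequence, accession, sites ("S5;T9"), confidence,
# then one column per sample.


def parse_sites(text: str) -> tuple[tuple[str, int], ...]:
    sites = []
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        sites.append((token[0], int(token[1:])))
    return tuple(sites)


def format_sites(sites: Iterable[tuple[str, int]]) -> str:
    return ";".join(f"{res}{off}" for res, off in sites)


def read_phosphopeptide_table(path, design) -> list[PhosphopeptideRecord]:
    from .core_io import design_samples, FormatError, validate_design

    validate_design(design)
    df = pd.read_csv(path, sep="\t", dtype={"psm_id": str, "sequence": str, "accession": str})
    required = ["psm_id", "sequence", "accession", "sites", "confidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {missing}")
    samples = design_samples(design)
    missing_s = [s for s in samples if s not in df.columns]
    if missing_s:
        raise FormatError(f"{path}: missing sample column(s): {missing_s}")
    records = []
    for row in df.itertuples(index=False):
        abund = pd.Series(
            [getattr(row, s) for s in samples], index=samples, dtype=float
        )
        records.append(
            PhosphopeptideRecord(
                psm_id=str(row.psm_id),
                peptide_sequence=str(row.sequence),
                parent_accession=str(row.accession),
                sites=parse_sites(row.sites),
                site_confidence=float(row.confidence),
                abundances=abund,
            )
        )
    return records


def write_phosphopeptide_table(path, records: Sequence[PhosphopeptideRecord], design) -> None:
    from .core_io import design_samples

    samples = design_samples(design)
    rows = []
    for rec in records:
        row = {
            "psm_id": rec.psm_id,
            "sequence": rec.peptide_sequence,
            "accession": rec.parent_accession,
            "sites": format_sites(rec.sites),
            "confidence": rec.site_confidence,
        }
        for s in samples:
            row[s] = rec.abundances.get(s, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
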