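"""Readers, writers and shared domain types.

Every external format the pipeline touches goes through this module:
tab-delimited abundance tables, the experimental-design table, GMT gene-set
collections, FASTA protein sequences and MatrixMarket single-cell counts.

Conventions
-----------
* Abundance tables are TSV, UTF-8, header row, first column the feature id,
  one column per sample.  Missing cells are written as the empty string and
  parsed as explicit missing (``NaN``), never as zero: in MS data a zero
  intensity and an unobserved value are different things.
* Sample metadata travels in a separate design table (sample_id, tissue,
  condition, replicate) rather than being encoded in column names.
* All protein coordinates are 1-based, inclusive residue numbers.
"""

from __future__ import annotations

import dataclasses
import io
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.io import mmread, mmwrite
from scipy import sparse

__all__ = [
    "FormatError",
    "ValidationError",
    "TISSUES",
    "CONDITIONS",
    "SampleDesign",
    "AbundanceMatrix",
    "GeneSet",
    "GeneSetCollection",
    "SingleCellCounts",
    "default_design",
    "validate_design",
    "read_design",
    "write_design",
    "read_abundance_table",
    "write_abundance_table",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
    "read_gene_mapping",
    "write_gene_mapping",
    "read_singlecell",
    "write_singlecell",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


TISSUES = ("SON", "NIL")
CONDITIONS = ("control", "WD")

SCALES = ("raw", "log2", "log2_adjusted")

# The 20 standard amino acids; anything else in a FASTA record is rejected.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SampleDesign:
    """One sample of the 2-tissue x 2-condition study layout."""

    sample_id: str
    tissue: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.replicate < 1:
            raise ValidationError(f"replicate must be a positive integer, got {self.replicate}")


def default_design(tissue: str, n_per_group: int = 6) -> list[SampleDesign]:
    """Standard design: ``n_per_group`` control and WD replicates of one tissue.

    Six versus six is the study default; Welch testing needs at least two
    per group.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2 for a two-group comparison")
    design = []
    for condition in CONDITIONS:
        for r in range(1, n_per_group + 1):
            design.append(
                SampleDesign(f"{tissue}_{condition}_{r}", tissue, condition, r)
            )
    return design


def validate_design(design: Sequence[SampleDesign]) -> None:
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample ids in design: {dupes}")
    if not design:
        raise ValidationError("empty design")


def design_samples(design: Sequence[SampleDesign], condition: str | None = None) -> list[str]:
    """Sample ids in design order, optionally restricted to one condition."""
    return [d.sample_id for d in design if condition is None or d.condition == condition]


def write_design(path: str | Path, design: Sequence[SampleDesign]) -> None:
    df = pd.DataFrame([dataclasses.asdict(d) for d in design])
    df.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "tissue", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"design table missing columns: {sorted(missing)}")
    design = [
        SampleDesign(r.sample_id, r.tissue, r.condition, int(r.replicate))
        for r in df.itertuples()
    ]
    validate_design(design)
    return design


@dataclass
class AbundanceMatrix:
    """Features x samples intensity table.

    ``data`` has unique feature ids as the index and sample ids as columns.
    ``scale`` tracks where the values sit in the processing chain: ``raw``
    reporter-ion style intensities (non-negative), ``log2`` normalized
    log2 abundances, or ``log2_adjusted`` protein-level-corrected
    phosphopeptide abundances.  Missing values are ``NaN`` on any scale.
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if self.scale == "raw":
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError("raw-scale abundances must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return AbundanceMatrix(self.data.loc[:, list(sample_ids)].copy(), self.scale)


def read_abundance_table(path: str | Path, design: Sequence[SampleDesign]) -> AbundanceMatrix:
    """Parse a raw-scale abundance TSV against a design.

    The first column holds feature ids; every design sample must be present
    as a column.  Columns are returned in design order.  Duplicate feature
    ids, missing sample columns and negative values are hard errors.
    """
    validate_design(design)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    wanted = design_samples(design)
    missing = [s for s in wanted if s not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing sample column(s): {missing}")
    df = df.loc[:, wanted]
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature id(s): {dupes[:5]}")
    values = df.apply(pd.to_numeric, errors="coerce")
    # empty string -> NaN is legitimate missing; any other unparsable token is not
    bad = values.isna() & df.notna() & (df.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    neg = values < 0
    if neg.to_numpy().any():
        r, c = np.argwhere(neg.to_numpy())[0]
        raise ValidationError(
            f"{path}: negative abundance at feature {values.index[r]!r}, "
            f"sample {values.columns[c]!r}"
        )
    values.index.name = df.index.name or "feature_id"
    return AbundanceMatrix(values, scale="raw")


def write_abundance_table(path: str | Path, matrix: AbundanceMatrix) -> None:
    """Write an abundance matrix as TSV with missing cells left empty.

    Floats are rendered with ``repr`` precision (17 significant digits) so
    a write/read round-trip is value-identical.
    """
    df = matrix.data.copy()
    df.index.name = df.index.name or "feature_id"
    df.to_csv(path, sep="\t", float_format="%.17g", na_rep="")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.term_id!r} has no members")


@dataclass
class GeneSetCollection:
    """A list of gene sets with unique term ids (one GMT file)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.term_id for s in self.sets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate term ids in collection: {dupes}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        for s in self.sets:
            if s.term_id == term_id:
                return s
        raise KeyError(term_id)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: term_id TAB description TAB member1 TAB member2 ...

    Duplicate members within a line are collapsed; lines with fewer than
    three fields and duplicated term ids are errors.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term_id, term_name, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {term_id!r} has no members")
            sets.append(GeneSet(term_id, term_name, frozenset(members)))
    return GeneSetCollection(sets)


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.members)]) + "\n")


def _fasta_accession(header_id: str) -> str:
    # UniProt "sp|ACC|NAME" / "tr|ACC|NAME" dialect yields ACC
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return header_id


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by accession.

    The accession is the first whitespace-delimited header token (with the
    UniProt ``sp|ACC|NAME`` dialect unwrapped to ``ACC``).  Sequences are
    upper-cased; duplicate accessions and non-amino-acid characters raise.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = _fasta_accession(record.id)
        if acc in sequences:
            raise FormatError(f"{path}: duplicate accession {acc!r}")
        seq = str(record.seq).upper().replace("-", "")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise FormatError(
                f"{path}: sequence {acc!r} contains non-amino-acid character(s) {sorted(bad)}"
            )
        sequences[acc] = seq
    return sequences


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_mapping(path: str | Path) -> dict[str, str]:
    """Accession -> gene symbol table (TSV, two columns with header).

    Each accession maps to exactly one gene symbol; a gene may own several
    accessions (isoforms).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: gene mapping needs two columns (accession, gene_symbol)")
    acc_col, gene_col = df.columns[:2]
    if df[acc_col].duplicated().any():
        dupes = df.loc[df[acc_col].duplicated(), acc_col].unique().tolist()
        raise ValidationError(f"{path}: accession mapped more than once: {dupes[:5]}")
    return dict(zip(df[acc_col], df[gene_col]))


def write_gene_mapping(path: str | Path, mapping: Mapping[str, str]) -> None:
    pd.DataFrame(
        {"accession": list(mapping.keys()), "gene_symbol": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class SingleCellCounts:
    """Genes x cells integer count matrix with optional cluster labels."""

    matrix: sparse.csr_matrix
    genes: list[str]
    barcodes: list[str]
    clusters: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene symbols in single-cell matrix")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("duplicate barcodes in single-cell matrix")
        if self.clusters is not None:
            unknown = set(self.clusters) - set(self.barcodes)
            if unknown:
                raise ValidationError(f"cluster labels for unknown barcodes: {sorted(unknown)[:5]}")


def read_singlecell(directory: str | Path) -> SingleCellCounts:
    """Read ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` (+ ``clusters.tsv``)."""
    directory = Path(directory)
    matrix = sparse.csr_matrix(mmread(directory / "matrix.mtx"))
    genes = (directory / "genes.tsv").read_text().split()
    barcodes = (directory / "barcodes.tsv").read_text().split()
    clusters = None
    cl_path = directory / "clusters.tsv"
    if cl_path.exists():
        df = pd.read_csv(cl_path, sep="\t", dtype=str)
        clusters = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return SingleCellCounts(matrix, genes, barcodes, clusters)


def write_singlecell(directory: str | Path, sc: SingleCellCounts) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "matrix.mtx"), sparse.coo_matrix(sc.matrix))
    (directory / "genes.tsv").write_text("\n".join(sc.genes) + "\n")
    (directory / "barcodes.tsv").write_text("\n".join(sc.barcodes) + "\n")
    if sc.clusters is not None:
        pd.DataFrame(
            {"barcode": sc.barcodes, "cluster": [sc.clusters[b] for b in sc.barcodes]}
        ).to_csv(directory / "clusters.tsv", sep="\t", index=False)


def read_transcriptome(path: str | Path) -> pd.Series:
    """Gene -> normalized count table (TSV, two columns with header)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: transcriptome table needs two columns (gene, count)")
    gene_col, count_col = df.columns[:2]
    if df[gene_col].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene symbols")
    s = pd.Series(df[count_col].to_numpy(dtype=float), index=df[gene_col], name=count_col)
    if (s < 0).any():
        raise ValidationError(f"{path}: negative counts")
    return s


def write_transcriptome(path: str | Path, counts: pd.Series, name: str = "count") -> None:
    df = pd.DataFrame({"gene_symbol": counts.index, name: counts.to_numpy()})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
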