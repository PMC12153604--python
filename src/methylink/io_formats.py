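"""Readers and writers for the external file formats the pipeline touches.

All genomic coordinates are **0-based half-open** in memory.  1-based inputs
(the methylation call table, GTF) are converted at the parser boundary and
converted back on write, so every downstream module works in one convention.

The canonical methylation-call dialect is a 6-column tab-separated cytosine
report::

    chrom  pos(1-based)  strand(+/-)  context(CG/CHG/CHH)  meth_count  total_count

Blank lines and lines starting with ``#`` are ignored.  Sites with
``total_count == 0`` carry no information (the cytosine was never sequenced)
and are dropped at parse time with a logged count rather than being treated
as 0% methylated.  A converter from the Bismark CX-report column order is
provided (:func:`convert_cx_report`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("methylink")

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

#: canonical column order of the methylation call dialect (file side)
METH_COLUMNS = ("chrom", "pos", "strand", "context", "meth_count", "total_count")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethylationCall:
    """One cytosine site in one sample.

    ``pos`` is the 0-based genomic coordinate of the cytosine.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    meth_count: int
    total_count: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValidationError(f"bad context {self.context!r}")
        if not (0 <= self.meth_count <= self.total_count):
            raise ValidationError(
                f"meth_count {self.meth_count} outside [0, total_count={self.total_count}]"
            )
        if self.total_count <= 0:
            raise ValidationError("total_count must be positive")

    @property
    def level(self) -> float:
        return self.meth_count / self.total_count


@dataclass(frozen=True)
class GeneModel:
    """A gene's span; source of upstream / gene-body / downstream regions."""

    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"{self.gene_id}: start must be < end")
        if self.strand not in STRANDS:
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (the last base for minus-strand genes)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    sample_id: str
    rpkm: float

    def __post_init__(self) -> None:
        if self.rpkm < 0:
            raise ValidationError(f"{self.gene_id}/{self.sample_id}: rpkm < 0")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"{self.set_id}: empty gene set")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"{self.set_id}: duplicate members")


# ---------------------------------------------------------------------------
# methylation call tables
# ---------------------------------------------------------------------------

def _data_line_number(path: Path, data_row: int) -> int:
    """File line number (1-based) of the ``data_row``-th non-blank, non-comment line."""
    seen = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            seen += 1
            if seen == data_row:
                return lineno
    return data_row + 1  # fall back to the row index itself


def read_methylation_frame(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read a methylation call table into a validated DataFrame.

    Returns columns ``chrom, pos, strand, context, meth_count, total_count,
    sample_id`` with ``pos`` converted to 0-based.  Rows with
    ``total_count == 0`` are dropped (count logged).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=list(METH_COLUMNS),
            dtype={"chrom": str, "strand": str, "context": str},
            skip_blank_lines=True,
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: malformed call table: {exc}") from exc
    if df.empty:
        log.warning("%s: empty call table", path)
        df = df.assign(sample_id=sample_id)
        return df.astype({"pos": int, "meth_count": int, "total_count": int}, errors="ignore")

    for col in ("pos", "meth_count", "total_count"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | (coerced != np.floor(coerced))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: line {_data_line_number(path, row)}: "
                f"non-integer value {df[col].iloc[row]!r} in column {col}"
            )
        df[col] = coerced.astype(np.int64)

    def _bad(mask: pd.Series, msg: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise ValidationError(f"{path}: line {_data_line_number(path, row)}: {msg}")

    _bad(~df["strand"].isin(STRANDS), "strand must be + or -")
    _bad(~df["context"].isin(CONTEXTS), "context must be CG, CHG or CHH")
    _bad(df["pos"] < 1, "pos must be >= 1 (1-based)")
    _bad(df["meth_count"] < 0, "meth_count must be >= 0")
    _bad(df["meth_count"] > df["total_count"], "meth_count exceeds total_count")

    uncovered = df["total_count"] == 0
    if uncovered.any():
        log.info("%s: dropped %d uncovered sites (total_count = 0)", path, int(uncovered.sum()))
        df = df.loc[~uncovered].reset_index(drop=True)

    df["pos"] = df["pos"] - 1  # to 0-based
    df["sample_id"] = sample_id
    return df


def read_methylation_calls(path: str | Path, sample_id: str) -> list[MethylationCall]:
    """Record-level API over :func:`read_methylation_frame`."""
    df = read_methylation_frame(path, sample_id)
    return [
        MethylationCall(r.chrom, int(r.pos), r.strand, r.context,
                        int(r.meth_count), int(r.total_count), sample_id)
        for r in df.itertuples(index=False)
    ]


def write_methylation_frame(df: pd.DataFrame, path: str | Path) -> None:
    """Write a call frame back to the canonical dialect (pos re-based to 1)."""
    out = df[list(METH_COLUMNS)].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def convert_cx_report(src: str | Path, dest: str | Path) -> None:
    """Convert a Bismark CX report to the canonical call dialect.

    CX-report columns: chrom, pos(1-based), strand, meth_count, unmeth_count,
    context, trinucleotide.  ``total = meth + unmeth``; uncovered rows are kept
    (the canonical reader drops them).
    """
    cx = pd.read_csv(
        Path(src), sep="\t", comment="#", header=None,
        names=["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"],
        dtype={"chrom": str, "strand": str, "context": str, "tri": str},
    )
    out = pd.DataFrame({
        "chrom": cx["chrom"], "pos": cx["pos"], "strand": cx["strand"],
        "context": cx["context"], "meth_count": cx["meth"],
        "total_count": cx["meth"] + cx["unmeth"],
    })
    out.to_csv(dest, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path, format: str = "bed") -> list[GeneModel]:
    """Read gene models from BED6 (0-based half-open) or GTF (1-based closed).

    For GTF only rows with feature type ``gene`` are used and coordinates are
    converted to 0-based half-open (start − 1).  Duplicate gene_ids and
    missing strands are rejected.
    """
    fmt = format.lower()
    if fmt in ("bed", "bed6"):
        genes = _read_bed6_genes(Path(path))
    elif fmt == "gtf":
        genes = _read_gtf_genes(Path(path))
    else:
        raise ValidationError(f"unknown annotation format {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def _read_bed6_genes(path: Path) -> list[GeneModel]:
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, usecols=range(6),
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str, "strand": str},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: malformed BED6: {exc}") from exc
    genes = []
    for i, r in enumerate(df.itertuples(index=False)):
        if r.strand not in STRANDS:
            raise ValidationError(f"{path}: row {i + 1}: missing or bad strand {r.strand!r}")
        genes.append(GeneModel(str(r.name), r.chrom, int(r.start), int(r.end), r.strand))
    return genes


def _read_gtf_genes(path: Path) -> list[GeneModel]:
    import gffutils

    gene_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3 and fields[2] == "gene":
                gene_lines.append(line)
    if not gene_lines:
        return []
    db = gffutils.create_db(
        "".join(gene_lines), dbfn=":memory:", from_string=True,
        force=True, keep_order=True, merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        if feat.strand not in STRANDS:
            raise ValidationError(f"{path}: gene {gid}: missing strand")
        genes.append(GeneModel(gid, feat.seqid, feat.start - 1, feat.end, feat.strand))
    return genes


def write_genes_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = [(g.chrom, g.start, g.end, g.gene_id, 0, g.strand) for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression_frame(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples RPKM/FPKM table (TSV, first column gene_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        log.warning("%s: empty expression table", path)
        return df
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ParseError(f"{path}: non-numeric value at gene {gene!r}, sample {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        gene = df.index[np.flatnonzero(df.isna().any(axis=1).to_numpy())[0]]
        raise ParseError(f"{path}: missing value at gene {gene!r}")
    if (df.to_numpy() < 0).any():
        r, c = np.argwhere(df.to_numpy() < 0)[0]
        raise ValidationError(
            f"{path}: negative expression at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Record-level API: one :class:`ExpressionRecord` per gene × sample cell."""
    df = read_expression_frame(path)
    return [
        ExpressionRecord(str(g), str(s), float(df.at[g, s]))
        for g in df.index for s in df.columns
    ]


def write_expression_frame(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read GMT: ``set_id TAB description TAB member1 TAB member2 ...``.

    Duplicate members within a set are deduplicated with a warning (first
    occurrence order kept).
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s.strip() or s.startswith("#"):
                continue
            fields = s.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT line needs >= 3 fields")
            set_id, name, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) != len(members):
                log.warning("%s: line %d: set %s has duplicate members; deduplicated",
                            path, lineno, set_id)
            sets.append(GeneSet(set_id, name, tuple(uniq)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *s.members]) + "\n")
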