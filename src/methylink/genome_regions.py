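"""Strand-aware gene regions and metagene bin coordinates.

Every gene defines three regions: a fixed-width flank upstream of the TSS,
the gene body, and a fixed-width flank downstream of the TTS (default flank
3 kb).  For metagene profiles the footprint is divided into fixed-width flank
bins and per-gene scaled body bins, indexed 5'→3' in the gene's
transcriptional orientation — for minus-strand genes the genomic order is
reversed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import GeneModel

REGION_CLASSES = ("upstream", "genebody", "downstream")

DEFAULT_FLANK = 3000


@dataclass(frozen=True)
class GeneRegion:
    gene_id: str
    region_class: str
    chrom: str
    start: int  # 0-based half-open; start == end for a fully clipped flank
    end: int
    strand: str


@dataclass(frozen=True)
class MetageneBinning:
    """Bin layout: ``n_flank_bins`` per flank plus ``n_body_bins`` over the body.

    Flank bins have fixed genomic width ``flank_size / n_flank_bins``; body
    bins scale with each gene's length.
    """

    n_flank_bins: int = 30
    n_body_bins: int = 60

    @property
    def n_total(self) -> int:
        return 2 * self.n_flank_bins + self.n_body_bins

    def body_slice(self) -> slice:
        return slice(self.n_flank_bins, self.n_flank_bins + self.n_body_bins)


def gene_regions(
    gene: GeneModel,
    flank_size: int = DEFAULT_FLANK,
    chrom_length: int | None = None,
) -> tuple[GeneRegion, GeneRegion, GeneRegion]:
    """The (upstream, genebody, downstream) regions of a gene.

    Upstream/downstream are defined in transcript orientation: for a
    minus-strand gene the upstream flank lies at higher genomic coordinates.
    Flanks are clipped at 0 and at ``chrom_length`` when given; together the
    three regions tile ``[start − flank, end + flank)`` (before clipping).
    """
    if flank_size <= 0:
        raise ValueError("flank_size must be > 0")
    lo = max(0, gene.start - flank_size)
    hi = gene.end + flank_size
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    left = GeneRegion(gene.gene_id, "", gene.chrom, lo, gene.start, gene.strand)
    body = GeneRegion(gene.gene_id, "genebody", gene.chrom, gene.start, gene.end, gene.strand)
    right = GeneRegion(gene.gene_id, "", gene.chrom, gene.end, hi, gene.strand)
    if gene.strand == "+":
        up = _with_class(left, "upstream")
        down = _with_class(right, "downstream")
    else:
        up = _with_class(right, "upstream")
        down = _with_class(left, "downstream")
    return up, body, down


def _with_class(r: GeneRegion, cls: str) -> GeneRegion:
    return GeneRegion(r.gene_id, cls, r.chrom, r.start, r.end, r.strand)


def assign_position(
    interval: tuple[int, int],
    gene: GeneModel,
    flank_size: int = DEFAULT_FLANK,
) -> str | None:
    """Region class of an interval relative to a gene, by interval midpoint.

    An interval straddling two regions belongs to its midpoint's region;
    returns None when the midpoint lies outside the ±flank footprint.
    """
    start, end = interval
    mid = (start + end) // 2
    if gene.start <= mid < gene.end:
        return "genebody"
    if gene.start - flank_size <= mid < gene.start:
        return "upstream" if gene.strand == "+" else "downstream"
    if gene.end <= mid < gene.end + flank_size:
        return "downstream" if gene.strand == "+" else "upstream"
    return None


def site_to_bin(
    pos: int,
    gene: GeneModel,
    binning: MetageneBinning = MetageneBinning(),
    flank_size: int = DEFAULT_FLANK,
) -> int | None:
    """Metagene bin index of a 0-based position, or None outside the footprint."""
    b = sites_to_bins(np.asarray([pos]), gene, binning, flank_size)[0]
    return None if b < 0 else int(b)


def sites_to_bins(
    pos: np.ndarray,
    gene: GeneModel,
    binning: MetageneBinning = MetageneBinning(),
    flank_size: int = DEFAULT_FLANK,
) -> np.ndarray:
    """Vectorised :func:`site_to_bin`; −1 marks positions outside the footprint.

    Positions are first mapped to a transcript-oriented offset ``u`` from the
    5'-most footprint base (for minus-strand genes the genomic axis is
    mirrored), then binned: flank bins have fixed width, body bins split the
    gene length evenly.
    """
    pos = np.asarray(pos, dtype=np.int64)
    length = gene.length
    if gene.strand == "+":
        u = pos - (gene.start - flank_size)
    else:
        u = (gene.end + flank_size - 1) - pos
    total_span = 2 * flank_size + length
    out = np.full(pos.shape, -1, dtype=np.int64)
    inside = (u >= 0) & (u < total_span)
    uu = u[inside]
    nf, nb = binning.n_flank_bins, binning.n_body_bins
    bins = np.empty(uu.shape, dtype=np.int64)
    up = uu < flank_size
    bins[up] = uu[up] * nf // flank_size
    body = (uu >= flank_size) & (uu < flank_size + length)
    bins[body] = nf + (uu[body] - flank_size) * nb // length
    down = uu >= flank_size + length
    bins[down] = nf + nb + (uu[down] - flank_size - length) * nf // flank_size
    out[inside] = bins
    return out


def regions_to_bed_rows(regions: Sequence[GeneRegion]) -> list[tuple]:
    """BED6 rows with ``name = gene_id|region_class``."""
    return [
        (r.chrom, r.start, r.end, f"{r.gene_id}|{r.region_class}", 0, r.strand)
        for r in regions
    ]
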