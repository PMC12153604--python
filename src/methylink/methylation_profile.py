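"""Region methylation, metagene profiles and methylation-level gene classes.

Two estimators are used deliberately:

* **Region summaries** use the weighted methylation level
  ``Σ meth / Σ total`` over covered cytosines — the standard region
  estimator, robust to uneven coverage.
* **Metagene profiles** use the mean of per-site levels (``m/c`` averaged
  over sites) per bin, which is what "average methylation rate" curves plot.

Genes with zero methylated reads in a region form the non-methylated class;
the remaining genes are rank-split into three equal-size groups
(Low / Middle / High), Low taking the remainder first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_regions import (
    DEFAULT_FLANK,
    GeneRegion,
    MetageneBinning,
    gene_regions,
    sites_to_bins,
)
from .io_formats import GeneModel

log = logging.getLogger("methylink")

METH_CLASSES = ("None", "Low", "Middle", "High")

DEFAULT_MIN_COVERAGE = 4
DEFAULT_CONTEXTS = ("CG",)


@dataclass(frozen=True)
class RegionMethylation:
    gene_id: str
    region_class: str
    sample_id: str
    level: float
    n_sites: int
    context: str = "CG"


@dataclass(frozen=True)
class MethylationClass:
    gene_id: str
    meth_class: str


class CallIndex:
    """Per-chromosome, position-sorted view of a methylation call frame.

    Built once per sample/group, queried per gene region; pooling across
    samples (summing read counts per site) happens before construction.
    """

    def __init__(self, calls: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        if calls.empty:
            return
        df = calls.sort_values(["chrom", "pos"], kind="stable")
        for chrom, sub in df.groupby("chrom", sort=False):
            self._by_chrom[str(chrom)] = (
                sub["pos"].to_numpy(np.int64),
                sub["meth_count"].to_numpy(np.int64),
                sub["total_count"].to_numpy(np.int64),
                sub["context"].to_numpy(),
            )

    def slice(
        self,
        chrom: str,
        start: int,
        end: int,
        contexts: Sequence[str] | None = None,
        min_coverage: int = 1,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(pos, meth, total) arrays for covered sites in [start, end)."""
        if chrom not in self._by_chrom:
            z = np.empty(0, dtype=np.int64)
            return z, z, z
        pos, m, t, ctx = self._by_chrom[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        pos, m, t, ctx = pos[lo:hi], m[lo:hi], t[lo:hi], ctx[lo:hi]
        keep = t >= min_coverage
        if contexts is not None:
            keep &= np.isin(ctx, np.asarray(contexts))
        return pos[keep], m[keep], t[keep]


def pool_samples(calls: pd.DataFrame) -> pd.DataFrame:
    """Sum read counts per site across samples (one row per site)."""
    if calls.empty:
        return calls
    grouped = (
        calls.groupby(["chrom", "pos", "strand", "context"], as_index=False, sort=False)
        [["meth_count", "total_count"]].sum()
    )
    return grouped


def region_methylation(
    calls: pd.DataFrame | CallIndex,
    region: GeneRegion,
    context_filter: Sequence[str] = DEFAULT_CONTEXTS,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    sample_id: str = "",
) -> RegionMethylation | None:
    """Weighted methylation level of one gene region; None with no covered sites."""
    index = calls if isinstance(calls, CallIndex) else CallIndex(calls)
    _, m, t = index.slice(region.chrom, region.start, region.end,
                          contexts=context_filter, min_coverage=min_coverage)
    if len(t) == 0:
        return None
    return RegionMethylation(
        gene_id=region.gene_id,
        region_class=region.region_class,
        sample_id=sample_id,
        level=float(m.sum() / t.sum()),
        n_sites=int(len(t)),
        context="+".join(context_filter),
    )


def region_methylation_table(
    calls: pd.DataFrame | CallIndex,
    genes: Sequence[GeneModel],
    flank_size: int = DEFAULT_FLANK,
    context_filter: Sequence[str] = DEFAULT_CONTEXTS,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    sample_id: str = "",
) -> pd.DataFrame:
    """Tidy table of weighted levels: one row per (gene, region) with coverage."""
    index = calls if isinstance(calls, CallIndex) else CallIndex(calls)
    rows = []
    for gene in genes:
        for region in gene_regions(gene, flank_size):
            rm = region_methylation(index, region, context_filter, min_coverage, sample_id)
            if rm is not None:
                rows.append((rm.gene_id, rm.region_class, rm.sample_id,
                             rm.level, rm.n_sites, rm.context))
    return pd.DataFrame(
        rows, columns=["gene_id", "region_class", "sample_id", "level", "n_sites", "context"]
    )


def metagene_profile(
    calls: pd.DataFrame | CallIndex,
    genes: Sequence[GeneModel],
    grouping: Mapping[str, str],
    binning: MetageneBinning = MetageneBinning(),
    context_filter: Sequence[str] = DEFAULT_CONTEXTS,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    flank_size: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Average per-site methylation per metagene bin for each gene group.

    Genes absent from ``grouping`` are ignored; genes shorter than the number
    of body bins are excluded (their body bins would be empty).  Every
    (group, bin) cell is emitted; cells with no sites carry NaN.
    """
    index = calls if isinstance(calls, CallIndex) else CallIndex(calls)
    groups = sorted(set(grouping.values()))
    g_idx = {g: i for i, g in enumerate(groups)}
    nb = binning.n_total
    sums = np.zeros((len(groups), nb))
    counts = np.zeros((len(groups), nb), dtype=np.int64)
    for gene in genes:
        label = grouping.get(gene.gene_id)
        if label is None:
            continue
        if gene.length < binning.n_body_bins:
            continue
        pos, m, t = index.slice(
            gene.chrom, gene.start - flank_size, gene.end + flank_size,
            contexts=context_filter, min_coverage=min_coverage,
        )
        if len(pos) == 0:
            continue
        bins = sites_to_bins(pos, gene, binning, flank_size)
        ok = bins >= 0
        gi = g_idx[label]
        np.add.at(sums[gi], bins[ok], m[ok] / t[ok])
        np.add.at(counts[gi], bins[ok], 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    rows = [
        (group, b, means[gi, b], int(counts[gi, b]))
        for group, gi in g_idx.items() for b in range(nb)
    ]
    return pd.DataFrame(rows, columns=["group", "bin", "mean_level", "n_sites"])


def methylation_binning(levels: Mapping[str, float]) -> list[MethylationClass]:
    """Split genes into None / Low / Middle / High methylation classes.

    Level exactly 0 → None.  The remaining genes are sorted ascending and cut
    into three contiguous rank groups whose sizes differ by at most one, the
    remainder going to the lower classes first.  Ties at the boundaries are
    broken by stable gene_id order.
    """
    if not levels:
        return []
    none = [g for g, v in levels.items() if v == 0]
    rest = sorted(((v, g) for g, v in levels.items() if v != 0))
    n = len(rest)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    out = [MethylationClass(g, "None") for g in none]
    pos = 0
    for size, cls in zip(sizes, ("Low", "Middle", "High")):
        for _, g in rest[pos:pos + size]:
            out.append(MethylationClass(g, cls))
        pos += size
    return out


def expression_histogram_by_meth_class(
    expression: Mapping[str, float],
    meth_classes: Iterable[MethylationClass],
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Histogram of log10(rpkm + 1) per methylation class.

    Only genes present in both inputs contribute; counts sum to that gene
    count.  Columns: meth_class, bin_left, count.
    """
    classes = {mc.gene_id: mc.meth_class for mc in meth_classes}
    rows: dict[tuple[str, float], int] = {}
    for gene_id, cls in classes.items():
        if gene_id not in expression:
            continue
        x = np.log10(expression[gene_id] + 1.0)
        left = np.floor(x / bin_width) * bin_width
        key = (cls, round(float(left), 10))
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [(c, b, n) for (c, b), n in sorted(rows.items())],
        columns=["meth_class", "bin_left", "count"],
    )
    return df
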