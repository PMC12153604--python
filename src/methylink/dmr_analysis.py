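"""Sliding-window differential-methylation calling between the H and L groups.

Reads are pooled across biological replicates within each group (counts
summed per site).  For every window with at least ``min_sites`` cytosines of
the requested context covered in both groups, the pooled methylated /
unmethylated read counts form a 2×2 table tested with a two-sided Fisher's
exact test.  Windows with p < alpha and |level_H − level_L| ≥ min_diff are
significant; overlapping significant windows of the same direction are merged
into one DMR whose counts are re-pooled and whose p-value is recomputed on
the merged span.  Contexts (CG / CHG / CHH) are tested independently.

Pooling replicates is the simplest estimator consistent with a Fisher test;
it ignores between-replicate overdispersion, which makes the raw p-values
anticonservative when replicates vary — a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_regions import DEFAULT_FLANK, assign_position
from .io_formats import GeneModel
from .methylation_profile import pool_samples

DMR_DIRECTIONS = ("M+", "M-")  # hyper / hypo in the H group


@dataclass(frozen=True)
class DMR:
    chrom: str
    start: int  # 0-based half-open
    end: int
    context: str
    level_H: float
    level_L: float
    p_value: float
    direction: str
    n_sites: int

    @property
    def diff(self) -> float:
        return self.level_H - self.level_L

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class DmrGeneLink:
    dmr: DMR
    gene_id: str
    region_class: str


def _site_arrays(pooled: pd.DataFrame, chrom: str, context: str):
    sub = pooled[(pooled["chrom"] == chrom) & (pooled["context"] == context)]
    sub = sub.sort_values("pos", kind="stable")
    return (sub["pos"].to_numpy(np.int64),
            sub["meth_count"].to_numpy(np.int64),
            sub["total_count"].to_numpy(np.int64))


def window_scan(
    calls_H: pd.DataFrame,
    calls_L: pd.DataFrame,
    context: str = "CG",
    window: int = 200,
    step: int = 50,
    min_sites: int = 4,
    min_diff: float = 0.1,
    test_all: bool = False,
) -> pd.DataFrame:
    """Per-window pooled statistics for one context.

    Returns one row per window position with >= ``min_sites`` sites covered
    in both groups: chrom, start, end, n_sites, mH, uH, mL, uL, diff,
    p_value.  Fisher's exact p is computed for windows with
    |diff| >= ``min_diff`` (all windows when ``test_all`` — used for null
    calibration); elsewhere it is NaN, which cannot affect DMR calls since
    significance also requires the difference threshold.
    """
    pooled_H = pool_samples(calls_H)
    pooled_L = pool_samples(calls_L)
    chroms = sorted(set(pooled_H.get("chrom", pd.Series(dtype=str)).unique())
                    & set(pooled_L.get("chrom", pd.Series(dtype=str)).unique()))
    rows = []
    for chrom in chroms:
        posH, mH, tH = _site_arrays(pooled_H, chrom, context)
        posL, mL, tL = _site_arrays(pooled_L, chrom, context)
        if len(posH) == 0 or len(posL) == 0:
            continue
        # union site grid with per-group counts (0 where a group lacks the site)
        pos = np.union1d(posH, posL)
        MH = np.zeros(len(pos), np.int64); TH = np.zeros(len(pos), np.int64)
        ML = np.zeros(len(pos), np.int64); TL = np.zeros(len(pos), np.int64)
        MH[np.searchsorted(pos, posH)] = mH; TH[np.searchsorted(pos, posH)] = tH
        ML[np.searchsorted(pos, posL)] = mL; TL[np.searchsorted(pos, posL)] = tL
        both = ((TH > 0) & (TL > 0)).astype(np.int64)

        csum = lambda a: np.concatenate([[0], np.cumsum(a)])
        cMH, cTH, cML, cTL, cB = map(csum, (MH, TH, ML, TL, both))

        first = (int(pos[0]) - window + step) // step * step
        starts = np.arange(max(0, first), int(pos[-1]) + 1, step, dtype=np.int64)
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, starts + window)
        n_both = cB[hi] - cB[lo]
        keep = n_both >= min_sites
        for s, l, h, nb in zip(starts[keep], lo[keep], hi[keep], n_both[keep]):
            wmH, wtH = cMH[h] - cMH[l], cTH[h] - cTH[l]
            wmL, wtL = cML[h] - cML[l], cTL[h] - cTL[l]
            if wtH == 0 or wtL == 0:
                continue
            diff = wmH / wtH - wmL / wtL
            if test_all or abs(diff) >= min_diff:
                p = float(stats.fisher_exact(
                    [[wmH, wtH - wmH], [wmL, wtL - wmL]], alternative="two-sided")[1])
            else:
                p = np.nan
            rows.append((chrom, int(s), int(s + window), int(nb),
                         int(wmH), int(wtH - wmH), int(wmL), int(wtL - wmL), diff, p))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "n_sites", "mH", "uH", "mL", "uL", "diff", "p_value"])


def _merged_dmr(
    arrays_H: tuple, arrays_L: tuple,
    chrom: str, context: str, start: int, end: int, min_sites: int,
) -> DMR:
    """Re-pool counts over a merged span and recompute the Fisher p."""
    posH, mH, tH = arrays_H
    posL, mL, tL = arrays_L
    loH, hiH = np.searchsorted(posH, [start, end])
    loL, hiL = np.searchsorted(posL, [start, end])
    smH, stH = int(mH[loH:hiH].sum()), int(tH[loH:hiH].sum())
    smL, stL = int(mL[loL:hiL].sum()), int(tL[loL:hiL].sum())
    n_sites = len(np.intersect1d(posH[loH:hiH], posL[loL:hiL]))
    level_H = smH / stH if stH else float("nan")
    level_L = smL / stL if stL else float("nan")
    p = float(stats.fisher_exact(
        [[smH, stH - smH], [smL, stL - smL]], alternative="two-sided")[1])
    direction = "M+" if level_H - level_L > 0 else "M-"
    return DMR(chrom, start, end, context, level_H, level_L, p, direction, n_sites)


def call_dmrs(
    calls_H: pd.DataFrame,
    calls_L: pd.DataFrame,
    context: str = "CG",
    window: int = 200,
    step: int = 50,
    min_sites: int = 4,
    min_diff: float = 0.1,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> list[DMR]:
    """Call DMRs for one context between the pooled H and L methylomes.

    With ``adjust="BH"`` window significance uses BH q-values instead of raw
    Fisher p-values.
    """
    wins = window_scan(calls_H, calls_L, context, window, step, min_sites,
                       min_diff, test_all=adjust == "BH")
    if wins.empty:
        return []
    sig = wins["p_value"].to_numpy()
    if adjust == "BH":
        from statsmodels.stats.multitest import multipletests
        sig = multipletests(np.nan_to_num(sig, nan=1.0), method="fdr_bh")[1]
    significant = wins[(sig < alpha) & (wins["diff"].abs() >= min_diff)]
    if significant.empty:
        return []
    pooled_H, pooled_L = pool_samples(calls_H), pool_samples(calls_L)
    arrays = {
        chrom: (_site_arrays(pooled_H, chrom, context),
                _site_arrays(pooled_L, chrom, context))
        for chrom in significant["chrom"].unique()
    }
    dmrs: list[DMR] = []
    significant = significant.assign(direction=np.where(significant["diff"] > 0, "M+", "M-"))
    for (chrom, direction), sub in significant.groupby(["chrom", "direction"], sort=True):
        aH, aL = arrays[chrom]
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for r in sub.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = r.start, r.end
            elif r.start < cur_e:  # overlap
                cur_e = max(cur_e, r.end)
            else:
                dmrs.append(_merged_dmr(aH, aL, chrom, context,
                                        cur_s, cur_e, min_sites))
                cur_s, cur_e = r.start, r.end
        if cur_s is not None:
            dmrs.append(_merged_dmr(aH, aL, chrom, context,
                                    cur_s, cur_e, min_sites))
    dmrs.sort(key=lambda d: (d.chrom, d.start, d.direction))
    return dmrs


def link_dmrs_to_genes(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneModel],
    flank: int = DEFAULT_FLANK,
) -> list[DmrGeneLink]:
    """One link per (DMR, gene) pair whose positional class is not none.

    A DMR within flank range of several genes links to each of them; the
    region class is decided by the DMR midpoint relative to each gene.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    by_id = {g.gene_id: g for g in genes}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, g.start - flank), g.end + flank, g.gene_id)
    links = []
    for dmr in dmrs:
        tree = trees.get(dmr.chrom)
        if tree is None:
            continue
        for iv in sorted(tree[dmr.midpoint], key=lambda iv: iv.data):
            gene = by_id[iv.data]
            cls = assign_position((dmr.start, dmr.end), gene, flank)
            if cls is not None:
                links.append(DmrGeneLink(dmr, gene.gene_id, cls))
    return links


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.chrom, d.start, d.end, d.context, d.level_H, d.level_L,
          d.diff, d.p_value, d.direction, d.n_sites) for d in dmrs],
        columns=["chrom", "start", "end", "context", "level_H", "level_L",
                 "diff", "p_value", "direction", "n_sites"],
    )


def dmrs_to_bed_rows(dmrs: Sequence[DMR]) -> list[tuple]:
    """BED rows: name = context|direction, score = round(−10·log10 p)."""
    rows = []
    for d in dmrs:
        score = int(round(-10 * np.log10(max(d.p_value, 1e-300))))
        rows.append((d.chrom, d.start, d.end, f"{d.context}|{d.direction}", score, "."))
    return rows
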