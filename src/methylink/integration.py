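"""Cross-omic statistics linking the methylome to the transcriptome.

* region-wise Spearman correlation between gene-region methylation and mean
  expression (rho < 0 means methylation tracks lower expression);
* distribution of expression log2 fold changes grouped by the position and
  direction of linked DMRs (UP_DMR = hyper-methylated in H, DOWN_DMR = hypo);
* E±/M± quadrant counts of DMR–DEG pairs per context and region;
* hypergeometric gene-set enrichment against user-supplied GMT sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dmr_analysis import DmrGeneLink
from .expression_analysis import DegRecord
from .genome_regions import REGION_CLASSES
from .io_formats import GeneSet

log = logging.getLogger("methylink")

EXACT_PERMUTATION_MAX_N = 9

E_PLUS = ("special_up", "other_up")
E_MINUS = ("special_down", "other_down")


@dataclass(frozen=True)
class CorrelationResult:
    region_class: str
    context: str
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    k: int
    n_study: int
    K: int
    N_background: int
    p_value: float
    fold: float
    q_value: float | None = None


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with average-rank ties.

    The p-value uses the t approximation for n > 9 and an exact two-sided
    permutation distribution for n ≤ 9 (all n! orderings enumerated).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= EXACT_PERMUTATION_MAX_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx = (rx - rx.mean())
        sy = ry - ry.mean()
        denom = np.sqrt((rx ** 2).sum() * (sy ** 2).sum())
        if denom == 0:
            return float("nan"), float("nan")
        perms = np.array(list(itertools.permutations(sy)))
        rhos = perms @ rx / denom
        obs = rx @ sy / denom
        p = float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))
        return float(obs), p
    return rho, float(stats.spearmanr(x, y).pvalue)


def region_expression_correlation(
    region_meth: Mapping[str, float],
    expression: Mapping[str, float],
    region_class: str = "",
    context: str = "CG",
) -> CorrelationResult | None:
    """Spearman correlation over genes having both a methylation level and an
    expression value; None (with a warning) when fewer than 3 genes overlap."""
    genes = sorted(set(region_meth) & set(expression))
    if len(genes) < 3:
        log.warning("correlation for %s/%s skipped: only %d genes with both values",
                    region_class, context, len(genes))
        return None
    x = [region_meth[g] for g in genes]
    y = [expression[g] for g in genes]
    rho, p = spearman(x, y)
    return CorrelationResult(region_class, context, rho, p, len(genes))


# ---------------------------------------------------------------------------
# DMR-linked expression change and quadrant tables
# ---------------------------------------------------------------------------

def expression_change_by_dmr(
    links: Sequence[DmrGeneLink],
    degs: Mapping[str, DegRecord],
) -> pd.DataFrame:
    """One expression log2fc per (DMR, gene) link, tagged by region and DMR direction.

    All linked genes contribute (not only significant DEGs); DMR direction is
    reported as UP_DMR (M+) / DOWN_DMR (M−).
    """
    rows = []
    for link in links:
        rec = degs.get(link.gene_id)
        if rec is None:
            continue
        direction = "UP_DMR" if link.dmr.direction == "M+" else "DOWN_DMR"
        rows.append((link.region_class, direction, link.gene_id,
                     link.dmr.context, rec.log2fc))
    return pd.DataFrame(rows, columns=["region_class", "dmr_direction",
                                       "gene_id", "context", "log2fc"])


def summarize_expression_change(change: pd.DataFrame) -> pd.DataFrame:
    """Median log2fc and pair count per (region_class, dmr_direction)."""
    if change.empty:
        return pd.DataFrame(columns=["region_class", "dmr_direction", "median_log2fc", "n"])
    out = (change.groupby(["region_class", "dmr_direction"])["log2fc"]
           .agg(median_log2fc="median", n="size").reset_index())
    return out


def quadrant_table(
    links: Sequence[DmrGeneLink],
    degs: Mapping[str, DegRecord],
) -> pd.DataFrame:
    """E±/M± counts of distinct (gene, DMR) pairs per context and region.

    Only genes with a DEG direction class other than ``none`` contribute
    (E+ = special_up ∪ other_up, E− = special_down ∪ other_down).  Every
    (context, region, E, M) cell present in the data is emitted; absent
    combinations for observed contexts are filled with zero.
    """
    seen: set[tuple] = set()
    counts: dict[tuple[str, str, str, str], int] = {}
    contexts: set[str] = set()
    for link in links:
        rec = degs.get(link.gene_id)
        if rec is None or rec.direction_class == "none":
            continue
        key = (link.gene_id, link.dmr.chrom, link.dmr.start, link.dmr.end,
               link.dmr.context, link.region_class)
        if key in seen:
            continue
        seen.add(key)
        e_dir = "E+" if rec.direction_class in E_PLUS else "E-"
        cell = (link.dmr.context, link.region_class, e_dir, link.dmr.direction)
        counts[cell] = counts.get(cell, 0) + 1
        contexts.add(link.dmr.context)
    rows = []
    for ctx in sorted(contexts):
        for region in REGION_CLASSES:
            for e in ("E+", "E-"):
                for m in ("M+", "M-"):
                    rows.append((ctx, region, e, m, counts.get((ctx, region, e, m), 0)))
    return pd.DataFrame(rows, columns=["context", "region_class",
                                       "expr_direction", "meth_direction", "count"])


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeom_pvalue(k, K: int, n: int, N: int):
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` may be a scalar or an array of counts.
    """
    arr = np.asarray(k)
    out = stats.hypergeom.sf(arr - 1, N, K, n)
    return float(out) if arr.ndim == 0 else out


def hypergeometric_enrichment(
    study: Iterable[str],
    gene_sets: Sequence[GeneSet],
    background: Iterable[str],
    method: str = "raw",
) -> list[EnrichmentResult]:
    """Over-representation of each gene set in the study list.

    The study list and every set are intersected with the background universe
    first; sets with no background members are skipped.  p is the
    hypergeometric upper tail P(X >= k); ``method="BH"`` adds BH q-values.
    Results are sorted by ascending p.
    """
    bg = set(background)
    study_set = set(study) & bg
    if not study_set:
        raise ValueError("empty study set (after background intersection)")
    N, n = len(bg), len(study_set)
    results = []
    for gs in gene_sets:
        members = set(gs.members) & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & study_set)
        p = hypergeom_pvalue(k, K, n, N)
        fold = (k / n) / (K / N)
        results.append(EnrichmentResult(gs.set_id, gs.name, k, n, K, N, p, fold))
    results.sort(key=lambda r: (r.p_value, r.set_id))
    if method == "BH" and results:
        from statsmodels.stats.multitest import multipletests
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(r.set_id, r.name, r.k, r.n_study, r.K,
                             r.N_background, r.p_value, r.fold, float(q))
            for r, q in zip(results, qs)
        ]
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.set_id, r.name, r.k, r.n_study, r.K, r.N_background,
          r.p_value, r.fold, r.q_value) for r in results],
        columns=["set_id", "name", "k", "n_study", "K", "N_background",
                 "p_value", "fold", "q_value"],
    )


def correlations_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.region_class, r.context, r.rho, r.p_value, r.n) for r in results],
        columns=["region_class", "context", "rho", "p_value", "n"],
    )
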