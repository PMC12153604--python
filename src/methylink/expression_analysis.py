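"""Expression-level gene classes and two-group differential expression.

Genes are binned by mean RPKM into non (≤1), low (≤10), middle (≤100) and
high (>100) expression.  Differential expression between the H and L groups
uses Welch's t on log2(rpkm + 1); genes are then assigned one of four
direction classes:

* ``special_up`` / ``special_down`` — expressed exclusively in one group
  (all samples of that group above the expression threshold, all samples of
  the other at or below it);
* ``other_up`` / ``other_down`` — significant shift (p < alpha) up or down in
  the H group;
* ``none`` otherwise.

Raw p-values are used by default (mirroring a plain p < 0.05 DEG rule);
Benjamini–Hochberg adjustment is available via ``adjust="BH"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXPRESSION_CLASSES = ("non", "low", "middle", "high")
DIRECTION_CLASSES = ("special_up", "special_down", "other_up", "other_down", "none")

DEFAULT_ALPHA = 0.05
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_EXPR_THRESHOLD = 1.0


@dataclass(frozen=True)
class ExpressionClass:
    gene_id: str
    expr_class: str


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    mean_H: float
    mean_L: float
    log2fc: float
    p_value: float
    direction_class: str


def expression_binning(rpkm_mean: float) -> str:
    """Expression class from mean RPKM: non ≤ 1 < low ≤ 10 < middle ≤ 100 < high."""
    if rpkm_mean < 0:
        raise ValueError("rpkm must be >= 0")
    if rpkm_mean <= 1:
        return "non"
    if rpkm_mean <= 10:
        return "low"
    if rpkm_mean <= 100:
        return "middle"
    return "high"


def _welch_p(h: np.ndarray, l: np.ndarray) -> float:
    """Welch's t p-value on log2(x+1); degenerate zero-variance cases handled."""
    x, y = np.log2(h + 1.0), np.log2(l + 1.0)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        return 1.0 if np.isclose(x.mean(), y.mean()) else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def deg_test(
    rpkm_H: Sequence[float],
    rpkm_L: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    expr_threshold: float = DEFAULT_EXPR_THRESHOLD,
    gene_id: str = "",
) -> DegRecord:
    """Differential-expression record for one gene (H vs L groups).

    log2fc = log2((mean_H + c) / (mean_L + c)) with pseudocount c, so zero
    means stay finite.
    """
    h = np.asarray(rpkm_H, dtype=float)
    l = np.asarray(rpkm_L, dtype=float)
    if len(h) < 2 or len(l) < 2:
        raise ValueError("need >= 2 samples per group")
    mean_H, mean_L = float(h.mean()), float(l.mean())
    log2fc = float(np.log2((mean_H + pseudocount) / (mean_L + pseudocount)))
    p = _welch_p(h, l)
    cls = deg_direction_class(log2fc, p, h, l, alpha=alpha, expr_threshold=expr_threshold)
    return DegRecord(gene_id, mean_H, mean_L, log2fc, p, cls)


def deg_direction_class(
    log2fc: float,
    p_value: float,
    rpkm_H: Sequence[float],
    rpkm_L: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    expr_threshold: float = DEFAULT_EXPR_THRESHOLD,
) -> str:
    """Direction class: group-exclusive expression first, then significance."""
    h = np.asarray(rpkm_H, dtype=float)
    l = np.asarray(rpkm_L, dtype=float)
    if (h > expr_threshold).all() and (l <= expr_threshold).all():
        return "special_up"
    if (l > expr_threshold).all() and (h <= expr_threshold).all():
        return "special_down"
    if p_value < alpha:
        if log2fc > 0:
            return "other_up"
        if log2fc < 0:
            return "other_down"
    return "none"


def deg_table(
    expression: pd.DataFrame,
    sample_groups: Mapping[str, str],
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    expr_threshold: float = DEFAULT_EXPR_THRESHOLD,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-gene DEG table from a genes × samples frame.

    ``sample_groups`` maps sample_id → "H" | "L".  With ``adjust="BH"`` the
    significance used for the other_up/other_down classes is the BH q-value
    (reported in a ``q_value`` column).
    """
    h_cols = [s for s in expression.columns if sample_groups.get(s) == "H"]
    l_cols = [s for s in expression.columns if sample_groups.get(s) == "L"]
    if len(h_cols) < 2 or len(l_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    H = expression[h_cols].to_numpy(float)
    L = expression[l_cols].to_numpy(float)
    mean_H, mean_L = H.mean(axis=1), L.mean(axis=1)
    log2fc = np.log2((mean_H + pseudocount) / (mean_L + pseudocount))
    p = np.array([_welch_p(H[i], L[i]) for i in range(len(expression))])
    sig = p
    out = pd.DataFrame({
        "gene_id": expression.index,
        "mean_H": mean_H, "mean_L": mean_L, "log2fc": log2fc, "p_value": p,
    })
    if adjust == "BH":
        from statsmodels.stats.multitest import multipletests
        out["q_value"] = multipletests(p, method="fdr_bh")[1]
        sig = out["q_value"].to_numpy()
    classes = [
        deg_direction_class(log2fc[i], sig[i], H[i], L[i],
                            alpha=alpha, expr_threshold=expr_threshold)
        for i in range(len(out))
    ]
    out["direction_class"] = classes
    return out.reset_index(drop=True)


def deg_records(table: pd.DataFrame) -> dict[str, DegRecord]:
    """DegRecord per gene from a :func:`deg_table` frame."""
    return {
        r.gene_id: DegRecord(r.gene_id, r.mean_H, r.mean_L, r.log2fc,
                             r.p_value, r.direction_class)
        for r in table.itertuples(index=False)
    }
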