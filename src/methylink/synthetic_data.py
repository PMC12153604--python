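"""Synthetic WGBS + expression data with the structure the analysis assumes.

The generator emulates a two-group (H vs L, 4 samples each) muscle
methylome/transcriptome experiment:

* non-overlapping genes on one chromosome, each with a ±3 kb footprint and
  geometrically spaced cytosine sites (mostly CG context);
* a piecewise metagene-shaped truth: high methylation in flanks (~0.65) and
  gene bodies (~0.75) with a pronounced dip to ~0.25 at the TSS, per-gene
  level variation drawn from beta distributions;
* beta-binomially overdispersed read counts at Poisson coverage;
* expression log-linearly coupled to the per-gene truth — negatively to
  upstream methylation and positively to gene-body methylation — with the
  downstream flank level correlated with the body level so that downstream
  methylation also tracks expression positively;
* injected DMRs (group-H level shifts) and DEGs (group-H mean fold changes)
  recorded in truth tables for recovery checks.

All randomness flows from a single seed; a fixed configuration yields
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GeneModel, write_expression_frame, write_genes_bed, write_methylation_frame


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 500
    chrom: str = "chr1"
    chrom_length: int | None = None  # derived from gene placement when None
    gene_length_range: tuple[int, int] = (1500, 4000)
    flank_size: int = 3000
    intergenic_gap: int = 500

    # cytosine sites
    cpg_spacing_mean: float = 25.0   # geometric mean gap between sites (bp)
    cg_fraction: float = 0.7         # remaining sites split CHG/CHH evenly
    non_cg_level: float = 0.02       # flat truth level for CHG/CHH sites

    # methylation truth profile (CG)
    flank_level: float = 0.65
    tss_level: float = 0.25
    body_level: float = 0.75
    tss_dip_halfwidth: int = 500     # bp, linear interpolation to tss_level
    level_concentration: float = 10.0  # beta concentration of per-gene levels

    # read counts
    coverage_mean: float = 30.0      # Poisson coverage per site per sample
    dispersion: float = 0.05         # beta-binomial intraclass correlation
    n_samples_per_group: int = 4

    # expression model (natural-log scale)
    baseline_log_mean: float = 2.5
    baseline_log_sd: float = 1.0
    beta_upstream: float = -4.0
    beta_body: float = 5.0
    noise_sd: float = 0.3
    nonexpressed_fraction: float = 0.25  # genes forced to rpkm <= 1

    # injected signal
    n_dmrs: int = 30
    dmr_effect: float = 0.4
    dmr_width: int = 300
    n_degs: int = 50
    deg_log2fc: float = 2.0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("flank_level", "tss_level", "body_level", "non_cg_level",
                     "cg_fraction", "nonexpressed_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.dispersion < 1:
            raise ValueError("dispersion must be in (0, 1)")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: list[GeneModel]
    calls: pd.DataFrame          # all samples, canonical columns + sample_id
    expression: pd.DataFrame     # genes x samples
    sample_groups: dict[str, str]
    dmr_truth: pd.DataFrame      # chrom, start, end, context, sign, gene_id
    deg_truth: pd.DataFrame      # gene_id, sign, log2fc
    site_pos: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# annotation and sites
# ---------------------------------------------------------------------------

def simulate_annotation(
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[GeneModel], np.ndarray, np.ndarray, np.ndarray]:
    """Place non-overlapping genes (footprints included) and their cytosines.

    Returns (genes, site positions, site contexts, site gene index).  Sites
    exist only inside gene footprints, so every site belongs to exactly one
    gene.  Raises when a fixed ``chrom_length`` cannot hold all genes.
    """
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    gaps = rng.integers(config.intergenic_gap, 2 * config.intergenic_gap + 1,
                        size=config.n_genes)
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    genes: list[GeneModel] = []
    cursor = config.flank_size + int(gaps[0])
    for i in range(config.n_genes):
        start = cursor
        end = start + int(lengths[i])
        genes.append(GeneModel(f"g{i:04d}", config.chrom, start, end, str(strands[i])))
        cursor = end + 2 * config.flank_size + int(gaps[i])
    needed = cursor + config.flank_size
    if config.chrom_length is not None and config.chrom_length < needed:
        raise ValueError(
            f"chrom_length {config.chrom_length} cannot hold {config.n_genes} genes "
            f"(need >= {needed})")

    pos_chunks, gene_idx_chunks = [], []
    for i, g in enumerate(genes):
        fp_start, fp_end = g.start - config.flank_size, g.end + config.flank_size
        span = fp_end - fp_start
        n_est = int(span / config.cpg_spacing_mean * 1.6) + 8
        gaps_s = rng.geometric(1.0 / config.cpg_spacing_mean, size=n_est)
        pos = fp_start + np.cumsum(gaps_s) - 1
        pos = pos[pos < fp_end]
        pos_chunks.append(pos)
        gene_idx_chunks.append(np.full(len(pos), i, dtype=np.int64))
    site_pos = np.concatenate(pos_chunks)
    site_gene = np.concatenate(gene_idx_chunks)
    u = rng.random(len(site_pos))
    ctx = np.where(u < config.cg_fraction, "CG",
                   np.where(u < config.cg_fraction + (1 - config.cg_fraction) / 2,
                            "CHG", "CHH"))
    return genes, site_pos, ctx, site_gene


def _gene_levels(config: SimulationConfig, rng: np.random.Generator, n: int):
    """Per-gene truth levels (upstream flank, body, downstream flank, tss).

    The downstream flank level is tied to the body level so downstream
    methylation inherits the body's positive coupling with expression.
    """
    nu = config.level_concentration

    def beta_around(mean):
        return rng.beta(mean * nu, (1 - mean) * nu, size=n)

    up = beta_around(config.flank_level)
    body = beta_around(config.body_level)
    down = np.clip(config.flank_level + 0.9 * (body - config.body_level)
                   + rng.normal(0, 0.03, size=n), 0.02, 0.98)
    tss = np.full(n, config.tss_level)
    return up, body, down, tss


def _site_truth_levels(
    config: SimulationConfig,
    genes: list[GeneModel],
    site_pos: np.ndarray,
    site_ctx: np.ndarray,
    site_gene: np.ndarray,
    up: np.ndarray, body: np.ndarray, down: np.ndarray, tss: np.ndarray,
) -> np.ndarray:
    """Piecewise truth level per site with a linear TSS dip (transcript-oriented)."""
    starts = np.array([g.start for g in genes])
    ends = np.array([g.end for g in genes])
    plus = np.array([g.strand == "+" for g in genes])

    s = starts[site_gene]
    e = ends[site_gene]
    is_plus = plus[site_gene]
    in_body = (site_pos >= s) & (site_pos < e)
    left = site_pos < s  # genomically left flank
    # transcript-oriented region class
    upstream = np.where(is_plus, left, ~left & ~in_body)
    base = np.where(in_body, body[site_gene],
                    np.where(upstream, up[site_gene], down[site_gene]))
    # TSS dip
    tss_pos = np.where(is_plus, s, e - 1)
    dist = np.abs(site_pos - tss_pos)
    w = config.tss_dip_halfwidth
    frac = np.clip(1.0 - dist / w, 0.0, 1.0)
    level = base + (tss[site_gene] - base) * frac
    level = np.where(site_ctx == "CG", level, config.non_cg_level)
    return np.clip(level, 0.0, 1.0)


# ---------------------------------------------------------------------------
# methylome and expression
# ---------------------------------------------------------------------------

def _inject_dmrs(
    config: SimulationConfig,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Choose injected DMR intervals inside distinct gene footprints."""
    n = min(config.n_dmrs, len(genes))
    which = rng.choice(len(genes), size=n, replace=False)
    rows = []
    for gi in sorted(which):
        g = genes[gi]
        fp_start, fp_end = g.start - config.flank_size, g.end + config.flank_size
        start = int(rng.integers(fp_start, fp_end - config.dmr_width))
        sign = 1 if rng.random() < 0.5 else -1
        rows.append((g.chrom, start, start + config.dmr_width, "CG", sign, g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                       "sign", "gene_id"])


def simulate_methylome(
    config: SimulationConfig,
    site_pos: np.ndarray,
    site_levels: np.ndarray,
    site_ctx: np.ndarray,
    group: str,
    dmr_truth: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Beta-binomial read counts per site for each sample of one group.

    Injected DMRs shift the truth level by ±effect (clipped to [0, 1]) in
    group H only.  Zero-coverage draws are omitted from the output (they
    would be dropped at parse time anyway).
    """
    levels = site_levels.copy()
    if group == "H" and len(dmr_truth):
        for r in dmr_truth.itertuples(index=False):
            inside = (site_pos >= r.start) & (site_pos < r.end) & (site_ctx == r.context)
            levels[inside] = np.clip(levels[inside] + r.sign * config.dmr_effect, 0.0, 1.0)
    nu = (1.0 - config.dispersion) / config.dispersion
    frames = []
    for s in range(config.n_samples_per_group):
        sample_id = f"{group}{s + 1}"
        cov = rng.poisson(config.coverage_mean, size=len(site_pos))
        p = np.empty(len(site_pos))
        interior = (levels > 0) & (levels < 1)
        p[~interior] = levels[~interior]
        p[interior] = rng.beta(levels[interior] * nu, (1 - levels[interior]) * nu)
        meth = rng.binomial(cov, p)
        keep = cov > 0
        frames.append(pd.DataFrame({
            "chrom": config.chrom, "pos": site_pos[keep], "strand": "+",
            "context": site_ctx[keep], "meth_count": meth[keep],
            "total_count": cov[keep], "sample_id": sample_id,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_expression(
    config: SimulationConfig,
    genes: list[GeneModel],
    up: np.ndarray,
    body: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression table (genes × samples) plus the injected-DEG truth table.

    ln(mean rpkm) = baseline + beta_upstream·(upstream − mean) +
    beta_body·(body − mean) ; a quarter of the genes are forced into the
    non-expressed stratum (rpkm ≤ 1) so all four expression classes exist.
    Injected DEGs (chosen among expressed genes) multiply the H-group mean by
    2^(±log2fc).
    """
    n = len(genes)
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    ln_mean = (baseline
               + config.beta_upstream * (up - config.flank_level)
               + config.beta_body * (body - config.body_level))
    forced_low = rng.choice(n, size=int(round(config.nonexpressed_fraction * n)),
                            replace=False)
    ln_mean[forced_low] = np.log(0.3) + rng.normal(0, 0.2, size=len(forced_low))

    expressed = np.setdiff1d(np.arange(n), forced_low)
    n_degs = min(config.n_degs, len(expressed))
    deg_idx = np.sort(rng.choice(expressed, size=n_degs, replace=False))
    signs = np.where(rng.random(n_degs) < 0.5, 1, -1)
    ln_mean_H = ln_mean.copy()
    ln_mean_H[deg_idx] += signs * config.deg_log2fc * np.log(2.0)

    cols = {}
    for group, lm in (("H", ln_mean_H), ("L", ln_mean)):
        for s in range(config.n_samples_per_group):
            cols[f"{group}{s + 1}"] = np.exp(lm + rng.normal(0, config.noise_sd, size=n))
    expr = pd.DataFrame(cols, index=[g.gene_id for g in genes])
    expr.index.name = "gene_id"
    deg_truth = pd.DataFrame({
        "gene_id": [genes[i].gene_id for i in deg_idx],
        "sign": signs,
        "log2fc": signs * config.deg_log2fc,
    })
    return expr, deg_truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full input bundle: annotation, methylomes for both groups, expression,
    and the injected-DMR/DEG truth tables."""
    rng = np.random.default_rng(config.seed)
    genes, site_pos, site_ctx, site_gene = simulate_annotation(config, rng)
    up, body, down, tss = _gene_levels(config, rng, len(genes))
    levels = _site_truth_levels(config, genes, site_pos, site_ctx, site_gene,
                                up, body, down, tss)
    dmr_truth = _inject_dmrs(config, genes, rng)
    calls_H = simulate_methylome(config, site_pos, levels, site_ctx, "H", dmr_truth, rng)
    calls_L = simulate_methylome(config, site_pos, levels, site_ctx, "L", dmr_truth, rng)
    expr, deg_truth = simulate_expression(config, genes, up, body, rng)
    calls = pd.concat([calls_H, calls_L], ignore_index=True)
    groups = {f"{g}{i + 1}": g for g in ("H", "L")
              for i in range(config.n_samples_per_group)}
    return SimulatedDataset(config, genes, calls, expr, groups,
                            dmr_truth, deg_truth, site_pos)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    """Write the bundle as plain-text inputs; returns a name → path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    write_genes_bed(ds.genes, outdir / "annotation.bed")
    paths["annotation"] = str(outdir / "annotation.bed")
    for sample_id, sub in ds.calls.groupby("sample_id", sort=True):
        p = outdir / f"meth_{sample_id}.tsv"
        write_methylation_frame(sub, p)
        paths[f"methylation:{sample_id}"] = str(p)
    write_expression_frame(ds.expression, outdir / "expression.tsv")
    paths["expression"] = str(outdir / "expression.tsv")
    ds.dmr_truth.to_csv(outdir / "dmr_truth.tsv", sep="\t", index=False)
    ds.deg_truth.to_csv(outdir / "deg_truth.tsv", sep="\t", index=False)
    paths["dmr_truth"] = str(outdir / "dmr_truth.tsv")
    paths["deg_truth"] = str(outdir / "deg_truth.tsv")
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(dataclasses.asdict(ds.config), fh, indent=2)
    paths["config"] = str(outdir / "sim_config.json")
    return paths
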