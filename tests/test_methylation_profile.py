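import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylink.genome_regions import GeneRegion, MetageneBinning, gene_regions
from methylink.io_formats import GeneModel
from methylink.methylation_profile import (
    CallIndex,
    expression_histogram_by_meth_class,
    metagene_profile,
    methylation_binning,
    pool_samples,
    region_methylation,
)

from conftest import make_calls


def brute_force_region_level(rows, region, contexts, min_cov):
    """Independent per-site loop oracle for the weighted region level."""
    meth = total = n = 0
    for chrom, pos, _strand, ctx, m, t in rows:
        if (chrom == region.chrom and region.start <= pos < region.end
                and ctx in contexts and t >= min_cov):
            meth += m
            total += t
            n += 1
    return (meth / total if total else None), n


class TestRegionMethylation:
    region = GeneRegion("g", "genebody", "chr1", 100, 200, "+")

    def test_weighted_level_hand_sum(self):
        calls = make_calls([("chr1", 110, "+", "CG", 3, 10),
                            ("chr1", 120, "+", "CG", 7, 10)])
        rm = region_methylation(calls, self.region)
        assert rm.level == pytest.approx(0.5)  # 10/20, not mean of 0.3, 0.7
        assert rm.n_sites == 2

    @pytest.mark.parametrize("meth,expected", [(0, 0.0), (10, 1.0)])
    def test_extreme_levels(self, meth, expected):
        calls = make_calls([("chr1", 110, "+", "CG", meth, 10)])
        assert region_methylation(calls, self.region).level == expected

    def test_no_covered_sites_gives_no_record(self):
        calls = make_calls([("chr1", 110, "+", "CG", 1, 2)])  # below min_coverage
        assert region_methylation(calls, self.region, min_coverage=4) is None

    def test_context_filter(self):
        calls = make_calls([("chr1", 110, "+", "CG", 8, 10),
                            ("chr1", 120, "+", "CHH", 0, 10)])
        rm = region_methylation(calls, self.region, context_filter=("CG",))
        assert rm.n_sites == 1 and rm.level == pytest.approx(0.8)

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(1, 40)
            rows = [("chr1", int(rng.integers(0, 400)), "+",
                     rng.choice(["CG", "CHG", "CHH"]),
                     0, int(rng.integers(0, 20)))
                    for _ in range(n)]
            rows = [(c, p, s, x, int(rng.integers(0, t + 1)), t)
                    for c, p, s, x, _, t in rows]
            rows = [r for r in rows if r[5] > 0]
            if not rows:
                continue
            region = GeneRegion("g", "genebody", "chr1", 50, 300, "+")
            level, n_sites = brute_force_region_level(rows, region, ("CG", "CHG"), 3)
            rm = region_methylation(make_calls(rows), region,
                                    context_filter=("CG", "CHG"), min_coverage=3)
            if level is None:
                assert rm is None
            else:
                assert rm.level == pytest.approx(level)
                assert rm.n_sites == n_sites


class TestMetageneProfile:
    def test_constant_site_level_gives_constant_profile(self):
        g = GeneModel("g", "chr1", 5000, 8000, "+")
        rows = [("chr1", p, "+", "CG", 5, 10) for p in range(2000, 11000, 40)]
        prof = metagene_profile(make_calls(rows), [g], {"g": "grp"})
        filled = prof.dropna(subset=["mean_level"])
        np.testing.assert_allclose(filled["mean_level"], 0.5)

    def test_single_site_hand_binning(self):
        g = GeneModel("g", "chr1", 5000, 8000, "+")
        calls = make_calls([("chr1", 5010, "+", "CG", 2, 10)])
        prof = metagene_profile(calls, [g], {"g": "grp"})
        by_bin = prof.set_index("bin")
        assert by_bin.loc[30, "mean_level"] == pytest.approx(0.2)  # first body bin
        assert by_bin.drop(index=30)["mean_level"].isna().all()

    def test_minus_gene_profile_equals_plus_mirror(self):
        rng = np.random.default_rng(3)
        gp = GeneModel("gp", "chr1", 5000, 8000, "+")
        gm = GeneModel("gm", "chr1", 5000, 8000, "-")
        pos = rng.choice(np.arange(2000, 11000), size=200, replace=False)
        meth = rng.integers(0, 11, size=200)
        rows_p = [("chr1", int(p), "+", "CG", int(m), 10) for p, m in zip(pos, meth)]
        # mirror each position through the footprint centre
        mirror = 2000 + (11000 - 1) - pos
        rows_m = [("chr1", int(p), "+", "CG", int(m), 10) for p, m in zip(mirror, meth)]
        prof_p = metagene_profile(make_calls(rows_p), [gp], {"gp": "x"})
        prof_m = metagene_profile(make_calls(rows_m), [gm], {"gm": "x"})
        np.testing.assert_allclose(prof_p["mean_level"], prof_m["mean_level"])

    def test_gene_order_permutation_invariance(self, small_dataset):
        idx = CallIndex(pool_samples(small_dataset.calls))
        genes = list(small_dataset.genes)
        grouping = {g.gene_id: "all" for g in genes}
        a = metagene_profile(idx, genes, grouping)
        b = metagene_profile(idx, genes[::-1], grouping)
        pd.testing.assert_frame_equal(a, b)

    def test_short_genes_excluded(self):
        g = GeneModel("tiny", "chr1", 5000, 5010, "+")  # shorter than 60 body bins
        calls = make_calls([("chr1", 5005, "+", "CG", 5, 10)])
        prof = metagene_profile(calls, [g], {"tiny": "grp"})
        assert prof["mean_level"].isna().all()


class TestMethylationBinning:
    def test_hand_rank_split(self):
        levels = {f"g{i}": v for i, v in enumerate([0, .1, .2, .3, .4, .5, .6])}
        classes = {c.gene_id: c.meth_class for c in methylation_binning(levels)}
        assert classes == {"g0": "None", "g1": "Low", "g2": "Low",
                           "g3": "Middle", "g4": "Middle",
                           "g5": "High", "g6": "High"}

    def test_all_zero_is_all_none(self):
        classes = methylation_binning({"a": 0.0, "b": 0.0})
        assert {c.meth_class for c in classes} == {"None"}

    def test_remainder_goes_to_low_first(self):
        levels = {f"g{i}": (i + 1) / 10 for i in range(7)}  # 7 nonzero genes
        classes = [c.meth_class for c in methylation_binning(levels)]
        sizes = {cls: classes.count(cls) for cls in ("Low", "Middle", "High")}
        assert sizes == {"Low": 3, "Middle": 2, "High": 2}

    def test_empty_input(self):
        assert methylation_binning({}) == []

    @given(st.lists(st.floats(0, 1, width=32), min_size=0, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_split_size_and_monotonicity_properties(self, values):
        levels = {f"g{i}": float(v) for i, v in enumerate(values)}
        classes = methylation_binning(levels)
        by_class = {}
        for c in classes:
            by_class.setdefault(c.meth_class, []).append(levels[c.gene_id])
        low = by_class.get("Low", [])
        mid = by_class.get("Middle", [])
        high = by_class.get("High", [])
        assert abs(len(low) - len(high)) <= 1
        if low and mid:
            assert max(low) <= min(mid) + 1e-12
        if mid and high:
            assert max(mid) <= min(high) + 1e-12
        assert all(v == 0 for v in by_class.get("None", []))


class TestExpressionHistogram:
    def _classes(self, genes):
        from methylink.methylation_profile import MethylationClass
        return [MethylationClass(g, "Low") for g in genes]

    def test_counts_conserved_and_zero_spike(self):
        expr = {f"g{i}": 0.0 for i in range(5)}
        hist = expression_histogram_by_meth_class(expr, self._classes(expr))
        assert hist["count"].sum() == 5
        assert len(hist) == 1 and hist["bin_left"].iloc[0] == 0.0

    def test_log_bin_placement(self):
        hist = expression_histogram_by_meth_class({"g": 9.0}, self._classes(["g"]))
        # log10(9 + 1) = 1.0 falls in the bin starting at 1.0
        assert hist["bin_left"].iloc[0] == pytest.approx(1.0)

    def test_genes_without_both_records_excluded(self):
        hist = expression_histogram_by_meth_class(
            {"g1": 1.0}, self._classes(["g1", "g2"]))
        assert hist["count"].sum() == 1
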