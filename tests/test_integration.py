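import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from methylink.dmr_analysis import DMR, DmrGeneLink
from methylink.expression_analysis import DegRecord
from methylink.integration import (
    expression_change_by_dmr,
    hypergeom_pvalue,
    hypergeometric_enrichment,
    quadrant_table,
    region_expression_correlation,
    spearman,
    summarize_expression_change,
)
from methylink.io_formats import GeneSet


def rank_then_pearson(x, y):
    """Oracle: average-rank both vectors, then plain Pearson correlation."""
    def avg_ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def hypergeom_tail_oracle(k, K, n, N):
    """Oracle: exact upper tail by direct combinatorial enumeration."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i),
                          math.comb(N, n))
    return float(total)


class TestSpearman:
    def test_monotone_and_antimonotone(self):
        meth = [.1, .2, .3, .4]
        assert spearman(meth, [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman(meth, [40, 30, 20, 10])[0] == pytest.approx(-1.0)

    def test_hand_rank_formula_value(self):
        rho, p = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(1 - 6 * 4 / (4 * 15))  # = 0.6
        # exact permutation p: how many of 4! orderings reach |rho| >= 0.6
        assert p == pytest.approx(
            sum(abs(rank_then_pearson([1, 2, 3, 4], pm)) >= 0.6 - 1e-12
                for pm in itertools.permutations([2, 1, 4, 3])) / 24)

    def test_agrees_with_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(17)
        for n in (5, 8, 12, 40, 200):
            x = rng.permutation(n) + rng.normal(0, 1e-9, n)  # tie-free
            y = rng.normal(size=n)
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    def test_ties_use_average_ranks(self):
        x = [1, 1, 2, 3, 3, 4, 5, 6, 7, 8, 9, 10]
        y = [2, 1, 1, 3, 5, 4, 4, 6, 8, 7, 9, 9]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(rank_then_pearson(x, y), abs=1e-12)


class TestRegionExpressionCorrelation:
    def test_restricted_to_shared_genes(self):
        meth = {"a": .1, "b": .2, "c": .3, "d": .4, "zzz": .9}
        expr = {"a": 10, "b": 20, "c": 30, "d": 40, "yyy": 5}
        res = region_expression_correlation(meth, expr, "genebody")
        assert res.n == 4
        assert res.rho == pytest.approx(1.0)

    def test_fewer_than_three_genes_gives_none(self, caplog):
        with caplog.at_level("WARNING", logger="methylink"):
            assert region_expression_correlation({"a": .1, "b": .2},
                                                 {"a": 1, "b": 2}) is None
        assert "skipped" in caplog.text


def _deg(gene, log2fc, cls):
    return DegRecord(gene, 2 ** log2fc, 1.0, log2fc, 0.01, cls)


def _link(gene, region, direction="M+", start=100, context="CG"):
    dmr = DMR("chr1", start, start + 200, context, 0.8, 0.2, 1e-3, direction, 5)
    return DmrGeneLink(dmr, gene, region)


class TestExpressionChangeByDmr:
    def test_single_link_bookkeeping(self):
        links = [_link("g1", "genebody", "M+")]
        degs = {"g1": _deg("g1", 1.5, "none")}  # all genes count, not only DEGs
        change = expression_change_by_dmr(links, degs)
        assert change.to_dict("records") == [{
            "region_class": "genebody", "dmr_direction": "UP_DMR",
            "gene_id": "g1", "context": "CG", "log2fc": 1.5}]

    def test_no_links_empty_table(self):
        assert expression_change_by_dmr([], {}).empty

    def test_symmetric_null_has_near_zero_medians(self):
        rng = np.random.default_rng(42)
        links, degs = [], {}
        for i in range(500):
            gene = f"g{i}"
            direction = "M+" if i % 2 == 0 else "M-"
            links.append(_link(gene, "genebody", direction, start=1000 + i * 500))
            degs[gene] = _deg(gene, float(rng.normal(0, 0.8)), "none")
        summary = summarize_expression_change(
            expression_change_by_dmr(links, degs))
        assert (summary["median_log2fc"].abs() < 0.1).all()


class TestQuadrantTable:
    def test_single_pair_count(self):
        links = [_link("g1", "upstream", "M+")]
        degs = {"g1": _deg("g1", -2.0, "other_down")}
        table = quadrant_table(links, degs)
        cell = table.set_index(["context", "region_class",
                               "expr_direction", "meth_direction"])["count"]
        assert cell[("CG", "upstream", "E-", "M+")] == 1
        assert cell.sum() == 1

    def test_duplicate_links_deduplicated(self):
        link = _link("g1", "upstream", "M+")
        degs = {"g1": _deg("g1", -2.0, "special_down")}
        table = quadrant_table([link, link], degs)
        assert table["count"].sum() == 1

    def test_counts_conserved_over_deg_linked_pairs(self):
        rng = np.random.default_rng(9)
        classes = ["special_up", "special_down", "other_up", "other_down", "none"]
        links, degs = [], {}
        for i in range(200):
            gene = f"g{i}"
            cls = classes[rng.integers(0, 5)]
            degs[gene] = _deg(gene, float(rng.normal()), cls)
            links.append(_link(gene, ["upstream", "genebody", "downstream"][i % 3],
                               "M+" if rng.random() < 0.5 else "M-",
                               start=1000 * i))
        table = quadrant_table(links, degs)
        expected = sum(degs[l.gene_id].direction_class != "none" for l in links)
        assert table["count"].sum() == expected

    def test_gene_without_deg_status_excluded(self):
        links = [_link("g1", "genebody")]
        assert quadrant_table(links, {"g1": _deg("g1", 0.1, "none")})["count"].sum() == 0


class TestHypergeometricEnrichment:
    def test_worked_tail_value(self):
        # N=20, K=5, n=5, k=3
        assert hypergeom_pvalue(3, 5, 5, 20) == pytest.approx(1126 / 15504, rel=1e-12)

    def test_certain_event_and_degenerate_study(self):
        assert hypergeom_pvalue(0, 5, 5, 20) == pytest.approx(1.0)
        background = [f"g{i}" for i in range(10)]
        sets = [GeneSet("S", "all ten", tuple(background))]
        (res,) = hypergeometric_enrichment(background, sets, background)
        assert res.k == res.K and res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            N = int(rng.integers(2, 30))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_pvalue(k, K, n, N) == pytest.approx(
                hypergeom_tail_oracle(k, K, n, N), rel=1e-10)

    def test_sets_intersected_with_background(self):
        background = ["g1", "g2", "g3", "g4"]
        sets = [GeneSet("S1", "x", ("g1", "g2", "offworld")),
                GeneSet("S2", "y", ("nope",))]
        results = hypergeometric_enrichment(["g1", "g2"], sets, background)
        assert [r.set_id for r in results] == ["S1"]  # S2 empty after intersection
        assert results[0].K == 2 and results[0].k == 2
        assert results[0].fold == pytest.approx((2 / 2) / (2 / 4))

    def test_empty_study_is_error(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], [GeneSet("S", "x", ("g1",))], ["g1"])

    def test_bh_q_values_monotone(self):
        rng = np.random.default_rng(8)
        background = [f"g{i}" for i in range(100)]
        study = background[:20]
        sets = [GeneSet(f"S{j}", "x",
                        tuple(rng.choice(background, size=10, replace=False)))
                for j in range(15)]
        results = hypergeometric_enrichment(study, sets, background, method="BH")
        qs = [r.q_value for r in results]
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in results)
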