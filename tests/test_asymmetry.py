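import numpy as np
import pytest
from scipy import stats

import gdttc
from gdttc.network import CorrelationRecord, EdgeSet

from oracles import enumerate_gene_modules, exact_binomial_upper_tail


def _edge(ga, gb, ta="A", tb="B"):
    return CorrelationRecord(
        gene_a=ga, tissue_a=ta, gene_b=gb, tissue_b=tb, n=50,
        r_orig=0.6, t_orig=5.0, p_orig=1e-5,
        r_decor=0.5, t_decor=4.0, p_decor=1e-4, is_edge=True,
    )


def _toy_edgeset(back_degree=2, m=30):
    """Gene g in A correlates with m genes in B; each member has
    ``back_degree`` total edges into A (one of them is g itself)."""
    records = [_edge("g", f"b{i}") for i in range(m)]
    for extra in range(back_degree - 1):
        records += [_edge(f"hub{extra}", f"b{i}") for i in range(m)]
    genes_a = tuple({r.gene_a for r in records}) + tuple(f"idle{i}" for i in range(200))
    genes_b = tuple(f"b{i}" for i in range(m))
    return EdgeSet("A", "B", records, genes_a=genes_a, genes_b=genes_b)


class TestDetectGeneToModule:
    def test_hand_built_asymmetric_module_detected(self):
        edges = _toy_edgeset(back_degree=2)
        mods = gdttc.detect_gene_to_module(edges, "A", "B")
        by_source = {m.source_gene: m for m in mods}
        assert "g" in by_source  # (the auxiliary hub qualifies symmetrically)
        mod = by_source["g"]
        assert mod.m == 30 and mod.am == pytest.approx(2.0)
        assert mod.passes_check1 and mod.passes_check2
        assert mod.reverse_size is None  # g absent from tissue B

    def test_boundary_back_degree_rejected_strictly(self):
        # AM = 3 is NOT < 30/10 = 3 -> rejected
        edges = _toy_edgeset(back_degree=3)
        mods = gdttc.detect_gene_to_module(edges, "A", "B")
        assert mods == []
        allm = gdttc.detect_gene_to_module(edges, "A", "B", return_all=True)
        g = [m for m in allm if m.source_gene == "g"][0]
        assert g.am == pytest.approx(3.0) and not g.passes_check1

    def test_reverse_module_check_blocks_bidirectional_hub(self):
        edges = _toy_edgeset(back_degree=2)
        # add the source gene id to tissue B with a large reverse module
        extra = [_edge(f"x{i}", "g") for i in range(10)]
        edges = EdgeSet(
            "A", "B", edges.records + extra,
            genes_a=edges.genes_a + tuple(f"x{i}" for i in range(10)),
            genes_b=edges.genes_b + ("g",),
        )
        mods = gdttc.detect_gene_to_module(edges, "A", "B", return_all=True)
        g = [m for m in mods if m.source_gene == "g"][0]
        assert g.reverse_size == 10
        assert not g.passes_check2

    def test_invariant_to_record_ordering(self, rng):
        edges = _toy_edgeset()
        shuffled = list(edges.records)
        rng.shuffle(shuffled)
        a = gdttc.detect_gene_to_module(edges, "A", "B")
        b = gdttc.detect_gene_to_module(
            EdgeSet("A", "B", shuffled, genes_a=edges.genes_a, genes_b=edges.genes_b),
            "A", "B",
        )
        assert [(m.source_gene, m.members) for m in a] == [
            (m.source_gene, m.members) for m in b
        ]

    def test_unknown_direction_rejected(self):
        with pytest.raises(gdttc.ValidationError, match="direction"):
            gdttc.detect_gene_to_module(_toy_edgeset(), "A", "C")

    def test_matches_literal_set_enumeration_on_random_graphs(self):
        """Adjacency-based detector == brute-force enumeration oracle."""
        rng = np.random.default_rng(17)
        for trial in range(5):
            na, nb = 150, 200
            genes_a = tuple(f"a{i}" for i in range(na))
            genes_b = tuple(f"b{i}" for i in range(nb))
            mask = rng.random((na, nb)) < 0.02
            # plant a couple of hub sources
            mask[0, :40] = True
            mask[1, 60:75] = True
            records = [
                _edge(genes_a[i], genes_b[j]) for i, j in zip(*np.nonzero(mask))
            ]
            edges = EdgeSet("A", "B", records, genes_a=genes_a, genes_b=genes_b)
            mods = gdttc.detect_gene_to_module(edges, "A", "B")
            expected = enumerate_gene_modules(edges, "A", "B")
            assert {m.source_gene: list(m.members) for m in mods} == expected


class TestModuleSizePvalue:
    def test_zero_size_covers_whole_sample_space(self):
        assert gdttc.module_size_pvalue(0, 5.0, 1000) == 1.0

    def test_exact_tail_matches_rational_oracle(self):
        p = gdttc.module_size_pvalue(30, 5.0, 1000)
        oracle = exact_binomial_upper_tail(30, 1000, 5.0 / 1000)
        assert p == pytest.approx(oracle, rel=1e-12)

    def test_monotone_nonincreasing_in_m(self):
        ps = [gdttc.module_size_pvalue(m, 5.0, 1000) for m in range(0, 51)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_oversized_module_rejected(self):
        with pytest.raises(ValueError):
            gdttc.module_size_pvalue(1001, 5.0, 1000)

    def test_superuniform_under_random_bipartite_null(self):
        """On Erdos-Renyi bipartite graphs, P(p < alpha) <= alpha + 3 SD."""
        rng = np.random.default_rng(23)
        alpha = 0.05
        hits = total = 0
        for _ in range(60):
            na, nb, dens = 80, 120, 0.12  # mean degree ~ 14
            mask = rng.random((na, nb)) < dens
            records = [
                _edge(f"a{i}", f"b{j}") for i, j in zip(*np.nonzero(mask))
            ]
            edges = EdgeSet(
                "A", "B", records,
                genes_a=tuple(f"a{i}" for i in range(na)),
                genes_b=tuple(f"b{j}" for j in range(nb)),
            )
            mods = gdttc.detect_gene_to_module(edges, "A", "B", return_all=True)
            for m in mods:
                total += 1
                hits += m.p_binomial < alpha
        assert total > 100
        bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / total)
        assert hits / total <= bound


class TestBipartiteSvdClusters:
    def test_two_planted_blocks_recovered(self):
        records = [_edge(f"a{i}", f"b{j}") for i in range(10) for j in range(10)]
        records += [_edge(f"c{i}", f"d{j}") for i in range(10) for j in range(10)]
        edges = EdgeSet("A", "B", records)
        out = gdttc.bipartite_svd_clusters(edges, 2, seed=0)
        a_cl = {out.row_labels[f"a{i}"] for i in range(10)}
        c_cl = {out.row_labels[f"c{i}"] for i in range(10)}
        assert len(a_cl) == 1 and len(c_cl) == 1 and a_cl != c_cl
        assert {out.column_labels[f"b{i}"] for i in range(10)} == a_cl
        assert {out.column_labels[f"d{i}"] for i in range(10)} == c_cl

    def test_k_one_puts_everything_together(self):
        edges = EdgeSet("A", "B", [_edge("a0", "b0"), _edge("a1", "b1")])
        out = gdttc.bipartite_svd_clusters(edges, 1)
        assert set(out.row_labels.values()) == {0}
        assert set(out.column_labels.values()) == {0}

    def test_k_larger_than_side_rejected(self):
        edges = EdgeSet("A", "B", [_edge("a0", "b0"), _edge("a1", "b1")])
        with pytest.raises(ValueError):
            gdttc.bipartite_svd_clusters(edges, 3)


class TestSourceNodeComposition:
    def test_reporting_percentages(self):
        out = gdttc.source_node_composition(345, 617, 20110, 53934)
        assert out["pct_coding_sources"] == 56
        assert out["pct_coding_expected"] == 37
        assert out["p_enrichment"] < 1e-15
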