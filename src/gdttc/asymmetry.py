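"""Asymmetric gene-to-module detection on a bipartite edge set.

The object of interest is a *source node*: a gene i in tissue A whose
cross-tissue neighborhood M (its module, the tissue-B genes correlated with
it) is large, while the module members' own back-degrees into tissue A are
small.  Two checks formalize "asymmetric":

check 1
    AM < m / 10 (strict), where m = |M| and AM is the average, over members
    J of M, of the number of tissue-A genes correlated with J (the average
    back-degree; the edge back to i itself counts).
check 2
    The same gene id measured in tissue B must not itself anchor a large
    reverse module: its module size toward A must be < m / 10 (vacuously
    true when the gene is absent from tissue B).  This guards against
    modules explained by common regulation within a single tissue.

Module-size significance is a binomial null: if genes in tissue A are
correlated with mean_degree tissue-B genes on average, the size of a random
module is Binomial(n_B, mean_degree / n_B), and p = P(X >= m) by exact tail
summation.

A spectral (SVD) bipartite co-clustering is included purely as a comparator;
it looks for *balanced* two-sided clusters and is typically uninformative for
the unidirectional patterns the detector above targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .containers import ValidationError
from .network import EdgeSet


@dataclass
class GeneModule:
    source_gene: str
    source_tissue: str
    target_tissue: str
    members: tuple[str, ...]
    m: int
    am: float
    reverse_size: int | None
    p_binomial: float
    passes_check1: bool
    passes_check2: bool

    def to_dict(self) -> dict:
        return {
            "source": self.source_gene,
            "source_tissue": self.source_tissue,
            "target_tissue": self.target_tissue,
            "members": list(self.members),
            "m": self.m,
            "am": self.am,
            "reverse_size": self.reverse_size,
            "p_binomial": self.p_binomial,
            "passes_check1": self.passes_check1,
            "passes_check2": self.passes_check2,
        }


def module_size_pvalue(m: int, mean_degree: float, n_target_genes: int) -> float:
    """P(X >= m) for X ~ Binomial(n_target_genes, mean_degree / n_target_genes).

    Exact tail summation of the probability mass function.
    """
    if n_target_genes <= 0:
        raise ValueError("n_target_genes must be positive")
    if not (0.0 < mean_degree < n_target_genes):
        raise ValueError(
            f"mean_degree must lie in (0, n_target_genes), got {mean_degree}"
        )
    if m > n_target_genes:
        raise ValueError(f"module size {m} exceeds target-gene count {n_target_genes}")
    if m <= 0:
        return 1.0
    q = mean_degree / n_target_genes
    ks = np.arange(m, n_target_genes + 1)
    p = float(np.sum(stats.binom.pmf(ks, n_target_genes, q)))
    return float(min(max(p, 5e-324), 1.0))


def _adjacency(edges: EdgeSet, source_tissue: str, target_tissue: str):
    if {source_tissue, target_tissue} != {edges.tissue_a, edges.tissue_b}:
        raise ValidationError(
            f"unknown direction {source_tissue!r}->{target_tissue!r} for edge set "
            f"({edges.tissue_a!r}, {edges.tissue_b!r})"
        )
    fwd: dict[str, set[str]] = {}
    back: dict[str, set[str]] = {}
    for rec in edges.records:
        if rec.tissue_a == source_tissue:
            s, t = rec.gene_a, rec.gene_b
        else:
            s, t = rec.gene_b, rec.gene_a
        fwd.setdefault(s, set()).add(t)
        back.setdefault(t, set()).add(s)
    return fwd, back


def detect_gene_to_module(
    edges: EdgeSet,
    source_tissue: str,
    target_tissue: str,
    min_size: int = 10,
    ratio: float = 0.1,
    check2_mode: str = "reverse_module",
    within_degree: Mapping[str, int] | None = None,
    return_all: bool = False,
) -> list[GeneModule]:
    """Find asymmetric gene-to-module relationships in one direction.

    Returns modules with m >= min_size passing both checks (or every
    candidate when ``return_all``), sorted by binomial p ascending, ties
    broken by m descending then source gene lexicographic.  The binomial
    null's mean degree is averaged over *all* source-tissue genes tested,
    including degree-zero ones.

    ``check2_mode='within_degree'`` replaces the reverse-module check with a
    caller-supplied within-target-tissue degree for the source gene id
    (within-tissue correlations are outside this package's scope).
    """
    if check2_mode not in ("reverse_module", "within_degree"):
        raise ValueError(f"unknown check2_mode {check2_mode!r}")
    if check2_mode == "within_degree" and within_degree is None:
        raise ValueError("check2_mode='within_degree' requires a within_degree table")
    fwd, back = _adjacency(edges, source_tissue, target_tissue)
    if source_tissue == edges.tissue_a:
        n_source, n_target = edges.n_genes_a, edges.n_genes_b
        target_universe = edges.genes_b
    else:
        n_source, n_target = edges.n_genes_b, edges.n_genes_a
        target_universe = edges.genes_a
    target_universe = set(target_universe) if target_universe is not None else None
    n_source = n_source or len(fwd)
    n_target = n_target or len(back)
    n_edges = sum(len(v) for v in fwd.values())
    mean_degree = n_edges / n_source if n_source else 0.0

    out: list[GeneModule] = []
    for gene in sorted(fwd):
        members = fwd[gene]
        m = len(members)
        if m < min_size:
            continue
        am = sum(len(back[j]) for j in members) / m
        check1 = am < ratio * m
        if check2_mode == "reverse_module":
            # module of the same gene id measured from tissue B toward A;
            # vacuous when the gene is absent from the target tissue
            present_in_target = (
                gene in target_universe if target_universe is not None else gene in back
            )
            reverse_size = len(back.get(gene, ())) if present_in_target else None
            check2 = True if reverse_size is None else reverse_size < ratio * m
        else:
            deg = within_degree.get(gene)
            reverse_size = deg
            check2 = True if deg is None else deg < ratio * m
        p = module_size_pvalue(m, mean_degree, n_target) if mean_degree > 0 else 1.0
        mod = GeneModule(
            source_gene=gene,
            source_tissue=source_tissue,
            target_tissue=target_tissue,
            members=tuple(sorted(members)),
            m=m,
            am=am,
            reverse_size=reverse_size,
            p_binomial=p,
            passes_check1=check1,
            passes_check2=check2,
        )
        if return_all or (check1 and check2):
            out.append(mod)
    out.sort(key=lambda md: (md.p_binomial, -md.m, md.source_gene))
    return out


@dataclass
class BipartiteClusters:
    row_labels: dict[str, int]
    column_labels: dict[str, int]
    k: int


def bipartite_svd_clusters(edges: EdgeSet, k: int, seed: int = 0) -> BipartiteClusters:
    """Spectral co-clustering of the bipartite adjacency (comparator method).

    Normalizes the adjacency, embeds both sides with the top singular
    vectors, and k-means the stacked embeddings into k balanced co-clusters
    (Dhillon's algorithm, via scikit-learn).  Provided for completeness: on
    unidirectional structures it is typically uninformative.
    """
    if not edges.records:
        raise ValidationError("cannot cluster an empty edge set")
    rows = sorted({r.gene_a for r in edges.records})
    cols = sorted({r.gene_b for r in edges.records})
    if k > min(len(rows), len(cols)):
        raise ValueError(
            f"k={k} exceeds smaller side size {min(len(rows), len(cols))}"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return BipartiteClusters({g: 0 for g in rows}, {g: 0 for g in cols}, 1)
    A = np.zeros((len(rows), len(cols)))
    ri = {g: i for i, g in enumerate(rows)}
    ci = {g: i for i, g in enumerate(cols)}
    for rec in edges.records:
        A[ri[rec.gene_a], ci[rec.gene_b]] = 1.0
    from sklearn.cluster import SpectralCoclustering

    model = SpectralCoclustering(n_clusters=k, random_state=seed)
    model.fit(A)
    return BipartiteClusters(
        row_labels={g: int(model.row_labels_[i]) for g, i in ri.items()},
        column_labels={g: int(model.column_labels_[i]) for g, i in ci.items()},
        k=k,
    )


def source_node_composition(
    n_coding_sources: int,
    n_sources: int,
    n_coding_universe: int,
    n_universe: int,
) -> dict:
    """Summarize the gene-type composition of source nodes.

    Reports the percentage of source nodes that are protein coding, the
    percentage expected from the annotation universe (both rounded to whole
    percent, as printed in summary figures), and a binomial enrichment
    p-value for the excess.
    """
    if not (0 < n_sources and 0 < n_universe):
        raise ValueError("counts must be positive")
    if n_coding_sources > n_sources or n_coding_universe > n_universe:
        raise ValueError("coding counts cannot exceed totals")
    frac_expected = n_coding_universe / n_universe
    p_enrich = float(stats.binom.sf(n_coding_sources - 1, n_sources, frac_expected))
    return {
        "pct_coding_sources": round(100.0 * n_coding_sources / n_sources),
        "pct_coding_expected": round(100.0 * frac_expected),
        "n_sources": n_sources,
        "n_coding_sources": n_coding_sources,
        "p_enrichment": p_enrich,
    }
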