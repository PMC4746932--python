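"""Hypergeometric gene-set enrichment with ontology-level filtering.

For a module of size n drawn from a universe of size N, the overlap k with a
gene set of size K follows a hypergeometric distribution under the null; the
enrichment p-value is the one-sided upper tail P(X >= k).  Significance is
Bonferroni-controlled at alpha divided by the number of sets *actually
tested* (after level filtering and intersection with the universe), not the
full collection size.

Ontology terms live at different depths of the is_a hierarchy and are not
comparable across depths, so testing can be restricted to terms at a fixed
"level": the number of terms on the shortest is_a path from the namespace
root, inclusive of both ends (the root itself is level 1).  Terms reachable
at multiple depths take the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
from scipy import stats

from .containers import GeneSetCollection, ValidationError


def ontology_levels(graph: nx.DiGraph) -> dict[str, int]:
    """Depth of every term: shortest is_a path from its namespace root.

    ``graph`` has child -> parent is_a edges (as produced by
    :func:`gdttc.io_formats.read_obo`).  Roots are the terms with no parent
    within their namespace and get level 1.  Terms unreachable from any root
    of their namespace are excluded from the mapping.
    """
    levels: dict[str, int] = {}
    namespaces: dict[str, str] = {
        n: data.get("namespace", "") for n, data in graph.nodes(data=True)
    }
    roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
    reversed_graph = graph.reverse(copy=False)
    for root in roots:
        ns = namespaces.get(root, "")
        dist = nx.single_source_shortest_path_length(reversed_graph, root)
        for term, d in dist.items():
            if namespaces.get(term, "") != ns:
                continue
            lvl = d + 1
            if term not in levels or lvl < levels[term]:
                levels[term] = lvl
    return levels


@dataclass
class EnrichmentResult:
    set_name: str
    level: int | None
    overlap: int
    set_size: int
    module_size: int
    universe_size: int
    p: float
    significant: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def hypergeom_pvalue(overlap: int, set_size: int, module_size: int, universe_size: int) -> float:
    """Upper-tail P(X >= overlap), X ~ Hypergeometric(universe, set, module)."""
    if overlap > min(set_size, module_size):
        raise ValueError("overlap exceeds min(set size, module size)")
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, module_size))
    return float(min(max(p, 5e-324), 1.0))


def hypergeom_enrich(
    module: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    level_filter: int | None = None,
    levels: Mapping[str, int] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test a module against every (level-eligible) gene set.

    The module must be a subset of the universe; every set is intersected
    with the universe before testing and sets left empty are not tested (and
    do not count toward the Bonferroni denominator).  With ``level_filter``,
    only sets whose name maps to that ontology level in ``levels`` are
    tested.  Results are sorted by p ascending.
    """
    universe = set(str(g) for g in universe)
    module = set(str(g) for g in module)
    if not universe:
        raise ValidationError("empty universe")
    if not module:
        raise ValidationError("empty module")
    extra = module - universe
    if extra:
        raise ValidationError(f"module genes outside the universe: {sorted(extra)[:5]}")
    if level_filter is not None and levels is None:
        raise ValueError("level_filter requires an ontology level mapping")

    tested: list[tuple[str, int | None, set[str]]] = []
    for gs in sets:
        lvl = levels.get(gs.name) if levels is not None else None
        if level_filter is not None and lvl != level_filter:
            continue
        members = set(gs.genes) & universe
        if not members:
            continue
        tested.append((gs.name, lvl, members))

    n_tested = len(tested)
    cutoff = alpha / n_tested if n_tested else float("nan")
    results = []
    for name, lvl, members in tested:
        k = len(module & members)
        p = hypergeom_pvalue(k, len(members), len(module), len(universe))
        results.append(
            EnrichmentResult(
                set_name=name,
                level=lvl,
                overlap=k,
                set_size=len(members),
                module_size=len(module),
                universe_size=len(universe),
                p=p,
                significant=p < cutoff,
            )
        )
    results.sort(key=lambda r: (r.p, r.set_name))
    return results
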