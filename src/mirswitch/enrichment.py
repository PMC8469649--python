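"""Ontology over-representation with a DAG-conditioned hypergeometric test.

Terms in an ontology inherit annotations from their descendants (the
true-path rule), so a parent of a genuinely enriched term is often itself
"enriched" purely by inclusion.  The conditional procedure walks the DAG
children-before-parents and, when testing a term, excludes the gene content
of its already-significant children from that term's test, so each term is
asked for evidence beyond what its more specific children already explain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .errors import OntologyStructureError, ValidationError


@dataclass
class OntologyDAG:
    """Terms, child->parent edges and gene annotations.

    ``direct_annotations`` maps a term to the genes annotated to it
    directly; ``propagated_annotations`` is filled by
    :func:`propagate_annotations` with the true-path closure (a term's set
    plus everything below it).
    """

    terms: list[str]
    edges: list[tuple[str, str]]  # (child, parent); multiple parents allowed
    direct_annotations: dict[str, set[str]]
    propagated_annotations: dict[str, set[str]] | None = None

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)
        return g

    def children_of(self, term: str) -> list[str]:
        return [c for c, p in self.edges if p == term]


def propagate_annotations(dag: OntologyDAG) -> OntologyDAG:
    """Apply the true-path rule: each term's set absorbs its children's.

    Terms are processed in topological order (children first), so one pass
    suffices; applying the operation twice changes nothing.
    """
    g = dag.graph()
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        raise OntologyStructureError(f"ontology contains a cycle through edge {cycle[0]}")
    propagated = {t: set(dag.direct_annotations.get(t, set())) for t in dag.terms}
    for term in order:  # children appear before parents along child->parent edges
        for _, parent in g.out_edges(term):
            propagated[parent] |= propagated[term]
    return replace(dag, propagated_annotations=propagated)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValidationError(f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    term: str
    universe_size: int      # N after conditioning
    term_genes_in_universe: int  # K
    selected_size: int      # n
    overlap: int            # k
    p_value: float
    conditioned: bool
    excluded_genes: set[str] = field(default_factory=set)


def conditional_enrichment(dag: OntologyDAG, selected_genes: set[str],
                           universe: set[str],
                           child_alpha: float = 0.01) -> list[EnrichmentResult]:
    """Over-representation of ``selected_genes`` per term, DAG-conditioned.

    Terms are visited children-before-parents.  A term whose children were
    already significant (p <= ``child_alpha``) is tested with those
    children's gene content removed from its own annotation set, from the
    universe and from the selection — for this term's test only.  Results
    for terms with no annotated gene in the universe are omitted.
    """
    if not selected_genes <= universe:
        raise ValidationError("selected genes must be a subset of the universe")
    if dag.propagated_annotations is None:
        dag = propagate_annotations(dag)
    prop = dag.propagated_annotations
    g = dag.graph()
    order = list(nx.topological_sort(g))  # children before parents
    p_of: dict[str, float] = {}
    results: list[EnrichmentResult] = []
    for term in order:
        sig_children = [c for c in g.predecessors(term)
                        if c in p_of and p_of[c] <= child_alpha]
        excluded = set().union(*(prop[c] for c in sig_children)) if sig_children else set()
        uni = universe - excluded
        sel = selected_genes - excluded
        term_genes = (prop[term] - excluded) & uni
        K = len(term_genes)
        if K == 0:
            continue
        N, n = len(uni), len(sel)
        k = len(term_genes & sel)
        p = hypergeom_upper_tail(k, K, n, N)
        p_of[term] = p
        results.append(EnrichmentResult(
            term=term, universe_size=N, term_genes_in_universe=K,
            selected_size=n, overlap=k, p_value=p,
            conditioned=bool(sig_children), excluded_genes=excluded,
        ))
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results (one row per tested term)."""
    return pd.DataFrame(
        [{"term": r.term, "N": r.universe_size, "K": r.term_genes_in_universe,
          "n": r.selected_size, "k": r.overlap, "p": r.p_value,
          "conditioned": r.conditioned, "excluded_count": len(r.excluded_genes)}
         for r in results],
        columns=["term", "N", "K", "n", "k", "p", "conditioned", "excluded_count"],
    )
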