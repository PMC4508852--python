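"""Gene Ontology handling: DAG levels and GO-term assignment to clusters/CDSs.

Term *level* is defined over ``is_a`` edges only: the root terms
(biological_process, molecular_function, ...) sit at level 1 and every other
term sits at 1 + the length of the *longest* ``is_a`` path from any root.
Functional comparisons downstream are restricted to terms at a fixed level
(level 6 by default) in the biological-process or molecular-function
namespaces, which balances specificity against coverage.

GO terms are used exactly as assigned: there is no propagation to ancestors
or descendants, because the shared-term and enrichment statistics count
overlaps between assigned term lists and propagation would inflate them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

BP = "biological_process"
MF = "molecular_function"


class OntologyCycleError(ValueError):
    pass


@dataclass
class Ontology:
    """A GO DAG restricted to is_a edges.

    ``graph`` stores one directed edge child -> parent per is_a relation.
    """

    graph: nx.DiGraph
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    _levels: dict[str, int] | None = field(default=None, repr=False)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    @property
    def levels(self) -> dict[str, int]:
        if self._levels is None:
            self._levels = compute_levels(self)
        return self._levels

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))


def compute_levels(ontology: Ontology) -> dict[str, int]:
    """Longest-path level of every term; roots are level 1.

    Raises :class:`OntologyCycleError` naming a cycle member if the is_a
    graph is not acyclic.
    """
    g = ontology.graph
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyCycleError(
            f"is_a graph contains a cycle through {cycle[0][0]}")
    # walk parents before children: reverse edges so parent -> child
    down = g.reverse(copy=False)
    levels: dict[str, int] = {}
    for term in nx.topological_sort(down):
        preds = list(down.predecessors(term))  # parents of `term`
        levels[term] = 1 if not preds else 1 + max(levels[p] for p in preds)
    return levels


@dataclass
class GOAssignment:
    entity_id: str
    terms: set[str]
    mode: str  # top3_union | most_confident | pfam_union


def assign_cluster_terms(hits, go_map: dict[str, set[str]],
                         mode: str = "top3_union") -> GOAssignment:
    """GO terms for one cluster from its ranked significant remote hits.

    ``top3_union``: union of mapped terms of the three highest-ranked
    significant hits (unmapped hits still consume a slot).
    ``most_confident``: terms of the highest-ranked significant hit that has
    at least one mapped term.
    """
    sig = [h for h in hits if getattr(h, "significant", True)]
    cluster_id = hits[0].cluster_id if hits else ""
    terms: set[str] = set()
    if mode == "top3_union":
        for h in sig[:3]:
            terms |= go_map.get(h.template_id, set())
    elif mode == "most_confident":
        for h in sig:
            mapped = go_map.get(h.template_id, set())
            if mapped:
                terms = set(mapped)
                break
    else:
        raise ValueError(f"unknown assignment mode: {mode!r}")
    return GOAssignment(entity_id=cluster_id, terms=terms, mode=mode)


def assign_pfam_terms(domain_hits, pfam_go_map: dict[str, set[str]],
                      evalue_cutoff: float = 1e-3) -> GOAssignment:
    """Union of GO terms over all significant (E < cutoff) domain matches."""
    entity = domain_hits[0].query_id if domain_hits else ""
    terms: set[str] = set()
    for h in domain_hits:
        if h.evalue < evalue_cutoff:
            terms |= pfam_go_map.get(h.target_id, set())
    return GOAssignment(entity_id=entity, terms=terms, mode="pfam_union")


def filter_level(terms, ontology: Ontology, level: int = 6) -> set[str]:
    """Keep terms whose longest-path level equals ``level`` in BP or MF."""
    levels = ontology.levels
    kept: set[str] = set()
    for t in terms:
        if t not in levels:
            logger.warning("GO term %s absent from ontology; dropped", t)
            continue
        if levels[t] == level and ontology.namespaces.get(t) in (BP, MF):
            kept.add(t)
    return kept
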