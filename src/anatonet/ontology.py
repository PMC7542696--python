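"""Ontology DAG handling: OBO parsing, ancestor closures, information content.

An anatomy ontology (e.g. Uberon) is modelled as a directed acyclic graph of
terms with child->parent edges restricted to the two relations that carry
anatomical subsumption/composition semantics: ``is_a`` and ``part_of``.
Information content (IC) of a term is estimated from an annotation corpus by
ancestor-propagated counting: a gene annotated to a term implicitly supports
every ancestor of that term.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: relations traversed for closure and Wang S-value propagation
KEPT_RELATIONS = ("is_a", "part_of")


class OntologyDAG:
    """A rooted DAG of ontology terms over is_a / part_of edges.

    Parameters
    ----------
    terms : iterable of str
        Non-obsolete term identifiers.
    edges : iterable of (child, parent, relation)
        relation must be one of ``is_a`` / ``part_of``. The child->parent
        graph must be acyclic.
    """

    def __init__(self, terms: Iterable[str], edges: Iterable[tuple[str, str, str]]):
        self.terms = frozenset(terms)
        edges = frozenset(edges)
        for child, parent, rel in edges:
            if rel not in KEPT_RELATIONS:
                raise ValueError(f"unsupported relation {rel!r} on edge {child}->{parent}")
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge {child}->{parent} references unknown term")
        self.edges = edges
        self._parents: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        self._children: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        for child, parent, rel in sorted(edges):
            self._parents[child].append((parent, rel))
            self._children[parent].append((child, rel))
        self._check_acyclic()
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, p, _ in self.edges)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"ontology graph is cyclic: {path}")

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, relation) pairs of ``term``."""
        return list(self._parents[term])

    def children(self, term: str) -> list[tuple[str, str]]:
        """(child, relation) pairs of ``term``."""
        return list(self._children[term])

    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self._parents[t])

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive transitive closure of ``term`` over is_a/part_of.

        The term itself is always included, matching the convention used by
        the MICA-based and Wang similarity measures.
        """
        if term not in self.terms:
            raise KeyError(term)
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        stack = [term]
        while stack:
            t = stack.pop()
            for parent, _ in self._parents[t]:
                if parent not in out:
                    out.add(parent)
                    stack.append(parent)
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result


def parse_obo(path) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyDAG`.

    Obsolete terms are excluded. Relations other than is_a/part_of are
    dropped; the number of dropped edges per relation type is logged.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms = set(graph.nodes())
    edges = set()
    dropped: Counter[str] = Counter()
    for child, parent, rel in graph.edges(keys=True):
        if rel in KEPT_RELATIONS:
            edges.add((child, parent, rel))
        else:
            dropped[rel] += 1
    if dropped:
        summary = ", ".join(f"{rel}: {n}" for rel, n in sorted(dropped.items()))
        logger.info("dropped %d non-is_a/part_of edges (%s)", sum(dropped.values()), summary)
    dag = OntologyDAG(terms, edges)
    dag.dropped_relations = dict(dropped)  # type: ignore[attr-defined]
    return dag


@dataclass(frozen=True)
class InformationContentTable:
    """Per-term annotation probability and information content.

    IC(t) = -ln p(t) with p(t) the fraction of corpus genes whose propagated
    annotation set contains t. Terms never reached by a propagated annotation
    have no defined IC and are listed in ``undefined`` rather than being
    assigned a fabricated value.
    """

    p: Mapping[str, float]
    ic: Mapping[str, float]
    n_genes: int
    undefined: frozenset[str] = field(default_factory=frozenset)

    def defined(self, term: str) -> bool:
        return term in self.ic

    @property
    def max_ic(self) -> float:
        return max(self.ic.values()) if self.ic else 0.0


def compute_ic(dag: OntologyDAG, profiles: Mapping[str, Iterable[str]]) -> InformationContentTable:
    """Information content of every term from an annotation corpus.

    Each gene contributes at most once per term: the gene's annotation set is
    propagated to the ancestor closure before counting, so duplicate or
    redundant (ancestor/descendant) annotations of the same gene do not
    inflate counts.
    """
    genes = [g for g, terms in profiles.items() if terms]
    if not genes:
        raise ValueError("empty annotation corpus: no annotated genes")
    counts: Counter[str] = Counter()
    n_genes = 0
    for gene in genes:
        reached: set[str] = set()
        for term in profiles[gene]:
            if term in dag:
                reached |= dag.ancestors(term)
        if not reached:
            continue
        n_genes += 1
        counts.update(reached)
    if n_genes == 0:
        raise ValueError("no gene annotation maps to a term of the ontology")
    p = {t: counts[t] / n_genes for t in counts}
    ic = {t: -math.log(pt) + 0.0 for t, pt in p.items()}  # +0.0 avoids -0.0 at the root
    undefined = frozenset(dag.terms - counts.keys())
    if undefined:
        logger.info("%d terms have zero propagated annotations (undefined IC)", len(undefined))
    return InformationContentTable(p=p, ic=ic, n_genes=n_genes, undefined=undefined)
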