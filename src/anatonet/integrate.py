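"""Accuracy-weighted integration of a PPI network with a semantic gene network.

Each source network gets a weight proportional to its measured prediction
accuracy:  W1 = AC1 / (AC1 + AC2),  W2 = AC2 / (AC1 + AC2).  The integrated
edge score is the convex combination  sim3 = W1*sim1 + W2*sim2,  with a
missing edge contributing score 0 on its side. Integration operates on the
unfiltered networks; the weights are estimated by evaluating the filtered
versions of each input.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .network import GeneNetwork


@dataclass(frozen=True)
class IntegrationWeights:
    """Accuracies of the two source networks and the derived convex weights."""

    ac_ppi: float
    ac_anatomy: float
    w_ppi: float
    w_anatomy: float


def compute_weights(ac_ppi: float, ac_anatomy: float) -> IntegrationWeights:
    """Weights proportional to each network's accuracy; they sum to 1."""
    if ac_ppi < 0 or ac_anatomy < 0:
        raise ValueError("accuracies must be non-negative")
    total = ac_ppi + ac_anatomy
    if total == 0:
        raise ValueError("at least one accuracy must be positive")
    return IntegrationWeights(ac_ppi=ac_ppi, ac_anatomy=ac_anatomy,
                              w_ppi=ac_ppi / total, w_anatomy=ac_anatomy / total)


def integrate_networks(ppi: GeneNetwork, anatomy: GeneNetwork,
                       weights: IntegrationWeights) -> GeneNetwork:
    """Weighted union of two unfiltered networks on a shared gene-name space.

    The node set is the union of both node sets. Every edge present in either
    network is rescored as W1*sim1 + W2*sim2 (absent side = 0); edges whose
    combined score is 0 are omitted, since a zero score is indistinguishable
    from absence.
    """
    if abs(weights.w_ppi + weights.w_anatomy - 1.0) > 1e-12:
        raise ValueError(f"inconsistent weights: {weights.w_ppi} + {weights.w_anatomy} != 1")
    g = nx.Graph()
    g.add_nodes_from(ppi.graph.nodes())
    g.add_nodes_from(anatomy.graph.nodes())
    for u, v, s1 in ppi.edges():
        s3 = weights.w_ppi * s1 + weights.w_anatomy * anatomy.score(u, v)
        if s3 > 0:
            g.add_edge(u, v, score=s3)
    for u, v, s2 in anatomy.edges():
        if g.has_edge(u, v):
            continue  # already combined from the PPI side
        s3 = weights.w_anatomy * s2  # PPI side absent -> 0
        if s3 > 0:
            g.add_edge(u, v, score=s3)
    return GeneNetwork(graph=g, provenance="integrated")
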