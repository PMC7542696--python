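"""Weighted gene networks: construction, STRING ingestion, filtering, stats.

All networks are simple undirected graphs with an edge ``score`` in [0, 1].
STRING combined scores (0-999 integers) are rescaled by 1/1000. Filtering is
strict (score > cutoff) and drops nodes left isolated.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GeneNetwork:
    """Undirected weighted gene graph.

    ``provenance`` tags the network's origin (ppi / anatomy / integrated /
    randomized); ``cutoff`` records the filtering threshold applied, if any.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    provenance: str = "anatomy"
    cutoff: float | None = None

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]], provenance: str = "anatomy",
                   cutoff: float | None = None) -> "GeneNetwork":
        g = nx.Graph()
        for u, v, score in edges:
            if u == v:
                continue
            if g.has_edge(u, v):
                g[u][v]["score"] = max(g[u][v]["score"], score)
            else:
                g.add_edge(u, v, score=float(score))
        return cls(graph=g, provenance=provenance, cutoff=cutoff)

    @classmethod
    def from_similarity_matrix(cls, matrix: pd.DataFrame, provenance: str = "anatomy") -> "GeneNetwork":
        """Unfiltered network from a symmetric gene similarity matrix.

        Zero-score pairs are omitted (a zero score is indistinguishable from
        absence under the integration zero-fill rule); the diagonal is never
        an edge.
        """
        genes = list(matrix.index)
        values = matrix.to_numpy()
        g = nx.Graph()
        g.add_nodes_from(genes)
        iu, ju = np.triu_indices(len(genes), k=1)
        for i, j in zip(iu, ju):
            s = values[i, j]
            if s > 0:
                g.add_edge(genes[i], genes[j], score=float(s))
        return cls(graph=g, provenance=provenance)

    # ---- views -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes())

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, data in self.graph.edges(data=True):
            yield u, v, data["score"]

    def scores(self) -> np.ndarray:
        return np.array([d["score"] for _, _, d in self.graph.edges(data=True)])

    def score(self, u: str, v: str, default: float = 0.0) -> float:
        data = self.graph.get_edge_data(u, v)
        return data["score"] if data else default

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(graph=self.graph.copy(), provenance=self.provenance, cutoff=self.cutoff)


def read_id_mapping(path) -> dict[str, str]:
    """Two-column TSV ``external_id<TAB>gene_name`` -> dict."""
    out: dict[str, str] = {}
    with _open(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                continue
            out[fields[0]] = fields[1]
    return out


def read_string_links(path, id_map: Mapping[str, str] | None = None) -> GeneNetwork:
    """Read a STRING-style ``protein.links`` edge list into a PPI network.

    Expects whitespace-separated columns ``protein1 protein2 combined_score``
    (header allowed) with integer scores on the 0-999 scale; scores are
    divided by 1000. Protein IDs are mapped to gene names via ``id_map``;
    unmapped IDs are retained under the raw ID and counted. Duplicate A-B/B-A
    rows collapse to one edge; conflicting scores keep the max with a warning.
    """
    id_map = id_map or {}
    g = nx.Graph()
    unmapped: set[str] = set()
    n_conflicts = n_malformed = 0
    with _open(path, "rt") as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if fields[0] in ("protein1", "#protein1"):
                continue
            if len(fields) < 3:
                n_malformed += 1
                logger.warning("skipping malformed STRING row: %r", line.rstrip())
                continue
            raw1, raw2, raw_score = fields[0], fields[1], fields[-1]
            try:
                score = int(raw_score) / 1000.0
            except ValueError:
                n_malformed += 1
                logger.warning("skipping malformed STRING row: %r", line.rstrip())
                continue
            u = id_map.get(raw1)
            if u is None:
                u = raw1
                if id_map:
                    unmapped.add(raw1)
            v = id_map.get(raw2)
            if v is None:
                v = raw2
                if id_map:
                    unmapped.add(raw2)
            if u == v:
                continue
            if g.has_edge(u, v):
                old = g[u][v]["score"]
                if old != score:
                    n_conflicts += 1
                    g[u][v]["score"] = max(old, score)
            else:
                g.add_edge(u, v, score=score)
    if unmapped:
        logger.warning("%d STRING IDs had no gene-name mapping; kept raw", len(unmapped))
    if n_conflicts:
        warnings.warn(f"{n_conflicts} duplicate edges with conflicting scores; kept max")
    net = GeneNetwork(graph=g, provenance="ppi")
    net.unmapped_ids = frozenset(unmapped)  # type: ignore[attr-defined]
    return net


def filter_network(net: GeneNetwork, cutoff: float) -> GeneNetwork:
    """Keep edges with score strictly above ``cutoff``; drop isolated nodes."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    g = nx.Graph()
    for u, v, data in net.graph.edges(data=True):
        if data["score"] > cutoff:
            g.add_edge(u, v, score=data["score"])
    return GeneNetwork(graph=g, provenance=net.provenance, cutoff=cutoff)


def score_histogram(net: GeneNetwork, bins: int = 10) -> pd.DataFrame:
    """Histogram of edge scores over [0, 1]: right-open bins, last bin closed."""
    counts, edges = np.histogram(net.scores() if net.n_edges else np.array([]),
                                 bins=bins, range=(0.0, 1.0))
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def select_cutoff(net: GeneNetwork, target_interactions: tuple[int, int]) -> float:
    """Cutoff whose strictly-surviving edge count falls in a target band.

    The surviving count is non-increasing in the cutoff, so a binary search
    over the sorted unique edge scores finds the band. When score ties
    straddle the band entirely (no achievable count lies inside), the
    cutoff whose count is nearest to the band is returned with a warning.
    """
    lo, hi = target_interactions
    scores = np.sort(net.scores())
    n = scores.size
    if not lo < hi <= n:
        raise ValueError(f"invalid band {target_interactions} for {n} edges")
    uniq = np.unique(scores)
    # candidate cutoffs: 0 and each unique score; count(c) = #scores strictly > c
    candidates = np.concatenate(([0.0], uniq))
    counts = n - np.searchsorted(scores, candidates, side="right")
    left, right = 0, len(candidates) - 1
    while left < right:  # smallest candidate index with count <= hi
        mid = (left + right) // 2
        if counts[mid] <= hi:
            right = mid
        else:
            left = mid + 1
    if lo <= counts[left] <= hi:
        return float(candidates[left])
    dist = np.where(counts > hi, counts - hi, np.where(counts < lo, lo - counts, 0))
    best = int(np.argmin(dist))
    warnings.warn(
        f"no cutoff yields a count in {target_interactions}; returning cutoff "
        f"{candidates[best]} with {counts[best]} edges")
    return float(candidates[best])


def degree_table(net: GeneNetwork) -> pd.DataFrame:
    """Per-gene degree of the given network view."""
    rows = sorted(net.graph.degree())
    return pd.DataFrame(rows, columns=["gene", "degree"])


def write_network(net: GeneNetwork, path) -> None:
    """TSV edge list ``gene1<TAB>gene2<TAB>score``; scores round-trip bit-exactly."""
    rows = sorted((min(u, v), max(u, v), score) for u, v, score in net.edges())
    with _open(path, "wt") as fh:
        for u, v, score in rows:
            fh.write(f"{u}\t{v}\t{score!r}\n")


def read_network(path, provenance: str = "anatomy", cutoff: float | None = None) -> GeneNetwork:
    g = nx.Graph()
    with _open(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            u, v, score = line.split("\t")
            g.add_edge(u, v, score=float(score))
    return GeneNetwork(graph=g, provenance=provenance, cutoff=cutoff)


def _open(path, mode):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)
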