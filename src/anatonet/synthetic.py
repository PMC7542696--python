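"""Synthetic fixtures and randomization controls.

The synthetic world emulates the real study inputs at desk scale: a small
anatomy-like ontology (a root with one subtree per gene module, each subtree a
balanced tree of is_a/part_of edges), modular annotation profiles (genes of
module k annotated to terms of subtree k), and a noisy STRING-style PPI
network with dense within-module edges (probability ``p_in``, thinned by a
false-negative rate ``q``) and sparse cross-module false positives
(probability ``p_out``). Edge confidences are integers on the 0-999 STRING
scale spanning the 0.7 cutoff so filtering is exercised.

Randomization controls mirror the two null models used for validation: a
fully randomized network (uniform simple graph with the same node and edge
counts, scores 1) and randomized profiles (each gene keeps its annotation
count, terms resampled uniformly from the observed entity vocabulary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .gene_similarity import AnnotationProfiles
from .network import GeneNetwork
from .ontology import OntologyDAG


@dataclass
class WorldConfig:
    """Generator parameters; the defaults are the package's study conditions."""

    depth: int = 2
    branching: int = 2
    n_modules: int = 5
    genes_per_module: int = 30
    annotations_per_gene: int = 4
    p_in: float = 0.35
    p_out: float = 0.02
    q: float = 0.10           # false-negative deletion rate on within-module edges
    part_of_fraction: float = 0.20
    score_low: int = 401      # STRING-style integer confidences, inclusive
    score_high: int = 999
    seed: int = 0


@dataclass
class SyntheticWorld:
    """Ground-truth fixture: ontology + profiles + PPI with planted modules."""

    dag: OntologyDAG
    profiles: AnnotationProfiles
    ppi: GeneNetwork
    modules: dict = field(default_factory=dict)          # gene -> module index
    module_terms: dict = field(default_factory=dict)     # module index -> term list
    config: WorldConfig = field(default_factory=WorldConfig)

    def write(self, outdir) -> dict[str, Path]:
        """Write OBO, profiles TSV, STRING-style links and an ID map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "obo": outdir / "ontology.obo",
            "profiles": outdir / "profiles.tsv",
            "links": outdir / "protein.links.txt",
            "id_map": outdir / "id_map.tsv",
        }
        write_obo(self.dag, paths["obo"])
        self.profiles.write_tsv(paths["profiles"])
        id_of = {g: f"org.{g}" for g in sorted(self.ppi.nodes())}
        rows = sorted((min(u, v), max(u, v), s) for u, v, s in self.ppi.edges())
        with open(paths["links"], "w") as fh:
            fh.write("protein1 protein2 combined_score\n")
            for u, v, s in rows:
                fh.write(f"{id_of[u]} {id_of[v]} {round(s * 1000)}\n")
        with open(paths["id_map"], "w") as fh:
            for g, pid in sorted(id_of.items()):
                fh.write(f"{pid}\t{g}\n")
        return paths


def write_obo(dag: OntologyDAG, path) -> None:
    """Minimal OBO 1.2 serialization of a DAG (is_a / relationship: part_of)."""
    parents = {t: sorted(dag.parents(t)) for t in dag.terms}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-anatomy\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            for parent, rel in parents[term]:
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")


def make_world(config: WorldConfig | None = None, **overrides) -> SyntheticWorld:
    """Generate a reproducible planted-module world from a config and seed."""
    if config is None:
        config = WorldConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)

    # ontology: root + one balanced subtree per module
    root = "T:0000000"
    terms = [root]
    edges = set()
    module_terms: dict[int, list[str]] = {}
    counter = 1
    for m in range(config.n_modules):
        sub_root = f"T:{counter:07d}"
        counter += 1
        terms.append(sub_root)
        edges.add((sub_root, root, "is_a"))
        level = [sub_root]
        subtree = [sub_root]
        for _ in range(config.depth):
            nxt = []
            for parent in level:
                for _ in range(config.branching):
                    child = f"T:{counter:07d}"
                    counter += 1
                    rel = "part_of" if rng.random() < config.part_of_fraction else "is_a"
                    terms.append(child)
                    edges.add((child, parent, rel))
                    nxt.append(child)
            level = nxt
            subtree.extend(level)
        module_terms[m] = subtree
    dag = OntologyDAG(terms, edges)

    # profiles: module genes annotated within their module subtree
    profiles: dict[str, list[str]] = {}
    modules: dict[str, int] = {}
    for m in range(config.n_modules):
        pool = module_terms[m]
        k = min(config.annotations_per_gene, len(pool))
        for i in range(config.genes_per_module):
            gene = f"g{m:02d}_{i:03d}"
            modules[gene] = m
            picks = rng.choice(len(pool), size=k, replace=False)
            profiles[gene] = [pool[j] for j in sorted(picks)]

    # PPI: planted modules plus cross-module noise, STRING-style confidences
    genes = sorted(modules)
    g = nx.Graph()
    g.add_nodes_from(genes)
    p_in_eff = config.p_in * (1.0 - config.q)
    for i, u in enumerate(genes):
        for v in genes[i + 1:]:
            p = p_in_eff if modules[u] == modules[v] else config.p_out
            if rng.random() < p:
                conf = int(rng.integers(config.score_low, config.score_high + 1))
                g.add_edge(u, v, score=conf / 1000.0)
    ppi = GeneNetwork(graph=g, provenance="ppi")
    return SyntheticWorld(dag=dag, profiles=AnnotationProfiles(profiles), ppi=ppi,
                          modules=modules, module_terms=module_terms, config=config)


def fully_randomize(net: GeneNetwork, seed: int) -> GeneNetwork:
    """Uniform simple graph G(n, m) on the same node set, all scores 1."""
    nodes = sorted(net.nodes())
    n, m = len(nodes), net.n_edges
    if m > n * (n - 1) // 2:
        raise ValueError(f"{m} edges exceed the {n}-node simple-graph maximum")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < m:  # rejection sampling of distinct unordered pairs
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        pair = (min(i, j), max(i, j))
        if pair not in chosen:
            chosen.add(pair)
            g.add_edge(nodes[pair[0]], nodes[pair[1]], score=1.0)
    return GeneNetwork(graph=g, provenance="randomized")


def randomize_profiles(profiles: AnnotationProfiles, seed: int,
                       vocabulary=None) -> AnnotationProfiles:
    """Reassign each gene's annotations uniformly at random.

    Per-gene annotation counts are preserved exactly; terms are drawn without
    replacement from the entity vocabulary observed in the input profiles
    (or a supplied vocabulary).
    """
    vocab = sorted(vocabulary if vocabulary is not None else profiles.vocabulary())
    rng = np.random.default_rng(seed)
    out = {}
    for gene in profiles.genes:
        k = len(profiles[gene])
        if k > len(vocab):
            raise ValueError(f"gene {gene} has more annotations ({k}) than the vocabulary")
        picks = rng.choice(len(vocab), size=k, replace=False)
        out[gene] = [vocab[i] for i in sorted(picks)]
    return AnnotationProfiles(out)


def holdout_entities(profiles: AnnotationProfiles, k: int = 30, min_genes: int = 10,
                     seed: int = 0) -> tuple[AnnotationProfiles, list[str]]:
    """Remove k randomly chosen entities with >= min_genes annotations.

    Returns the training profiles (held-out entities removed from every gene;
    genes emptied by the removal are dropped) and the held-out entity list,
    to be used for evaluation only.
    """
    counts = profiles.entity_counts()
    eligible = sorted(t for t, c in counts.items() if c >= min_genes)
    if len(eligible) < k:
        raise ValueError(f"only {len(eligible)} entities have >= {min_genes} annotations; "
                         f"cannot hold out {k}")
    rng = np.random.default_rng(seed)
    held = sorted(rng.choice(eligible, size=k, replace=False).tolist()) if k else []
    held_set = set(held)
    out = {}
    for gene in profiles.genes:
        kept = profiles[gene] - held_set
        if kept:
            out[gene] = kept
    return AnnotationProfiles(out), held
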