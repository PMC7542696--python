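import numpy as np
import pytest

from anatonet import AnnotationProfiles, OntologyDAG, TermSimilarity, compute_ic


@pytest.fixture
def toy_dag():
    """R at the root; A, B is_a R; C is_a A."""
    return OntologyDAG({"R", "A", "B", "C"},
                       {("A", "R", "is_a"), ("B", "R", "is_a"), ("C", "A", "is_a")})


@pytest.fixture
def toy_profiles():
    return AnnotationProfiles({"g1": {"C"}, "g2": {"A"}, "g3": {"B"}})


@pytest.fixture
def toy_ic(toy_dag, toy_profiles):
    return compute_ic(toy_dag, toy_profiles)


@pytest.fixture
def lin(toy_dag, toy_ic):
    return TermSimilarity(toy_dag, method="lin", ic=toy_ic)


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyDAG:
    """Random rooted DAG: each non-root term gets 1-2 parents among earlier terms."""
    terms = [f"T{i}" for i in range(n_terms)]
    edges = set()
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.4 and i > 1)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            rel = "part_of" if rng.random() < 0.3 else "is_a"
            edges.add((terms[i], terms[int(p)], rel))
    return OntologyDAG(terms, edges)


def random_profiles(rng: np.random.Generator, dag: OntologyDAG, n_genes: int,
                    max_terms: int = 4) -> AnnotationProfiles:
    terms = sorted(dag.terms)
    out = {}
    for i in range(n_genes):
        k = int(rng.integers(1, max_terms + 1))
        picks = rng.choice(len(terms), size=min(k, len(terms)), replace=False)
        out[f"g{i}"] = {terms[j] for j in picks}
    return AnnotationProfiles(out)
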