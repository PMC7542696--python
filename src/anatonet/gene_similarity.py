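"""Gene-level similarity from ontology annotation profiles.

A gene's anatomical profile is the set of ontology terms annotated to it.
Pairwise gene similarity is the best-match average: each term of each profile
is matched to its most similar term in the other profile, and the matches are
averaged over both profiles:

    sim(G1, G2) = [ sum_i max_b sim(t_ai, t_b) + sum_j max_a sim(t_bj, t_a) ]
                  / (m + n)

with m, n the two profile sizes. Genes without a profile score 0 against
every gene.
"""

from __future__ import annotations

import gzip
import logging
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .ontology import OntologyDAG
from .similarity import TermSimilarity

logger = logging.getLogger(__name__)


class AnnotationProfiles(Mapping[str, frozenset]):
    """Mapping gene -> set of ontology terms (the gene's anatomical profile).

    Duplicate terms within a profile collapse; genes with empty profiles are
    dropped with a warning.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        data = {}
        for gene, terms in mapping.items():
            terms = frozenset(terms)
            if terms:
                data[gene] = terms
            else:
                logger.warning("gene %s has an empty profile; dropped", gene)
        self._data = data

    def __getitem__(self, gene: str) -> frozenset:
        return self._data[gene]

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    @property
    def genes(self) -> list[str]:
        return sorted(self._data)

    def vocabulary(self) -> frozenset:
        """All terms occurring in any profile."""
        out: set[str] = set()
        for terms in self._data.values():
            out |= terms
        return frozenset(out)

    def entity_counts(self) -> dict[str, int]:
        """Number of annotated genes per term (no ancestor propagation)."""
        counts: dict[str, int] = {}
        for terms in self._data.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        return counts

    def genes_annotated_to(self, term: str) -> frozenset:
        return frozenset(g for g, terms in self._data.items() if term in terms)

    def restrict_to_ontology(self, dag: OntologyDAG) -> "AnnotationProfiles":
        """Drop (and log) terms absent from the ontology."""
        dropped = 0
        out = {}
        for gene, terms in self._data.items():
            kept = frozenset(t for t in terms if t in dag)
            dropped += len(terms) - len(kept)
            if kept:
                out[gene] = kept
        if dropped:
            logger.warning("dropped %d annotations to terms absent from the ontology", dropped)
        return AnnotationProfiles(out)

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def read_tsv(cls, path) -> "AnnotationProfiles":
        """Read profiles from TSV.

        Two dialects are accepted: wide (``gene<TAB>TERM1;TERM2;...``) and
        long (``gene<TAB>term``, one annotation per line).
        """
        out: dict[str, set] = {}
        with _open(path, "rt") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"malformed profile line: {line!r}")
                gene, rhs = fields
                terms = rhs.split(";") if ";" in rhs else [rhs]
                out.setdefault(gene, set()).update(t for t in terms if t)
        return cls(out)

    def write_tsv(self, path) -> None:
        with _open(path, "wt") as fh:
            for gene in self.genes:
                fh.write(f"{gene}\t{';'.join(sorted(self._data[gene]))}\n")


def _open(path, mode):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def sim_term_to_profile(term: str, profile: Iterable[str], f: TermSimilarity) -> float:
    """Best match of ``term`` against a profile: max_b sim(term, b)."""
    profile = list(profile)
    if not profile:
        raise ValueError("empty profile")
    return max(f(term, b) for b in profile)


def sim_genes(g1: str, g2: str, profiles: Mapping[str, Iterable[str]], f: TermSimilarity) -> float:
    """Best-match-average similarity between two genes' profiles."""
    p1 = list(profiles.get(g1, ()))
    p2 = list(profiles.get(g2, ()))
    if not p1 or not p2:
        return 0.0
    total = sum(sim_term_to_profile(t, p2, f) for t in p1)
    total += sum(sim_term_to_profile(t, p1, f) for t in p2)
    return total / (len(p1) + len(p2))


def build_similarity_matrix(profiles: AnnotationProfiles, f: TermSimilarity) -> pd.DataFrame:
    """Full symmetric gene-by-gene similarity matrix.

    The term-level similarity matrix is computed once over the profile
    vocabulary, then each gene pair is a best-match average over the relevant
    sub-block. Requires at least two genes.
    """
    genes = profiles.genes
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to build a similarity matrix")
    terms = sorted(t for t in profiles.vocabulary() if t in f.dag)
    term_index = {t: i for i, t in enumerate(terms)}
    tmat = f.matrix(terms)
    idx = {g: np.array(sorted(term_index[t] for t in profiles[g] if t in term_index), dtype=int)
           for g in genes}
    n = len(genes)
    out = np.ones((n, n))
    for i in range(n):
        gi = idx[genes[i]]
        if gi.size == 0:
            out[i, :] = 0.0
            out[:, i] = 0.0
        for j in range(i, n):
            gj = idx[genes[j]]
            if gi.size == 0 or gj.size == 0:
                out[i, j] = out[j, i] = 0.0
                continue
            sub = tmat[np.ix_(gi, gj)]
            score = (sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (gi.size + gj.size)
            out[i, j] = out[j, i] = score
    return pd.DataFrame(out, index=genes, columns=genes)
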