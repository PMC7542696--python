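"""Pairwise semantic similarity between ontology terms.

Four measures are provided. Resnik, Lin and Schlicker score a pair by its most
informative common ancestor (MICA); Wang ignores the corpus and scores shared
ancestry weighted by semantic-contribution values decayed along is_a/part_of
edges. All four are symmetric and return values in [0, 1] (Resnik after
normalization by the corpus maximum IC).
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .ontology import InformationContentTable, OntologyDAG

METHODS = ("resnik", "lin", "schlicker", "wang")

#: Wang semantic-contribution decay per traversed relation
DEFAULT_WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class TermSimilarity:
    """Callable computing sim(t1, t2) by a chosen method.

    Parameters
    ----------
    dag : OntologyDAG
    method : one of ``resnik``, ``lin``, ``schlicker``, ``wang``
    ic : InformationContentTable, required for the IC-based methods
    wang_weights : mapping relation -> decay factor (Wang only)
    resnik_normalization : ``"max_ic"`` (default; divide the MICA IC by the
        corpus maximum so scores live in [0, 1]) or ``"raw"``.
    """

    def __init__(
        self,
        dag: OntologyDAG,
        method: str = "lin",
        ic: InformationContentTable | None = None,
        wang_weights: Mapping[str, float] | None = None,
        resnik_normalization: str = "max_ic",
    ):
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
        if method != "wang" and ic is None:
            raise ValueError(f"method {method!r} requires an information content table")
        if resnik_normalization not in ("max_ic", "raw"):
            raise ValueError(f"unknown resnik_normalization {resnik_normalization!r}")
        self.dag = dag
        self.method = method
        self.ic = ic
        self.wang_weights = dict(wang_weights or DEFAULT_WANG_WEIGHTS)
        self.resnik_normalization = resnik_normalization
        self._svalue_cache: dict[str, dict[str, float]] = {}

    def __call__(self, t1: str, t2: str) -> float:
        if t1 not in self.dag or t2 not in self.dag:
            raise KeyError(f"unknown term in pair ({t1!r}, {t2!r})")
        return getattr(self, f"sim_{self.method}")(t1, t2)

    # ---- MICA-based measures -------------------------------------------

    def mica(self, t1: str, t2: str) -> str | None:
        """Most informative common ancestor, or None when no common ancestor
        has a defined IC (zero-count terms are never MICA candidates)."""
        assert self.ic is not None
        common = self.dag.ancestors(t1) & self.dag.ancestors(t2)
        best, best_ic = None, -1.0
        for a in common:
            ica = self.ic.ic.get(a)
            if ica is not None and ica > best_ic:
                best, best_ic = a, ica
        return best

    def sim_resnik(self, t1: str, t2: str) -> float:
        assert self.ic is not None
        m = self.mica(t1, t2)
        if m is None:
            return 0.0
        raw = self.ic.ic[m]
        if self.resnik_normalization == "raw":
            return raw
        max_ic = self.ic.max_ic
        return raw / max_ic if max_ic > 0 else 0.0

    def sim_lin(self, t1: str, t2: str) -> float:
        assert self.ic is not None
        m = self.mica(t1, t2)
        if m is None:
            return 0.0
        denom = self._ic_of(t1) + self._ic_of(t2)
        if denom == 0:
            return 0.0
        return 2.0 * self.ic.ic[m] / denom

    def sim_schlicker(self, t1: str, t2: str) -> float:
        # relevance similarity: Lin score damped by how common the MICA is
        assert self.ic is not None
        m = self.mica(t1, t2)
        if m is None:
            return 0.0
        denom = self._ic_of(t1) + self._ic_of(t2)
        if denom == 0:
            return 0.0
        lin = 2.0 * self.ic.ic[m] / denom
        return lin * (1.0 - self.ic.p[m])

    def _ic_of(self, term: str) -> float:
        assert self.ic is not None
        ic = self.ic.ic.get(term)
        if ic is None:
            raise ValueError(f"term {term!r} has undefined IC (zero propagated annotations)")
        return ic

    # ---- Wang method ----------------------------------------------------

    def svalues(self, term: str) -> dict[str, float]:
        """Semantic contributions S_term(a) for every ancestor a of term.

        S_term(term) = 1; for an ancestor a, S_term(a) is the maximum over
        child edges (c -> a) within the ancestor set of w_rel * S_term(c).
        """
        cached = self._svalue_cache.get(term)
        if cached is not None:
            return cached
        anc = self.dag.ancestors(term)
        s: dict[str, float] = {}

        def value(a: str) -> float:
            got = s.get(a)
            if got is not None:
                return got
            if a == term:
                s[a] = 1.0
                return 1.0
            best = 0.0
            for child, rel in self.dag.children(a):
                if child in anc:
                    cand = self.wang_weights[rel] * value(child)
                    if cand > best:
                        best = cand
            s[a] = best
            return best

        for a in anc:
            value(a)
        self._svalue_cache[term] = s
        return s

    def sim_wang(self, t1: str, t2: str) -> float:
        s1, s2 = self.svalues(t1), self.svalues(t2)
        common = s1.keys() & s2.keys()
        if not common:
            return 0.0
        num = sum(s1[a] + s2[a] for a in common)
        # num <= denom term-by-term; min() guards float summation overshoot at 1
        return min(1.0, num / (sum(s1.values()) + sum(s2.values())))

    # ---- bulk interface --------------------------------------------------

    def matrix(self, terms: list[str]) -> np.ndarray:
        """Symmetric pairwise similarity matrix over ``terms``."""
        n = len(terms)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                out[i, j] = out[j, i] = self(terms[i], terms[j])
        return out

    def dump_tsv(self, terms: list[str], path) -> None:
        """Debug dump: one ``term1<TAB>term2<TAB>score`` row per unordered pair."""
        with open(path, "w") as fh:
            for i, t1 in enumerate(terms):
                for t2 in terms[i:]:
                    fh.write(f"{t1}\t{t2}\t{self(t1, t2)!r}\n")
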