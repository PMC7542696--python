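"""Brute-force reference implementations, independent of the package's code
paths: ancestor sets by exhaustive path enumeration, MICA-based similarities
by explicit common-ancestor scans, Wang S-values by explicit path-product
maximization, and ROC AUC by concordant-pair counting."""

import math


def ancestors_by_paths(dag, term):
    """Reflexive ancestor set via exhaustive upward path enumeration."""
    out = set()
    stack = [(term, (term,))]
    while stack:
        node, path = stack.pop()
        out.update(path)
        for parent, _ in dag.parents(node):
            stack.append((parent, path + (parent,)))
    return out


def ic_by_counting(dag, profiles):
    """p(t) and IC(t) by direct definition: fraction of genes with t in the
    ancestor closure of their annotation set."""
    genes = list(profiles)
    p, ic = {}, {}
    for t in dag.terms:
        n = sum(1 for g in genes
                if any(t in ancestors_by_paths(dag, a) for a in profiles[g]))
        if n:
            p[t] = n / len(genes)
            ic[t] = -math.log(p[t]) + 0.0
    return p, ic


def mica_ic(dag, ic, t1, t2):
    common = ancestors_by_paths(dag, t1) & ancestors_by_paths(dag, t2)
    vals = [ic[a] for a in common if a in ic]
    return max(vals) if vals else None


def sim_resnik(dag, ic, t1, t2):
    m = mica_ic(dag, ic, t1, t2)
    if m is None:
        return 0.0
    mx = max(ic.values())
    return m / mx if mx > 0 else 0.0


def sim_lin(dag, ic, t1, t2):
    m = mica_ic(dag, ic, t1, t2)
    if m is None or ic[t1] + ic[t2] == 0:
        return 0.0
    return 2 * m / (ic[t1] + ic[t2])


def sim_schlicker(dag, p, ic, t1, t2):
    common = ancestors_by_paths(dag, t1) & ancestors_by_paths(dag, t2)
    cands = [(ic[a], a) for a in common if a in ic]
    if not cands or ic[t1] + ic[t2] == 0:
        return 0.0
    best_ic, best = max(cands)
    return (2 * best_ic / (ic[t1] + ic[t2])) * (1 - p[best])


def wang_svalues(dag, term, weights):
    """S_term(a) = max over all directed paths term->a of the product of edge
    weights, by explicit enumeration of every path."""
    s = {term: 1.0}

    # enumerate every path, not just the greedy one
    def all_paths(node, value):
        for parent, rel in dag.parents(node):
            v = value * weights[rel]
            if v > s.get(parent, 0.0):
                s[parent] = v
            all_paths(parent, v)

    all_paths(term, 1.0)
    return s


def sim_wang(dag, t1, t2, weights):
    s1 = wang_svalues(dag, t1, weights)
    s2 = wang_svalues(dag, t2, weights)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    return sum(s1[a] + s2[a] for a in common) / (sum(s1.values()) + sum(s2.values()))


def sim_genes_pairwise(g1, g2, profiles, simfn):
    """Best-match average by direct double loop."""
    p1, p2 = list(profiles[g1]), list(profiles[g2])
    total = sum(max(simfn(a, b) for b in p2) for a in p1)
    total += sum(max(simfn(b, a) for a in p1) for b in p2)
    return total / (len(p1) + len(p2))


def roc_auc_pairs(scores, labels):
    """Concordant positive-negative pairs (+ half ties) over all pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def count_above(scores, cutoff):
    return sum(1 for s in scores if s > cutoff)
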