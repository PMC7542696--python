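"""Candidate gene prediction and its leave-one-out evaluation.

Prediction uses the Hishigaki neighborhood statistic: for a gene u and an
anatomical entity f, the observed number of f-annotated genes among u's
immediate network neighbors, n_f(u), is compared with its expectation under a
uniform spread of the tot_f annotated genes across the tot_N network genes,

    e_f = tot_f * n(u) / tot_N,        score = (n_f(u) - e_f)^2 / e_f .

The chi-square form is symmetric around e_f; for ranking, the sign of
(n_f - e_f) is applied by default so depleted neighborhoods rank below
enriched ones (the unsigned form is available via ``signed=False``).

Evaluation is per entity: each annotated gene is held out in turn, scored
with its own annotation masked, and ranked against all unannotated genes of
the reconciled profile universe present in the network; ROC AUC uses the
midrank (Mann-Whitney) formulation, PR AUC the trapezoid over the
precision-recall staircase.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Collection, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve

from .gene_similarity import AnnotationProfiles
from .network import GeneNetwork

logger = logging.getLogger(__name__)


def roc_auc(scores, labels) -> float:
    """ROC AUC via midranks: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both positives and negatives")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall staircase by trapezoid integration."""
    precision, recall, _ = precision_recall_curve(np.asarray(labels, dtype=int), scores)
    return float(_trapezoid_auc(recall, precision))


def hishigaki_score(net: GeneNetwork, gene: str, annotated: Collection[str],
                    tot_f: int | None = None, tot_n: int | None = None,
                    signed: bool = True) -> float:
    """Neighborhood enrichment score of ``gene`` for one entity.

    ``annotated`` is the set of genes currently annotated to the entity (the
    caller masks the gene's own annotation during leave-one-out). ``tot_f``
    defaults to the number of annotated genes present in the network and
    ``tot_n`` to the network size. Isolated genes and entities absent from
    the network universe (e_f = 0) score 0.
    """
    if gene not in net.graph:
        raise KeyError(gene)
    neighbors = set(net.graph[gene])
    annotated_in_net = set(annotated) & net.nodes()
    if tot_f is None:
        tot_f = len(annotated_in_net)
    if tot_n is None:
        tot_n = net.n_nodes
    return _hishigaki(neighbors, annotated_in_net, tot_f, tot_n, signed)


def _hishigaki(neighbors: set, annotated, tot_f: int | None, tot_n: int, signed: bool) -> float:
    n_u = len(neighbors)
    if n_u == 0:
        return 0.0
    if tot_f is None:
        tot_f = len(annotated)
    e_f = tot_f * n_u / tot_n
    if e_f == 0:
        return 0.0
    n_f = len(neighbors & set(annotated))
    delta = n_f - e_f
    score = delta * delta / e_f
    return math.copysign(score, delta) if signed else score


@dataclass
class EvaluationResult:
    """Per-entity ROC/PR AUCs for one network plus summary statistics."""

    network: str
    per_entity: pd.DataFrame  # columns: entity, roc_auc, pr_auc, n_pos

    @property
    def mean_roc_auc(self) -> float:
        return float(self.per_entity["roc_auc"].mean())

    @property
    def mean_pr_auc(self) -> float:
        return float(self.per_entity["pr_auc"].mean())

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric in ("roc_auc", "pr_auc"):
            s = self.per_entity[metric]
            rows.append({
                "metric": metric, "mean": s.mean(), "median": s.median(),
                "q1": s.quantile(0.25), "q3": s.quantile(0.75), "n_entities": len(s),
            })
        return pd.DataFrame(rows)


class _Scorer:
    """Shared state for scoring many (gene, entity) pairs on one network."""

    def __init__(self, net: GeneNetwork, profiles: AnnotationProfiles, signed: bool = True):
        self.net = net
        self.signed = signed
        self.nodes = net.nodes()
        self.tot_n = net.n_nodes
        self.adj = {g: set(net.graph[g]) for g in net.graph.nodes()}
        self.universe = sorted(set(profiles) & self.nodes)
        self.profiles = profiles

    def positives(self, entity: str) -> list[str]:
        return sorted(g for g in self.universe if entity in self.profiles[g])


def loocv_entity(net: GeneNetwork, profiles: AnnotationProfiles, entity: str,
                 min_genes: int = 10, signed: bool = True,
                 _scorer: _Scorer | None = None) -> tuple[float, float, int]:
    """Leave-one-out ROC and PR AUC for one entity.

    Each annotated gene is scored with its own annotation to the entity
    masked (both from the neighborhood counts and from tot_f); every
    unannotated gene of the profile universe present in the network is scored
    as a negative with the full annotation set. Returns
    (roc_auc, pr_auc, n_positives).
    """
    sc = _scorer or _Scorer(net, profiles, signed=signed)
    positives = sc.positives(entity)
    if len(positives) < min_genes:
        raise ValueError(
            f"entity {entity!r} has {len(positives)} annotated genes in the network; "
            f"needs >= {min_genes}")
    pos_set = set(positives)
    negatives = [g for g in sc.universe if g not in pos_set]
    if not negatives:
        raise ValueError(f"entity {entity!r} has no negative genes to rank against")
    scores, labels = [], []
    for g in positives:  # mask the held-out gene's own annotation
        masked = pos_set - {g}
        scores.append(_hishigaki(sc.adj[g], masked, len(masked), sc.tot_n, signed))
        labels.append(True)
    for g in negatives:
        scores.append(_hishigaki(sc.adj[g], pos_set, len(pos_set), sc.tot_n, signed))
        labels.append(False)
    scores_arr = np.asarray(scores)
    if np.all(scores_arr == scores_arr[0]):
        warnings.warn(f"all prediction scores identical for entity {entity!r}; ROC AUC 0.5")
    return roc_auc(scores_arr, labels), pr_auc(scores_arr, labels), len(positives)


def evaluate_network(net: GeneNetwork, profiles: AnnotationProfiles,
                     min_genes: int = 10, signed: bool = True,
                     name: str | None = None) -> EvaluationResult:
    """Leave-one-out evaluation over every evaluable entity.

    An entity is evaluable when at least ``min_genes`` of its annotated genes
    are present in the network (and at least one unannotated gene remains).
    """
    sc = _Scorer(net, profiles, signed=signed)
    counts: dict[str, int] = {}
    for g in sc.universe:
        for t in profiles[g]:
            counts[t] = counts.get(t, 0) + 1
    rows = []
    for entity in sorted(counts):
        n_pos = counts[entity]
        if n_pos < min_genes or n_pos == len(sc.universe):
            continue
        r, p, n = loocv_entity(net, profiles, entity, min_genes=min_genes,
                               signed=signed, _scorer=sc)
        rows.append({"entity": entity, "roc_auc": r, "pr_auc": p, "n_pos": n})
    per_entity = pd.DataFrame(rows, columns=["entity", "roc_auc", "pr_auc", "n_pos"])
    return EvaluationResult(network=name or net.provenance, per_entity=per_entity)


def predict_candidates(net: GeneNetwork, profiles: AnnotationProfiles, entity: str,
                       top: int | None = None, signed: bool = True) -> pd.DataFrame:
    """Ranked novel candidates for an entity (the tool's applied mode).

    Scores every network gene not annotated to the entity, using the full
    annotation set, and returns them ranked by decreasing score.
    """
    annotated = profiles.genes_annotated_to(entity) & net.nodes()
    if not annotated:
        raise ValueError(f"no annotated genes for entity {entity!r} are in the network")
    adj = {g: set(net.graph[g]) for g in net.graph.nodes()}
    tot_n = net.n_nodes
    rows = [{"gene": g,
             "score": _hishigaki(adj[g], annotated, len(annotated), tot_n, signed)}
            for g in sorted(net.nodes() - annotated)]
    out = pd.DataFrame(rows).sort_values(["score", "gene"], ascending=[False, True],
                                         ignore_index=True)
    return out.head(top) if top else out


def compare_networks(results: list[EvaluationResult]) -> pd.DataFrame:
    """Per-entity AUCs aligned across networks on the common evaluable entities.

    Columns are a (network, metric) MultiIndex; a summary with means and
    medians per network is attached as ``.attrs['summary']``.
    """
    if not results:
        raise ValueError("no evaluation results to compare")
    common = None
    for res in results:
        ents = set(res.per_entity["entity"])
        common = ents if common is None else common & ents
    frames = {}
    for res in results:
        df = res.per_entity.set_index("entity").loc[sorted(common), ["roc_auc", "pr_auc"]]
        frames[res.network] = df
    out = pd.concat(frames, axis=1)
    summary = pd.DataFrame({
        name: {"mean_roc_auc": df["roc_auc"].mean(), "median_roc_auc": df["roc_auc"].median(),
               "mean_pr_auc": df["pr_auc"].mean(), "median_pr_auc": df["pr_auc"].median()}
        for name, df in frames.items()
    }).T
    out.attrs["summary"] = summary
    return out


def plot_auc_boxplots(results: list[EvaluationResult], path, metric: str = "roc_auc") -> None:
    """Boxplot of per-entity AUC distributions, one box per network.

    The median is drawn as a red line and the mean as a square marker.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = [res.per_entity[metric] for res in results]
    labels = [res.network for res in results]
    fig, ax = plt.subplots(figsize=(1.8 * len(results) + 2, 4))
    ax.boxplot(data, tick_labels=labels, showmeans=True,
               medianprops={"color": "red"},
               meanprops={"marker": "s", "markerfacecolor": "black", "markeredgecolor": "black"})
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
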