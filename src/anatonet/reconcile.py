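"""Gene-name reconciliation between annotation profiles and PPI networks.

Annotation repositories and STRING use different naming authorities, so the
same gene can appear under different symbols. Reconciliation runs three
sequential rounds: (1) direct name match, (2) match via shared Ensembl
identifiers, (3) match of profile names against network-gene synonyms. A gene
matched in one round is not retried in later rounds; for rounds 2-3 the
network node is renamed to the profile's gene name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .gene_similarity import AnnotationProfiles
from .network import GeneNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReconciliationReport:
    """Per-round match counts plus the final matched/mismatched partition."""

    round1_direct: int
    round2_ensembl: int
    round3_synonym: int
    matched: frozenset
    mismatched: frozenset
    renames: Mapping[str, str] = field(default_factory=dict)  # network node -> new name

    @property
    def total_matched(self) -> int:
        return len(self.matched)

    def to_rows(self) -> list[tuple[str, int]]:
        return [
            ("genes_in_profiles", len(self.matched) + len(self.mismatched)),
            ("round1_direct_matches", self.round1_direct),
            ("round2_ensembl_matches", self.round2_ensembl),
            ("round3_synonym_matches", self.round3_synonym),
            ("total_matched", self.total_matched),
            ("mismatched", len(self.mismatched)),
        ]


class AmbiguousMatchError(ValueError):
    """A profile gene matched more than one distinct network node."""


def reconcile_genes(
    profiles: AnnotationProfiles,
    net: GeneNetwork,
    ensembl_map: Mapping[str, str] | None = None,
    synonyms: Mapping[str, Iterable[str]] | None = None,
    case_sensitive: bool = True,
) -> tuple[AnnotationProfiles, ReconciliationReport]:
    """Align profile gene names to the network; rename network nodes in place.

    ``ensembl_map`` maps gene names (either side) to Ensembl IDs; ``synonyms``
    maps network gene names to alias sets. Matching is case-sensitive exact by
    default (model-organism symbols are case-meaningful). Ambiguous matches
    (one profile gene resolving to two distinct network nodes) raise
    :class:`AmbiguousMatchError` listing the collision.
    """
    ensembl_map = dict(ensembl_map or {})
    synonyms = {k: frozenset(v) for k, v in (synonyms or {}).items()}
    fold = (lambda s: s) if case_sensitive else (lambda s: s.lower())

    profile_genes = sorted(profiles)
    net_nodes = sorted(net.nodes())
    net_by_name = {fold(n): n for n in net_nodes}

    matched: set = set()
    renames: dict[str, str] = {}

    # round 1: direct name/symbol match
    for g in profile_genes:
        if fold(g) in net_by_name:
            matched.add(g)
    round1 = len(matched)
    claimed_nodes = {net_by_name[fold(g)] for g in matched}

    # round 2: shared Ensembl identifier
    ensembl_to_nodes: dict[str, list] = {}
    for node in net_nodes:
        if node in claimed_nodes:
            continue
        eid = ensembl_map.get(node)
        if eid is not None:
            ensembl_to_nodes.setdefault(eid, []).append(node)
    for g in profile_genes:
        if g in matched:
            continue
        eid = ensembl_map.get(g)
        nodes = ensembl_to_nodes.get(eid, []) if eid is not None else []
        nodes = [n for n in nodes if n not in renames]
        if len(nodes) > 1:
            raise AmbiguousMatchError(
                f"profile gene {g!r} matches network nodes {sorted(nodes)} via Ensembl ID {eid!r}")
        if nodes:
            matched.add(g)
            renames[nodes[0]] = g
    round2 = len(matched) - round1

    # round 3: profile name among network-gene synonyms
    alias_to_nodes: dict[str, list] = {}
    for node, aliases in synonyms.items():
        if node in claimed_nodes or node in renames or node not in net.graph:
            continue
        for alias in aliases:
            alias_to_nodes.setdefault(fold(alias), []).append(node)
    for g in profile_genes:
        if g in matched:
            continue
        nodes = [n for n in alias_to_nodes.get(fold(g), []) if n not in renames]
        if len(nodes) > 1:
            raise AmbiguousMatchError(
                f"profile gene {g!r} matches network nodes {sorted(nodes)} via synonyms")
        if nodes:
            matched.add(g)
            renames[nodes[0]] = g
    round3 = len(matched) - round1 - round2

    if renames:
        nx.relabel_nodes(net.graph, renames, copy=False)
    mismatched = frozenset(set(profile_genes) - matched)
    report = ReconciliationReport(
        round1_direct=round1, round2_ensembl=round2, round3_synonym=round3,
        matched=frozenset(matched), mismatched=mismatched, renames=renames)
    logger.info("reconciliation: %d direct, %d ensembl, %d synonym, %d mismatched",
                round1, round2, round3, len(mismatched))
    reconciled = AnnotationProfiles({g: profiles[g] for g in sorted(matched)})
    return reconciled, report


def filter_entities(profiles: AnnotationProfiles, min_genes: int = 10) -> AnnotationProfiles:
    """Drop entities annotated to fewer than ``min_genes`` genes.

    Genes whose profile becomes empty are removed. The pass is iterated to a
    fixed point (a convergence that in practice arrives after one effective
    pass, since a gene is only dropped once it supports no surviving entity).
    """
    current = {g: set(terms) for g, terms in profiles.items()}
    for _ in range(len(profiles) + 2):
        counts: dict[str, int] = {}
        for terms in current.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        keep = {t for t, c in counts.items() if c >= min_genes}
        nxt = {}
        for g, terms in current.items():
            kept = terms & keep
            if kept:
                nxt[g] = kept
        if nxt == current:
            return AnnotationProfiles(nxt)
        current = nxt
    raise AssertionError("entity filtering failed to converge")


def write_report(report: ReconciliationReport, path) -> None:
    with open(path, "w") as fh:
        for name, value in report.to_rows():
            fh.write(f"{name}\t{value}\n")
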