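"""Desk-scale reproduction studies on the planted-module synthetic world.

One study run builds the three networks (PPI, semantic, integrated) from a
seeded synthetic world, evaluates them by per-entity leave-one-out AUC, and
repeats the evaluation for the two randomization controls of the integrated
network: a randomized-profile rebuild (the semantic side reconstructed from
shuffled annotations) and a fully randomized network with the same node and
edge counts. The semantic and integrated cutoffs are selected to keep the
interaction count in (E, 1.5E) around the filtered PPI edge count E, the same
proportionality the organism-scale band has to its PPI networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .evaluate import EvaluationResult, evaluate_network
from .gene_similarity import build_similarity_matrix
from .integrate import compute_weights, integrate_networks
from .network import GeneNetwork, filter_network, select_cutoff
from .ontology import compute_ic
from .reconcile import filter_entities
from .similarity import TermSimilarity
from .synthetic import SyntheticWorld, WorldConfig, fully_randomize, make_world, \
    randomize_profiles


@dataclass
class StudyRun:
    """All networks and evaluation results of one seeded study run."""

    world: SyntheticWorld
    networks: dict
    results: dict          # name -> EvaluationResult
    weights: object
    cutoffs: dict

    def mean_roc(self, name: str) -> float:
        return self.results[name].mean_roc_auc

    def mean_pr(self, name: str) -> float:
        return self.results[name].mean_pr_auc


def _semantic_network(world: SyntheticWorld, method: str) -> GeneNetwork:
    ic = compute_ic(world.dag, world.profiles) if method != "wang" else None
    simfn = TermSimilarity(world.dag, method=method, ic=ic)
    matrix = build_similarity_matrix(world.profiles, simfn)
    return GeneNetwork.from_similarity_matrix(matrix, provenance="anatomy")


def _semantic_from_profiles(world: SyntheticWorld, profiles, method: str) -> GeneNetwork:
    ic = compute_ic(world.dag, profiles) if method != "wang" else None
    simfn = TermSimilarity(world.dag, method=method, ic=ic)
    matrix = build_similarity_matrix(profiles, simfn)
    return GeneNetwork.from_similarity_matrix(matrix, provenance="anatomy")


def run_study(seed: int, method: str = "wang", ppi_cutoff: float = 0.7,
              min_genes: int = 10, config: WorldConfig | None = None,
              with_controls: bool = True) -> StudyRun:
    """Build, integrate and evaluate one synthetic world.

    Returns evaluation results keyed ``ppi``, ``anatomy``, ``integrated`` and,
    when ``with_controls`` is set, ``integrated_randomized_profiles`` and
    ``integrated_fully_randomized``.
    """
    if config is None:
        config = WorldConfig(seed=seed)
    else:
        config.seed = seed
    world = make_world(config)
    eval_profiles = filter_entities(world.profiles, min_genes=min_genes)

    ppi_full = world.ppi
    ppi = filter_network(ppi_full, ppi_cutoff)
    band = (ppi.n_edges, max(ppi.n_edges + 1, int(round(1.5 * ppi.n_edges))))

    anat_full = _semantic_network(world, method)
    anat_cutoff = select_cutoff(anat_full, band)
    anat = filter_network(anat_full, anat_cutoff)

    res_ppi = evaluate_network(ppi, eval_profiles, min_genes=min_genes, name="ppi")
    res_anat = evaluate_network(anat, eval_profiles, min_genes=min_genes, name="anatomy")
    weights = compute_weights(res_ppi.mean_roc_auc, res_anat.mean_roc_auc)

    integ_full = integrate_networks(ppi_full, anat_full, weights)
    integ_cutoff = select_cutoff(integ_full, band)
    integ = filter_network(integ_full, integ_cutoff)
    res_integ = evaluate_network(integ, eval_profiles, min_genes=min_genes, name="integrated")

    networks = {"ppi": ppi, "anatomy": anat, "integrated": integ,
                "ppi_unfiltered": ppi_full, "anatomy_unfiltered": anat_full,
                "integrated_unfiltered": integ_full}
    results = {"ppi": res_ppi, "anatomy": res_anat, "integrated": res_integ}
    cutoffs = {"ppi": ppi_cutoff, "anatomy": anat_cutoff, "integrated": integ_cutoff}

    if with_controls:
        # randomized-profile control: rebuild the semantic side from shuffled
        # annotations, reintegrate, evaluate against the REAL profiles
        shuffled = randomize_profiles(world.profiles, seed=seed + 10_000)
        anat_rp_full = _semantic_from_profiles(world, shuffled, method)
        anat_rp = filter_network(anat_rp_full, select_cutoff(anat_rp_full, band))
        res_rp_anat = evaluate_network(anat_rp, eval_profiles, min_genes=min_genes,
                                       name="anatomy_randomized_profiles")
        w_rp = compute_weights(res_ppi.mean_roc_auc, max(res_rp_anat.mean_roc_auc, 1e-9))
        integ_rp_full = integrate_networks(ppi_full, anat_rp_full, w_rp)
        integ_rp = filter_network(integ_rp_full, select_cutoff(integ_rp_full, band))
        results["integrated_randomized_profiles"] = evaluate_network(
            integ_rp, eval_profiles, min_genes=min_genes,
            name="integrated_randomized_profiles")
        results["anatomy_randomized_profiles"] = res_rp_anat
        networks["integrated_randomized_profiles"] = integ_rp

        # fully randomized control: same |V| and |E| as the filtered
        # integrated network, uniform structure, scores 1
        rand = fully_randomize(integ, seed=seed + 20_000)
        results["integrated_fully_randomized"] = evaluate_network(
            rand, eval_profiles, min_genes=min_genes, name="integrated_fully_randomized")
        networks["integrated_fully_randomized"] = rand

    return StudyRun(world=world, networks=networks, results=results,
                    weights=weights, cutoffs=cutoffs)


def paired_auc_table(runs: list[StudyRun], names: tuple[str, ...] = ("ppi", "integrated"),
                     metric: str = "roc_auc") -> pd.DataFrame:
    """Per-entity AUCs of several networks aligned within each run.

    Rows are (seed index, entity); columns are the network names. Only
    entities evaluable in every requested network of a run are kept.
    """
    frames = []
    for k, run in enumerate(runs):
        dfs = {n: run.results[n].per_entity.set_index("entity")[metric] for n in names}
        df = pd.DataFrame(dfs).dropna()
        df.insert(0, "run", k)
        frames.append(df.reset_index())
    return pd.concat(frames, ignore_index=True)
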