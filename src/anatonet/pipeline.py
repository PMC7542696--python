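"""End-to-end pipeline: ontology -> semantic network -> integration -> evaluation.

Stages, in order: parse ontology; build the semantic (anatomy-based) gene
network from the full annotation profiles; ingest and filter the PPI network;
reconcile gene names and filter entities; filter the semantic network; evaluate
both filtered networks to obtain accuracy weights; integrate the unfiltered
networks; select and apply the integrated cutoff; evaluate all three networks
on the reconciled profiles; emit comparison tables. Every stage logs the counts
it produced, and all intermediates are written with checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import evaluate, gene_similarity, integrate, network, ontology, reconcile, similarity

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and parameters of one pipeline run.

    Cutoff modes for the semantic and integrated networks: an explicit value,
    an absolute interaction band ``(lo, hi)`` (the organism-scale default is
    500,000-750,000), or ``"match_ppi"`` which targets (E, 1.5*E) around the
    filtered PPI edge count E - the same proportionality the absolute band has
    at organism scale.
    """

    obo: str = ""
    profiles: str = ""
    string_links: str = ""
    id_map: str | None = None
    ensembl_map: str | None = None
    synonyms: str | None = None
    method: str = "wang"
    ppi_cutoff: float = 0.7
    anatomy_cutoff: float | None = None
    anatomy_band: tuple[int, int] | str = "match_ppi"
    integrated_cutoff: float | None = None
    integrated_band: tuple[int, int] | str = "match_ppi"
    min_genes: int = 10
    accuracy_metric: str = "roc"   # roc | pr : mean AUC used for weights
    signed_scores: bool = True
    seed: int = 0
    outdir: str = "anatonet_out"

    #: the organism-scale interaction band used in the source study
    DEFAULT_BAND = (500_000, 750_000)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("anatomy_band"), list):
            raw["anatomy_band"] = tuple(raw["anatomy_band"])
        if isinstance(raw.get("integrated_band"), list):
            raw["integrated_band"] = tuple(raw["integrated_band"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("anatomy_band", "integrated_band"):
            if isinstance(data[key], tuple):
                data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _resolve_band(band, ppi_edges: int) -> tuple[int, int]:
    if band == "match_ppi":
        return (ppi_edges, max(ppi_edges + 1, int(round(1.5 * ppi_edges))))
    lo, hi = band
    return int(lo), int(hi)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artifacts to ``config.outdir``.

    Returns a dict with the three filtered networks, their evaluation results,
    the integration weights and the aligned comparison table.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def persist(write_fn, path: Path):
        write_fn(path)
        written.append(path)

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {name!r} failed ({exc}); check the inputs this "
                f"stage consumes and rerun") from exc
        return result

    # 1. ontology
    dag = stage("parse_ontology", lambda: ontology.parse_obo(config.obo))
    logger.info("stage parse_ontology: %d terms, %d edges", len(dag), len(dag.edges))

    # 2. profiles (full set; network construction uses the original profiles)
    full_profiles = stage("read_profiles",
                          lambda: gene_similarity.AnnotationProfiles.read_tsv(config.profiles)
                          .restrict_to_ontology(dag))
    logger.info("stage read_profiles: %d genes, %d entities",
                len(full_profiles), len(full_profiles.vocabulary()))

    # 3. semantic gene network (unfiltered)
    ic = ontology.compute_ic(dag, full_profiles) if config.method != "wang" else None
    simfn = similarity.TermSimilarity(dag, method=config.method, ic=ic)
    matrix = stage("build_semantic_network",
                   lambda: gene_similarity.build_similarity_matrix(full_profiles, simfn))
    anat_full = network.GeneNetwork.from_similarity_matrix(matrix, provenance="anatomy")
    logger.info("stage build_semantic_network (%s): %d genes, %d interactions (unfiltered)",
                config.method, anat_full.n_nodes, anat_full.n_edges)

    # 4. PPI ingestion and filtering
    id_map = network.read_id_mapping(config.id_map) if config.id_map else None
    ppi_full = stage("read_ppi", lambda: network.read_string_links(config.string_links, id_map))
    ppi = network.filter_network(ppi_full, config.ppi_cutoff)
    logger.info("stage read_ppi: %d genes, %d interactions raw; %d genes, %d interactions "
                "at cutoff %.2f", ppi_full.n_nodes, ppi_full.n_edges,
                ppi.n_nodes, ppi.n_edges, config.ppi_cutoff)

    # 5. reconciliation (renames the PPI nodes in place) and entity filtering
    ensembl_map = network.read_id_mapping(config.ensembl_map) if config.ensembl_map else None
    synonyms = None
    if config.synonyms:
        synonyms = {}
        with open(config.synonyms) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) >= 2:
                    synonyms.setdefault(fields[0], set()).add(fields[1])
    reconciled, report = stage(
        "reconcile", lambda: reconcile.reconcile_genes(full_profiles, ppi_full,
                                                       ensembl_map=ensembl_map,
                                                       synonyms=synonyms))
    if report.renames:  # keep the filtered view consistent with the renamed raw PPI
        ppi = network.filter_network(ppi_full, config.ppi_cutoff)
    eval_profiles = reconcile.filter_entities(reconciled, min_genes=config.min_genes)
    logger.info("stage reconcile: rounds (%d, %d, %d), matched %d, mismatched %d; "
                "after entity filter: %d genes, %d entities",
                report.round1_direct, report.round2_ensembl, report.round3_synonym,
                report.total_matched, len(report.mismatched),
                len(eval_profiles), len(eval_profiles.vocabulary()))
    persist(lambda p: reconcile.write_report(report, p), out / "reconciliation.tsv")

    # 6. semantic network cutoff
    if config.anatomy_cutoff is not None:
        anat_cutoff = config.anatomy_cutoff
    else:
        band = _resolve_band(config.anatomy_band, ppi.n_edges)
        anat_cutoff = network.select_cutoff(anat_full, band)
    anat = network.filter_network(anat_full, anat_cutoff)
    logger.info("stage filter_semantic: cutoff %.4f -> %d genes, %d interactions",
                anat_cutoff, anat.n_nodes, anat.n_edges)

    # 7. accuracy weights from the filtered source networks
    res_ppi = stage("evaluate_ppi", lambda: evaluate.evaluate_network(
        ppi, eval_profiles, min_genes=config.min_genes, signed=config.signed_scores, name="ppi"))
    res_anat = stage("evaluate_anatomy", lambda: evaluate.evaluate_network(
        anat, eval_profiles, min_genes=config.min_genes, signed=config.signed_scores,
        name="anatomy"))
    metric = "mean_roc_auc" if config.accuracy_metric == "roc" else "mean_pr_auc"
    weights = integrate.compute_weights(getattr(res_ppi, metric), getattr(res_anat, metric))
    logger.info("stage weights: AC_ppi=%.4f AC_anatomy=%.4f -> W=(%.4f, %.4f)",
                weights.ac_ppi, weights.ac_anatomy, weights.w_ppi, weights.w_anatomy)

    # 8. integration of the unfiltered networks, cutoff, filtering
    integ_full = stage("integrate",
                       lambda: integrate.integrate_networks(ppi_full, anat_full, weights))
    if config.integrated_cutoff is not None:
        integ_cutoff = config.integrated_cutoff
    else:
        band = _resolve_band(config.integrated_band, ppi.n_edges)
        integ_cutoff = network.select_cutoff(integ_full, band)
    integ = network.filter_network(integ_full, integ_cutoff)
    logger.info("stage integrate: %d genes, %d interactions unfiltered; cutoff %.4f -> "
                "%d genes, %d interactions", integ_full.n_nodes, integ_full.n_edges,
                integ_cutoff, integ.n_nodes, integ.n_edges)

    # 9. evaluation of all three networks and comparison
    res_integ = stage("evaluate_integrated", lambda: evaluate.evaluate_network(
        integ, eval_profiles, min_genes=config.min_genes, signed=config.signed_scores,
        name="integrated"))
    comparison = evaluate.compare_networks([res_ppi, res_anat, res_integ])
    logger.info("stage compare: %d common entities; mean ROC AUC ppi=%.4f anatomy=%.4f "
                "integrated=%.4f", len(comparison), res_ppi.mean_roc_auc,
                res_anat.mean_roc_auc, res_integ.mean_roc_auc)

    # 10. persist artifacts
    persist(lambda p: network.write_network(anat_full, p), out / "anatomy_unfiltered.tsv")
    persist(lambda p: network.write_network(anat, p), out / "anatomy_filtered.tsv")
    persist(lambda p: network.write_network(ppi, p), out / "ppi_filtered.tsv")
    persist(lambda p: network.write_network(integ, p), out / "integrated_filtered.tsv")
    for res in (res_ppi, res_anat, res_integ):
        persist(lambda p, r=res: r.per_entity.to_csv(p, sep="\t", index=False),
                out / f"auc_{res.network}.tsv")
    persist(lambda p: comparison.to_csv(p, sep="\t"), out / "comparison.tsv")
    persist(lambda p: comparison.attrs["summary"].to_csv(p, sep="\t"), out / "summary.tsv")
    config.to_yaml(out / "config.yaml")
    written.append(out / "config.yaml")
    with open(out / "checksums.txt", "w") as fh:
        for path in written:
            fh.write(f"{_checksum(path)}  {path.name}\n")

    return {
        "dag": dag,
        "profiles": full_profiles,
        "eval_profiles": eval_profiles,
        "networks": {"ppi": ppi, "anatomy": anat, "integrated": integ,
                     "ppi_unfiltered": ppi_full, "anatomy_unfiltered": anat_full,
                     "integrated_unfiltered": integ_full},
        "cutoffs": {"ppi": config.ppi_cutoff, "anatomy": anat_cutoff,
                    "integrated": integ_cutoff},
        "weights": weights,
        "results": {"ppi": res_ppi, "anatomy": res_anat, "integrated": res_integ},
        "reconciliation": report,
        "comparison": comparison,
    }
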