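# anatonet

Network-based candidate gene prediction for anatomical entities, by
integrating anatomy-ontology annotations with protein–protein interaction
(PPI) networks.

Model-organism databases annotate genes to anatomy-ontology terms (e.g.
Uberon entities such as *pectoral fin*). `anatonet` turns those annotations
into a weighted **anatomy-based gene network**, integrates it with a
STRING-style PPI network, and ranks candidate genes for an anatomical entity
by a neighborhood statistic — for developmental biologists and systems
biologists who want ontology-aware gene prioritization, and for
methods people who want the evaluation harness around it.

## The method

**Term similarity.** Four semantic similarity measures between ontology terms
over is_a/part_of edges: Resnik (IC of the most informative common ancestor,
normalized by the corpus maximum IC), Lin
`2·IC(MICA) / (IC(t1) + IC(t2))`, Schlicker's relevance similarity
`Lin · (1 − p(MICA))`, and Wang's structure-only measure from
semantic-contribution S-values decayed along edges (0.8 is_a, 0.6 part_of).
Information content is `IC(t) = −ln p(t)` with `p(t)` the fraction of corpus
genes whose ancestor-propagated annotations contain `t`.

**Gene similarity (best-match average).** For genes with profiles
`t(G1) = (t_a1…t_am)` and `t(G2) = (t_b1…t_bn)`:

    sim(G1,G2) = [ Σ_i max_b sim(t_ai, t_b)  +  Σ_j max_a sim(t_bj, t_a) ] / (m + n)

All gene pairs form the unfiltered anatomy-based network; a score cutoff
(chosen so the interaction count matches the filtered PPI network) gives the
filtered view.

**Integration.** Each source network is weighted by its measured prediction
accuracy `AC` (mean per-entity ROC AUC): `W1 = AC1/(AC1+AC2)`,
`W2 = AC2/(AC1+AC2)`, and every edge of the union is rescored
`sim3 = W1·sim1 + W2·sim2` (a missing side contributes 0).

**Prediction and evaluation.** The Hishigaki neighborhood statistic scores a
gene `u` for entity `f` by comparing annotated immediate neighbors `n_f(u)`
with the expectation `e_f = tot_f · n(u) / tot_N`:

    score = sign(n_f − e_f) · (n_f − e_f)² / e_f

Evaluation is per-entity leave-one-out: each annotated gene is held out,
scored with its annotation masked, and ranked against all unannotated genes;
ROC AUC uses the midrank Mann–Whitney formulation and PR AUC the trapezoid
over the precision–recall staircase. Randomization controls (fully randomized
networks; randomized annotation profiles) separate biological signal from
network-size effects.

## Worked example

Everything below runs on the built-in synthetic world: a small anatomy-like
ontology, five planted gene modules annotated within their own subtrees, and
a noisy STRING-style PPI network.

```python
from anatonet import (make_world, filter_network, filter_entities, select_cutoff,
                      evaluate_network, compute_weights, integrate_networks,
                      TermSimilarity, build_similarity_matrix, GeneNetwork,
                      predict_candidates)

world = make_world(seed=1)                      # ontology + profiles + noisy PPI
simfn = TermSimilarity(world.dag, method="wang")
matrix = build_similarity_matrix(world.profiles, simfn)
anatomy_full = GeneNetwork.from_similarity_matrix(matrix)

ppi = filter_network(world.ppi, 0.7)            # STRING 0.7 combined-score cutoff
band = (ppi.n_edges, int(1.5 * ppi.n_edges))    # match the PPI interaction count
anatomy = filter_network(anatomy_full, select_cutoff(anatomy_full, band))

profiles = filter_entities(world.profiles, min_genes=10)
res_ppi = evaluate_network(ppi, profiles, name="ppi")
res_anat = evaluate_network(anatomy, profiles, name="anatomy")
w = compute_weights(res_ppi.mean_roc_auc, res_anat.mean_roc_auc)

integrated_full = integrate_networks(world.ppi, anatomy_full, w)
integrated = filter_network(integrated_full, select_cutoff(integrated_full, band))
res_int = evaluate_network(integrated, profiles, name="integrated")

print(f"weights: W_ppi={w.w_ppi:.3f}, W_anatomy={w.w_anatomy:.3f}")
for res in (res_ppi, res_anat, res_int):
    print(f"{res.network:>10}: mean ROC AUC {res.mean_roc_auc:.3f}, "
          f"mean PR AUC {res.mean_pr_auc:.3f} over {len(res.per_entity)} entities")

entity = world.module_terms[0][0]
print(predict_candidates(integrated, world.profiles, entity, top=3))
```

prints

```
weights: W_ppi=0.482, W_anatomy=0.518
       ppi: mean ROC AUC 0.927, mean PR AUC 0.586 over 35 entities
   anatomy: mean ROC AUC 0.995, mean PR AUC 0.963 over 35 entities
integrated: mean ROC AUC 0.956, mean PR AUC 0.626 over 35 entities
      gene      score
0  g00_006  48.600000
1  g00_016  40.128571
2  g00_015  33.800000
```

The integrated network recovers held-out annotations better than the PPI
network alone (0.956 vs 0.927 mean ROC AUC): the semantic side downweights
the PPI's cross-module false positives. The top-ranked candidates for the
module-0 entity are unannotated module-0 genes — exactly the genes the
planted ground truth says should be predicted.

The same workflow is available from the shell via the `anatonet` console
script (`make-fixture`, `build-net`, `filter-net`, `net-stats`, `reconcile`,
`integrate`, `evaluate`, `predict`, `randomize`, `holdout`, `run-all`); real
data enters as an OBO ontology, a `gene<TAB>TERM1;TERM2;...` profile TSV, a
STRING `protein.links` file and optional ID-mapping/synonym tables. See
`docs/methods.md` for model details and parameter guidance.

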