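# Methods notes

## Model and assumptions

The package operationalizes a guilt-by-association premise: genes regulating
the same anatomical structure are more likely to interact than random gene
pairs, so a PPI network and a semantic network built from anatomy-ontology
annotations carry partially independent evidence about the same latent gene
modules. Integration forms a convex combination of the two edge-score sources
so that interactions supported by both are promoted and one-source-only
interactions must be strong to survive filtering.

Assumptions worth keeping in mind:

- The ontology is a DAG over is_a/part_of; other relations carry no
  similarity signal here and are dropped at parse time (counted in the log).
- Annotation corpora are treated as flat gene→term sets; annotation
  evidence codes, qualifiers and negative annotations are out of scope.
- The Hishigaki statistic uses only the immediate (1-hop) neighborhood and
  counts genes, not edge weights; edge scores matter only through filtering.
- Evaluation assumes unannotated = negative, the usual closed-world
  approximation; true-but-unknown associations depress measured AUC.

## Information content and the similarity measures

IC is computed from the annotation corpus supplied by the caller (normally
the study's own profiles) by ancestor-propagated counting, so `p` is
monotone non-decreasing from child to parent and `IC(root) = 0` whenever all
genes map under one root. Natural log is used; the base rescales Resnik
uniformly and cancels in Lin, and Resnik is normalized downstream, so the
choice is cosmetic. Terms never reached by a propagated annotation get **no**
IC: they are flagged `undefined` and excluded as MICA candidates rather than
assigned a fabricated value.

Resnik's raw score is unbounded, which would make its gene-score scale
incommensurable with the other three measures and with the convex integration
step; the default therefore divides by the corpus maximum IC
(`resnik_normalization="max_ic"`, `"raw"` available). Consequences to know:
normalized Resnik self-similarity is `IC(t)/IC_max`, not 1.

Wang edge decay weights default to 0.8 (is_a) and 0.6 (part_of), the
method's canonical constants; both are configurable. S-values are computed
by maximizing the decay product over paths (memoized recursion over the
ancestor sub-DAG). When several common ancestors tie for maximal IC any
maximizer gives the same MICA-based score, so no tie rule is observable.

## Gene similarity and networks

Gene similarity is the best-match average of Eq form
`[Σ_i max-match + Σ_j max-match] / (m+n)`; it is symmetric by construction
and lies in [0,1] for all normalized measures. Genes without usable profiles
score 0 against everything and enter the analysis only through the PPI side.
The matrix builder computes the term-level similarity matrix once over the
profile vocabulary and then reduces sub-blocks, which is exactly equivalent
to the pairwise definition (tested against the double-loop form at 1e-12).

Networks are simple undirected graphs with scores in [0,1]. STRING combined
scores are divided by 1000 (keeping 700 → 0.700); duplicate A–B/B–A rows
collapse, conflicting duplicates keep the max with a warning. Filtering is
strict (`score > cutoff`) and prunes isolated nodes. A zero score is treated
as absence everywhere (the integration zero-fill rule makes the two
indistinguishable), so zero-score pairs are never materialized as edges.

Cutoff selection targets an interaction-count band via binary search over the
sorted unique scores. At organism scale the band is the absolute
500,000–750,000 window around the 0.7-filtered STRING networks; at fixture
scale the pipeline's `match_ppi` mode uses `(E, 1.5·E)` around the filtered
PPI edge count `E`, the same proportionality. If score ties make every
achievable count miss the band, the nearest achievable cutoff is returned
with a warning rather than an error; only a structurally invalid band is
rejected.

## Reconciliation and entity filtering

Name reconciliation runs three disjoint rounds — direct symbol match, shared
Ensembl identifier, then network-gene synonyms — renaming network nodes to
the profile's symbol in rounds 2–3. Matching is case-sensitive by default
(symbol case is meaningful in model organisms; a fold switch exists). A
profile gene resolving to two distinct nodes aborts with the collision listed
rather than guessing. Entity filtering (default: ≥ 10 annotated genes) is run
to a fixed point; note the fixed point is reached after one effective pass,
because a gene is only dropped once its profile is empty, i.e. it supports no
surviving entity.

## Prediction, LOOCV and AUC conventions

The signed Hishigaki score `sign(n_f − e_f)·(n_f − e_f)²/e_f` is the default:
the plain chi-square form is symmetric around the expectation, which would
rank strongly depleted neighborhoods above mildly enriched ones; the unsigned
form is kept behind `signed=False` for fidelity checks. Isolated genes and
entities absent from the network universe score 0, and such entities are
skipped in evaluation.

Per-entity LOOCV masks the held-out gene's own annotation from both the
neighbor counts and `tot_f`; negatives are all genes of the reconciled
profile universe present in the network and not annotated to the entity,
scored with full annotations. `tot_N` is the network's node count. ROC AUC is
the midrank Mann–Whitney statistic (ties get half credit); PR AUC is the
trapezoid over the scikit-learn precision–recall staircase (which appends the
recall-0/precision-1 endpoint). Both conventions are stated because AUC
values are not comparable across tie/integration conventions. If all scores
for an entity are identical the ROC AUC is 0.5 and a warning is raised.

## The synthetic world

The generator emulates the shape of the real inputs, not their scale: a root
with `n_modules = 5` subtrees (depth 2, branching 2 → 7 terms each, 36 terms
total, 20% part_of edges); 30 genes per module, each annotated to 4 terms of
its module's subtree (expected ≈ 17 genes per term, comfortably above the
10-annotation evaluation filter and leaving ≥ 20 evaluable entities); PPI
edges within modules with `p_in = 0.35` thinned by a false-negative rate
`q = 0.10`, cross-module false positives with `p_out = 0.02`, and integer
confidences uniform on [401, 999] so the 0.7 STRING cutoff removes a
realistic fraction. Everything derives from one `numpy` generator seeded by
the config, so regeneration is bit-identical.

What it does **not** emulate: scale-free degree structure, the heavily
right-skewed STRING score distribution, annotation-depth bias (shallow terms
annotated more often), naming discrepancies (the fixture's names always
reconcile in round 1), and inter-module ontology similarity beyond a shared
root. Passing tests therefore demonstrate correctness of the machinery and
the qualitative integration effect under modular ground truth — not
organism-scale effect sizes.

Randomization controls: the fully randomized network is uniform G(n, m) on
the same node set with scores 1 (endpoint-shuffling would be an alternative
reading of "same nodes, same edges"; uniform resampling was chosen);
randomized profiles keep each gene's annotation count and draw terms
uniformly without replacement from the observed vocabulary (a
frequency-weighted mode is a one-line change but uniform is the
minimal-assumption default). Held-out-entity evaluation reuses the same
cutoff procedure as the main pipeline so comparisons are like-for-like.
Alternate-profile evaluation (e.g. GO-BP profiles) needs no new code:
`evaluate_network` accepts any profile set over any ontology — build the
profiles TSV, restrict to the GO DAG, and evaluate the already-built
networks with it.

## Design choices that were genuinely open

- **Accuracy for the integration weights** is the mean per-entity ROC AUC of
  each filtered source network (`accuracy_metric="pr"` switches to PR AUC).
  Integration itself operates on the *unfiltered* networks while weights come
  from the filtered ones — evaluation requires filtered networks, so the
  asymmetry is inherent.
- **Negative universe** in LOOCV: the reconciled profile genes present in the
  network (not all network genes), keeping the three network types comparable
  on a shared universe.
- **IC corpus**: the user-supplied profiles, not ontology-internal term
  frequencies; this is the reproducible choice and is what the fixtures use.
- **Desk-scale study sizes**: 10 replicate worlds of 150 genes / 36 terms for
  the acceptance study; large enough that ≈ 35 entities per world are
  evaluable and the paired integration-vs-PPI contrast is stable across every
  seed, small enough to iterate quickly.

## Known limitations

- `build_similarity_matrix` is dense O(genes² · profile terms); organism-scale
  runs (10⁴–10⁵ genes) need the chunked/streaming path of the network writer
  and patience, or a coarser gene set.
- The OBO reader handles the term/is_a/relationship/is_obsolete subset that
  anatomy ontologies use; OWL constructs and cross-ontology bridging axioms
  are out of scope.
- Only two networks integrate at a time; multi-source integration would need
  a different weighting scheme.
- PR AUC by trapezoid differs slightly from average precision; comparisons
  should stay within one convention.
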