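# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limits of what the test suite demonstrates.

## Problem setting

A biomedical knowledge graph (KG) is a set of (subject, predicate, object)
facts over typed entities — drugs, proteins, diseases, pathways, protein
complexes, genetic disorders.  Link prediction (LP) asks a model to rank
all candidate entities as completions of (s, p, _) or (_, p, o); a good
model ranks held-out true facts near the top.  The package implements the
full study around this task: six embedding scoring models, the training
regimes that determine their performance, filtered rank evaluation, an
interpretable bottom-up rule learner, and transfer of pretrained
embeddings to small downstream polypharmacy-style tasks.

## Scoring models

All models map entities and relations to d-dimensional real or complex
vectors and score a triple with f(e_s, r_p, e_o); higher is more
plausible (distance models return negated distances):

| model    | domain | score |
|----------|--------|-------|
| TransE   | R^d    | −‖e_s + r_p − e_o‖ |
| TransH   | R^d    | −‖(e_s − w_pᵀe_s w_p) + r_p − (e_o − w_pᵀe_o w_p)‖, ‖w_p‖=1 |
| RotatE   | C^d    | −‖e_s ∘ r_p − e_o‖, \|r_{p,i}\|=1 |
| DistMult | R^d    | ⟨e_s, r_p, e_o⟩ |
| ComplEx  | C^d    | Re(⟨e_s, r_p, conj(e_o)⟩) |
| ConvE    | R^d    | g(vec(g([e_s; r_p] ∗ w)) W) · e_o |

Notable choices:

- **ComplEx conjugation.** The trilinear product is taken against the
  conjugated object embedding.  Without conjugation the score is symmetric
  in (s, o) and the model cannot represent antisymmetric relations — it
  collapses onto DistMult-like behaviour.  A property test asserts that
  ComplEx admits asymmetric parameterizations while DistMult never does.
- **RotatE phases.** Relations are stored as angle vectors θ with
  r = exp(iθ), so the unit-modulus constraint holds exactly at every
  optimizer step rather than being re-projected after each update.
- **TransH normals** are re-normalized to unit length after each step.
- **ConvE specifics** (the formula fixes none of them): the reshaped
  subject and relation embeddings are stacked vertically, convolved with
  32 valid-mode 3×3 filters, rectified, projected back to d, rectified,
  and dotted with the object embedding.  All configurable.
- **Head queries.** Each model scores all candidate subjects of (_, p, o)
  natively; ConvE shares the per-relation feature table across a batch.
  An optional reciprocal-relations mode (separate relation embeddings for
  head queries) exists but is off by default; on the synthetic KG it gave
  no improvement.
- **Distance computations** use the ‖t‖² − 2t·e + ‖e‖² decomposition
  (GEMM) for the L2 norm.  Cancellation can leave a perfect match with a
  distance of order 1e-8 instead of exactly zero; tests use tolerances
  accordingly.  L1 falls back to explicit difference tensors.

All gradients are derived analytically (complex parameters carry
∂L/∂Re + i ∂L/∂Im) and are verified against central finite differences
for every model and both query directions in the test suite.

## Training

The primary objective is **1vsAll with cross-entropy**: each training
triple contributes the CE of the true object under a softmax over all
candidate objects plus the symmetric subject-side term, averaged over the
batch and both directions.  Softmax terms are stabilized by
max-subtraction; with all-equal scores the loss is exactly ln(N_e).
Alternatives: **negative-sampling CE** (binary logistic on k corruptions
per positive) and **negative-sampling margin ranking**
(mean hinge, margin γ), the baseline regime the study compares against.
Corruptions replace exactly one slot; an optional filter resamples
corruptions that are known-true facts, falling back (with a warning)
after 20 rounds on saturated relations.

Optimizers: Adam (default 1e-3) and Adagrad; both update complex tables
through their real views.  The study recipe for the synthetic KG is
Adagrad (rate 0.5) with N3 regularization weight 1e-3 (weighted, applied
to the embeddings each batch touches), batch 512, 100 epochs — chosen
over Adam/cosine alternatives by a small sweep on validation MRR.  The
negative-sampling objectives score triples pointwise (per-triple forward
and backward, never the full vocabulary), so a margin-ranking epoch costs
a fraction of a 1vsAll epoch.  Early stopping monitors filtered
validation MRR on a fixed subsample every few epochs and returns the
best checkpoint seen — never a worse one.  Training is deterministic
given the config seed under single-threaded execution.

The HPO harness draws configurations from a seeded scrambled Sobol
sequence — log-uniform for learning rate and regularization weight,
categorical for embedding size and objective — trains each trial and
scores it by best validation MRR, ties to the earliest trial.

## Filtered evaluation

For each test triple and direction, candidates that would form a
*different* known-true fact (train ∪ valid ∪ test, including augmented
reverses) are removed before ranking; the target always stays.  Ties take
the mean rank of the tied block, so a constant scorer earns exactly the
analytic (N+1)/2 — optimistic and pessimistic variants are available for
diagnosis.  MRR pools (triple, direction) pairs; HITS@k is the fraction
of queries ranked ≤ k.  The evaluator only requires the
`score_all_objects`/`score_all_subjects` contract, so embedding models,
the rule predictor and the planted-ground-truth oracle all run through
identical code, checked rank-for-rank against exhaustive sorting.

## Synthetic data

The generator emulates the statistical shape of a large heterogeneous
biomedical KG without claiming entity-level fidelity:

- **Entities:** 600 by default — 150 drugs, 180 proteins, 120 diseases,
  60 pathways, 50 complexes, 40 genetic disorders.
- **Relations:** 8, each with fixed subject/object classes.  The
  drug-drug interaction analogue (`ddi`) is symmetric and dominant
  (10,000 of 21,600 triples ≈ 46%); `ppi` is symmetric (3,000);
  `drug_target` duplicates `dpi` fact-for-fact under a new label
  (planted redundancy for the ablation study); the rarest relation
  (`complex_pathway`, 100) sits two orders of magnitude below the
  dominant one, matching the log-scale frequency skew of real KGs.
- **Planted ground truth:** entity factors are isotropic complex
  Gaussians in C^16 around a *class center*; relation factors are random
  plus a *schema-aligned bias*, and are real-valued for symmetric
  relations so the planted score is exactly symmetric.  A pair is a fact
  iff Re(⟨e_s, r_p, conj(e_o)⟩) exceeds the relation's threshold, set by
  the target-count quantile; 5% of each relation's facts are replaced by
  uniform random admissible pairs (noise), which score below threshold by
  construction.  Symmetric relations emit both orientations.
- **Class structure in the factors.** Embeddings of typed biomedical
  entities separate by type, and the planted score must reproduce that:
  without it, wrong-class candidates (whose factors are random) routinely
  outrank true completions and even exact factor recovery cannot rank
  well.  Each class pair used by a relation owns a block of latent
  dimensions; on the block of pair (A, B) class A's center has phase 1
  and class B's phase i at magnitude κ (same-class blocks stay real), and
  the relation's bias component b (with b_k = conj(μ_A,k) μ_B,k /
  |μ_A,k μ_B,k|, weight ρ) then gives the relation's own ordered class
  pair a baseline of +κ²ρ per block dimension, the reversed orientation a
  negative baseline, and all other ordered class pairs exactly zero.
  κ = 2.0 and ρ = 4.0 are the smallest values (on a coarse grid) at which
  the oracle self-consistency check below holds across generator seeds.
- **Self-consistency:** an oracle scoring directly with the planted
  factors achieves filtered MRR ≈ 1 and HITS@10 = 1.0 on noise-free
  held-out facts — no schema mask needed; only the query entity itself is
  excluded for same-class relations (self-pairs are inadmissible).
- **Task KGs:** four polypharmacy-style tasks reuse the same entity
  factors under fresh relation factors — two drug-drug effect tasks
  (250 facts per relation), a deliberately small drug-protein target
  task (150 per relation; the low-data transfer scenario), and a larger
  drug-protein expression task (400 per relation) — plus a pool of
  no-interaction pairs that score below every task threshold and collide
  with no pretraining fact.

What the generator does **not** model: multi-relation membership for the
peripheral classes (diseases, pathways and disorders each appear in a
single relation, so their within-class geometry is estimated from ~20
facts per entity — visible as lower per-relation metrics), pathway
hierarchies, literal attributes, and real identifier semantics.  Passing
tests demonstrate recovery of planted low-rank structure under
class/frequency skew, not performance on real biomedical data.

## Splits, reverses, leakage

Splits are seeded shuffles at 80/10/10 (floor for train and valid, the
remainder to test).  Reverse augmentation of the symmetric relations is
applied *after* splitting and only to the training partition; an added
reverse that coincides with a held-out triple is dropped, since for a
symmetric relation it is the same fact and training on it would leak the
label.  The evaluation filter set is the augmented train plus raw
valid/test.  The pre-split augmentation order is available behind the
same API for diagnosis.

## Rule learning

Bottom-up mining: sample a ground path (connected fact sequence) from
the training KG, take the first fact as head and each non-empty prefix
of the remainder as body, and enumerate lawful constant→variable
replacements — constants only in the head and the body atom adjacent to
it, every body atom connected to what precedes it, no unbound head
variables.  Scoring is exact grounding enumeration: occurrences = number
of distinct head-argument instantiations whose body is satisfiable,
confidence = co-occurrences/occurrences (a rule with 150 co-occurrences
over 238 occurrences has 63% confidence).  The mining budget is an
iteration count, not wall-clock time, for reproducibility.  Thresholds
below 1 are confidence cutoffs, values ≥ 1 minimum support counts.
Prediction aggregates firing rules by maximum confidence (ties broken by
the remaining confidences, then entity index) and returns the firing
rules as explanations; a soundness test re-grounds every explanation.

## Downstream experiments

- **Transfer:** ComplEx is trained on a task KG under two arms with
  identical seeds and budgets — entity table initialized from the
  pretraining checkpoint (relation table always fresh, as task relations
  are new labels) versus entirely from scratch.  Reported per arm: final
  filtered MRR/HITS@10, epochs-to-peak, epochs to reach 95% of the arm's
  own best validation MRR, and epochs to reach 95% of the *scratch* arm's
  best — a common bar ("epochs to reach similar or better performance"),
  which is the headline speed comparison: the own-best bar rises with an
  arm's ceiling and so penalizes the arm that transfers better.  Task
  arms train with batch 64 (task KGs hold a few hundred triples) and
  validate every epoch so epoch counts are well resolved.
- **Relation classification:** entity pairs → relation label (plus an
  explicit no-interaction class), one-hidden-layer softmax network over
  concatenated pair embeddings (complex tables flatten to [Re | Im];
  hadamard and sum combinations available).  Arms: pretrained-frozen,
  pretrained-finetuned, scratch.  Metrics are one-vs-rest macro AUROC and
  AUPRC; MAP is the macro mean of per-class average precision, checked
  against hand-computed values on a fixed table.
- **Ablation:** one relation removed at a time, the model retrained with
  the same seed and budget, HITS@10 deltas reported against the full-KG
  baseline, optionally propagated through the transfer tasks.  Deltas
  conflate information loss with a test-composition shift (the removed
  relation's own triples leave the reduced test set), so removals of
  relations with hard queries can show small positive deltas; the robust
  desk-scale findings are that the dominant symmetric relation's removal
  causes the largest drop and the planted-redundant relation's removal a
  strictly milder change — fine-grained ordering among the mild removals
  sits below the evaluation's sampling error.

## Problem sizes and recipes

All study runs are sized for one CPU: the default KG trains ComplEx
(d=32, 100 epochs) in roughly a minute per run.  The acceptance
experiments use the full default KG with 3 seeds for parameter recovery
and ablation and 5 seeds for the objective and transfer comparisons; the
objective comparison uses a short equal budget (20 epochs) for both
objectives, and the ablation runs use 25 epochs per retraining since
only the *ordering* of deltas is asserted.  These sizes are the
package's own desk-scale choices; absolute metric values at this scale
are not comparable to full-scale published numbers on real KGs.

## Known limitations

- The peripheral entity classes are single-relation by design, capping
  aggregate metrics below the planted-oracle ceiling.
- The rule learner's sampling schedule is plain uniform path sampling,
  not a reinforcement-learned schedule; inference cost grows with rule
  count and is not optimized.
- ConvE head-direction training scores all candidate subjects through
  the network and is the slowest path; at desk scale it is feasible but
  it is the first thing to scale down.
- No GPU kernels, no distributed training, no GNN models.
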