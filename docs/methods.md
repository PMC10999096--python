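# Methods

## Problem setting

Structure-based virtual screening ranks a chemolibrary by predicted
binding to a receptor structure. A *target-specific* scoring function is
trained on one target's own bioactivity data and used to rescore docked
poses produced by any docking engine. This package implements the whole
retrospective protocol around that idea — data curation, featurization
of docked complexes, model training with Bayesian tuning, and
early-enrichment evaluation — for data shaped like a ChEMBL export plus
externally docked poses. Docking itself, decoy generation by graph
neural networks, and receptor preparation (protonation, partial
charges) are out of scope: poses and decoys are consumed, not produced,
and interaction typing downstream is rule-based.

## Curation model

A record is one measured potency (compound, assay kind, relation,
value in nM). The pipeline keeps relations `=` (certain) and `>`
(lower-bound censored, the compound cannot be active); `<` and `~` are
discarded. Potencies transform as pIC50 = 9 − log₁₀(IC50 nM), so 1 µM ↔
pIC50 6, the activity threshold (inclusive). Inactives carry a fixed
regression target of pIC50 = 2, far below the threshold, which lets
regressors exploit inactive-enriched training sets.

Aggregation conventions, where the underlying protocol leaves room:

* **Replicate averaging** — arithmetic mean of IC50 in nM, then the log
  transform (`mean_scale="pic50"` averages on the log scale instead).
* **Dispersion filter** — a compound is rejected when the *population*
  SD (ddof = 0) of its replicate pIC50s is ≥ 2 log units. The filter is
  applied per assay kind: biochemical and cellular readouts of the same
  compound differ systematically (cellular potency is typically the
  weaker one) and are not replicates of each other. An SD threshold on
  raw nM would be vacuous at micromolar scale, hence the log scale.
  Both scale choices are configurable.
* **Censored records dominate** — any `>` record marks the compound
  inactive regardless of other values.
* **Assay split** — training: biochemical but not cellular data; test:
  cell-assayed compounds. A test active needs *both* cellular and
  biochemical pIC50 ≥ 6; a test inactive is decided by cellular potency
  alone. A cell-active compound without confirmed biochemical activity
  fits neither rule and is excluded with a log entry. Compounds with
  only binding-affinity (K_d) data are excluded by default
  (`include_binding_only` adds them to training).
* Structure standardization keeps the largest organic fragment,
  neutralizes charges where valid, and canonicalizes the tautomer; the
  pipeline is deterministic and open-source end to end.

## Featurization

All circular-environment identifiers are 32-bit FNV-1a hashes of
canonical byte tuples — never a process-seeded hash — folded by modulo
into the target width. Depth-0 hashes the atom invariants (element,
heavy degree, attached-H count, formal charge, aromaticity, ring
membership); depth-d hashes (d, own depth-(d−1) id, sorted (bond order,
neighbor id) pairs). Environments covering the same atom set are
deduplicated (lowest depth wins, ties by smaller id), which reproduces
the classic circular-fingerprint duplicate rule and makes every scheme
invariant to input atom order.

* **Morgan (ligand-only)** — 512 bits, radius 2 for model features;
  the similarity analyses (dissimilar split, clustering,
  nearest-neighbor) use the field-standard RDKit Morgan fingerprint at
  2048 bits, radius 2.
* **PLEC** — for every heavy-atom interface contact within 4.5 Å
  (closed boundary; the cutoff is configurable since reference
  implementations differ), all pairs of ligand environments at depths
  0..1 with protein environments at depths 0..5 are hashed and folded
  into 4092 bits. A diagonal depth-pairing variant is available behind
  a flag. A contact-free complex yields a valid all-zero vector.
* **GRID** — 2^9 + 3·2^9 + 4 = 2052 counts: folded environment counts
  of ligand and pocket atoms inside the bounding sphere of diameter
  `voxel_width` = 16 Å around the ligand centroid; SPLIF contact-pair
  counts in three distance bins (0–2, 2–3, 3–4.5 Å); hydrogen-bond
  counts per bin (donor = N/O with H, acceptor = any N/O, no partial
  charges); one salt-bridge count (charged N⁺/O⁻ cross pairs ≤ 4 Å).
  Only the total length is externally anchored; the sub-block
  decomposition is this package's documented convention. The bounding
  region is a sphere rather than an axis-aligned box so the vector is
  exactly invariant under rigid rototranslation.
* **Combined** — Morgan ∥ PLEC concatenation (4604 values), always in
  canonical scheme order regardless of argument order.

## Models and tuning

Five learners — random forest, gradient-boosted trees (XGBoost),
support vector machine, and feed-forward networks with one (ANN) or at
least two (DNN) hidden layers — each in a classification variant
(outputs P(active)) and a regression variant (outputs predicted pIC50).
Higher score means better in both modes, so rankings are comparable.

Hyperparameters are searched with a Tree-structured Parzen Estimator:
random start-up (default 10 trials), then candidates drawn from a
Parzen model of the best γ = 25% of trials and scored by the good/bad
density ratio; numeric dimensions use Gaussian kernels (log-space for
log-uniform), categoricals use Laplace-smoothed frequencies. The CV
objective is 1 − PR-AUC for classifiers and RMSE for regressors
(both configurable), over 5 shuffled folds. The entire
tune → fit → score chain is a deterministic function of the seed.
Default budget: 50 evaluations. Repeated-runs experiments refit the
final model under seeds base..base+n−1 (default 10 runs) on the fixed
split and report the median NEF1%; the representative run for PR curves
is the one closest to the median (ties broken by a seeded choice).

## Evaluation conventions

With N molecules, A actives, top fraction f = 0.01 and n_top =
max(1, ⌊fN⌋):

* EF_f = (actives in top n_top / A) / f — the *recall* form. It is
  adopted because its maximum, min(n_top, A)/A/f, reproduces the
  published maxima exactly (3443/67 → 50.75; 3426/57 → 59.65), which a
  precision-ratio form does not; that alternative form remains
  available behind a flag.
* NEF_f = EF_f / maxEF_f ∈ [0, 1]; a random ranking expects
  NEF = 1/maxEF (0.020 and 0.017 at the two compositions above).
* Ties in the ranking are broken by ascending compound id
  (deterministic); a seeded shuffle-within-ties mode exists for
  randomization experiments. Decoys and measured inactives are pooled
  as negatives.
* PR curves and their step-integrated area come from scikit-learn's
  `precision_recall_curve` / `average_precision_score`.
* The dissimilar test set keeps molecules whose *maximum* Tanimoto
  similarity (RDKit Morgan 2048/r2) to any training molecule is
  strictly below 0.70; decoys are filtered by the same rule. Hit
  clustering is single-linkage: connected components of the
  similarity ≥ 0.70 graph, so a chain a~b~c clusters together even if
  sim(a, c) < 0.70.
* Group comparisons: Shapiro-Wilk normality per group, then Welch's
  unequal-variance two-sided t-test; constant groups are flagged
  instead of tested.

## Synthetic fixtures: what they emulate, and what they do not

The generator reproduces the *shape* and *bookkeeping* of the real
inputs, not their chemistry. Toy molecules are valence-respecting
acyclic C/N/O/S graphs embedded sequentially with every bond at 1.5 Å;
"receptors" are shells of labeled pseudo-residues around the ligand,
with about a third of the residues placed ~4 Å outside randomly chosen
ligand atoms so every docked complex has ligand-dependent background
contacts, as real poses do. H-bond donor/acceptor counts are exact by
construction (donors are O-H/N-H leaves, non-donor acceptors are
ethers), which makes property-matched decoys (heavy atoms ±1, donors
±1, acceptors ±1, Tanimoto < 0.4 to the template) cheap to sample by
rejection. The decoy contract is a minimal stand-in for graph-generative
decoy engines: matched in three bulk properties, structurally
dissimilar, never property-matched to *training* actives.

The planted-signal benchmark gives each assayed compound a latent
binder flag B; decoys are non-binders by construction. The anchor triad
(N, O, O placed 3.2 Å from the first three ligand atoms) is present in
a complex iff B, and the activity label equals B with probability
(1 + s)/2, where s = `signal_strength`. At s = 1 features separate
actives perfectly; at s = 0 labels are independent of features. All
randomness derives from one spec seed through counter-based splitting,
so every sub-generator is independently reproducible and a fixed seed
yields a byte-identical bundle.

Passing tests on these fixtures demonstrate that the pipeline's
plumbing, conventions and learners behave correctly and can recover a
known interaction signal at realistic composition ratios. They do not
demonstrate chemical realism: real potency landscapes, pose quality,
decoy bias and scaffold effects are all absent, so performance numbers
on fixtures say nothing about screening performance on real targets.

## Problem sizes used in the checks

The end-to-end recovery check runs the SVM regressor on PLEC features
over a benchmark of about 1,900 test molecules (90 test actives, decoy
ratio 20, signal strength 0.9), 10 seeded runs, with a signal-free
(s = 0) control; the composition check runs the generator at the full
published composition (1565 training compounds, 93 test compounds, 3350
decoys). The cross-algorithm recovery check uses a smaller benchmark
(200 training compounds, decoy ratio 10, PLEC folded to 1024 bits) with
3 runs per learner — sizes chosen so the whole suite stays quick while
the compositions under test keep the study's ratios.

## Known limitations

* The receptor side has no protonation or charge model; interaction
  typing is element/valence rule-based, so GRID's H-bond and
  salt-bridge counts are coarse.
* The own-brand circular fingerprint is not bit-compatible with any
  external implementation (by design — identifiers are FNV-1a); RDKit
  fingerprints are used wherever cross-tool comparability matters.
* MOL2 parsing covers the common Tripos dialect (MOLECULE/ATOM/BOND);
  exotic records are skipped with a warning.
* The TPE implementation is compact and single-objective; it does not
  support conditional (tree-structured) search spaces.
* pIC50 = 2 for inactives is a convention inherited from the protocol
  this package implements; no claim of optimality is made.
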