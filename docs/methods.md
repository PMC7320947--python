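# Methods

This note documents the modeling choices behind `consvote`: what each stage
assumes, which knobs matter, what the synthetic generators do and do not
emulate, and where the design was genuinely open.

## Curation

Records are eliminated in a fixed order: empty or unparseable SMILES first
(both counted as "no SMILES" — the same failure class from the modeler's
point of view), then inconclusive outcomes, then duplicated structures. The
duplicate key is the RDKit canonical SMILES, so equivalent encodings of one
structure collide; a string-identity key would silently miss them. All
copies of a duplicated structure are removed by default, whatever their
labels, because a structure measured twice with conflicting outcomes is
unreliable and one measured twice with the same outcome still biases the
set. `keep_concordant_duplicates=True` offers the common alternative of
keeping one copy when the labels agree. The audit log reconciles exactly:
`n_output = n_input − n_no_smiles − n_inconclusive − n_duplicates`.

Class balancing keeps every active and selects the same number of inactives
by greedy MaxMin diversity picking. Distances are 1 − Tanimoto similarity on
ECFP4/1024 bit vectors (two empty fingerprints count as identical). The
first pick is a uniformly random pool index from the seeded generator; each
later pick maximizes the minimum distance to the selected set, with ties
broken toward the lowest index so a run is a pure function of (pool, k,
seed). Balancing happens before featurization; if later featurization drops
rows, the resulting drift from 1:1 is reported rather than re-balanced.

## Featurization

Three blocks mirror the common multi-representation setup:

* **Descriptors** — RDKit's full 2D descriptor list (≈210 columns:
  physicochemical, topological, fragment counts). 3D descriptors would
  require conformer generation, which is out of scope; the block name keeps
  the conventional "1,2,3D" label only for mapping purposes.
* **ECFP + pharmacophore** — hashed circular fingerprints with diameter 4
  (ECFP4 convention, radius-2 environments) and 1024 bits. Because
  descriptor software families disagree on radius-vs-diameter naming,
  `diameter_is_radius=True` interprets the number literally. The 2D
  pharmacophore-pair fingerprint encodes pairs of typed features (donor,
  acceptor, aromatic, hydrophobe, positive/negative ionizable, from RDKit's
  base feature definitions) at topological distances binned 1–8 bonds plus
  an 8+ tail, 168 bits total. Unit-width bins were chosen so positional
  isomers (para vs meta substitution) map to different bits; wider
  conventional bins do not separate them. Plain alkanes carry no typed
  features and hash to the zero vector.
* **External block** — interaction fingerprints, docking scores or any other
  externally computed numeric table are ingested from CSV and row-aligned to
  the compound set; their generation is out of scope.

Filtering drops constant columns (exact test: column max equals min — a
float std of ~1e−15 from summation order must still count as constant) and
then makes a single left-to-right pass dropping any column whose absolute
Pearson correlation with an already-kept column reaches the limit (default
0.997). Which member of a correlated pair survives is order-dependent by
construction; how many independent signals survive is not. Standardization
(z-score, population sd) is fit on training rows only and applied unchanged
to every other row — fitting on all rows would leak test information into
the scale.

## Splits and learners

`make_splits` draws a stratified 70/30 train/test split, then assigns
stratified 5-fold CV labels *within the training partition*; every fold's
class count is within one compound of the stratified ideal. Running CV
inside the training partition (rather than on the full set) keeps the test
partition untouched by model selection; the report can carry training, CV,
test and external rows side by side.

Two learner families satisfy one contract — active-class probabilities in
[0, 1]:

* **GBT** — `HistGradientBoostingClassifier`, grid over tree depth
  {2, 4, 6, 8, 10}.
* **MLP** — `MLPClassifier`, grid over hidden layers {1, 2} × neurons per
  layer {16, 64, 256}. Any standard optimizer satisfies the contract; the
  search is over architecture, not weight updates.

Grids are brute-force: every point is scored by mean CV AUC and the winner
is refit on the full training partition; ties break toward the simpler
model (smaller depth, fewer weights). A single-point grid skips the search
and just refits. All stage seeds derive from one run-level seed through a
labeled hash, so every stochastic stage replays exactly.

## Threshold optimization

Candidate cutoffs are the unique predicted probabilities plus a sentinel
just above the maximum (the "call nothing active" operating point); there is
no interpolation between ROC points. Class calls are inclusive
(active ⇔ p ≥ t), which makes the smallest probability reproduce the (1,1)
ROC endpoint. The optimum minimizes d = √((1−TPR)² + FPR²); ties break
toward higher sensitivity (screening favours catching actives), then the
lower cutoff. Squared distances are compared in exact integer arithmetic on
the confusion counts — `(fn·N)² + (fp·P)²` — so two geometrically tied
operating points are recognized as tied regardless of floating-point
rounding order. When every probability is equal, only the two trivial
operating points exist and the result is flagged degenerate.

Thresholds are always optimized on training predictions and frozen for
every evaluation set; re-optimizing on evaluation labels would leak label
information into the operating point.

## Consensus

Consensus 1 pools the per-model probabilities row-wise (min/ave/max) and
treats the pooled score as a new classifier. Consensus 2 first thresholds
each model at its *own* optimized cutoff (not 0.5) and keeps only compounds
with unanimous class calls; pooling, ROC and all metrics are then computed
on the kept rows only. Excluded compounds are returned as explicit no-calls
(predicted class −1), never silently dropped — a screening user must see
them. The six-model consensus (both families × three blocks) is the same
operation with M = 6; there is no special casing. The pooled score's own
classification cutoff is re-optimized on pooled *training* probabilities and
frozen thereafter, consistent with the leakage stance above.

## Metrics and reporting

Active is the positive class throughout. MCC uses the standard formula with
the zero-denominator convention MCC = 0; sensitivity and specificity are
undefined (NaN, flagged as missing) when their class is absent rather than
reported as 0. Rendered tables round to two decimals; the JSON report keeps
full precision. By construction FPR = 1 − Sp and TPR = Sn, so at the
optimized cutoff (1−Sn)² + (1−Sp)² equals the optimizer's d² — the test
suite checks this identity across modules.

## Synthetic data

`gen_feature_dataset` draws class-conditional Gaussian blocks: each column
is `√ρ·g + √(1−ρ)·ε` with a row-shared latent `g` (within-block correlation
ρ, default 0.3) and unit marginal variance; the informative columns add
`class_separation · y` plus a per-compound *shared difficulty* latent
(sd 0.9) common to all blocks. The difficulty term is what makes models
trained on different blocks make correlated errors — without it, six
conditionally independent models almost never vote unanimously and the
excluded fraction is unrealistically high (observed 0.65–0.8 versus the
0.3–0.5 regime typical of real multi-representation consensus studies).
Labels are flipped independently with probability 0.08 (assay noise).
Defaults (n = 3000, separation 1.8 with the interaction-fingerprint block at
0.85× as the weakest representation) put held-out primary-model AUC in the
0.75–0.85 band typical of large bioassay classifiers.

`gen_probability_matrix` generates per-model probabilities through a
logistic link over a Gaussian latent: score_m = disc_m·(y−½) + √c·shared +
√(1−c)·noise_m + offset_m. Discrimination controls each model's AUC
(Φ(disc/√2) for the raw score), `c` the inter-model noise correlation, and
the offset miscalibrates a model without changing its ranking. This is the
simplest mechanism giving independent control of AUC, correlation and
calibration.

`gen_toy_smiles` samples from a packaged list of 200 valid aromatic
drug-like SMILES (benzene/pyridine scaffolds × polar substituents × alkyl
chains) and, for n ≥ 6, plants one empty-SMILES row, one inconclusive row
and one duplicate pair (the same structure encoded aromatic and kekulized,
with conflicting labels) so every curation rule is exercised.

What the generators do **not** emulate: real chemical-space geometry,
activity cliffs, assay-specific artifact structure, or the descriptor
distributions of any particular bioassay. Passing tests demonstrate that the
pipeline's logic is correct and that its qualitative behaviour (consensus ≥
median primary model; unanimity voting trades coverage for accuracy) holds
under controlled conditions — not that any particular real screen will reach
the same numbers.

## Problem sizes used in checks

Oracle-equivalence checks run at small n (≤ 50 rows, ≤ 12 fingerprints)
where exhaustive enumeration is exact; distributional checks use n =
5,000–10,000; the end-to-end trend experiment runs 50 seeds of the default
n = 3000 study with single-point grids (GBT depth 6, MLP 1×32) — the grid
search itself is validated separately on small data, and fixing the
architecture keeps the repeated-seed experiment cheap without changing the
consensus logic under test.

## Known limitations

* Descriptor coverage is RDKit's 2D set, not any commercial 3D-aware set;
  absolute AUCs on real data will differ from studies built on richer
  descriptors.
* Pharmacophore fingerprint parameters (feature definitions, bins, length)
  follow documented defaults and are not claimed equivalent to any
  proprietary generator.
* MaxMin is greedy, not optimal diversity selection; its output depends on
  the seeded first pick.
* Consensus 2 errors out when no compound is unanimous or the kept rows are
  single-class; with many weak, weakly correlated models this regime is
  reachable and the error names the cause rather than guessing.
* No probability calibration, weighted fusion or stacking — raw
  probabilities are pooled by design.
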