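# consvote

Consensus binary classification for drug-interaction screening.

High-throughput bioassays (e.g. cytochrome P450 2C9 inhibition screens, where
inhibition flags a drug–drug interaction risk) yield large active/inactive
tables that are noisy, redundant and imbalanced. A single QSAR classifier cut
at probability 0.5 is rarely the best screen. `consvote` implements the full
pipeline that practitioners use to do better:

1. **Curation** — drop records with missing/unparseable SMILES or
   inconclusive outcomes, remove duplicated structures (canonical-SMILES
   key), and balance classes 1:1 by keeping every active and picking an
   equally sized, structurally diverse inactive subset with the greedy
   **MaxMin** algorithm on ECFP Tanimoto distances.
2. **Featurization** — three feature blocks: physicochemical/topological
   descriptors (RDKit), circular **ECFP** + 2D pharmacophore-pair
   fingerprints, and an ingested external block (e.g. protein–ligand
   interaction fingerprints with docking scores). Constant columns and
   near-duplicate columns (|Pearson r| ≥ 0.997) are filtered; surviving
   columns are z-scored with training-row statistics only.
3. **Learning** — gradient-boosted trees (grid over tree depth) and
   multi-layer perceptrons (grid over layers × neurons), selected by mean
   AUC under stratified 5-fold CV nested in a stratified 70/30 split.
4. **Threshold optimization** — for each model the operating cutoff t* is
   the ROC point minimizing the distance to perfect classification,

       d = √((1 − TPR)² + FPR²),   calls: active ⇔ p ≥ t*

   optimized on training predictions and frozen for every evaluation set.
5. **Consensus** — *consensus 1* pools the per-model active-class
   probabilities row-wise (min/ave/max); *consensus 2* first lets each model
   vote with its own optimized cutoff and keeps only unanimous compounds
   (the rest become explicit no-calls), then pools. Performance is reported
   as AUC, MCC, sensitivity and specificity, with excluded-compound ratios.

A synthetic-data module generates multi-block feature tables and correlated
multi-model probability matrices with controllable signal, so the entire
pipeline is testable without external downloads.

## Worked example

Combine four correlated primary models by unanimity voting and inspect the
consensus estimates:

```python
from consvote import ConsensusModel, SyntheticProbSpec, gen_probability_matrix

matrix = gen_probability_matrix(SyntheticProbSpec(n=2000, m_models=4, seed=7))
results = ConsensusModel(matrix, scheme=2).fit()
print(results.summary())
```

```
Consensus 2 (4 primary models, n=2000; active = positive class)
        AUC    MCC     Sn     Sp  threshold      d  n_kept  excluded_ratio  actives_kept_%
mode
min   0.905  0.751  0.875  0.875      0.360  0.176    1019           0.491          49.657
ave   0.911  0.751  0.870  0.881      0.444  0.177    1019           0.491          49.657
max   0.906  0.757  0.864  0.893      0.646  0.173    1019           0.491          49.657
```

Reading the `ave` row: averaging the four models' probabilities over the
1019 compounds on which all models agree gives AUC 0.911; at the optimized
cutoff 0.444 (distance d = 0.177 from the perfect-classification corner) the
consensus catches 87% of actives (Sn) while rejecting 88% of inactives
(Sp). 49% of compounds received conflicting votes and are returned as
no-calls rather than forced predictions — the price of the higher-confidence
calls on the kept set.

`results.predict("ave")` returns the per-compound table (kept flag, pooled
probability, predicted class with −1 for no-calls).

The same stages are scriptable from the shell:

```bash
consvote synth assay --n 200 --out data/
consvote curate --in data/assay.csv --out curated.smi --log log.json
consvote featurize --in curated.smi --blocks descriptors,ecfp_pfp --out blocks/
consvote train --features blocks/ecfp_pfp.csv --labels labels.csv --family gbt --seed 42 --out run/
consvote threshold --probs run/probabilities.csv --out run/roc/
consvote consensus --probs probs.csv --thresholds th.json --scheme 2 --mode ave --out calls.csv
```

## Layout

| module | contents |
|---|---|
| `consvote.curation` | record curation, MaxMin selection, class balancing, assay CSV / .smi I/O |
| `consvote.featurization` | ECFP, descriptor and pharmacophore blocks, correlation filtering, standardization, external-feature ingestion |
| `consvote.learners` | stratified splits, grid training, probability contract |
| `consvote.roc` | ROC curves, AUC, distance-to-corner threshold optimization |
| `consvote.consensus` | probability pooling, unanimity voting, `ConsensusModel` / `ConsensusResults` |
| `consvote.metrics` | confusion metrics (MCC/Sn/Sp) and the structured evaluation report |
| `consvote.synthetic` | synthetic feature tables, probability matrices, toy assay fixtures |
| `consvote.pipeline` | end-to-end study runner |
| `consvote.cli` | `consvote` command-line interface |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
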