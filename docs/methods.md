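# Methods

## The procedure

The package implements a two-stage wrapper for selecting a compact gene
panel that predicts a rare binary phenotype (the motivating case: KRAS
mutation status across lung-cancer cell lines profiled on ~978 L1000
landmark genes, with roughly 24 negatives per positive).

1. **mRMR ranking.** Every gene's continuous expression is discretized into
   three states and genes are ranked by greedy forward selection under the
   difference (MID) objective: relevance `I(g, t)` minus the mean mutual
   information with already-selected genes. The first gene is simply the
   relevance argmax (the redundancy term is defined as 0 for an empty
   selected set). The top 200 ranked genes move on.
2. **Incremental feature selection.** For each classifier family and each
   prefix size k = 1..200, leave-one-out cross-validation produces a
   confusion matrix, from which sensitivity, specificity, accuracy and MCC
   are computed. The MCC-vs-k curve's peak (ties to smaller k) is the
   family's panel; the highest peak across families is the final selection.

### Assumptions

- The phenotype is binary and both classes are present; the positive class
  is declared explicitly, never inferred.
- The ranking is computed **once on the full dataset, outside the LOOCV
  loop**. Cross-validation covers classifier training only. This mirrors
  the classical two-stage protocol, but it means the reported MCC is
  optimistic about generalisation to samples that did not inform the
  ranking (feature-selection bias). Anyone using the numbers for external
  claims should nest the ranking inside the CV loop or hold out a
  validation set.
- Expression values are used as-is: no normalisation, no per-feature
  scaling in the classifiers (an optional z-scaling switch exists on
  `ClassifierSpec` for sensitivity analysis).

## Tunable parameters

| parameter | default | units / range | rationale |
|---|---|---|---|
| `threshold_sigma` | 0.5 | per-gene sd | three-state discretization at mean ± t·sd, the scheme of the classical C/C++ mRMR tool; exposed because the optimum is data-dependent |
| `top_n` | 200 | genes | stage-1 cut; prefixes beyond ~200 genes add redundancy faster than signal |
| `max_k` | `top_n` | genes | IFS sweep bound, capped at the ranking length for small runs |
| kNN `n_neighbors` | 1 / 3 / 5 | neighbours | the three kNN families; odd k means no vote ties with binary labels |
| SVM | RBF, C=1, gamma=1/n_features | — | the classical libsvm-style defaults |
| decision tree | `min_samples_split=20` | samples | CART-style stopping, matching rpart's default split threshold |
| neural net | 1 hidden layer × 8 units, lbfgs | — | the classical single-hidden-layer formulation; quasi-Newton training is stable and fast at these sample sizes; seeded |

Mutual information is the plug-in (maximum-likelihood) estimate in bits
with the 0·log 0 ≡ 0 convention and no small-sample bias correction. The
plug-in estimator is positively biased at small n — visible in the null
model, where the mean relevance of pure-noise genes shrinks toward zero as
n grows but never reaches it. Ranking is invariant to the log base.

## Numerical choices

- **Tie-breaking in the greedy argmax:** candidates whose scores are within
  1e-10 of the step maximum are treated as tied and the lowest input gene
  index wins. The tolerance exists because mathematically equal candidates
  (exact duplicates, permuted-state copies) produce scores that differ only
  in float round-off; without it the selection would depend on summation
  order.
- **IFS peak ties** go to the smaller prefix (parsimony); across families,
  equal peak MCCs go to the smaller panel, then declaration order.
- **MCC with a zero denominator factor** (degenerate predictor or
  degenerate truth) is defined as 0.
- **Zero-variance genes** discretize to the all-medium state, get zero
  relevance, and can never be ranked first unless every gene is constant.
- **Values exactly on a discretization threshold** go to the medium state
  (strict inequalities); affine invariance of the discretization holds
  except exactly on a boundary, where float rounding decides.
- **kNN LOOCV fast path:** leaving sample i out and predicting it with kNN
  is exactly a k-nearest vote among the other N−1 points, so the IFS loop
  computes one pairwise squared-distance matrix and updates it
  incrementally per added feature instead of retraining N models per
  prefix. The test suite asserts bit-identity of this path with naive
  per-fold retraining.
- **Checkpointing:** per-(family, k) confusion counts can be appended to a
  TSV; a resumed IFS build is identical to a fresh one because each record
  is a deterministic function of its inputs.
- Metrics are reported to 3 decimal places; full precision is kept
  internally.

## The synthetic-data generator

`SyntheticConfig`/`generate` emulate the statistical structure the analysis
assumes, at the study's scale by default: 978 genes, 156 positive and 3582
negative samples (~4% prevalence, scalable down). Per gene, values are
Gaussian with sd `noise_sd`; informative genes gain a mean shift of
`effect_size · noise_sd` in positives; each redundant gene is an
informative parent's values plus Gaussian noise whose sd is calibrated from
the parent's empirical variance so the pair's correlation hits
`block_correlation`. Output is bit-reproducible under the seed.

What it does *not* emulate: bead-array technical artifacts, heavy-tailed or
multimodal expression distributions, correlated noise across samples,
batch effects, or any perturbation structure. Tests passing on this
generator therefore demonstrate that the algorithmic machinery is correct
and that the pipeline recovers planted Gaussian mean-shift signal; they do
not certify performance on real expression data.

Scaled-down study conditions used by the end-to-end checks (chosen to keep
a laptop-scale run while preserving the 1:9 imbalance direction and a
realistic signal density): 120 genes, 60 positive vs 540 negative samples,
8 informative genes at a 2-sd shift for recovery; 30 genes, 50 vs 200
samples, one informative gene with a 0.95-correlated near-duplicate for
redundancy demotion.

## Design choices that were genuinely open

- **Discretization scheme**: nothing in the two-stage protocol fixes how
  continuous expression becomes discrete for MI. The mean ± 0.5·sd
  three-state scheme of the classical mRMR software is the default here;
  results on real data shift with the threshold, which is why it is a
  config knob and why full-scale reproductions should expect qualitative,
  not exact, agreement.
- **MID vs MIQ**: the difference form of the objective is implemented; the
  quotient variant is not.
- **Classifier prefixes use continuous values**, not the discretized
  states: the discretization exists only to make MI estimable, while the
  classical kNN/SVM implementations of this pipeline operate on raw
  expression.
- **No class reweighting** in any classifier: imbalance is handled by
  reporting MCC, not by changing the learners.

## Known limitations

- LOOCV with non-kNN families is genuinely O(N) model fits per prefix;
  full-scale six-family sweeps at N ≈ 3700 are expensive (the CLI exposes a
  family subset flag, and kNN families use the fast path).
- The selection-bias caveat above applies to every reported curve.
- The plug-in MI estimator's bias grows with state-space size; with three
  expression states and binary labels it is mild but non-zero.
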