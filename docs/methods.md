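# Methods

## Overview

The package estimates the continuous outcome of a protein functional assay
(an endophenotype) for missense variants from five molecular features, and
derives pathogenic/benign calls from the estimate via published assay
thresholds. All models are protein-specific: a dataset holds a single
protein, and pooling across proteins is refused at the data layer.

## Features

Two features are conservation descriptors computed from a multiple sequence
alignment (MSA) of the protein's orthologs or homologs, at the alignment
column holding the variant position:

* Shannon entropy `H = −Σᵢ pᵢ ln pᵢ` over the column's amino-acid
  frequencies. Implemented with the conventional non-negative sign, so a
  fully conserved column scores 0 and the maximum is `ln 20 ≈ 3.0`.
* The PSSM element for the native residue, `ln(f_nat,col / f_nat,msa)`:
  positive where the native residue is enriched in its column relative to
  the alignment background.

Conventions: natural logarithms throughout (any fixed base rescales the
features uniformly and is absorbed by the regression coefficients); gaps are
excluded from both the column frequencies and the alignment-wide background;
when the native residue is absent from its column, its column frequency is
floored at `1/(depth + 1)` — a minimal pseudocount that keeps the log-ratio
finite while staying below the smallest observable frequency. A native
residue absent from the entire alignment has no defined background and is an
error. FASTA input is validated strictly: only the 20 canonical amino acids
plus gap (`-`, with `.` normalised to `-`); ambiguity codes such as `X` are
rejected rather than silently coerced, since they would corrupt the
frequencies. Protein positions are 1-based; alignment columns are 0-based
internally and 1-based in all user-facing output.

Three features depend only on the replacement: the BLOSUM62 entry for the
(native, mutant) pair, and differences (always mutant − native; the sign
convention is arbitrary and absorbed by the coefficients) on two residue
property scales shipped as package data — van der Waals side-chain volumes
(Richards 1974, via Creighton 1993) and the Kyte–Doolittle hydropathy index
(1982). Both scales are user-overridable via a two-column text file, since
several volume/hydrophobicity tabulations circulate in the literature.

Feature vectors come in two sizes: *three* (BLOSUM62, entropy, PSSM) and
*five* (adding the two property deltas); the three-feature vector is an
exact prefix of the five-feature one.

## Regression models

Five families: MLR (ordinary least squares), Ridge, Lasso, ElasticNet and
RBF kernel ridge, all via scikit-learn. Hyperparameters are tuned by grid
search minimising cross-validated mean squared error on the training set
only — leave-one-out CV for the penalised linear families, 3-fold CV
(shuffled, seeded) for the kernel family. Grid ranges: Ridge α ∈ [0.05,
100]; Lasso α ∈ [0.05, 5]; ElasticNet α ∈ [0.05, 5] with l1_ratio ∈ [0.1,
1]; kernel α ∈ [0.01, 5] and γ ∈ [0.1, 10]. Density is a package choice: 20
logarithmically spaced α values and 10 evenly spaced l1_ratio/γ values,
user-overridable. Exact CV-score ties are broken toward the largest α
(strongest regularisation), then the smallest γ — deterministic and
favouring simpler models.

The penalised and kernel families operate on z-scored features with the
scaler fit on the training set only (penalty terms are scale-sensitive;
training-only fitting prevents leakage). MLR uses raw features, and a
rank-deficient design raises an error by default (an opt-in minimum-norm
fallback exists; silent pseudo-inversion hides data problems). The intercept
is always included for the linear families; kernel ridge has no explicit
intercept and relies on the standardisation. Fitted models are reduced to
plain arrays (coefficients, or dual coefficients plus the scaled training
features), so prediction is a pure numpy computation and models serialise
to JSON.

LOOCV of a model specification performs exactly *n* fits, with tuning nested
inside each fold; the held-out record never influences its fold's scaler,
grid search or fit.

## Train/test plans and resampling

Plans are defined by their rules, not by realized sizes: LOOCV (train and
test sources coincide), a seeded random split (default 75/25,
`round(fraction·n)` training records), or independent sources, in which case
variants shared between train and test are removed from the training set.
Disjointness of the realized sets is verified at run time. Variant identity
is `(protein, position, native, mutant)`; all data are protein-level.

Random under-sampling balances the training set before fitting: records are
classified by a score→class rule (for SGE: pathogenic < −1.328,
benign > −0.748, strict inequalities — boundary scores are intermediate),
intermediate records are dropped, and each remaining class is downsampled
without replacement to the minority count, deterministically per seed.
`imbalanced-learn` is not a dependency; the resampling procedures are
implemented here directly (seeded numpy; SMOTE below).

## Binarization

Estimates become calls via threshold schemes. SGE is three-class: estimates
inside (−1.328, −0.748) are *unknown* and excluded from performance
computations. The HDR schemes are two-class (BRCA1: 0.53; BRCA2: 2.25); an
estimate exactly at a two-class cut is called benign so that every estimate
receives exactly one call and *unknown* can only arise from the SGE band.
Only the BRCA2 cut value is published, not its direction; the default —
below 2.25 → pathogenic — follows the BRCA1 HDR rule (loss of function
lowers repair activity) and can be flipped with a `direction` override.

## Baseline classifiers

Feature-identical classifiers trained on binary labels rather than assay
scores. Random Forest "defaults" are pinned explicitly for reproducibility
across library versions: 100 trees, unlimited depth, √p candidate features,
Gini impurity. The neural network has one hidden layer of 5 units; the
remaining details are unpinned in the source material and fixed here as
ReLU activation, the Adam optimiser, at most 1000 iterations, seeded.
Training folds are balanced by SMOTE minority oversampling — synthetic
points `x + u(x_nn − x)`, `u ~ U(0,1)`, with `x_nn` one of the 5 nearest
neighbours within the minority class (fewer for small classes; a singleton
is duplicated) — applied strictly per training fold so a held-out variant
never influences the synthetic points.

## Performance assessment

Pathogenic is the positive class everywhere. Six metrics are computed from
the confusion counts: sensitivity, specificity, accuracy, MCC, PPV, NPV.
Degenerate denominators are flagged, not hidden: MCC with any zero marginal
is reported as 0.0 with an `mcc_degenerate` flag; a conditional rate with no
observations (e.g. PPV with TP+FP = 0) is NaN with a flag. Continuous
estimates are assessed with Spearman's rank correlation (average ranks for
ties; large-sample t-approximation for the p-value, via scipy). The
discordance listing reports variants on which exactly one of two call sets
is correct, carrying the continuous estimate for audit.

## Synthetic data generator

No assay data or curated alignments ship with the package; the generator
makes the structure the analyses assume explicit:

* **Alignment**: reference row uniform over the 20 amino acids; each other
  row mutates each column independently with a per-column rate drawn once
  from Beta(0.6, 1.4), substitutions uniform over the alphabet; no gaps by
  default (a gap-rate option exists). Columns therefore span fully conserved
  to near-uniform.
* **Variants**: sampled without replacement from all 19·L substitutions,
  with features computed by the real feature modules. The assay score is
  `β₀ + βᵀx + ε`, `ε ~ N(0, σ²)`, with β = (−0.40, 0.12 BLOSUM62, 0.55
  entropy, −0.50 PSSM, 0.0004 ΔV, −0.004 ΔKD): conservation carries the
  signal and the two property deltas are near-negligible by design, so
  three- and five-feature fits perform indistinguishably.
* **Noise**: σ = 1.15, calibrated once (scripted) so that a correctly
  specified linear fit at the default conditions (n = 500 variants,
  150-residue protein, 40-row alignment) reaches a median held-out Spearman
  ρ ≈ 0.55 — the moderate-accuracy regime the method operates in.
* **Class structure**: sampling is steered so 70% of variants have noiseless
  scores above the benign threshold and 30% below the pathogenic one
  (candidates inside the band are not sampled); clinical labels are the
  thresholded noiseless scores with a 5% flip rate for annotation noise.
  Observed (noisy) scores still land in the intermediate band near the
  thresholds, which is what exercises the unknown/intermediate machinery.

What the generator does **not** emulate: phylogenetic correlation between
alignment rows (rows are conditionally independent given the column rates),
position clustering of variants in functional domains, assay-specific error
structure (heteroscedasticity, batch effects), and any nonlinearity in the
feature→score map. Passing tests therefore demonstrate the correctness and
the qualitative behaviour of the machinery — parameter recovery, the
specificity/sensitivity imbalance on benign-heavy data and its mitigation by
under-sampling — not performance on real mutational-scanning data.

## Problem sizes used by the test suite and acceptance script

Synthetic studies use the default conditions above. Parameter recovery and
held-out correlation use 100 replicates at n = 500; the binarized-call
comparison uses 50 replicates (25 in the acceptance script) at n = 400–500
with 75/25 splits; the tuned families (grid search with nested LOOCV) are
run on single splits. These sizes are the package's chosen defaults for a
single-workstation run and can be raised freely through `SimulationConfig`.

## Known limitations

* The binarized-call evaluation is against assay-derived classes of held-out
  noisy scores; with truth taken from noiseless labels a correctly specified
  model recovers them almost perfectly, which is uninformative about the
  imbalance behaviour.
* Kernel ridge stores its (scaled) training features in the model file, so
  serialised kernel models grow with n.
* The Spearman p-value uses the large-sample t-approximation; it is
  inaccurate below n ≈ 10 (exact permutation p-values are not implemented).
* No genomic coordinates, transcripts or HGVS parsing: variants are
  protein-level only.
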