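# Methods

## Scope and model

`fpqsar` implements a ligand-based QSAR regression workflow for potency
prediction from substructure fingerprint counts. The response is pIC50 =
−log₁₀(IC50/M); the design matrix is a compounds × descriptors table of
nonnegative integer substructure counts (the PaDEL SubFPC family or any
table in the same dialect). The workflow assumes a single protein target,
independent compounds (no explicit handling of congeneric-series
clustering at the modelling stage), and additive descriptor effects only
insofar as the learners can represent them — the model families themselves
(trees, forests, RBF-SVM, multilayer perceptron) are nonparametric.

## Curation rules

Records are kept when standard_type is IC50 (case-insensitive), the
relation is "=" or absent, the value is a finite positive number, and the
unit is a recognized molar concentration (pM … M). Qualified values
(">", "<", "≥", "≤") are removed rather than imputed: a bound is not a
measurement. Replicates per compound are combined by the median of their
pIC50s; if the replicate range exceeds a concordance threshold (default
1.0 log unit) the compound is dropped entirely, since discordant assays
carry no usable consensus. Activity classes default to active ≥ 6.0 /
inactive ≤ 5.0 pIC50 (the conventional 1 µM and 10 µM cut points); both
are configurable and used only for descriptive chemical-space summaries,
never in modelling. SMILES standardization is a pluggable hook with a
pass-through default; the package deliberately ships no structure
normalization of its own.

## Collinearity filter

Pearson correlation is computed on the full descriptor table (before any
data splitting, so every split sees the same feature set). Zero-variance
columns are removed first (their correlation is undefined). Then, while
any pair exceeds the cutoff (default 0.7) in |r|, the worst pair is found
and the member with the larger mean absolute correlation against all
surviving columns is dropped; ties drop the later column in input order,
making the filter fully deterministic. Pairs with |r| exactly at the
cutoff are retained (strict trigger). The surviving set's maximum
off-diagonal |r| ≤ cutoff is asserted on every run. This greedy heuristic
is non-exhaustive — it does not search for the largest admissible subset —
but it is order-stable and auditable: every removal records the partner
and |r| that triggered it.

## Modelling protocol

100 independent 80/20 splits at full scale (|train| = round(0.8·n));
every statistic is reported as mean ± sample sd (ddof = 1) across splits.
Within each split, models are fit on the training portion only; pooled
k-fold cross-validation (default k = 10) runs on the training portion, so
the test set never influences fitting, fold assignment, or tuning.

Defaults per family (all configurable):

* **DT** — CART with cost-complexity pruning; candidate α values from the
  pruning path (subsampled to ≤ 20), scored by internal 5-fold CV, chosen
  by the 1-SE rule (sparsest tree within one standard error of the best).
  min_samples_leaf = 5.
* **SVM** — ε-SVR, RBF kernel, cost 1, γ = 1/p, ε = 0.1.
* **DNN** — multilayer perceptron (64, 32) with ReLU, adam, squared-error
  loss, up to 300 epochs with early stopping on a 10% validation split.
  Inputs are standardized and the target centred/scaled inside the
  adapter: networks do not train usefully on raw count features and a
  pIC50-scale response. Topology and optimizer are package defaults — no
  canonical architecture exists for this problem.
* **RF** — 500 trees at full scale; mtry either fixed or tuned per split
  by pooled-CV Q² over the deduplicated grid {⌊√p⌋, ⌊p/3⌋, ⌊p/2⌋, p},
  ties to the smaller value.

All randomness flows from explicit integer seeds; child seeds are derived
with a small deterministic hash so that stages never share streams.

## Statistics

R² is the squared Pearson correlation of observed and predicted values —
the form that underlies experimental-vs-predicted plots and the rm²
machinery. The 1 − SSE/SST form is exposed separately
(`press_q_squared`) and can go negative; reports state which is used
where. Q² denotes the R² of pooled out-of-fold predictions (one
prediction per sample, each from a model that never saw it), not a
per-fold average: pooling gives a single well-defined statistic. The rm²
pair uses the origin-constrained slope k = Σyŷ/Σŷ²; the reported rm² is
the mean of the forward (y on ŷ) and reverse (ŷ on y) metrics and Δrm²
their absolute difference. Negative (r² − r0²) arising from floating
error on near-perfect fits is clamped to zero before the square root.
For weak models rm² can legitimately go negative — the origin-constrained
fit of shrunken predictions on observations is poor in the reverse
direction — which is exactly the insensitivity-to-chance behaviour the
metric is built for. Acceptability predicates (R² > 0.6, Q² > 0.5,
rm² > 0.5, strict) are pure functions reported alongside the numbers.

## Y-scrambling

The real point is (training R², pooled k-fold Q²) on the intact response;
each permuted point repeats both computations after an independent
uniform shuffle of y against the fixed descriptor matrix. For random
forests the "training" R² is computed from out-of-bag predictions: a
forest nearly interpolates the samples it trained on, so its literal
resubstitution R² stays near 1 even on permuted responses and would be
uninformative; OOB resubstitution is also what classical RF
implementations return for training-set predictions. A real
structure–activity relationship shows the real point strictly dominating
the permuted cloud in both coordinates; a spurious one leaves it inside
the cloud.

## Applicability domain

Leverages are hat-matrix diagonals of the intercept-augmented,
correlation-filtered training design, computed via QR decomposition
(never an explicit inverse; rank deficiency is an error directing the
user back to the feature filter, since leverage is undefined on a
singular design). The warning leverage is h\* = 3(p+1)/n with p the
number of descriptors used for modelling and n the training-set size.
Standardized residuals divide by the training residual sd (ddof = 1),
which is reused to standardize test residuals — no leave-one-out
studentization, matching the plain ±3 band convention. Both thresholds
are strict; boundary compounds are in-domain.

## Importance

"Gini" importance for regression forests is the total node-variance
decrease credited to a feature, summed over a tree's nodes (sample-
weighted, rescaled by training-set size so it equals the tree's RSS
reduction) and averaged over trees — the regression analogue of
classification Gini, reported raw (unnormalized) so magnitudes are
comparable across runs and to node-purity importances from classical RF
implementations. Per-split scores from the protocol are aggregated to
mean ± sample sd; ranking is by descending mean with lexicographic
tie-breaks. The SubFPC name → substructure description table ships as a
static resource for annotation.

## Clustering

Binning clustering is realized as the connected components of the
threshold graph with an edge wherever pairwise Tanimoto similarity ≥ the
cutoff (default 0.8) — single linkage at the cutoff: a compound similar
enough to any member joins the bin. Tanimoto is computed on
presence/absence bits by default; the count-based min/max variant is
available behind a flag for sensitivity analysis. Singletons and clusters
under the retention size (default N ≥ 20) are dropped; retained clusters
are summarized (mean ± sample sd of pIC50, MW, ALogP) and prioritized by
mean-pIC50 excess over the whole-dataset mean, ties to larger N then
smaller id. Raising the cutoff can only refine the partition, never merge
bins.

## Synthetic data

The generator emulates the *shape* of a curated kinase-inhibitor study,
not its chemistry:

* **Counts** — independent Poisson(λ = 2) truncated at 10 per cell,
  matching the small-integer character of substructure counts; λ and the
  cap are configurable. Real fingerprints have correlated, zero-inflated,
  hierarchically structured columns; synthetic base columns are exchange-
  able and independent except for planted collinear blocks.
* **Collinear blocks** — a duplicate is its source plus rounded Gaussian
  jitter; the jitter sd is solved from r = σₓ/√(σₓ² + σₑ²) and shrunk
  geometrically until the empirical correlation meets the target
  (rounding and clipping eat correlation, so the analytic solution is a
  starting point, and the result is re-verified after generation).
* **Response** — sparse linear signal over chosen informative columns
  plus Gaussian noise; the intercept is anchored so mean pIC50 ≈ 6.5
  (cosmetic realism, configurable). `noise_sd_for_r2` solves the noise
  level for a chosen noiseless-signal ("oracle") R² from the variance
  decomposition R² = V/(V + σ²).
* **Raw records** — planned, exactly counted contamination: non-IC50
  endpoints, qualified relations, and missing values (removed by
  curation); micromolar-unit records and within-concordance replicates
  (kept). The planned survivor and unique-compound counts are returned as
  ground truth, which is what makes curation accounting exactly testable.
* **Clusters** — each planted cluster owns a disjoint bit region with a
  120-bit prototype; members flip d bits with d bounded by
  (k − 2d)/(k + 2d) ≥ target, so every within-cluster pair provably meets
  the similarity target while all cross-similarities are 0. Pairwise
  similarities are brute-force verified before the matrix is returned.
  A target below the 0.8 cutoff triggers a warning (unrecoverable by
  design). Cluster potency offsets are planted on top of the base mean.

Because synthetic compounds carry no structures, SMILES columns are empty
and no chemistry-level curation (salt stripping, tautomers) is exercised;
passing tests demonstrate the statistical machinery, not robustness to
structural noise in real extracts.

## Problem sizes and numerical choices

Full-scale defaults (100 splits, 10 folds, 500 trees, 100 permutations,
cutoffs 0.7 / 0.8, retention N ≥ 20) are the package defaults. The test
suite and the acceptance script run the same code at desk scale — the
package's own choice of economical but statistically meaningful sizes:
n = 300 / p = 50 / 10 splits for the end-to-end run, n = 1000 with 5
informative of 50 features at oracle R² = 0.8 for signal recovery
(20 seeds), n = 500 for null calibration, n = 250 with 50 permutations
for Y-scrambling. Monte-Carlo assertions fix their seeds; the null-
containment check votes over three independent replicates because any
single percentile assertion on an exchangeable null fails at its nominal
rate by construction.

Ties, boundaries, and degenerate inputs are all pinned down: strict
inequalities at AD and acceptability thresholds, boundary |r| = cutoff
retained, constant vectors rejected by correlation-based statistics
(undefined, not 0), empty fingerprint pairs rejected by `tanimoto` but
given similarity 0 inside the pairwise matrix so clustering never
crashes, and rank-deficient AD designs raised as errors rather than
silently regularized.

## Known limitations

* The correlation filter is greedy, not optimal; a different removal
  order could keep a larger admissible subset.
* rm²'s forward/reverse average is one of several conventions in the
  external-validation literature; the forward-only variant is available
  via the one-way internals.
* The DNN is a small MLP, not a tuned deep architecture; it exists to
  compare model families under one protocol, not to maximize accuracy.
* Binning clustering at a single cutoff is sensitive to chaining through
  borderline pairs; the synthetic clusters avoid this by construction,
  real data may not.
* Leverage-based AD assumes the descriptor space is meaningfully
  Euclidean after filtering; it does not detect activity cliffs or
  assay-condition shifts.
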