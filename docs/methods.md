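# Methods

## Deconvolution model

Bulk methylation is modelled as a weighted mixture of cell-type signatures:
E[Yᵢ] = wᵢμᵀ with wᵢ on the simplex-with-slack {w ≥ 0, Σw ≤ 1}. The slack
(1 − Σw) absorbs cell types present in the tissue but absent from the
reference; estimates are therefore *not* renormalized to sum to one. μ is
estimated by the per-cell-type mean beta matrix **M** computed from purified
reference samples over the library CpGs.

Per sample, min‖Y − Mw‖² over the constraint set is a convex quadratic
program in K variables. Because K is the number of cell types (≤ ~10 in
practice), it is solved **exactly by active-set enumeration**: for every
subset of fractions allowed to be positive, with the sum constraint either
slack or tight, the equality-constrained least-squares solution is computed
(≤ 2·2ᴷ small solves) and the feasible candidate with the smallest residual
is returned. The optimum of a convex QP lies at one of these active sets, so
no iterative solver or tolerance tuning is involved; a KKT-residual check
(contract: < 1e-6 relative) guards the result, and a rank-deficient
signature matrix triggers a non-identifiability warning rather than an
error.

Accuracy metrics: per cell type, R² is the squared Pearson correlation
between true and predicted fractions across samples ("proportion of
variation explained"); RMSE is computed on the percentage scale
(fractions × 100), so an RMSE of 2.0 means two percentage points of average
error; MSPE τ² = RMSE². Means over cell types are unweighted.

## Dispersion separability

For a CpG set, Db\* holds the K(K−1)/2 Euclidean distances between
cell-type centroids (fixed lexicographic pair order so serialized summaries
are reproducible) and Dw\* the per-type mean of sample-to-own-centroid
distances, d_wk = (1/n_k)Σᵢ c_ik — an unweighted mean with no n−1
correction. The Modified DSC is min(Db\*)/min(Dw\*). Distances are computed
on beta values directly (no M-value/logit transform). Properties: invariant
to sample permutation and to positive scaling of the data; undefined (an
error, not +∞) when min(Dw\*) = 0, which can only arise from duplicated
samples or single-sample groups and would otherwise let the search diverge.

The classic batch-effect DSC is included for reference as
trace(S_b)/trace(S_w) with sample-share weighting:
S_b = Σₖ (n_k/N)(c_k−c̄)(c_k−c̄)ᵀ and
S_w = Σₖ (n_k/N)·(1/n_k)Σᵢ(x_ik−c_k)(x_ik−c_k)ᵀ. Only the traces are formed
(never the J×J matrices). It plays no role in the search.

**Leave-one-out contributions.** MDSC₋ⱼ (the score with CpG j deleted) is
needed for every library member at every search iteration. Squared Euclidean
distances are additive over CpGs, so each CpG's share of every squared
pairwise-centroid distance and every squared sample-to-centroid distance is
precomputed once; deleting CpG j subtracts one row before square roots and
minima are re-taken. The whole LOO vector costs O(J\*(K² + N)) per
iteration, and tests enforce equality with naive recomputation to 1e-10.

## The search

- Step 0: one-vs-rest two-sample t statistics per CpG and cell type
  (pooled-variance by default, the classical purified-reference screen;
  Welch available via a flag). Zero-variance CpGs get t = 0 so constant
  probes can never rank as DMLs. The pool Q takes the L/2 most positive and
  L/2 most negative CpGs per cell type; a CpG claimed by several types
  enters once (P ≤ LK), since duplicates in a probability vector are
  incoherent. Ties in the rankings break by CpG id (stable).
- Step 1: J\* CpGs are drawn without replacement with probabilities π.
  Sampling uses Gumbel top-k keys, which is distributionally identical to
  sequential draws with renormalized weights (Plackett–Luce) but vectorized;
  a test checks empirical inclusion frequencies against exhaustive
  enumeration of sequential draws. In random-size mode J\* is redrawn
  uniformly on [j_min, j_max] at every iteration.
- Steps 2–4: compute MDSC and the LOO vector; members get
  π_j ← π_j·(MDSC/MDSC₋ⱼ); non-members are not updated; then all P
  probabilities are floored at ε = 1e-12 and rescaled to sum to one. The
  floor prevents multiplicative underflow from permanently deleting a CpG
  from the search space. Iterations with degenerate within-dispersion are
  skipped with probabilities untouched (logged, NaN in the trace).
- Step 5: the running best library (strictly larger MDSC replaces; ties keep
  the earlier iteration) is returned with a full per-iteration trace.
  Identical seed, config and inputs reproduce the result bit for bit.

Typical production settings are 100,000 iterations with either a fixed size
in {72, 120, 180, 240, 300, 360, 540} or a random size in [50, 1500]
(capped at P); tests and the acceptance script use a few thousand
iterations on a few hundred candidates, where the enrichment behaviour is
already unambiguous.

## Simulators

**Proof-of-principle generator.** 100 features, 3 cell types, 6 samples
each. A fraction of features is "differential": each such feature
independently assigns the mean triple (0, +Δ, −Δ) to the three cell types
in a uniformly random order; everything else is standard Normal. The
per-feature random assignment makes the expected squared distance between
any two cell-type centroids J_diff·2Δ² + 2J/n (the +Δ/−Δ pair contributes
4Δ² with probability 1/3, Δ² otherwise), which a test verifies by Monte
Carlo. The default DSC grid is 21 differential fractions (0–100% in steps
of 5) × magnitudes 1–10.

**Beta mixture model.** Bulk beta values are Beta-distributed with mean
m = w·μⱼ and variance m(1−m)/(1+φⱼ), i.e. shapes (mφⱼ, (1−m)φⱼ). The
per-CpG fitter maximizes the likelihood in (μⱼ ∈ (0,1)ᴷ, φⱼ > 0) with an
identity-linked mean in the fractions (logit/log transforms for the box
constraints, Nelder–Mead on the 200-sample designs used here), falling back
to method-of-moments estimates (flagged) on non-convergence. Constant
fractions across samples make μⱼ unidentifiable and are rejected. The
synthetic stand-in model `random_beta_model` (used where no real reference
is fitted) draws per-CpG baselines uniform on (0.1, 0.9) plus N(0, 0.15)
cell-type deviations clipped to (0.02, 0.98), and φ uniform on (20, 100) —
values chosen once as representative of array data.

**Two-group compositions.** Dirichlet draws with parameters
(base mean)×concentration. The default base is a whole-blood-like profile
(granulocyte-dominant: Gran 0.69, CD4T 0.132, Mono 0.062, CD8T 0.060,
NK 0.029, B 0.027) and concentration 50, giving inter-individual
granulocyte sd ≈ 0.065 — realistic blood variability. Group 2's mean moves
d/2 of mass from the largest to the smallest component, so the total
absolute mean difference equals the dissimilarity d.

**Prediction-error emulation.** Deconvolution error with per-type MSPE τ²_k
(percentage points squared) is emulated by adding independent
N(0, τ²_k/100²) noise on the fraction scale, clipping to [0,1] and rescaling
rows that exceed unit sum. This truncated-Gaussian scheme is the minimal one
whose per-type RMSE matches τ_k; it is a documented stand-in, not a claim
about any particular deconvolution method's error law beyond its second
moment.

**Null EWAS / false-positive study.** Methylation is simulated with *no*
group effect; the groups differ only in cell composition. Each CpG is fit
by OLS: Y = α₀ + α₁·group + Σₖ₌₁^{K−1} γₖ·wₖ + ε (one cell type dropped for
identifiability; the intercept absorbs the slack), and the fraction of CpGs
with two-sided p < 0.05 for α₁ is recorded — every rejection is a type-I
error, so this fraction is the empirical false-discovery proportion. The
regressions share a design within a replicate, so they are computed as one
vectorized least-squares solve across CpGs. With true fractions as
covariates the level holds at ~5% regardless of dissimilarity; unadjusted,
it inflates steeply with dissimilarity. Default scaled-down design:
n = 100 per group, 500 CpGs, 10 replicates.

**Planted-DML references.** `synth_reference` draws Beta-distributed
purified profiles where, per cell type, a set number of CpGs shift their
mean by ±effect in that type only (half hyper, half hypo; baselines drawn
so shifted means stay inside (0.05, 0.95)); a truth table supports
enrichment tests. Passing tests on these synthetic references show the
machinery recovers planted structure under the model's assumptions; they do
not capture array artefacts, probe cross-reactivity, lineage-correlated
signatures, or the NK/CD8T cross-contamination known to blur real blood
references.

## EWAS variance explained

Per CpG, OLS of beta on an intercept plus K−1 estimated cell fractions;
R²_j is reported (clipped to [0,1]; NaN for zero-variance CpGs; a collinear
design is handled by least squares via the pseudoinverse). Two libraries'
estimates are compared by Δ_j = R²_{j,A} − R²_{j,B} and the proportion of
CpGs with Δ_j > 0 (strict). When fractions sum to a constant, R² is
invariant to which cell type is dropped (tested).

## Degenerate inputs and numerical choices

- Matrices must be finite; real beta values are range-checked at read time
  ([0,1], with `--allow-any-real` for simulated Normal features); missing
  values are an error — no imputation.
- min(Dw\*) = 0 → error (see above). trace(S_w) = 0 likewise.
- Probability vector: always nonnegative, sums to 1 within 1e-9 after every
  iteration (floor ε = 1e-12).
- QP feasibility tolerances 1e-12; returned fractions are clipped at 0 and
  rescaled only if the sum exceeds 1 by round-off.
- Beta draws are clipped to [1e-12, 1−1e-12] to guard against exact 0/1
  from floating-point underflow at extreme shapes.
- Writers emit `#` metadata headers (version, seed, timestamp); with
  timestamps suppressed, identical inputs give byte-identical outputs.

## Known limitations

- The Modified DSC tends to favour small libraries (Euclidean distances
  saturate in high dimension); alternative distance metrics are not
  implemented.
- Only the min/min summary of the dispersion vectors is provided.
- The search is single-threaded by design; run parallel seeds externally if
  wanted.
- No array preprocessing, QC or normalization: inputs are assumed to be
  clean beta matrices. No IDOL (requires training data) and no
  ANOVA/F-statistic library builder.
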