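# Methods

This note records the models implemented in `riemannmi`, the numerical
choices behind them, what the synthetic generator does and does not emulate,
and the design decisions taken where more than one reading was defensible.

## Geometry of SPD covariance matrices

All classifiers operate on spatial covariance matrices `P = X Xᵀ/(Ts−1)` of
band-limited EEG epochs, under the affine-invariant metric

`δ_R(P₁,P₂) = ‖log(P₁⁻¹P₂)‖_F`, computed from the generalized eigenvalues of
the pair. The metric is invariant under congruence `P → W P Wᵀ` for any
invertible `W`, which is what makes it appropriate for EEG: an unknown linear
mixing of cortical sources into electrodes cancels out.

**Matrix functions.** Square roots, logs, exponentials and inverse square
roots go through symmetric eigendecompositions, with eigenvalues clipped at
`1e-12` of the largest before logs/inverse roots. All of them accept stacked
`(..., n, n)` input, so the Karcher-mean inner loop is vectorized across an
entire trial set — this is what keeps the nested cross-validations of the
pipelines affordable on one CPU.

**Karcher mean.** Fixed-point flow
`M ← M^{1/2} exp(s · mean_i log(M^{-1/2} P_i M^{-1/2})) M^{1/2}`, initialized
at the arithmetic mean, unit step. Convergence is declared when the
Frobenius norm of the mean tangent displacement falls below `1e-8` times the
mean Frobenius norm of the inputs. Two numerical hardenings, both observed
to matter in practice: (i) if the residual fails to decrease, the step is
halved and the previous iterate restored (unit steps oscillate on widely
spread, ill-conditioned sets), recovering ×1.2 per successful step up to the
configured step; (ii) the default iteration cap is 300, because the linear
convergence rate measured on random SPD sets with condition ~1e3 is ≈0.87
per iteration, which needs ~160 iterations to reach 1e-8. Non-convergence
raises an error carrying the last iterate and residual rather than returning
silently.

**Tangent vectorization.** `upper()` takes the row-major upper triangle with
off-diagonal entries scaled by √2, making the map a linear isometry:
`‖upper(S)‖₂ = ‖S‖_F`, and hence `‖tangent_vectorize(P,Q)‖₂ = δ_R(P,Q)`.
Without the √2 convention, Euclidean classifiers in the tangent plane would
silently down-weight off-diagonal covariance structure. The vectorization
returns coordinates in the *whitened* frame; the matching reconstruction
(used by the Fisher-geodesic filter) is `ref^{1/2} exp(unvec(s)) ref^{1/2}`,
which round-trips exactly at full rank.

**Covariance conditioning.** If a trial's SCM has smallest eigenvalue below
`1e-10` of the largest, trace-normalized shrinkage
`(1−γ)P + γ(tr P/n)I` is applied with the smallest
`γ ∈ {1e-6, 1e-4, 1e-2}` that restores conditioning (logged). A trial that
cannot be rescued (e.g. all-zero) raises a degenerate-trial error.

## Classifiers

**MDRM** stores one Karcher mean per class and assigns a query to the
nearest mean. Distances equal to the minimum within a relative `1e-10` are
treated as ties and resolved to the first class in sorted label order —
distances produced by eigendecompositions are never bit-identical, so exact
comparison would make the documented tie rule unreachable.

**FGDA / FGMDRM.** Fisher geodesic discriminant analysis is implemented as a
Fisher discriminant on tangent vectors anchored at the Riemannian mean of
the training covariances: generalized eigenproblem of (between-class,
within-class) scatter, ridge `1e-9·tr(S_W)/dim` on the within term when
ill-conditioned (escalated ×100 on failure), top `r` eigenvectors
orthonormalized by QR. `r` defaults to C−1 and may be set up to the full
tangent dimension, where the filter becomes the identity and FGMDRM
reproduces MDRM decisions exactly (tested). Filtering projects the tangent
vector onto the retained subspace and reconstructs an SPD matrix, so FGMDRM
literally runs MDRM on filtered covariances.

A finding worth recording: on the synthetic generator below, FGDA filtering
*costs* one to three points of accuracy relative to plain MDRM at moderate
separation. The generator's within-class variability is an unstructured
Wishart jitter, so discarding tangent dimensions removes signal without
removing any shared noise; the filter pays off only when noise is structured
and common across classes, which real EEG has and this generator
deliberately does not. Tests assert the mean degradation over seeds stays
within two points rather than pretending filtering helps here.

**KNN** is deterministic Euclidean k-nearest neighbours (default k = 5, odd
enforced): majority vote, ties by smallest summed distance, then label
order. It exists because distance-based classification in the tangent plane
is the second pipeline's final stage; sklearn's implementation is not used
so the tie behaviour is fully specified and testable against an exhaustive
scan.

**Cohen's kappa** `(p_o − p_e)/(1 − p_e)` with `p_e` from marginal products;
the degenerate case `p_e = 1` (both vectors constant and equal) returns 0
with a warning, since no chance correction is possible.

## Subject-specific decision tree (SSDT)

`rank_ovr` scores every class by stratified k-fold CV accuracy (default 10
folds) of the base classifier on "class vs pooled rest", keeping the natural
3:1 imbalance and plain accuracy as the score. The tree chains
`max(C−2, 1)` binary nodes in ranking order; node i's training pool excludes
the targets of earlier nodes (they can no longer reach it correctly;
switchable). The final node is by default a multiclass classifier over *all*
C classes, so trials wrongly passed down by binary nodes remain recoverable;
a config switch restricts it to the remaining classes. Routing: a binary
node that claims a sample ends the walk; the final node's decision is
returned as-is. Consequence, tested explicitly: when the final node is
trained on all classes it is the same classifier as the flat baseline, so
the tree can only differ from flat through binary-node captures — it can
lose only on samples wrongly *captured*, never on samples passed down.

Two-class problems degenerate to the base classifier with a warning.

## SJGDA feature stack

Tangent vectors have `n(n+1)/2` dimensions — 253 for 22 channels — against
a few hundred trials, so the second pipeline reduces them per tree node:

1. **Discretization**: per-feature equal-frequency binning (8 bins default),
   fitted on all rows including unlabelled ones; constant features collapse
   to one bin with a warning. MI estimates are plug-in, in bits.
2. **JMI ranking**: greedy forward selection; the first feature maximizes
   `I(X_k; Y)`, every later pick maximizes
   `Σ_{X_j ∈ selected} I(X_k, X_j; Y)` (cumulative scores are updated
   incrementally, so the full ordering costs O(n²) pair-MI evaluations).
   Ties keep the lower feature index. With ≤ 8 features the ordering is
   verified against an exhaustive re-evaluation of the recursion.
3. **Semi-supervised path (MAR-C)**: when unlabelled rows exist and the semi
   flag is on, every MI term is assembled from class-conditionals `p(x|y)`
   estimated on labelled rows (Laplace 0.5 smoothing so cells seen only in
   unlabelled rows keep mass) and class priors re-estimated by EM on the
   unlabelled marginal — the class-prior-change missingness assumption:
   conditionals transfer, priors do not. With zero unlabelled rows the code
   takes the plain supervised path, so the reduction is bit-identical by
   construction (tested).
4. **Length selection**: `m` maximizes stratified-CV accuracy of the
   downstream classifier over a user grid (default: 8 points up to
   min(100, n features), the cap dropping to 60 for 14-channel-style data
   via config); ties prefer the smallest `m`.
5. **GDA**: kernel Fisher discriminant with polynomial kernel
   `(scale·⟨x,y⟩ + coef0)^degree` (defaults degree 2, coef0 1,
   scale 1/dim). Solved on the double-centered Gram matrix; between- and
   within-class scatter in kernel space, ridge `1e-8` on the within term
   escalated ×10 up to `1e-2`; `d = 1` output dimension by default;
   training projections normalized to unit within-class variance. The
   centering is folded into effective coefficients so a query's projection
   is a plain kernel sum `Σ_j β_j k(x_j, z) + b`, verified against a naive
   double loop.
6. **Concatenation**: the output is `[f_G | f_SJ]` (GDA projection plus the
   top-m raw features), with every coordinate standardized using
   training-row statistics. The standardization is a deliberate design
   choice: without it the unit-variance GDA coordinate dominates Euclidean
   KNN distances and the concatenation degenerates to `f_G` alone,
   violating the intended property that SJGDA is at least as good as either
   block.

The denominator of the kernel Fisher criterion uses within-class scatter
(standard kernel FDA); total scatter is mathematically equivalent up to a
monotone eigenvalue transform and is not separately exposed.

## Pipelines and evaluation

Method 1: band-pass (5th-order Butterworth prototype, 8–30 Hz, zero-phase
by default; causal available) → SCM per trial → SSDT with FGMDRM nodes.
Method 2: band-pass → SCM → Karcher mean of *training* covariances as
tangent anchor → per-node SJGDA + KNN inside the SSDT; an unlabelled trial
pool feeds only the feature-ranking path. Per-node feature selection is the
default (each node ranks features for its own binary or multiclass
problem); a shared global feature space is available through the same
estimator applied flat.

`crossval` is stratified k-fold (leave-one-out when folds equals the trial
count) with *all* fitting — node ranking, feature ranking, length
selection, GDA, every Riemannian mean — inside the training fold. Reports
carry per-fold accuracy and kappa, a pooled confusion matrix, the per-fold
node order with its OVR CV accuracies, and the selected `m` per node.

Epoching convention: half-open, 0-based windows
`[cue + round(start·fs), cue + round(end·fs))`, so 0.5–2.5 s at 250 Hz is
exactly 500 samples; off-by-one conventions differ between BCI toolchains,
so this one is pinned and tested.

## Synthetic generator

Class identity is carried exactly where the classifiers look: class c has
covariance `Σ_c = Toeplitz(0.5^{|i−j|}) + separation·(u_c u_cᵀ + v_c v_cᵀ)`
with class-specific orthonormal directions; a trial of class c draws its
covariance from `Wishart(df, Σ_c/df)` and its time series as zero-mean
Gaussian samples, then band-limits them to 8–30 Hz. `separation = 0` makes
all classes identically distributed — the chance-level anchor — and MDRM
accuracy is monotone in separation (tested). Defaults (8 channels, 250 Hz,
2 s epochs, 100 trials/class, df 200, separation 5) are the calibrated
benchmark on which MDRM reaches ≥ 95% ten-fold CV accuracy.

The mixed-separability scenario (`make_mixed_separability_covariances`)
fixes four classes: two with strong distinct patterns (strength 1.5), two
sharing a background and differing only by a weak 0.3 differential, with
Wishart df 16 — a four-class problem where roughly half the error mass is
an genuinely hard pair. These values were chosen once, by calibration of
the scenario itself, before the comparative experiments were frozen.

What the generator does *not* emulate: structured, class-shared noise
(muscle/ocular artifacts, volume-conduction common mode), nonstationarity
across a session, heterogeneous per-class variability, and realistic
spectra beyond band-limiting. Two consequences, both visible in the
results and documented rather than patched: FGDA filtering does not pay off
here (see above), and the decision tree's advantage over a well-tuned flat
classifier is small — its non-inferiority holds (the final node *is* the
flat classifier), but consistent strict improvement does not materialize on
this data family, because binary captures correct about as many flat errors
as they introduce. Passing the framework tests therefore demonstrates
correctness and non-inferiority of the tree machinery, not that it will
beat flat decoders on real recordings.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the pipelines at the
benchmark size (400 trials, 8 channels) with 5 outer folds, the
tree-vs-flat scenario at 10 repetitions × 100 trials/class with a 50/50
holdout, and the SJGDA comparison at 5 seeds × 160 trials with 5-fold CV —
sizes chosen so the whole suite completes in a few minutes on one CPU while
keeping every Monte-Carlo bound (3 SE) meaningful. The three-class
chance-level Monte-Carlo averages 40 replicates of n = 100 000 because a
single replicate's standard error (~0.15 points) exceeds the 0.1-point
tolerance the anchor is held to.

## Known limitations

* The GDF/MAT readers for the public competition distributions are thin
  conveniences behind optional dependencies, not validated parsers; event
  code mapping beyond the four-class cue codes is the caller's job.
* FGDA's published construction leaves regularization and the per-node
  component count open; both are exposed as configuration with the defaults
  above rather than asserted as canonical.
* The MAR-C estimator is this package's own (EM over priors with labelled
  conditionals); other consistent estimators of the same quantity exist.
* Kappa's variance estimate used for chance anchors assumes balanced
  classes and independence; it is an anchor check, not an inference tool.
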