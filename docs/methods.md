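# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `brainmodes`. It is written for a reader who wants to
know exactly what the package computes and what the synthetic tests do
and do not demonstrate.

## The eigen-microstate model

The package analyzes node × time activity matrices (e.g., parcellated
BOLD time courses). Each node's time course is standardized to zero
mean and unit *sample* variance (`ddof = 1`); the standardized sessions
are concatenated into an N × M ensemble matrix and divided by the
root-sum-square of all elements, a dataset constant S, so that the sum
of squared entries is exactly 1. Each column of the ensemble is a
*microstate* — the whole-brain activity pattern at one time point.

The economy-size SVD `A = U Σ Vᵀ` of the normalized ensemble yields the
*basic modes* (eigen-microstates) `E_i = σ_i u_i`, with weights
`w_i = σ_i²` summing to 1: the fraction of total ensemble variance each
spatial pattern carries. The rows of `Vᵀ` are unit-norm temporal
coefficient series: how much the microstate at each time point loads on
each mode. The same decomposition is obtained from the eigenvectors of
`A Aᵀ`; the test suite cross-checks the SVD route against a dense
eigendecomposition on small random matrices.

Because the SVD fixes neither sign nor (for degenerate spectra) order,
modes are reported under a deterministic convention: each mode is
flipped so that its largest-magnitude element is positive, ties broken
by the lowest node index.

Choosing `ddof = 1` for the z-scoring makes the functional-connectivity
identity below exact: with sample scaling, `(1/(M−1)) Σ_t A_it A_jt` *is*
the Pearson correlation of nodes i and j.

## Leading-mode selection

A mode is *leading* when it passes all three criteria:

1. **Scree elbow.** The Kneedle knee-point detector is run on the
   descending weight curve over the first `n_top` ranks (default 30):
   normalize the curve to the unit square, flip the convex decreasing
   curve to concave increasing, and locate the maximum of its
   difference from the diagonal, subject to the standard sensitivity
   threshold (S = 1). Modes *strictly before* the elbow rank pass. A
   flat curve yields no elbow and the criterion fails for all modes.
2. **Mean-weight threshold.** The weight must exceed 1/N, the average
   over all N possible modes.
3. **Permutation significance.** The node entries of every time column
   are shuffled independently, destroying spatial organization while
   preserving each column's value multiset; the weight spectrum of the
   shuffled instance is recomputed and the observed rank-i weight is
   compared against the null distribution of rank-i weights
   (rank-matched, not max-statistic). p-values use the add-one
   estimator `(1 + #{null ≥ obs}) / (1 + B)`.

The leading set is reported as the longest prefix of the weight
ordering passing all three. An aggregate p-value for the total weight
of that prefix (against matching null prefix sums) is also reported; it
is an interpretation layered on the same null, not a selection
criterion.

**Null normalization.** Each shuffled instance is pushed through the
same normalization pipeline as the observed data (row z-scoring, unit
total energy) before its spectrum is taken. This detail matters: the
observed ensemble has exactly unit-variance rows, and comparing it
against shuffles that violate this constraint makes the null
measurably conservative (≈0.3% rejections at α = 0.05 on pure noise at
N = 40, M = 300). When the caller supplies the raw sessions the shuffle
acts on the raw values, which makes the permutation family a group
acting on data whose null distribution is invariant — the classical
exactness argument for randomization tests — and the empirical
rejection rate is nominal (4.1% ± 0.8% over 800 pure-noise replicates).
Shuffling the already-standardized ensemble remains available and is
only slightly conservative (≈1–2%).

## FC reconstruction

On standardized data, FC equals `A_raw A_rawᵀ/(M−1)` and substituting
the decomposition gives

    FC_ij = (S²/(M−1)) Σ_k E_ik E_jk ,

a superposition of rank-1 *coactivation patterns*, one per mode, with
the S² factor undoing the pre-SVD normalization. Truncating the sum at
k modes gives the reconstructed FC; at full rank the identity is exact
to machine precision (asserted at 1e−10), and by orthogonality of the
modes the reconstruction error is monotonically non-increasing in k.
The reconstructed diagonal is reported as computed, not forced to 1 —
its deviation from 1 is a useful convergence diagnostic. Similarity
between FC matrices is Pearson correlation over the strictly lower
triangle (the diagonal of an original FC is constant and would
contribute no variance).

Population-level FC uses the concatenated ensemble; individual FC uses
single-session ensembles. Both run through the same code path.

## Fingerprinting

Given per-subject FC matrices from two runs, the similarity table holds
`sim(subject i run 1, subject j run 2)`. Identification is correct when
the row argmax is the diagonal; exact ties are counted incorrect (they
indicate degenerate inputs) and logged. Both query directions and
their average are reported, since the direction convention is not
standardized in the field. Differential identifiability is
`I_diff = (mean diagonal − mean off-diagonal) × 100`.

## State comparison

Modes from two conditions are matched by the Hungarian assignment
maximizing total |spatial correlation|, recording the sign of each
matched pair, so order inversions and sign flips between conditions are
explicit.

State differences are tested with a paired permutation scheme: the
observed statistic is the difference between the state-B and state-A
group-mode quantities (per-node σ-scaled amplitudes `E_i`, or
within/between-system means of the mode's coactivation matrix); the
null flips each subject's state labels independently and recomputes
both group statistics. Because SVD order/sign are not stable under
resampling, every recomputed group mode is re-matched and sign-aligned
to the fixed state-A reference mode before differencing — without this
the null is corrupted by eigenvector indeterminacy. Two-sided add-one
p-values are corrected with Benjamini–Hochberg FDR across nodes (or
across the 28 system pairs). The σ-scaled patterns are the default
comparand; a flag switches to the unit-norm patterns `u_i`.

The permutation loop exploits the Gram structure: the Gram matrix of
any state mixture is the sum of precomputed per-subject Gram blocks, so
each permutation costs one N × N eigendecomposition instead of an
N × M SVD (identical spatial modes and weights; temporal coefficients
are not needed there).

**Power and design.** The label-flip null is contaminated by a
`(1 − 2f)·Δ` term (f = flipped fraction) at exactly the nodes carrying
the true effect Δ, which bounds per-node power at small n. With 19
paired subjects, detections of a moderate planted effect are reliable
but few per cohort; the acceptance battery therefore pools a small
number of replicate cohorts and uses a generous permutation count
(2000), which lowers the attainable p floor and is what
Benjamini–Hochberg needs with ~100 tests.

## Map association with spatial-autocorrelation surrogates

Correlating two smooth brain maps inflates significance if the null
ignores spatial autocorrelation. The surrogate null here: permute the
map's values (destroying alignment with any fixed target), smooth with
a squared-exponential kernel over a geometric grid of length scales,
mix in an unsmoothed "nugget" component, and rescale so the candidate's
25-bin variogram best matches the original's. The variogram of the
mixture `a(sm + t·nug)` is an exact quadratic form in `(a, t)` per bin,
so the scale is fitted analytically on a fine nugget-ratio grid; the
fit metric is relative error weighted by pair counts (a bin's empirical
variogram has sampling sd ≈ γ/√count). The nugget component is
essential: pure kernel smoothing of a permutation cannot reproduce the
short-distance variogram of maps with any fine-scale roughness. A
`resample` option rank-remaps surrogate values onto the original value
multiset. The two-sided p compares |r| of the observed pair against
|r| of surrogate-vs-target.

Distances are straight-line Euclidean on the supplied coordinates, not
geodesic; with ~100 nodes the empirical variogram of a *single* smooth
map realization carries wiggles that no distribution-level surrogate
family can match per-bin, so the match is asserted on the typical
(median) well-populated bin.

## The synthetic-data generator

The generator emulates the study design the analysis targets:
multi-subject, multi-run (test–retest), optionally two-state cohorts of
band-limited node × time series that are noisy superpositions of a few
orthonormal, spatially smooth, system-structured spatial modes.

- **Spatial basis.** K patterns are built as random per-system offsets
  plus squared-exponential-kernel-smoothed noise on the node
  coordinates, then QR-orthonormalized. Default coordinates place each
  system's nodes around a random cluster center (sd 18 in a 100-unit
  box), so the partition is spatially coherent and the patterns are
  genuinely autocorrelated.
- **Equal-energy construction.** A sequence of left Givens rotations
  (a Schur–Horn / equal-norm-frame argument; left rotations preserve
  the column Gram) equalizes the spectrum-weighted energy of every
  node. Every node then has identical noiseless signal variance, so
  the row-wise z-scoring applied by the analysis is a single global
  rescale and the planted modes are *exactly* the modes of the
  standardized data: with zero noise the decomposition returns them
  with |r| = 1 and top-K weights summing to 1 to machine precision.
  Without this step the planted basis is provably not recoverable
  exactly, because z-scoring rescales rows by pattern-dependent
  factors. Real cortical data do not have identical per-node variances;
  this is a deliberate idealization that buys exact ground truth.
- **Spectrum.** Mode strengths default to `1.2 · 0.84^k`: descending
  with clear gaps (so a scree elbow exists) and sized so that at the
  default observation noise (sd 0.2) the weakest of five planted modes
  carries several times the weight of the largest pure-noise
  (Marchenko–Pastur edge) mode at N = 100, M = 400.
- **Temporal loadings.** White noise smoothed with a 5-sample moving
  average (mimicking the low-pass character of hemodynamic series),
  then orthogonalized against the constant vector and each other (QR)
  and scaled to unit sample variance — exactly zero-mean, exactly
  orthogonal. Only the low-rank covariance structure matters
  downstream; no hemodynamic forward model is attempted.
- **Subjects and runs.** Each subject receives a fixed perturbed basis
  (planted modes plus `subject_effect` × a random tangent pattern,
  re-orthonormalized, re-balanced) reused across its runs; loadings and
  noise are redrawn per run. This creates stable subject signatures
  for fingerprinting. Defaults: 20 subjects, 2 runs, M = 300,
  noise sd 0.2, subject_effect 0.3.
- **Two states.** State B replaces mode 1 by
  `(1−e)·mode1 + e·(system-mean-flattened mode1)`, re-orthonormalized
  and re-balanced — a state that reduces the spatial inhomogeneity of
  the dominant pattern. The same subject tangent is applied in both
  states, so subjects are paired. The two-state study conditions used
  in the acceptance battery are 19 subjects, M = 480, subject_effect
  0.1, state_effect 0.6. The re-balancing partially redistributes the
  flattening, which keeps the detected nodes' changes pointing against
  the original amplitudes (shrinkage), the qualitative signature the
  analysis should recover; alternatives that skip re-balancing raise
  raw detection counts but break that signature through
  renormalization artifacts.

All generators are pure functions of their inputs and seed
(`numpy.random.SeedSequence` spawning per subject/run).

**What passing synthetic tests do not show.** The generator has
Gaussian stationary noise, exact low-rank structure, equal per-node
variances, and no motion artifacts, drift, hemodynamic convolution, or
geodesic geometry. Results on it certify the correctness and
calibration of the machinery, not effect sizes on real cortical data;
the headline numbers of any real-data study (counts of leading modes,
reconstruction similarities, identification accuracies) will differ.

## Numerical choices and degenerate inputs

- Zero-variance node time courses raise a typed error naming the node;
  constant maps and constant FC triangles raise `UndefinedSimilarity`.
- Retained rank defaults to full `min(N, M)`; truncation is the
  caller's choice; weights are always reported for the retained rank.
- The elbow detector requires ≥ 3 weights and a non-increasing curve
  (tolerance 1e−12 for floating-point jitter).
- Add-one p-value estimators never return 0; ties count as
  exceedances.
- Identification ties are counted incorrect (conservative) and logged.
- TSV output uses `%.17g` (repr round-trip); reading uses pandas'
  round-trip float parser, so write → read is bit-exact.

## Problem sizes

The test-suite and acceptance battery run at N = 30–100 nodes,
M = 80–480 time points, 2–20 subjects, 200–2000 permutations, and
99–500 surrogates; these sizes were chosen so that every stochastic
check has comfortable statistical margin while the complete battery
runs in minutes on one CPU. All of them are configurable upward.

## Known limitations

- The ensemble SVD is dense and in-memory; no streaming/incremental
  path (a 1000-node × 10⁶-column ensemble is the practical ceiling).
- Euclidean, not geodesic, distances for the surrogate machinery.
- No parametric (Marchenko–Pastur) significance alternative for mode
  selection.
- No Fisher-z averaging of FC across subjects, no thresholded graph
  metrics, and no volumetric/surface (NIfTI/CIFTI) ingestion — node ×
  time tables are the interface.
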