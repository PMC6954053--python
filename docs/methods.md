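# Methods

`speechpop` reimplements, as a tested library, the population-level analyses
used to characterize ensemble activity in human dorsal ("arm/hand") motor
cortex while participants speak prompted syllables or words: cross-validated
population distances, phoneme-geometry permutation testing, single-trial
decoding, demixed PCA of the condition-invariant signal, jPCA rotatory
dynamics, and tensor-maximum-entropy surrogate significance testing.  The
human recordings these analyses were developed on are access-restricted, so
the package ships a spike-train simulator that plants exactly the latent
structure the analyses are designed to detect; every analysis is validated
by parameter recovery against that planted ground truth, by independent
brute-force oracles, and by statistical calibration under the null.

## Task and data model

A session consists of trials with three events: an audio **prompt**, a **go
cue** ~2 s later, and the **acoustic onset (AO)** of speech a few hundred
milliseconds after go.  One condition is **silent** (the prompt is ambient
noise; nothing is spoken).  Data per trial are per-electrode spike times
plus an optional high-frequency LFP (HLFP) power channel — a multiunit
proxy used only as a decoding feature.  Defaults mirror a typical session:
10 spoken conditions plus silence, 100 electrodes, 30 trials per condition.

Silent trials receive a *faux AO* downstream of generation: the go cue plus
the block-mean go-to-AO latency of that block's spoken trials (dataset-wide
mean as fallback), so silent and spoken epochs can be aligned identically.

## Synthetic generator

Each electrode's intensity is a baseline (gamma-distributed across
electrodes, shape 3, scale 5 Hz → mean 15 Hz, a realistic threshold-crossing
range) plus four planted population latents, rectified at zero (the clipped
mass fraction is logged and warned about above 20%):

* a **prompt response** (unit loading × smooth plateau over ~0.1–0.9 s after
  the prompt),
* a **condition-invariant kick** (logistic ramp, 150 ms 10–90% rise,
  centered 200 ms after go),
* a **rotation** in a fixed 2-D orthonormal electrode-space plane,
  z' = 2πω·S·z with condition phases uniformly spaced around the circle,
  gated on 150 ms *before* AO (articulator motion precedes sound, and the
  peri-AO analysis epoch starts 150 ms before AO), and
* **condition tuning** (per-condition loadings, gated around articulation).

The prompt/CIS/rotation loadings are drawn jointly orthonormal, so planted
subspaces can be compared to recovered ones without ambiguity.  Silent
trials carry no latent drive.  Gains are population norms in Hz; the
defaults (prompt 15, CIS 30, rotation 20, tuning 15) were fixed once so the
planted effects have the same character as the reported phenomena: the
prompt-epoch modulation is measurable but several-fold smaller than
speaking-epoch modulation, the leading dPCA component is almost purely
condition-invariant, and peri-AO dynamics are strongly rotatory.  Spikes are
drawn by exact thinning against each electrode's maximum rate (intensity
interpolated on a 1 ms grid); HLFP power is the smoothed intensity plus
Gaussian noise, rectified.

What the generator does **not** emulate: trial-to-trial latent amplitude and
timing variability beyond reaction-time jitter, non-Poisson spiking
statistics, electrode noise correlations, drift, or behavioral errors.  One
visible consequence: with deterministic latents and 2080-dimensional feature
vectors, leave-one-out decoding saturates at 100% at default gains, where
real recordings top out near 85%.  Passing tests therefore demonstrate
correctness of the estimators and calibration of the tests, not expected
effect sizes on real data.

## Preprocessing

Spike trains are binned at 1 ms, convolved with a Gaussian kernel (25 ms
s.d. for PSTHs and distance time courses, 28 ms for dPCA, 30 ms for jPCA),
truncated at ±4 s.d. and renormalized at window edges so an isolated spike
integrates to one spike, then block-averaged to the requested bin.  Windows
are half-open `[start, end)` in seconds with the alignment event at zero.
Soft normalization divides each unit by (its rate range across conditions
and times + offset); 5 Hz offset for dPCA, 10 Hz for jPCA; ranges are stored
so the transform inverts exactly.  Condition centering subtracts each unit's
across-condition mean at every time point and is likewise invertible.

## Cross-validated neural distance

The squared distance between two conditions' mean rate vectors is estimated
as

D = (1/N₁N₂) Σᵢ Σⱼ (y₁ᵢ − y₂ⱼ)ᵀ (ȳ₁^{∖i} − ȳ₂^{∖j}),

pairing each trial difference with leave-one-out means so the two factors
share no trials.  D is exactly unbiased for ‖μ₁−μ₂‖² and can be negative;
the reported signed distance is d = sign(D)·√|D| (Hz).  The implementation
uses the algebraic identity D = ‖ȳ₁−ȳ₂‖² − trS₁/N₁ − trS₂/N₂ (Sₖ unbiased
covariances), verified against the literal double sum to 1e-10.  Note that
while D is unbiased, d is not: under the null, D's distribution is
right-skewed, so E[d] is slightly negative; epoch averages of d should be
read with that in mind.  Distances grow with electrode count, so
comparisons hold the population fixed.

Epoch statistics compare a prompt epoch (0–1 s after prompt) with a speaking
epoch (0–1.75 s after go) across conditions by exact Wilcoxon signed-rank
test (n ≤ 25), and the modulation ratio is the ratio of across-condition
mean epoch means.  Per-electrode task modulation uses two-sided rank-sum
tests of each condition against silence on AO±0.5 s mean rates, Bonferroni
corrected over conditions.

## Phoneme geometry

Phoneme instances (150 ms window rates) yield a phoneme × phoneme matrix of
signed distances; diagonals are means over 20 random half-splits.  The
articulatory-grouping statistic is mean(within-group) − mean(between-group)
distance over unordered pairs, singleton groups excluded; the null permutes
the phoneme→group assignment preserving group sizes (equivalently shuffles
matrix rows and columns jointly), 10,000 times by default, with the add-one
p-value p = (1+#{null ≤ obs})/(n_perm+1), one-sided lower tail.  Phonemes
are processed in sorted-label order so a fixed seed yields an identical null
regardless of input ordering.  UPGMA clustering is implemented directly
(negative distances clamped to zero, ties broken lexicographically, heights
reported as distance/2); it is checked against SciPy average linkage on
random matrices, and trees export to Newick.

## Decoding

Feature vectors concatenate per-electrode spike counts and mean HLFP power
in ten 100 ms bins spanning AO±0.5 s (104 electrodes → 2080 features).
Classification is one-vs-one ECOC over linear hinge-loss SVMs (C = 1):
features are z-scored on the training trials of each leave-one-trial-out
fold (constant features mapped to zero), one binary classifier is trained
per class pair, and the predicted class minimizes the summed hinge loss,
ties to the lowest class index.  The binary learner is the standard
liblinear dual-coordinate-descent algorithm (numba-compiled; validated
against scikit-learn's LinearSVC, which optimizes the same objective — the
in-package solver exists because the protocol refits every pair classifier
in every fold and shuffle, ~10⁵–10⁶ small fits per analysis).  Chance is
the distribution of the full procedure over 101 random label permutations.
The original outlier-fraction option of the reference toolbox is omitted.

## Demixed PCA (condition-invariant signal)

On the soft-normalized (5 Hz), go-aligned −0.2…0.4 s trial-averaged tensor
of spoken conditions, the centered data splits exactly into a
condition-invariant marginalization X_CI (condition mean, time-only
structure) and X_CD = X − X_CI (condition and condition×time).  Per
marginalization a reduced-rank ridge regression min ‖X_m − F D X‖² + μ‖FD‖²
is solved in closed form (F = top left singular vectors of AX with
A = X_m Xᵀ(XXᵀ+μI)⁻¹, D = FᵀA); candidate components from both
marginalizations compete for a budget of 8, ranked by explained variance.
μ defaults to 1e-6 × total variance; a leave-one-trial-per-condition
cross-validation of μ over a log grid (10 repetitions) is available when
single-trial data are supplied.  Because the CI/CD cross-term vanishes
identically, each component's variance share splits exactly into CI and CD
parts; the "% CI" of a component is the CI part over their sum, and the
leading CI component's condition×time projection is the CIS₁ time course.
Encoders within a marginalization are orthonormal; across marginalizations
they need not be, so pairwise angles plus a Kendall rank-correlation test on
electrode weightings (α = 0.01) report non-orthogonality, and the principal
angle between CIS₁ and the jPC plane is computed directly.  The component
budget is a plain parameter; results on the synthetic sessions are stable
over budgets of 2–12, as the planted CI structure is rank 1.

## jPCA (rotatory dynamics)

The soft-normalized (10 Hz), condition-centered, AO-aligned −0.15…0.10 s
tensor is sampled every 10 ms and PCA-reduced to k = 6 (conditions
stacked).  The rotatory model x' = M_skew·x is fit by least squares over the
k(k−1)/2 antisymmetric basis in closed form; derivatives are forward
differences paired with the left sample, per-condition boundary samples
dropped.  An unconstrained M_full provides the nested reference
(R²(full) ≥ R²(skew) always).  R² uses 1 − SSE/Σ‖dX − mean dX‖², applied
identically to data and surrogates so the significance test is internally
consistent.  Planes come from conjugate eigenvector pairs of M_skew ordered
by |eigenvalue|; plane frequency is |imag λ|/2π; a fresh 2×2 skew fit in
plane 1 gives the in-plane R².  The plane basis is rotated so conditions
are maximally spread along jPC₁ at the epoch start (closed form: top
eigenvector of the start-state covariance; oracle: exhaustive angle sweep),
majority of conditions starting positive, rotation sense counterclockwise.
For joint [CIS₁, jPC₁, jPC₂] visualization, jPCA can be run in the
(units−1)-dimensional orthogonal complement of CIS₁.

Frequency-recovery validation uses a 1 s window so the slowest planted
rotation (1 Hz) completes a full cycle; at the standard 0.25 s epoch a 1 Hz
plane is identifiable but its orientation is noise-sensitive.  k = 6 is a
parameter; with a rank-2 planted rotation, recovery is insensitive to k
between 2 and 10.

## Tensor-maximum-entropy surrogates

The jPCA-space tensor (soft-normalized, uncentered) is summarized by its
additive mean (sum of the three per-mode means minus twice the grand mean)
and the three covariances of the residual's mode unfoldings, whose traces
agree exactly.  The maximum-entropy Gaussian matching those marginal
covariances has covariance diagonal in the Kronecker product of the
constraint eigenbases with joint eigenvalues λ_{tnc} = 1/(ν_t+ν_n+ν_c).
The convex dual f(ν) = −Σ log(ν_t+ν_n+ν_c) + Σ⟨ν, s⟩ is minimized by cyclic
exact coordinate updates: given the other modes, each mode's multipliers
solve independent scalar equations Σ 1/(ν+a) = s by safeguarded Newton,
vectorized across eigenindices.  (A generic quasi-Newton line search was
tried first and repeatedly stepped outside the positivity domain of the
log-partition; the coordinate scheme respects it by construction.)
Convergence requires the largest relative marginal residual < 1e-6.
Near-zero constraint eigenvalues are floored at 1e-9 × the mode maximum and
traces renormalized to their common mean, which keeps degenerate problems
(e.g. an exactly additive tensor, whose surrogates collapse onto the mean)
well-posed.  Surrogates are mean + eigenbasis rotation of independent
normals scaled by √λ; their expected per-mode covariances equal the
constraints exactly.

Significance: the observed 6-D skew-fit R² is compared with the same
statistic on n surrogates (1000 by default; 200 in tests and the acceptance
run, a documented scale-down), each surrogate passing through the identical
centering → PCA → skew-fit pipeline.  p is the plain exceedance fraction
#{null ≥ observed}/n; the add-one variant is reported alongside since the
convention is not fixed in the literature this follows.

## Numerical and design choices

* Times in seconds, rates in Hz; windows half-open; alignment event at 0.
* The worked one-unit example A = {1, 3}, B = {0, 0} evaluates to D = 3
  (four double-sum terms of 3), d = √3 — frozen in the tests from the
  brute-force oracle.
* UPGMA tie-break: lexicographically smallest (min-label, min-label) pair.
* ECOC ties: lowest class index.  SVM C = 1, dual tolerance 1e-4.
* dPCA with μ = 0 on rank-deficient data uses a pseudo-inverse.
* jPCA singular normal equations get a 1e-10 ridge with a warning.
* Seeds: every stochastic entry point takes an explicit seed or Generator;
  identical inputs give bit-identical outputs.

## Known limitations

* The generator's latents are deterministic given the condition; decoding
  and significance tests are therefore easier than on real data (see above).
* d (signed root) is biased slightly negative under the null even though D
  is unbiased; inference should be based on D or on permutation nulls.
* The TME null matches first- and second-order structure only; it does not
  test against alternatives with matched higher-order moments.
* NWB ingestion is not included; datasets enter through the tabular CSV
  schema or in-memory construction.
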