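# Methods

This note documents the statistical procedures implemented in `somnomet`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical conventions that make runs reproducible.

## Data model and preprocessing

A `MetaboliteTable` is a samples × metabolites matrix of non-negative
abundances with per-sample annotations: sleep–wake state (REM/NREM/Wake),
conditioning protocol (DS/IS/CO/none) and zeitgeber time (hours since
lights-on). Missing measurements are NaN; a literal zero on read is rejected
so "absent" and "measured as zero" cannot be conflated silently.

Preprocessing applies, in order: missing-value handling (default
half-minimum imputation per metabolite; alternatively drop the metabolite),
log transform (default base 10) and column autoscaling to unit variance
(ddof = 1). These are the customary defaults of metabolomics preprocessing
suites; since upstream pipelines rarely state their exact normalization, the
applied steps are recorded in `transform_log` on every processed matrix, and
each step is switchable. Preprocessing never reorders samples or
metabolites. Resampling statistics (fold changes, permutation p, bootstrap
CI) always operate on the *raw* abundances so ratios remain interpretable;
the multivariate stages operate on the processed matrix.

## PCA gate

PCA is computed by SVD of the column-centered matrix. The outlier gate
follows the two-component Hotelling-T² ellipse: sample i is flagged iff
T²ᵢ = t²ᵢ₁/λ₁ + t²ᵢ₂/λ₂ > (2(n−1)/(n−2)) · F₂,ₙ₋₂(0.95). Exactly two
components are used because outlier ellipses are conventionally assessed in
the 2-D score plot. The threshold is mildly conservative at small n (the
long-run null flag rate rises toward 5% as n grows; at n ≈ 20–30 it sits
near 1–2%), which errs on the side of keeping samples. Flagged samples are
removed and the remaining table is re-preprocessed before any supervised
stage, so scaling never leaks information from discarded samples.

## PLS-DA

Class structure is modelled by NIPALS PLS2 regression of the centered data
on centered one-hot class indicators, with 3 components by default
(configurable). With g classes, the indicator matrix has rank g − 1;
components beyond the rank come out as zero vectors and contribute nothing.
Determinism is guaranteed by a fixed sign convention (the largest-magnitude
entry of each weight/loading vector is positive) and by deterministic
initialization (the Y-residual column with the largest sum of squares).

- **R²Y** is the fraction of indicator variance reproduced by the fitted
  components.
- **VIP**: VIPⱼ² = p · Σₐ SSYₐ (wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ with SSYₐ = (tₐ·tₐ)(cₐ·cₐ)
  the indicator sum of squares captured by component a. The normalization
  identity mean(VIP²) = 1 holds for every fit and is property-tested.
- **Q²** is 1 − PRESS/TSS accumulated over stratified k-fold cross-validation
  (default 10-fold; leave-one-out when `folds == n`). Within each fold,
  centering statistics come from the training rows only; predictions use the
  regression form B = W(PᵀW)⁻¹Cᵀ. The fold scheme for the cross-validated
  statistic is not uniquely dictated by common practice, so it is
  configurable; 10-fold is stable at the n ≈ 30 scale these designs use.
- **Permutation significance**: the test statistic is the between/within
  sum-of-squares ratio of the component-1 scores; class labels are permuted
  and the model refit (one component suffices, as the statistic only uses
  component 1). p = (1 + #{stat ≥ stat_obs})/(n_perm + 1). A Q²-based
  statistic was considered and rejected as the default because it is an
  order of magnitude slower per permutation for the same decision at the
  effect sizes of interest.
- The top-5% VIP selection uses ceil(0.05·p) metabolites, ties broken by
  metabolite id, so selections are reproducible across platforms.

## Per-metabolite resampling statistics

Fold change is the ratio of raw group means, reported signed: ratio if ≥ 1,
else −1/ratio, so |FC| ≥ 1 and the |FC| > 1.5 filter is symmetric. The
permutation test reassigns group labels preserving group sizes, with
statistic |log(mean_a/mean_b)| — the log-ratio matches the effect scale of
the fold-change filter — and the add-one correction (1+k)/(B+1), which keeps
p in (0, 1] and the test valid. 10,000 permutations and 10,000 bootstrap
replicates are the pipeline defaults; type-I calibration at the 0.05
threshold is verified by simulation in the acceptance suite. The permutation
unit is the full label shuffle; per-value replacement schemes would break
exchangeability of the two-group design.

The bootstrap CI resamples within each group with replacement and takes the
ratio of means per replicate. The default interval is the **expanded
percentile** interval: the replicate distribution is cut at
Φ(−t_{α/2, m−1}·√(m/(m−1))) and its mirror, with m the smaller group size.
The plain percentile interval (available via `method="percentile"`)
measurably under-covers at the group sizes these experiments use — about
92% empirical coverage instead of 95% at n = 10 per group with cv 0.2
log-normal noise, because the bootstrap distribution of a mean-ratio is
systematically too narrow at small n; BCa is worse still here (≈ 89%). The
expansion restores near-nominal coverage (≈ 96% in the same simulation) and
degenerates gracefully: for constant groups the interval collapses to a
point, and as m grows the adjustment vanishes. Coverage is re-measured from
scratch by `scripts/acceptance.py`.

No multiple-testing correction is applied to the per-metabolite calls (they
are reported as raw permutation p-values, as is conventional for these
volcano/Venn summaries); a Benjamini–Hochberg column is emitted alongside
for users who want it, but it does not enter the significance flag.

## Consolidation set and enrichment

Within one sleep–wake state, the consolidation set is
significant(DS/IS) \ significant(IS/CO): metabolites that differ between the
memory-forming and shock-only protocols but not between shock-only and
context-only — i.e. tied to the context–shock association rather than shock
exposure. The operation is monotone (growing DS/IS grows the output;
growing IS/CO shrinks it), which is property-tested.

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) with universe N = detected metabolites (after case-folding ids),
pathway size K after intersection with the universe, selection size n and
overlap k. The detected-metabolite universe (rather than the whole library)
matches testing only measurable compounds; the policy is switchable. Output
is sorted by (p, pathway name) for total determinism. The bundled GMT
library is a small synthetic fixture for demonstrations and tests; real
studies should supply their own library, and enrichment results are always
library-dependent.

## Sleep architecture

Hypnograms are epoch sequences (default epoch 4 s, the common rodent scoring
epoch; configurable — all printed thresholds are multiples of any divisor of
60 s). Episodes are maximal runs. Sampling triggers fire at run start +
threshold for the first run reaching the threshold (defaults REM 60 s,
NREM 300 s, Wake 300 s). Transition ratios are outgoing-conditional
frequencies (each from-state's row sums to 1), which makes rows comparable
across groups. Band power averages per-epoch Hann-window periodograms
within state and integrates half-open bands ([0.5, 4) Hz delta,
[6, 10) Hz theta by default) against a [0.5, 30) Hz total, so bands that
partition the total give densities summing exactly to 1; densities are
scale-invariant. Band edges follow rodent-sleep convention and are
overridable.

## Behavior

Discrimination index (A − B)/max(A, B) over conditioning-context vs
neutral-context freezing; antisymmetric under swapping A and B (max is
symmetric) and undefined when both are zero. Shock reactivity is pre-shock
movement over movement during the first shock. Correlations are two-tailed
Pearson r with the exact p from t = r√((n−2)/(1−r²)) on n−2 df; p-values
are reported exactly and thresholded (0.05) only downstream.

## Synthetic generators

- **Metabolome**: per-metabolite baselines log-uniform over three decades
  (10²–10⁵), matching mass-spec dynamic range; multiplicative log-normal
  noise with unit mean (so group-mean ratios converge to planted effects);
  planted effects as per-group mean multipliers; optional outlier samples
  scaled globally. Defaults: 200 metabolites, 10 samples/group, cv 0.2 —
  the scale of the motivating experiments.
- **Hypnogram**: semi-Markov chain; episode lengths exponential (the
  simplest model consistent with reported mean durations — real episode
  distributions are heavier-tailed), rounded to whole epochs (min 1); next
  state drawn from the transition row with self-transitions excluded. REM
  mean episode defaults to 62.6 s, the reported single-episode mean.
- **EEG**: one dominant sinusoid per state (NREM 2 Hz, REM 7 Hz, Wake 8 Hz)
  plus white noise at 128 Hz. This is a spectral caricature — no spindles,
  sawtooth waves, 1/f background or artifacts — sufficient to exercise band
  power, not to validate scoring algorithms.
- **Behavior**: bivariate normal freezing pairs with planted correlation,
  clipped to [0, 100]%; the correlation is planted pre-clipping and recorded
  in the truth record.

Because the generators are stylized, passing tests demonstrate correctness
of the *computations* and sensible operating characteristics under the
stated noise model; they do not certify performance on real tissue data,
where missingness patterns, batch structure and heavy-tailed noise are more
complex.

## Numerical conventions and problem sizes

All stochastic procedures accept a seed; the pipeline expands one global
seed into independent substreams per stage (so changing the number of
permutations does not perturb bootstrap draws), and reports serialize to
canonical JSON (sorted keys) so identical seeds give identical bytes.
NIPALS iterates to a relative score tolerance of 1e−12 (cap 1000
iterations). Degenerate inputs fail loudly: constant columns cannot be
autoscaled, single-class labels cannot be fit, folds that would lack a class
raise before fitting, zero denominators are named with their sample.

The calibration runs in `scripts/acceptance.py` use 2,000 simulated datasets
with 2,000 resamples each and 1,000 label permutations — sizes chosen so the
Monte-Carlo standard error of the reported rates (≈ 0.5 percentage points)
is small against the tolerance bands while the whole script completes in
seconds on one CPU.

## Known limitations

- Sparse/orthogonal PLS variants, >2-component outlier ellipsoids, and
  topology-aware pathway analysis are out of scope.
- Paired or covariate-adjusted designs are not supported; contrasts are
  independent two-group comparisons.
- Automatic sleep scoring from EEG/EMG, artifact rejection, and video-based
  freezing detection are upstream of this package's inputs.
- The cross-validation scheme behind a published Q² value can rarely be
  recovered from a paper; comparisons of absolute Q² across tools should fix
  the fold scheme explicitly.
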