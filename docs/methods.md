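# Methods

`crossband` implements a crossmodal decoding pipeline: predict the
continuous fluctuations of occipital EEG band power (alpha, 8.5–12 Hz;
delta, 1.1–4 Hz) from simultaneously acquired fast-fMRI parcel time
series, in subjects the model has never seen, and then ask *where* the
predictive information lives. This note describes the model and its
assumptions, the synthetic data the package is validated on, the
numerical choices, and the limits of what the tests show.

## The decoding model

Each EEG power sample (interpolated to fMRI TR times, TR ≈ 0.378 s) is
predicted from a 60-TR window of every region's BOLD signal, with the
EEG sample aligned to the window's 30th TR. Centering the target inside
the window deliberately avoids assuming a hemodynamic lag or response
shape: regions may contribute from any lead or lag within ±11 s. With
84 regions the design has 60 × 84 = 5040 predictors per window; windows
slide by one TR (59-TR overlap), so a clean segment of T TRs yields
T − 59 windows, and the first 29 / last 30 EEG samples of a segment are
never targets.

The decoder is ridge regression,

  minimize ‖y − Xβ − b‖² + λ‖β‖²,  b unpenalized,

evaluated by leave-one-subject-out (LOSO) cross-validation: for each
held-out subject the model is trained on all other subjects, λ is chosen
by an inner 5-fold cross-validation that never touches the held-out
subject, and performance is the Pearson correlation between predictions
and the held-out subject's true EEG power. Each fold is repeated with
distinct seeds (default 10) that re-randomize the inner CV partitions;
the subject's score is the mean over repeats.

### λ selection and window overlap

λ is selected by grid search over 30 log-spaced per-observation values
in [10⁻⁶, 10³] (multiplied by the training count to the absolute-λ
objective), each candidate scored by mean validation MSE over a fresh
5-fold partition. Two numerical points matter:

- **Folds partition contiguous blocks of windows, not windows.**
  Adjacent windows share 59 of 60 TRs; observation-level random folds
  would place near-copies of every validation row in the training set
  and make all λ look alike. Blocks are subject-pure contiguous row
  ranges (default ~2–3 per subject's run).
- **Gram/kernel caching.** Per-block Gram matrices (XᵀX, Xᵀy, column
  sums) are computed once per design; any region subset's Gram is a
  row/column slice, so evaluating thousands of single-region and
  region-pair models reuses one pass over the data. All
  (candidate × fold) ridge systems are assembled from block statistics
  and solved in one batched LAPACK call; CV scoring solves use single
  precision (candidate ranking is driven by MSE differences far above
  fp32 resolution), final fits are double precision. When features
  outnumber windows (84 regions at small n) the dual/kernel form is
  used; both forms are tested against centered normal equations at
  1e-6 relative error.

The reference implementation's stochastic-gradient learner is treated as
an optimization detail: the contract is the ridge objective, solved in
closed form (an SGD solver is available via `fit_ridge(..., solver="sgd")`
for cross-checking).

### The temporal-shuffle control

The null condition permutes the retained fMRI TRs within each run
(jointly across regions, preserving spatial covariance) while leaving
the EEG untouched. Because overlapping windows make predictions strongly
autocorrelated, a single shuffle's held-out r has a spread of roughly
√(60 / n_windows) per subject; `null_loso` therefore averages the
per-subject null r over several independent shuffles (default: as many
as there are seed repeats), estimating the null mean rather than one
noisy draw. A per-region (row-breaking) shuffle is available via a flag.

## Data preparation

- Multitaper spectrograms: 5 s windows sliding every 0.1 s, DPSS tapers
  with time-bandwidth 3 and 5 tapers (not dictated by the protocol;
  exposed as parameters). Band power is the mean over frequency bins
  whose centers fall in the closed band; channels (O1, O2, Oz) are
  averaged after band extraction; the series is linearly interpolated to
  TR times, with TRs outside the window-center support marked missing.
  Power stays on a linear scale since the target is later min-max
  rescaled per subject.
- TR masking: motion strictly above 0.3 mm; z-scored 40–52 Hz power
  above 1 (per-run threshold overrides supported); local outliers beyond
  6 scaled MADs (1.4826 × MAD) from the running median in a centered,
  edge-truncated 1000-TR window, applied to delta and artifact-band
  power but not to alpha (whose natural fluctuations would be flagged).
  The first 20 TRs of each run are always discarded. Masked TRs split
  runs into contiguous segments; segments shorter than 60 TRs (one
  window) are dropped.
- Normalization: per subject, each region's retained series is z-scored
  (sample SD; per-run scope available as an option) and the EEG target
  is min-max rescaled to [0, 1] across all of the subject's retained
  segments. Normalization is strictly within subject, so held-out
  subjects never influence training statistics. Subjects without a clear
  eyes-closed alpha rhythm (a per-subject flag) are excluded from alpha
  analyses only.

## Downstream analyses

**Anatomical groups.** LOSO performance for cortex-only, subcortex-only,
non-gray-only, brainwide and shuffled-control inputs, compared by a
repeated-measures ANOVA (subject as blocking factor) with Tukey's HSD
computed from the RM residual mean square via the studentized range
distribution. Note the pooled error term: Tukey p-values are guaranteed
no smaller than the *matched-error* contrast t-test, not than a
pair-specific paired t.

**Single-region maps.** Each bilateral region (L/R parcels concatenated
as separate predictors, not averaged) is evaluated alone; for delta the
non-gray regions are always included and the baseline is the
non-gray-only model, so a region counts as informative only beyond the
systemic signal; for alpha the baseline is the shuffled control.
Per-region two-tailed paired t-tests across subjects, raw p by default
with optional Benjamini–Hochberg flags.

**Bootstrap ordering control.** Region labels are shuffled within each
subject 1000 times; each shuffle's ordered region means get an OLS line
against rank. The decision statistic is the ordered-means slope: the map
is significant when the real slope falls outside the central 95% of null
slopes. A literal pointwise mean ± t·SD/√n envelope does not calibrate
(multiplicity across ranks); the slope rule attains ~95% null coverage
by construction and is what the calibration test checks. Pointwise
percentile envelopes are returned for display.

**Pairwise benefits and clustering.** A model is trained on every pair
of bilateral gray regions (delta: plus all non-gray regions); the pair's
benefit is its LOSO mean r minus the better of its two single-region
scores. Each region's row of the symmetric benefit matrix is its
profile; profiles are clustered with k-means (squared Euclidean,
k-means++, 50 restarts). The spec's alternative diagonal treatment
(dropping the self column per row) would misalign features across rows,
so the diagonal is fixed at 0 and all columns kept. The cluster count is
chosen by the gap statistic: B Monte-Carlo reference draws uniform in
the PCA-aligned bounding box, Gap(k) = mean log W* − log W,
SE(k) = sd(log W*)·√(1+1/B), and the smallest k with
Gap(k) ≥ Gap(k+1) − SE(k+1); k = 1 is reported as "no suitable
clustering". Cluster-pair benefit summaries use a t-based 95% CI over
the benefit entries spanning the pair (the entries level is one of
several plausible readings; it is the only one computable without extra
assumptions). A supplementary comparison clusters the plain BOLD
correlation matrix with the same machinery and reports the adjusted Rand
index against the benefit-based solution.

*A geometric caveat on the sequential gap rule.* For three clusters at
near-equal mutual separations (or collinear centers), the k=1→2 drop in
data dispersion almost exactly matches the drop for a uniform reference
in the PCA-aligned box — the box adapts to the layout's dimensionality —
so the sequential rule stops at k = 1 regardless of noise level. The
rule reliably walks to the true k when separations are hierarchical
(e.g., a small far-away group plus two resolvable groups). The synthetic
network-recovery conditions are therefore planted with hierarchical
geometry (9 + 9 + 2 regions), and the blob calibration uses unequal
separations; this is a property of the published selection rule, not of
this implementation.

**Iterative pruning.** After a full-region fit, each region's importance
is Σβ² over its 60 columns, averaged over LOSO folds and seed repeats.
The bottom 10% (⌊0.1·n⌋, at least 1; ties broken toward the smallest
norms) are removed and the model retrained, down to 5 regions. λ chosen
on the full model is reused across iterations by default (re-optimizing
at every iteration is available but changes nothing qualitative and
multiplies runtime by the candidate count). Per-iteration performance is
compared with the full model by paired t-tests, BH-corrected across
iterations. Subjects left with fewer than 30 windows are excluded from
the trace: correlations on a handful of points are meaningless (two
windows give r = ±1 exactly).

## The synthetic data generator

The generator emulates what the analysis assumes about real
simultaneous EEG–fMRI:

- **Latents.** Stationary AR(1) vigilance processes with time constants
  of 8 s (arousal-like), 12 s (visual-like) and 20 s (systemic),
  keeping latent power below ~0.1 Hz.
- **BOLD.** Region signal = double-gamma HRF (peak ~5 s, undershoot
  ~15 s, ratio 1/6, unit absolute sum) convolved with the
  gain-weighted sum of its networks' latents, plus white region noise
  (SD 1.0). The decoding model never assumes this HRF; it is purely a
  data-generating choice, and an extra EEG→BOLD lag is exposed as a
  config parameter since the real lag structure is unknown.
- **EEG.** A 10 Hz carrier amplitude-modulated by √(alpha power) and a
  1.1–4 Hz filtered-noise carrier modulated by √(delta power), plus
  broadband noise, so that measured band power is linear in the latents.
  Band power also receives a *private* AR(1) component (default SD 0.6,
  τ = 6 s) invisible to fMRI: it sets a realistic ceiling on attainable
  decoding r, standing in for EEG measurement noise and electrophysiology
  that has no hemodynamic correlate.
- **Structure.** Default (84-region atlas): arousal network = bilateral
  thalamus/caudate/putamen/pallidum (8 regions), visual network = 12
  occipital-parietal cortical parcels, diffuse delta loading on 30
  cortical parcels and a systemic component on all 8 non-gray parcels;
  alpha power = 1.0·arousal + 0.8·visual, delta power = systemic.
  Subject-specific gains (SD 0.2) multiply both the BOLD and EEG sides.
- **Artifacts.** Poisson motion spikes (1/min) of 0.5 mm over a ~0.05 mm
  baseline — above the 0.3 mm threshold by construction — and Poisson
  45 Hz EEG bursts (0.5/min, 1 s) that drive the artifact band.

What it does **not** emulate: gradient/ballistocardiogram residuals,
cardiac/respiratory waveforms, HRF variability across regions/subjects,
non-stationary vigilance statistics, spatially correlated region noise,
and scanner drifts. Passing tests therefore demonstrate that the
*pipeline logic* is correct and calibrated under the stated generative
assumptions, not that real data would yield comparable r.

## Problem sizes used by the test suite

Tests scale the simulations so the full suite runs on one CPU in tens of
minutes; all sizes are the package's own choices, stated here:

- Decoding calibration: 16-region preset, 10 subjects × 3000 TRs,
  1 repeat, 12 λ candidates; null averaged over 6 shuffles.
- Network recovery: 9 + 9 + 2 singleton regions, 6 subjects × 800 TRs,
  6 λ candidates (alpha); 20 + 1 regions, 4 subjects × 550 TRs, 5 λ
  candidates (delta); 20 seeds each.
- Pruning: 10 + 74 regions, 6 subjects × 550 TRs, 6 λ candidates,
  20 seeds. The pruning preset plants one unit-variance latent per
  informative region with a shared time constant and no private EEG
  noise, so every informative region is distinctly and equally
  informative — the condition under which "the performance peak retains
  all informative regions" is the correct expectation.
- Gap calibration: 36-point blob and 30-point null instances, 100 runs,
  B = 30; the network-recovery gap selection uses B = 100 (alpha) and
  B = 50 (delta).

## Known limitations

- The λ grid replaces Bayesian optimization with exhaustive evaluation
  at the same budget; identical contracts, different search path.
- The gap statistic's sequential rule is intrinsically marginal for
  equilateral/collinear cluster geometry (see above); single-linkage or
  the global-max-SE variant would behave differently, but the published
  rule is implemented as stated.
- Dataset pooling across acquisitions with different TRs trains
  separately and averages per-subject r arithmetically for display;
  no formal meta-analysis is attempted.
- Plots are out of scope; all outputs are tabular/JSON.
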