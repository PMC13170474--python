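# Methods

`doceeg` re-implements, as a tested pipeline over synthetic data, an
EEG-and-outcome analysis comparing two anesthetics (esketamine vs
propofol) in patients with disorders of consciousness (DoC): permutation
entropy as a complexity marker, PLV-gated band-wise wPLI connectivity,
cluster-based permutation testing of time-frequency group differences,
FDR-controlled group comparisons, and confounder-adjusted outcome models.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic harness can and cannot show.

## Signal model of the synthetic generator

Each recording is a channel × sample matrix built per canonical band
(δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz, half-open intervals so the
bands partition the axis):

* a **shared band-limited Gaussian oscillator** injected into every channel
  with a fixed per-channel phase lag, magnitude drawn uniformly in
  [π/8, 3π/8] with random sign. Lags are bounded away from 0 and π because
  the weighted phase lag index is by construction blind to zero-lag
  coupling; without explicit lags no coupling target would be reachable.
* **independent per-channel band noise**, mixed with the shared component
  in power proportion c : (1 − c), where c ∈ [0, 1] is the band's coupling
  parameter;
* a **1/f^k background** (profile-specific exponent k, fixed 0.2 relative
  power weight by default), and an overall scaling to 30 µV RMS.

Volume conduction is emulated separately and exactly as the thing wPLI is
supposed to reject: `mix_volume_conduction` replaces each channel by
(1−l)·self + l·(instantaneous channel mean), a zero-lag mixture whose
cross-spectra are real.

Four state profiles encode the study's qualitative physiology: awake
(gamma-dominant power and coupling, γ coupling ≈ 0.55), esketamine
maintenance (global suppression, slow-wave power dominance, but relative
preservation of β power and γ coupling), propofol maintenance (stronger
slow-wave dominance, hardest β/γ suppression, steeper 1/f), and recovery
(slow-band-led rebound, δ > θ > α > γ > β). The profile numbers were
chosen once to reproduce orderings and approximate ranges, not exact
published index values, which are descriptive in the source material.

The clinical cohort generator draws group-wise Gaussian continuous
variables (truncated where the scale demands: CRS-R integers clipped to
0–23, positive times), lognormal disease durations, categorical draws for
sex/etiology/baseline state/vasopressor use, and a binary 3-month
improvement flag from a logistic model (intercept −2.36; group effect
ln 6.84; small age, etiology and baseline-CRS-R effects). The defaults
mirror the published two-group (n = 17 + 17) cohort; the intercept was set
so the propofol-profile improvement probability is ≈ 25% at the covariate
means. "Improved" is defined as an upward move on the ordered ladder
UWS < MCS− < MCS+ < EMCS between baseline and 3 months, and the generated
3-month state is constructed to be consistent with the flag.

## Preprocessing

Fixed order: zero-phase Butterworth bandpass (default 0.5–45 Hz, order 4
forward–backward, ≈ 48 dB/octave) → average reference → amplitude-threshold
epoch rejection (default 150 µV, on the 2-s/50%-overlap candidate grid,
half-open windows indexed by start time) → optional integer-factor
decimation with FIR anti-aliasing → epoch extraction. Zero-phase filtering
matters because filter delay would bias every phase-based metric
downstream. Artifact handling is deliberately a transparent absolute-
amplitude rule rather than a subspace-reconstruction method: the analyses
only require clean epochs, and threshold rejection is exactly verifiable
against ground-truth injected artifacts (flat-topped 0.2–0.5 s pulses at
Poisson times).

Note that average referencing interacts with the generator's shared-source
model: subtracting the channel mean removes part of the common oscillator
and perturbs pairwise phase geometry, which lowers absolute wPLI levels
(awake γ ≈ 0.23 after referencing at 16 channels vs ≈ 0.57 without).
Orderings and group contrasts survive; absolute levels are montage- and
channel-count-dependent, as they are in real data.

## Permutation entropy

Bandt–Pompe ordinal patterns with embedding m = 3, delay τ = 1 (both
config-exposed, m ∈ [2, 6]), ties broken by occurrence order (stable
sort), normalised by log(m!) to [0, 1]. m = 3 at the 250 Hz analysis rate
is the common anesthesia-EEG choice and matches the [0, 1] normalised
range the analysis reports. PE is computed per 2-s epoch per channel on
the same grid as the connectivity stage (so PE and wPLI timecourses stay
aligned) and summarised as the channel mean. The optimized counter is
checked against a brute-force enumeration oracle, and PE is verified
invariant under strictly increasing transforms.

## Connectivity

Welch-style cross-spectra from single-Hanning-tapered FFTs of the 2-s/50%
epochs (0.5 Hz bins). The "multitaper … Hanning-windowed" description in
the source is internally contradictory; a single Hann taper honors every
explicitly stated parameter, and the taper argument is the hook for
alternatives. Per channel pair:

* PLV = |mean over epochs of the unit cross-spectral phasor|, per bin,
  band-averaged;
* wPLI = |Σ_e Im S_xy| / Σ_e |Im S_xy| per bin (0 where the denominator
  vanishes), band-averaged.

Pairs whose band PLV does not exceed 0.1 are zeroed (gate applied per pair
per band; the surviving values stay continuous, nothing is binarized), and
the whole-brain index is the mean over the strict upper triangle including
gated zeros, keeping a fixed n(n−1)/2 denominator across subjects.

Numerical guard: band bins where Σ|Im S| ≤ 1e-12 × Σ|S| are treated as
having no imaginary content. The wPLI ratio normalises magnitude away, so
without this guard a noise-free zero-lag mixture would score spurious
phase-lag consistency from rounding noise alone.

**Known estimator property:** the non-debiased wPLI has a positive null
bias ≈ 2/√(πE) for E epochs (≈ 0.15 at the 59-epoch/60-s grid, < 0.1 only
beyond ≈ 170 epochs; the debiased squared estimator is deliberately out of
scope). Absolute wPLI values at desk scale therefore sit on this floor;
all group comparisons are floor-matched by construction and unaffected.

## Cluster-based permutation test

Channel-averaged sliding-window Hanning TFRs (defaults 1 s window, 0.25 s
step — the source does not state its values — in dB). Pixelwise pooled-
variance two-sample t; pixels beyond the two-tailed uncorrected p < 0.05
threshold form maximal 4-connected same-sign components (4-connectivity is
the conservative choice when adjacency is unstated) scored by cluster mass
(sum of t). The null is the distribution of the maximum |mass| over both
signs under random group relabelings (uniform with replacement, observed
labeling excluded), with p = (1 + #{null ≥ |mass|})/(n_perm + 1) — never
zero, strong familywise control, two-tailed by construction. Identical
seeds give identical p-values; swapped group labels flip cluster signs
exactly and reproduce p-values to Monte-Carlo precision (the seeded draw
is not symmetric under relabeling, only its distribution is).

## Inference layer

Shapiro–Wilk (α = 0.05 in both groups) routes continuous comparisons to
the pooled-variance Student t (with Cohen's d, pooled-SD denominator) or
Mann–Whitney U (rank-biserial r = 1 − 2U/(n_A n_B); exact enumeration when
n_A + n_B ≤ 12 without ties, tie-corrected normal approximation
otherwise). Pooled rather than Welch t because it is the only formula that
exactly reproduces the published baseline CRS-R row from its summary
statistics. 2×2 categoricals use the two-sided Fisher exact test (sum of
hypergeometric probabilities ≤ observed) with Cramér's V from the
uncorrected χ²; tables with more than two levels use the uncorrected
χ² (an exact r×c network test would be Monte-Carlo in the available
stack and would break report determinism). EEG families (PE per phase;
five bands per phase) are Benjamini–Hochberg adjusted.

Outcome models: logistic regression for 3-month improvement and OLS for
respiratory-recovery time, both adjusting for age, etiology (TBI vs CVD)
and baseline CRS-R; Wald 95% CIs on the log-odds scale (matching the
aOR-with-symmetric-log-CI reporting style), exponentiated coefficients for
the logistic model. Separation — including single-class outcomes and
diverging Wald SEs — is flagged explicitly and returns NaN estimates
rather than silently unstable numbers; rank-deficient linear designs raise
an error naming the collinear columns. EEG metrics (maintenance PE,
recovery γ wPLI) can be added as covariates and compared against the
reduced model by likelihood-ratio χ². The 3-month ordinal contrast is
implemented, as in the source, as a t-test on the 0–3 coded state ladder —
statistically crude for an ordinal scale, and flagged as such in its
docstring.

## Problem sizes and determinism

Desk-scale defaults: 16 channels, 60 s per recording at 250 Hz (59 epochs
on the 2-s/50% grid), 17 subjects per group, 200–500 permutations — sizes
chosen so the full suite and the acceptance script each run in minutes
while keeping every contrast well powered; 64 channels, 1000 Hz and 1000
permutations are plain configuration changes. Every stochastic stage
derives its seed from one config seed through `numpy.random.SeedSequence`
spawning, and identical configs produce byte-identical JSON reports.

## What passing tests do and do not show

The generator produces stationary Gaussian band mixtures with fixed lags
and a clean logistic outcome model. Real DoC EEG is nonstationary, has
heavy-tailed artifacts, electrode-geometry-dependent leakage, and
etiology-dependent structure, none of which are modelled (no biophysical
head model, no CRS-R item-level simulation). Passing the suite therefore
shows that the estimators and tests are implemented correctly and behave
as theory predicts under controlled conditions — recovery of known
coupling orderings, nominal type-I error, unbiased recovery of known
effect sizes — not that the pipeline's clinical conclusions would
replicate on patient recordings. Desk-scale absolute connectivity values
sit on the estimator's null floor and should be compared only within, not
across, epoch-count regimes.
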