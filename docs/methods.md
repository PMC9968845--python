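# Methods

mvlab studies how motor-imagery EEG decoding degrades when a model
trained on one subject or session is applied to another. Because no
public recording carries ground-truth subject/session parameters, every
analysis runs on synthetic sensorimotor-rhythm (SMR) cohorts whose
generative parameters are known and stored, so the pipeline can be
tested end to end against the quantities it is supposed to recover.

## Synthetic cohorts

A session is a continuous 20-channel recording (FC5…CP6, 250 Hz,
microvolts) of cued left/right-hand motor-imagery trials arranged in
runs. Each trial is 2 s fixation, 4 s imagery, rest; runs hold a
balanced, randomly ordered set of trials; the default layout is
8 runs × 30 trials (240 trials, 120 per class).

The signal model is additive:

* **Background.** 1/f-power Gaussian noise (10 µV RMS per channel),
  70% of its variance spatially correlated through a Gaussian
  distance kernel over the electrode layout and 30% channel-independent
  sensor noise. The independent part keeps channel covariances
  full-rank; a purely kernel-mixed background is near-singular over 20
  channels and lets CSP find physically meaningless nulls.
* **Rhythms.** One mu and one beta source per hemisphere: unit-variance
  narrowband Gaussian processes (4th-order Butterworth-filtered white
  noise, mu ±1 Hz, beta ±2 Hz around the subject's peak frequencies)
  mixed through Gaussian gain maps centred on C3 and C4. At the map
  peak the mu RMS is `snr` times the background RMS inside 8–30 Hz;
  beta amplitude is half the mu amplitude.
* **Modulation.** During imagery the mu power contralateral to the
  imagined hand is scaled to `1 − erd_depth_contra` (ipsilateral
  `1 − erd_depth_ipsi`); beta desynchronizes together with mu at 0.8 of
  the mu depth (the rebound comes only after imagery: for 2 s after
  offset the contralateral beta power is scaled to `1 + ers_rebound`).
  Envelope transitions use 250 ms linear ramps to avoid spectral
  splatter. A trial lapses (no modulation at all) with probability
  `lapse_rate`.

### Variability hierarchy

Parameters are drawn at three levels; `inter_subject_sd` and
`inter_session_sd` (default 0.3 and 0.1, a fixed 3:1 ratio) scale the
priors so that between-subject variance always dominates within-subject
between-session variance:

* **Subject** — peak frequencies (truncated normals around 10/20 Hz),
  contralateral ERD depth (around 0.7), the ipsilateral-to-contralateral
  depth ratio (around 0.35; drawing the two depths independently would
  too often erase the contrast that carries the class information),
  `snr` (log-normal around 7), lapse rate, a global recording gain
  (log-normal; anatomy and electrode impedance scale EEG amplitude
  severalfold across people without changing decodability), topography
  width, per-channel gain jitter, and a *baseline vigilance* factor.
* **Session** — the same quantities perturbed around the subject's
  values, dominated by a day-level vigilance factor.
* **Run** — within a session, vigilance drifts from run to run and the
  effective topography picks up a small per-run jitter; both scale with
  `inter_session_sd` (σ = 0.25 and 0.08 per channel at the default),
  so zero session dispersion gives identical-distribution runs.

Vigilance is the load-bearing construct: a low-vigilance day scales both
ERD depths down, raises the lapse probability, and (quadratically in the
shortfall, so only genuinely bad days are affected) distorts the
topography. This single latent cause makes a session's *self-test*
accuracy predictive of how well models trained on it transfer — the
property the Best/Worst selection strategies assume — while ordinary
days stay mutually consistent. Run-level drift is what makes pooling
many sessions profitable: a model trained on one session has seen only
a handful of run states.

Defaults were calibrated so that the synthetic multi-subject cohort
reproduces the qualitative accuracy spectrum reported for online
CSP+LDA motor-imagery studies — most subjects decodeable (70–95%), a
20–25% tail that is effectively BCI-inefficient — not to match any
individual subject.

The generator is deterministic: one cohort seed is expanded through
`numpy.random.SeedSequence.spawn` into per-subject and per-session
streams, so cohorts are bit-identical across runs and machines.

A 5 kHz mode synthesizes at 250 Hz and upsamples by 20; it exists to
exercise the decimation stage, not to add spectral content above
125 Hz.

### What the generator does not emulate

Ocular/muscular artifacts, electrode drift within a session,
non-stationary noise floors, volume-conduction head modelling, and any
feedback-induced learning across trials. Passing tests therefore show
that the *analysis* behaves correctly under a controlled covariate-shift
model — not that it is robust to artifacts in real recordings.

## Preprocessing

Downsample (polyphase anti-aliased, integer factors only) → 50 Hz notch
(4th-order Butterworth band-stop, ±2 Hz; the stop-band width is a
package choice) → 8–30 Hz band-pass (4th-order Butterworth) → epoch.
All filters are applied forward-backward (zero phase, effective order
doubled) because the analyses are offline; this protects ERD latency
estimates. Epochs are cut after whole-recording filtering, so no
per-epoch padding is required. t = 0 is imagery onset; the
classification window is [0, 4] s and the time-frequency window
[−2, 8] s.

## Time-frequency analysis and the ERD/ERS index

Complex Morlet wavelets (fixed 7 cycles, 8–30 Hz in 1 Hz steps, mne
backend) on 1 s reflection-padded epochs; power is computed per trial
and averaged afterwards (induced convention — ERD/ERS is not
phase-locked). The ERD/ERS index on a channel is

    (P_post − P_pre) / P_pre × 100 %

with P_pre the mean uncorrected 8–30 Hz power over [−2, 0] s and P_post
over [0, 4] s. Baseline correction (subtraction of the reference-mean)
is available for maps but the index always uses raw power.

The generative model provides an independent oracle
(`expected_erd_index`): band variances of each additive component give
the index the wavelet estimator should recover. The wavelet estimate is
systematically ~2–5 points shallower than the oracle because the
envelope ramps and the wavelet's temporal support smear the fixed
window edges; tests use tolerances that account for this.

## CSP + LDA decoding

Per trial, the normalized spatial covariance `X Xᵀ / trace(X Xᵀ)`
(trace exactly 1); class covariances are arithmetic means. Spatial
filters solve the generalized eigenproblem `Σ_r w = λ Σ_l w`
(`scipy.linalg.eigh`); the model keeps the `n_pairs` largest- and
smallest-λ filters, ordered [top₁…top_np, bottom₁…bottom_np], ties
broken by first occurrence, each filter scaled to unit norm (downstream
LDA is invariant to filter scale). `Σ_l` gets a ridge of
`1e−10·trace` only when its condition number exceeds 1e12. Features are
`log var(wᵀX)` per filter — raw variance, not normalized by the sum
over filters; the normalized variant is available behind a flag.
Analyses that look at feature distributions use one pair (2-D
features); the online-style replay uses three pairs (6-D).

LDA is closed form: unscaled within-class scatter
`S = Σ_k Σ_{x∈D_k} (x−μ_k)(x−μ_k)ᵀ`, weight `w = S⁻¹(μ₁−μ₂)`, bias
`b = −½(μ₁+μ₂)ᵀS⁻¹(μ₁−μ₂)`, so the discriminant vanishes exactly at
the midpoint of the class means. A ridge of `1e−8·trace(S)/dim` is
added only when S is ill-conditioned. `g(x) ≥ 0` predicts class 1
(left) — the boundary tie goes deterministically to class 1. Identical
class means raise a `DegenerateSeparationWarning` and fall back to the
tie-break.

## Transfer matrices and distribution statistics

For m sessions, model (i) — CSP(1 pair)+LDA fit on *all* trials of
session i — is scored on every session j, giving an m×m accuracy grid
whose diagonal is the within-session self-test (train = test, as the
study design prescribes). Each cell keeps session j's 2-D features in
session i's CSP space, summarized by: pooled mean (per dimension),
pooled per-dimension sd with 1/(2n) normalization, mean Euclidean
distance of trials to their own class centre (Dist_w), and the
Euclidean distance between class centres (Dist_b).

Diagonal and off-diagonal cells of the multi-subject and multi-session
designs are compared per statistic with Student's two-sample t-tests
(Welch available by flag) under Bonferroni correction: family α = 0.05
over 12 comparisons (6 statistics × {self-test, transfer}), adjusted
threshold 0.05/12 ≈ 4.17×10⁻³. The two multi-session subjects'
matrices are pooled into one group.

## Training-set selection strategies

Six ways to pick the training set for a target session: Prev/Next
(adjacent session in acquisition order; cross-session tasks only,
unavailable at the ends), Best/Worst (highest/lowest self-test accuracy
among candidates), Closest (smallest symmetrized Gaussian KL divergence
between pooled 2-D feature clouds, computed in the *candidate's* CSP
space — the space its classifier will operate in), and All (every
candidate concatenated). Ties break to the lowest session index. The
KL uses the closed multivariate-normal form on a mean+covariance fit of
each cloud (240 points support a stable 2-D Gaussian fit; symmetrizing
removes direction ambiguity); covariances get a tiny ridge
(1e−9·trace/dim).

## Study presets, sizes and determinism

`run_study` drives: cohort generation → preprocessing → per-session
ERD/ERS table (C3/C4, per class) → cross matrices → per-cell
distribution statistics → strategy tables, writing plain CSVs plus a
manifest with a SHA-256 checksum per file. One global seed is expanded
into per-stage child seeds by stable hashing of stage names, so stages
can be rerun in isolation; a rerun with the same seed is byte-identical.

The `exp1` preset is 8 subjects × 1 session (one 8×8 matrix,
cross-subject strategies); `exp2` is 10 sessions per subject (one 10×10
matrix and a cross-session strategy table per subject).

Heavy validation runs (the acceptance script and the cohort-scale
tests) use sessions of 4 runs × 16 trials instead of the full 8 × 30,
and the strategy-ordering checks pool four replicate 10-session
subjects per seed; these sizes keep the statistical contrasts
detectable while the full suite stays desk-scale. The ERD-recovery
check uses 20 two-run sessions at high snr with lapses disabled, the
controlled condition under which the imposed depth is identifiable.

## Known limitations

* The covariate-shift structure is parametric and low-dimensional;
  real inter-subject variability includes qualitative differences
  (e.g. absent mu rhythm) the generator cannot produce.
* The ERD/ERS index inherits the estimator dilution described above;
  absolute index values depend on the beta/mu amplitude ratio, which is
  fixed at 0.5.
* Strategy orderings are statements about cohort averages under the
  default dispersions; individual seeds can and do deviate, which is
  why ordering checks are framed over replicate cohorts.
* The between-design t-tests on the feature statistics treat matrix
  cells as independent although they derive from a handful of subjects
  (8 and 2). Across replicate synthetic cohorts drawn from one common
  prior, the Std comparisons are therefore dominated by the random
  composition of the small cohorts and reach the Bonferroni-corrected
  threshold only in a minority of replicates; the between-class
  distance comparison is markedly more stable, and the within-design
  ordering (transfer shrinks Dist_b relative to self-test) holds in
  every replicate.
* EDF export is not provided (no EDF-writing backend); sessions are
  exchanged as npz+JSON+CSV bundles, and EDF recordings can be *read*
  through mne with a sidecar event table.
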