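# Methods

This note documents the models, conventions and numerical choices behind
`wmtier`, in the order of the pipeline.

## Epoching

Resting recordings are segmented on a fixed grid starting at sample 0 into
non-overlapping epochs of `epoch_len_s` (default 2 s); a trailing remainder
shorter than one epoch is discarded. From the candidates (45 for a 90 s
recording), `n_select` (default 20) are drawn uniformly without replacement
with a caller-supplied seed that is recorded in the epoch set's provenance,
so any draw can be reproduced exactly. Only the first resting session is
analysed; a second session stored in the container (`rest2`) is kept but
ignored, since a post-task baseline is contaminated by the task. Task
trials contribute one epoch each, taken from phase onset: the full 2 s
memory-encoding phase, and the first 2 s of the 3 s memory-maintaining
phase. Trials are not filtered by behavioural correctness; a caller can
pass any subset of trials to impose such a mask.

## Spectral conventions

All spectral features use the plain FFT of each 2 s epoch — no taper, no
zero padding, no overlap — giving 0.5 Hz bins. A frequency bin belongs to
band [lo, hi) by the half-open rule, so adjacent bands never double-count
a bin. The filter bank is delta 1–4, theta 4–8, alpha 8–13, beta 13–30,
gamma 30–45 Hz; relative power normalises by the 1–45 Hz total.

* **Relative power**: per-epoch power spectra are averaged *before* the
  band/total ratio; the pairwise feature is the asymmetry index
  (P_X−P_Y)/(P_X+P_Y) ∈ [−1, 1].
* **Coherence**: auto- and cross-spectra are means of per-epoch
  periodogram terms; per-bin magnitude-squared coherence is averaged over
  in-band bins with equal weight (a `pooled` switch sums the spectra over
  bins before the ratio instead). Bins with a zero auto-spectrum are
  excluded; a band with no usable bin raises. With a single epoch the
  statistic is identically 1 (an algebraic identity), which is why at
  least ~20 epochs are used in practice.
* Identity check: the epoch-averaged estimator equals
  `scipy.signal.coherence` with a boxcar window, `noverlap=0` and no
  detrending, which the tests assert to 1e-10.

## FB-PLI

Each channel is band-pass filtered with a zero-phase forward-backward
4th-order Butterworth (SOS form); zero phase distortion is essential
because PLI is a pure phase statistic. A linear-phase FIR alternative is
config-exposed. The instantaneous phase is the four-quadrant angle of the
Hilbert analytic signal computed over the whole epoch; an optional
edge-trim fraction discards boundary samples where filter and Hilbert
transients bias the phase.

PLI = |mean sign(sin Δφ)| with sign(0) = 0. Sine magnitudes below 1e-9
are treated as exact zero lag: mathematically y = a·x has Δφ ≡ 0 and PLI
0, but floating-point filtering and FFTs leave ±1e-13 phase noise whose
*signs* are not random, so without the dead zone a volume-conduction
surrogate would show spurious PLI up to ~0.1. The tolerance is far below
any physiologically meaningful lag (1e-9 rad ≈ 25 fs at 6 Hz).

**Chance floor.** For band-limited signals, per-epoch PLI of independent
channels is biased above zero: the phase difference decorrelates no faster
than the bandwidth allows, giving roughly T·bw effective samples per epoch
and an expected |PLI| ≈ sqrt(2/(π·T·bw)) — about 0.32 (delta), 0.28
(theta), 0.25 (alpha), 0.15 (beta/gamma) for 2 s epochs. Averaging
per-epoch PLI over epochs (the pipeline's rule) does not remove this bias.
Tests therefore judge "no coupling" against a Monte-Carlo chance oracle
(filtered independent Gaussian noise) rather than against zero; a flat
"below 0.2" criterion is unattainable for the narrow low bands.

## WM-TIER transform

The inter-state change (f_task − f_rest)/f_rest is computed per feature
and participant. Features with |f_rest| < 1e-6 are excluded cohort-wide
(not imputed): a feature unusable for one participant cannot enter
leave-one-participant-out evaluation consistently. No clipping is applied;
changes of bounded features may exceed [−1, 1]. ME-TIER and MM-TIER are
built and evaluated separately, never pooled.

## Feature selection and LOPO-CV

Fisher's criterion F = [(m₁−m)² + (m₂−m)²]/(s₁²+s₂²) uses unbiased class
variances and an additive denominator floor of 1e-12 so two constant equal
classes score 0 rather than 0/0; for three classes the sums extend over
all classes. Ranking is a stable descending sort (ties to the lower
feature index); the top `dc` (default 100, covering the optimal sizes
observed in practice, ≤ 71) are candidates. For each n = 1..dc the LOPO
accuracy of the top-n features is measured; the optimal d is the smallest
n attaining the curve maximum (parsimony tie-break).

Two protocols are provided. `paper` mode ranks once on the full cohort
before the LOPO loop — the original framework's protocol, which lets each
fold's held-out participant influence the ranking and therefore carries
selection bias; the package logs a warning once per process. `nested` mode
recomputes the ranking inside every training fold; an instrumentation test
verifies that the held-out row never reaches ranking, standardisation
statistics, or the SVM kernel width in any fold. `paper` is the default
for fidelity; use `nested` for unbiased estimates.

LOPO accuracy estimates on null data are biased *below* chance for
prior-sensitive classifiers (training priors shift against the held-out
class — the classic leave-one-out anti-learning effect, ~0.29 for LDA at
N = 20 with one feature). Chance-level calibration tests therefore use
uniform-random prediction (exactly 1/3 for three balanced classes) or KNN,
which shows only a mild version of the bias.

## Classifiers

* **LDA** is implemented from the closed-form decision function with
  pooled within-class covariance (scatter sum / (N−2)), equal class
  penalty weights, and priors equal to training class proportions. If the
  covariance condition number exceeds 1e8 it is ridge-regularised with
  λ = 1e-6·trace(Σ)/d. A decision value of exactly 0 goes to the negative
  (second sorted) class. Predictions are cross-checked against
  scikit-learn's LDA in the tests.
* **SVM** uses scikit-learn's `SVC` with C = 100 and
  γ = 1/(d · mean per-feature variance of the training inputs) — computed
  on the standardised training fold, where it reduces to 1/d.
* **KNN** (K = 3, Euclidean) is implemented directly so ties are
  deterministic: equal distances at the K-th neighbour resolve to the
  lower training index, and a vote tie to the class of the nearest
  neighbour.
* **LR** selects (penalty ∈ {L1, L2}, C ∈ {0.001..100}) by an inner
  leave-one-out grid search on the training portion of each fold;
  accuracy ties prefer the smaller C, then L2 — the stronger-regularised,
  more conservative model.
* Features are z-scored with training-fold statistics before SVM/KNN/LR
  (the γ rule presumes commensurate scales); LDA is scale-equivariant and
  uses raw features.
* Three-class problems use one-against-one majority voting for the binary
  classifiers (LDA, SVM): three pairwise models vote, a label with ≥ 2
  votes wins, a three-way tie is resolved by the largest absolute decision
  value and then by the fixed precedence AD > MCI > HC. KNN and LR
  predict three classes natively.

## Group contrasts

Edge-wise statistics use the mean difference, calibrated by permutation
rather than a t-distribution, to avoid variance assumptions on bounded
connectivity values: sign-flipping of per-participant differences for the
paired rest-to-task contrast (all 2^n flips enumerated exactly when
2^n ≤ n_perm), group-label shuffling for unpaired contrasts; 10,000
permutations by default, seeded, with p = (1+k)/(1+B). Multiple
comparisons are corrected with Benjamini–Hochberg FDR across the edges of
each band at α = 0.05 (Bonferroni available). Effects are signed as the
first-listed state/group minus the second, so a task-state increase is
positive. This permutation+FDR procedure is this package's own choice of
test, not a reproduction of any particular clinical analysis.

## Synthetic cohorts

Each channel is a sum of five narrowband oscillations (one per band) plus
1/f^1.0 background noise scaled so the in-band (1–45 Hz) SNR is 0 dB by
default. An oscillation has a per-recording carrier drawn from the middle
half of its band, slow frequency jitter (SD = bandwidth/6, smoothed over
0.25 s) and a weak phase-diffusion random walk — independent channels
decorrelate across epochs while staying band-limited. Coupling is imposed
in phase: the target channel's band phase equals the source phase plus a
von-Mises(μ, κ) lag redrawn every 0.5 s block, making within-epoch phase
statistics stationary while epochs vary. κ = 0 means independence; at
0 dB SNR the measured PLI saturates near 0.55 for κ ≳ 10 because phase
estimation noise flips signs, so "strong coupling vs none" spans roughly
0.26–0.55 under default noise and up to ~0.95 at 6 dB.

The default cohort follows the study protocol: 27 HC / 24 MCI / 21 AD
participants, 30 channels of the 10–20 montage, 500 Hz, one 90 s resting
session, and 10 trials × 3 task types × 2 sessions of 2 s ME + 3 s MM
phases. Rest-to-task coupling changes follow the qualitative group
patterns: HC gains parietal theta coupling (P3–Pz, P4–CPz) and loses
fronto-central coupling (Fz–FCz, F3–FC3); AD loses coupling diffusely
(fronto-central, central, temporal, occipital) with no compensatory
increase; MCI changes centrally (C3–Cz up, C4–FC4 down). Edges destined
to strengthen start from weak resting coupling (κ = 1.5) and edges
destined to weaken from strong coupling (κ = 10), so both directions have
dynamic range within the PLI saturation limits. Participant-level
lognormal random effects (σ = 0.25) on κ create inter-individual
variability; the same factor applies to an edge at rest and task, so the
planted change survives the random effect.

What the generator does *not* emulate: volume conduction and a realistic
leadfield (channels are independent except for planted couplings),
artifacts (blinks, EMG), non-stationarity over the session,
amplitude–amplitude coupling, and realistic per-band power ratios.
Passing tests therefore demonstrate that the pipeline recovers the kind of
band-specific phase-coupling structure it targets — not clinical validity
on real EEG.

## Desk-scale test sizes

Tests run the pipeline at reduced scale as the package's own choice of
desk-scale conditions: 250 Hz (125 Hz for the seeded recovery sweep),
10–17 channels chosen to include the planted electrodes, 44 s resting
recordings, and 5–8 trials per type in one session. The end-to-end
three-class check keeps the full study group sizes (27/24/21). The
parameter-recovery sweep uses a strong-effect regime (6 dB SNR, κ random
effect σ = 0.1, 16 task epochs) in which the two group-distinguishing
edges rank in the global top 4 of 225 TIER features in 20/20 seeds.

## Known limitations

* `paper`-mode accuracies are optimistically biased by design (see above);
  nested mode is the defensible estimate.
* Per-epoch PLI retains the band-limited chance floor; comparisons between
  conditions are meaningful, absolute PLI values near the floor are not.
* The EDF writer is minimal (16-bit, one-second records, whole-second
  recordings) — sufficient for fixtures and export, not a general-purpose
  EDF+ implementation.
* The permutation contrasts assume exchangeability within/between groups;
  no covariate adjustment (age, sex) is provided.
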