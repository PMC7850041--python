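# Methods

This note records the models, conventions and numerical choices behind
`memsme`, in the spirit of a statistics package's model documentation.

## Behavioural statistics

**Serial-position curve.** Per subject and position, the fraction of
presented items later recalled. Practice lists are never generated or
scored; list indices start at the first scored list.

**Temporal clustering score.** For each recall transition (output rank
r → r+1 within a list), the serial-position distance of the recalled
item is percentile-ranked against the distances of all items *not yet
recalled* at that point (the just-recalled item excluded). The
percentile convention is

    score = (#other candidates strictly farther + ½ · #tied) / #other candidates,

which makes a unique nearest-neighbour transition score exactly 1.0 and
gives expectation exactly 0.5 under a uniformly random recall order
(for any candidate multiset, averaging the half-tie rank over a uniform
target gives ½). Transitions with no alternative candidate are skipped;
repetitions and extra-list intrusions are outside the data model (the
events table contains only correct first recalls). Across-list
transitions are never scored. Subject score = mean over all transitions.

**Adjusted ratio of clustering (ARC).** Per categorized list with N
recalls across categories with counts n_i:

    R    = number of adjacent same-category recall pairs
    E[R] = Σ n_i (n_i − 1) / N          (exact chance expectation)
    maxR = N − #categories recalled
    ARC  = (R − E[R]) / (maxR − E[R]).

The chance expectation uses denominator N: each of the N−1 adjacent
slots is a same-category pair with probability Σ n_i(n_i−1)/(N(N−1)),
so E[R] = Σ n_i(n_i−1)/N, which is what places chance at 0 (verified by
simulation in the tests). Degenerate lists (fewer than two recalls, or
a single recalled category, where maxR = E[R]) are excluded from the
subject mean.

**Group tests on recall.** Per-item recalled (0/1) is modelled with a
*linear* mixed model (random intercept per subject; fixed effects:
categorical serial position, task variant, group), fitted by maximum
likelihood so likelihood-ratio tests are valid; the group main effect
and the group × task interaction are 1-df LR χ² statistics. A linear
probability model keeps the LR χ² reporting conventional for this
literature; it is not a logistic fit. Degenerate fits (boundary
random-effect variance on near-homogeneous data) are reported with
`converged = False` and NaN statistics rather than dropped. Clustering
scores are compared between groups with Welch's unequal-variance t.

## Spectral pipeline

**Preprocessing.** Excluded channels (epileptogenic/inter-ictal) are
dropped first. Monopolar montages are re-referenced to neighbouring
contact differences; bipolar input passes through unchanged. Line noise
is removed with a zero-phase (forward–backward) Butterworth band-stop
of order 4 over 58–62 Hz. High-frequency analyses require
fs ≥ 340 Hz (2 × 170); the generator default is 500 samples/s, which
also covers the classifier's 180 Hz ceiling.

**Morlet decomposition.** Complex Morlet wavelets with wave number 5
(Gaussian SD σ_t = 5/(2πf), truncated at 3.5 σ, L1-normalized
envelope), applied by FFT convolution with the data FFT shared across
frequencies. Epochs carry a 1.0 s buffer at each end — at the lowest
analysis frequency (3 Hz) three wavelet SDs span 0.8 s — and the buffer
is trimmed after convolution, so edge artefacts never reach analysis
windows. The default SME grid is 20 log-spaced frequencies on
[3, 170] Hz.

**Power features.** Wavelet power is log-transformed, averaged over the
encoding window (400–1100 ms post-onset for the SME; 0–1366 ms for the
classifier), then z-scored over items within each session per
channel × frequency — one feature per item/channel/frequency with exact
zero mean and unit SD per session. Zero-variance cells map to 0 with a
warning. The z-scoring is applied after window-averaging so the
per-cell unit-SD contract holds exactly.

**SME contrast.** Welch's unequal-variance t per channel × frequency,
recalled minus not-recalled; positive t = more power during successful
encoding. Multi-session subjects are pooled at the item level after
within-session z-scoring (maximizing item counts per contrast).
Region × band cells average t over a region's channels and the grid
frequencies inside the closed band interval (theta 4–8 Hz, following
the methods convention over the looser 3–8 Hz introduction usage; HFA
45–170 Hz); grid frequencies outside both bands do not enter cells.
Group contrasts are Welch t per cell with Benjamini–Hochberg step-up
applied jointly over all 8 cells.

## Theta connectivity

Phase comes from the same Morlet transform at 4, 5, 6, 7, 8 Hz. Per
item and pair, the phase-difference time series over 400–1100 ms is
summarized by its *circular* mean (the resultant angle of
exp(i(φ_a − φ_b))); the PLV of a recall class is the modulus of the
mean unit phasor over that class's items. The connectivity SME is
PLV(recalled) − PLV(not recalled) averaged over the five frequencies.
Its null uses 500 label shuffles — one shared shuffle sequence across
all pairs, preserving class sizes and cross-pair dependence — and
Z = (observed − null mean)/null SD. ROI edges average Z over channel
pairs spanning each unordered pair of distinct regions; subjects
without an inter-ROI pair are excluded from group tests with a warning.
Exported display networks keep |Z| > 1.96. Zero null SD yields a
missing edge with a warning.

## Recall classifier

Features: log Morlet power over 0–1366 ms at 8 log-spaced frequencies
on [3, 180] Hz per electrode, z-scored within session (a flag restores
raw windowed log power). Model: L2-penalized logistic regression with
inverse-regularization C = 2.4 × 10⁻⁴ — C follows the scikit-learn
convention, smaller = stronger penalty — and observation weights
n_total/(2 n_class) (sklearn's 'balanced'), fitted with the
deterministic liblinear solver. Cross-validation is leave-one-session-
out when a subject has ≥ 2 sessions, otherwise leave-one-list-out;
out-of-fold probabilities are pooled, the ROC is a threshold sweep over
the pooled probabilities and the AUC its trapezoidal area (equal, to
rounding, to the normalized Mann–Whitney U — asserted in tests at
1e-10). Folds whose training data contain one class are skipped and
their items drop from the pool. Permutation significance permutes the
labels across items with the fold structure fixed, re-runs the full CV,
and reports p = (1 + #{null AUC ≥ observed})/(n_perm + 1); the default
n_perm = 1000 is exposed, the pipeline driver leaves it off by default
because it multiplies runtime by the shuffle count.

## Cohort matching

Propensity scores come from a binomial GLM of case membership on
standardized demographic/coverage covariates (constant columns are
dropped; quasi-separation is flagged, not fatal). Matching is greedy
without replacement: cases in descending propensity order each take
their `match_ratio` (default 3) nearest unused controls by |Δ
propensity| on the probability scale (logit scale available), with
handedness required to match exactly; ties break on subject id, making
the procedure deterministic. Without-replacement is enforced so the
matched control pool contains distinct subjects (ratio × #cases when
feasible; shortfalls are flagged). Balance reporting gives standardized
mean differences (pooled-SD denominator) and Welch t p-values for case
vs all controls and case vs matched controls, for every model
covariate.

## Synthetic-data generator

The generator is first-class code: it defines the conditions every test
runs under.

*Behaviour.* Recall probability per serial position defaults to
0.25 + 0.35·exp(−(pos−1)/2.5) — a primacy advantage with no recency
boost, as the post-list distractor suppresses recency; mean recall rate
≈ 0.33. A per-subject ability shift (SD 0.08 on the probability scale)
gives the between-subject variance real cohorts show and random-
intercept models require. Recall *order* is a sequential softmax over
not-yet-recalled items with weight exp(−s_t·|lag|)·exp(s_c·same-cat);
the first recall uses exp(−s_t·(pos−1)) so the s_t → ∞ limit is exact
study order, and s_t = s_c = 0 is a uniform random permutation (placing
the temporal score at 0.5 and ARC at 0). Categorized lists are 3
categories × 4 exemplars in successive same-category pairs with
adjacent pairs from distinct categories, sampled by rejection.

*Signals.* Epochs (default −0.2 to 1.5 s around onset plus a 1.0 s
buffer per side, 500 samples/s) are 1/f-shaped noise (spectral shaping
of white noise, exponent 1.0) plus unit-SD band-limited components:
theta (4–8 Hz) and broadband high-frequency (45–170 Hz). Effect deltas
are declared in approximate z-units of the downstream session-
normalized features: the component amplitude is scaled by
exp(delta·scale/2) on recalled items with per-band scale constants
(0.90 theta, 0.27 HFA) equal to the measured item-to-item SD of
windowed band log power under the defaults — a single constant cannot
serve both bands because short-window theta power is intrinsically much
noisier than broadband HFA. Phase coupling for designated channel
pairs replaces the two channels' theta components by a *shared*
waveform on a per-item basis with probability base_plv (not recalled)
or base_plv + sync_plv_delta (recalled), which yields an empirical PLV
contrast close to sync_plv_delta at study-scale item counts.

*Cohort.* Covariates follow plausible epilepsy-surgery marginals (age
≈ N(40, 12), 80/15/5% R/L/A handedness, 4-region coverage and
seizure-onset-zone indicators); the binary group label is drawn from a
logistic model on the standardized design with user-supplied
coefficients, retained for recovery tests.

*What the generator does not emulate* — and hence what passing tests do
not show about recorded data: epileptiform and muscle/eye artefacts,
real word-pool semantics (categories are symbolic integers),
non-stationary noise, volume conduction between neighbouring contacts,
heterogeneous electrode counts per subject, and the true effect
topography of memory encoding. Tests demonstrate calibration and
recovery of *injected* effects, not properties of any clinical cohort.

## Problem sizes and determinism

Default study scale for calibration runs: 20–25 scored lists × 12
items per session, 4–21 channels over the four regions (frontal, MTL,
LTC, parietal), 500 connectivity shuffles. The test suite uses these
desk-scale sizes (e.g. 50-seed sign-recovery runs restrict the wavelet
grid to the band-internal frequencies, which leaves region × band cells
unchanged). All randomness derives from explicit integer seeds through
`numpy.random.SeedSequence`; identical seeds give bit-identical tables,
epochs and JSON artifacts, and every pipeline output is stamped with
the root seed and a hash of the analysis parameters (output paths
excluded from the hash).

## Known limitations

- The linear-probability mixed model can produce fitted probabilities
  outside [0, 1]; it is used for LR testing, not prediction.
- The permutation Z assumes exchangeability of item labels within
  subject; slow within-session drift would violate it in real data.
- Greedy matching is order-dependent by construction (descending case
  propensity); optimal matching is out of scope.
- The generator's PLV injection controls the *alignment probability*,
  not the PLV directly; the realized contrast depends on item counts
  and the theta SNR.
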