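# Methods

This note records the models, defaults, numerical choices and known
limitations of the `dyadsync` pipeline, in the order data flows through
it.

## Motion energy

Movement displacement is the summed absolute difference of raw integer
RGB values between frames `i·s` and `(i−1)·s` inside a rectangular
region of interest (default step s = 5, i.e. 6 Hz at 30 fps). Output
length is `floor((n_frames − 1)/s)`; sample i is stamped at time
`i·s/fps`. Differences are taken per channel and summed — no luminance
collapse — because the change signal of interest is any pixel change,
and summing channels is the simplest monotone aggregate. A
`count_changed` mode counts pixels whose largest per-channel change
exceeds a threshold (default 10) instead; unthresholded counting would
saturate on sensor noise. The default mode is `sum_abs`. No detrending
or normalization happens at this stage: the windowed correlation
downstream standardizes within each window, which also makes all WLCC
outputs invariant to affine scaling of the series.

## Windowed lagged cross-correlation

Windows are tumbling (10 s long, 10 s step) by default; overlap is
configurable. Within a window starting at sample `s` with length `W`,
the correlation at lag ℓ pairs `da[t]` with `naive[t−ℓ]`; lagged
samples are drawn from beyond the window edge when the series extends
there, and truncated otherwise. A window contributes a missing value at
a lag when fewer than `min_window_fraction` (default 0.8) of its pairs
exist or when either slice has zero variance; missing values propagate
(never silently become zeros). The per-lag aggregate is the plain mean
of window correlations (a Fisher-z mean is available). Sign convention:
positive lag means the DA's behavior correlates with the naive
partner's earlier behavior.

The three summary indices average the aggregated profile over fixed
lag sets: lags {−1, 0, +1} samples (~Lag 0ms) and the remaining
positive/negative lags out to 1000 ms (five lags each at 6 Hz). The
seven coarser prediction bins are means of the aggregated profile over
1000-ms lag bands: bin 0 is the ~Lag 0ms set; bin ±b covers lags in
((b−1) s, b s] on that side, excluding bin 0's samples, out to ±3 s.

## Speech rate

Syllable nuclei are proxied by voiced intensity peaks inside utterance
intervals. Candidate local maxima are accepted greedily in time order
when the intensity valley between a candidate and the previously
accepted peak is at least `min_dip_db` (default 2 dB) below both and
the peaks are at least `min_separation_s` (default 100 ms) apart;
otherwise the higher of the two competing peaks is retained. These
defaults follow common syllable-nucleus practice for conversational
speech.

The rate series counts onsets in left-aligned half-open windows
[t, t+5 s), slid in exact steps of 1/3 s (windows fully inside the
span only), scaled by 20. Note that count × 20 is syllables per 100 s,
not per minute (that would be × 12); the conventional factor is kept as
the default because every downstream coordination metric z-scores the
series, making them invariant to this affine scale. The half-open
window convention makes boundary counting unambiguous; computing window
starts as `t0 + j/3` on a rational grid avoids cumulative drift over
8-minute conversations.

## Cross-recurrence quantification

Both series are z-scored (a zero-variance series is a reported error,
not a silent exclusion), delay-embedded with dimension m = 3 and delay
τ = 3 samples (1 s at 3 Hz — one window's worth of context for short
behavioral series), and thresholded at radius ε under the euclidean
norm. The main diagonal is *not* excluded: a cross-recurrence plot
between two distinct series has no trivial line of identity (a
self-comparison therefore shows LMAX equal to the embedded length —
intentional, and used as a limit-case test). No Theiler window is
applied by default (`theiler=0`), but one is available.

Indices: RR is the density of recurrent points; DET the fraction of
recurrent points on diagonal lines of length ≥ lmin (default 2); L and
LMAX the mean and maximum of those line lengths; ENTR the Shannon
entropy (nats) of their length histogram; T2 the mean gap between the
*start* indices of consecutive vertical runs within a column
(recurrence time of the second type — the toolbox-standard reading of
"average distance between repetitions"). Undefined values (L with no
lines, T2 with no column revisited twice) are reported as NaN, never
as 0, so that condition averages are not biased toward zero.

The radius is calibrated once, globally, by bisection so the pooled
mean RR across all real pairs hits a target (default 5%, tolerance
±10% relative). A single global ε preserves between-condition RR
differences; a per-pair fixed-RR radius would erase exactly the effect
the RR contrast is meant to measure. Because RR(ε) is a step function,
bisection can in principle straddle the target on tiny datasets; this
raises a calibration error with diagnostics rather than returning a
silently out-of-tolerance radius.

## Virtual pairs

Within every (veracity, conflict) condition cell, conversations are
re-paired by a seeded random derangement with respect to dyad
membership (no virtual pair joins members of one original dyad; every
conversation appears exactly once on each side). Both condition labels
are matched. Unequal series lengths are right-truncated to the common
length. One plan per seed; the pipeline can average over several
seeded plans (default 1).

## Prediction

Twenty features per conversation: 14 movement lag-bin means (7 bins ×
head / lower body) and 6 CRQA indices. Rows with any missing feature
are flagged and excluded from model fitting, never imputed. Folds are
grouped by dyad and stratified by class (`StratifiedGroupKFold`), so
no dyad contributes to both training and test; the veracity label is
within-dyad (each dyad has one deceptive and one truthful
conversation), the conflict label between-dyad.

Feature selection on each training fold is an elastic-net-penalized
logistic regression (mixing ratio 0.5 by default, configurable). The
penalty strength is tuned on a log-spaced grid by 3-fold inner
cross-validation scoring the *entire* select-then-refit procedure —
features selected at each candidate penalty, an unpenalized refit on
them, held-out log-loss of that refit — with the one-standard-error
rule choosing the strongest penalty within one SE of the best score.
Two numerical details matter here. First, scoring the penalized model
itself (rather than the refit) rewards weak penalties for reduced
shrinkage and over-selects badly; the criterion must match the
deployed two-stage predictor. Second, the inner log-loss clips
probabilities at 10⁻³: the unpenalized refit diverges on separable
inner-training splits, and an unbounded log-loss lets a single
wrong-side validation point condemn an otherwise excellent subset. An
empty selection predicts the training-fold majority class.

Pooled fold confusions per repeat are summarized by the conjugate-Beta
balanced-accuracy posterior: sensitivity ~ Beta(TP+1, FN+1),
specificity ~ Beta(TN+1, FP+1) with uniform priors, balanced accuracy
their mean, summarized by Monte-Carlo draws (posterior mean, central
95% interval, P(BA ≤ 0.5)). This closed-form conjugate formulation is
this package's implementation of a Bayesian balanced accuracy that
keeps sensitivity and specificity at comparable weight; it is
validated in the test suite against a numerical-convolution oracle for
the average-of-two-Betas distribution. Results aggregate posterior
mean, CI bounds, sensitivity, specificity and P(BA ≤ 0.5) across
repeats (default 100) and tally per-repeat feature selections. The
reported p is the posterior probability that balanced accuracy is at
or below chance.

## Synthetic dyad generator

The generator defines the conditions under which the pipeline is
validated; its defaults are fixed once and are not fitting knobs.

*Movement.* Each participant's latent is a zero-mean
Ornstein–Uhlenbeck process simulated by Euler–Maruyama at the sampling
rate (defaults θ = 0.8 s⁻¹, σ = 1, 6 Hz) — smoothly autocorrelated
like real motion energy, trivially seedable. The DA latent is
(1−g)·independent OU + g·(naive latent delayed by round(k·rate)
samples); the lag is exact on the sample grid because the naive latent
is simulated with a k-sample prefix. Both latents pass through a
softplus to mimic nonnegative displacement. Condition effects enter
only through (g, k, c) — coordination structure, never marginal
levels — so any condition difference a metric reports is a coupling
difference by construction.

*Speech.* Turns strictly alternate with exponential durations (mean
8 s, truncated at a 1 s minimum to avoid degenerate turns) separated
by a 0.25 s gap. Each turn's generating syllable rate is
(1−c)·own base rate + c·partner's realized rate on the previous turn,
plus Gaussian noise (0.4 syll/s), clipped at zero; onsets are a
Poisson process within the turn. Default base rates 3.5 and 4.5
syll/s — within the conversational range and deliberately different
between partners.

*Video.* A horizontally gradient-textured block inside each region of
interest jiggles left/right on alternating frames with an offset
proportional to the participant's displacement sample (held across the
fps/rate frames of each sample). The gradient texture makes the frame
difference approximately linear in the offset change, so motion-energy
extraction rank-recovers the latent series (ρ > 0.9 in tests); an
independent-noise texture would saturate at any nonzero shift.

*What the generator does not emulate.* Real camera noise, lighting
drift, occlusion and person tracking; articulatory and prosodic detail
(onsets are a homogeneous Poisson process within turns); overlapping
speech and backchannels; long-range nonstationarity in engagement.
Passing tests therefore show the *analysis chain* is correct and can
recover injected coupling at realistic sizes — not that real
conversational data meet these assumptions.

## Study-level defaults

Conversations default to 480 s (two 8-minute conversations per dyad);
studies to 20 dyads, half per conflict condition, veracity order
counterbalanced by seeded draw. The default condition effects encode
the qualitative design target — coordination greatest in deceptive
disagreement — as g/k/c = (0.7, 0.5 s, 0.7) for deceptive
disagreement, (0.5, 0.5, 0.5) deceptive agreement, (0.4, 0.3, 0.4)
truthful disagreement, (0.3, 0.3, 0.3) truthful agreement; the
lower-body control channel keeps a fixed weak coupling (g = 0.15,
k = 0) in all cells. Replicate-based tests use 240 s conversations
and 6–10 pairs per group, sizes at which the recovery properties hold
with comfortable margins; the acceptance script runs the full
20-dyad × 480 s study.

## Known limitations and honest caveats

- The real-vs-virtual contrast on *speech-rate RR* can invert: strict
  turn alternation anti-aligns real partners' rate series (one speaks
  while the other is silent), which lowers real pairs' pointwise
  recurrence relative to re-paired pseudo-dyads even when rate
  matching is present. The matching effect itself is recovered
  reliably *within* pairing type (matched > unmatched). Interpret
  surrogate contrasts per modality.
- Embedding parameters (m, τ, ε policy) materially affect CRQA levels;
  every run logs the full parameter set, and ε calibration is global
  by design.
- The balanced-accuracy posterior conditions on pooled fold
  confusions; repeats are correlated through the shared dataset, so
  the across-repeat spread reflects fold-assignment variability, not
  sampling variability of new dyads.
- WLCC windows are tumbling by default; whether overlapping windows or
  edge-truncated windows should contribute is configurable, and the
  defaults are stated here rather than hidden.
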