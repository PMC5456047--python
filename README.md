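# dyadsync

Multimodal analysis of interpersonal coordination in dyadic
conversation: how two people's body movement and speech rate become
coupled while they talk, and whether that coupling carries information
about deception and disagreement.

The package re-implements, as a tested and reusable pipeline, the
analysis chain of a "devil's advocate" conversation design, in which
one participant (the DA) covertly argues against their own opinion
while the naive partner is unaware deception may occur. It is intended
for researchers in behavioral dynamics who want the full chain — from
video frames and utterance annotations to condition-level coordination
tables and cross-validated predictions — with every numerical step
testable against brute-force oracles and synthetic data with known
ground truth.

## What it computes

**Motion energy** (`dyadsync.motion`). A participant's continuous
movement-displacement signal from video by frame subtraction inside a
region of interest: at 30 fps every 5th frame is compared, giving a
6 Hz series of summed absolute RGB change (or of changed-pixel counts).

**Windowed lagged cross-correlation, WLCC** (`dyadsync.wlcc`). For
windows of 10 s and lags ℓ on the sample grid (1/6 s steps up to
±5 s), the Pearson correlation r_w(ℓ) of the DA's series against the
naive partner's series shifted by ℓ, aggregated over windows into a
lag profile r̄(ℓ). Positive lags pair the DA with the partner's
*earlier* behavior (DA following). Three indices summarize the
profile: **~Lag 0ms** (mean of r̄ over lag 0 ±1 sample),
**DAFollows 1000ms** and **NaiveFollows 1000ms** (mean of r̄ over the
remaining positive / negative lags out to 1 s).

**Speech rate** (`dyadsync.speech`). Voiced intensity peaks inside
tagged utterances serve as syllable-nucleus proxies; counting onsets in
5-second windows slid by 333 ms (count × 20) yields a 3 Hz
estimated-syllable-rate series per speaker.

**Cross-recurrence quantification, CRQA** (`dyadsync.crqa`). Both rate
series are z-scored and delay-embedded (default m = 3, τ = 3 samples);
the cross-recurrence plot marks state pairs within radius ε, and six
indices quantify it: RR (recurrence rate), DET (fraction of recurrent
points on diagonal lines ≥ 2), L (mean line length), LMAX (longest
line), T2 (mean gap between starts of vertical runs), and ENTR
(entropy of the line-length distribution). A single global ε is
calibrated so the pooled mean RR hits a target (default 5%).

**Virtual pairs** (`dyadsync.surrogates`). Each DA is re-paired with a
naive participant from a different dyad in the same condition cell (a
seeded derangement); all metrics recomputed on these pseudo-dyads give
the task-level baseline against which real coordination is judged.

**Prediction** (`dyadsync.predict`). Twenty features per conversation
(7 WLCC lag-bin means × {head, lower body} + 6 CRQA indices) enter a
dyad-grouped, stratified 5-fold cross-validation repeated many times:
elastic-net-penalized logistic regression selects features on each
training fold (penalty tuned by inner CV with the one-standard-error
rule), an unpenalized refit predicts the held-out fold, and pooled
confusion counts get a Bayesian balanced accuracy — sensitivity
~ Beta(TP+1, FN+1) and specificity ~ Beta(TN+1, FP+1), balanced
accuracy their average, reported as posterior mean, 95% interval and
P(BA ≤ 0.5).

**Synthetic dyads** (`dyadsync.simulate`). Every stage is exercised on
generated conversations with known structure: Ornstein–Uhlenbeck
movement latents with tunable coupling gain g and lag k
(DA = (1−g)·own + g·partner delayed by k, softplus-transformed),
alternating-turn speech whose per-turn syllable rate partially matches
the partner's previous turn (weight c), condition effects injected
only through (g, k, c), and rendered frame stacks whose ROI pixel
change tracks the latent series.

## Worked example

```python
from dyadsync import (MovementSimParams, generate_movement_pair,
                      lag_profile, summarize)

params = MovementSimParams(duration_s=480, coupling_gain=0.7,
                           coupling_lag_s=0.5, seed=42)
naive, da = generate_movement_pair(params)
profile = lag_profile(da, naive)
s = summarize(profile)
print(f"profile peak at {profile.argmax_lag_s()*1000:.0f} ms")
print(f"~Lag 0ms            = {s.lag0:.3f}")
print(f"DAFollows 1000ms    = {s.da_follows_1000:.3f}")
print(f"NaiveFollows 1000ms = {s.naive_follows_1000:.3f}")
```

prints

```
profile peak at 500 ms
~Lag 0ms            = 0.478
DAFollows 1000ms    = 0.693
NaiveFollows 1000ms = 0.162
```

The generator injected a 0.5 s coupling lag with the naive participant
leading; the lag profile peaks at exactly +500 ms, and the asymmetry of
the two follower indices (0.693 vs 0.162) correctly attributes the
following to the DA. Continuing with speech:

```python
from dyadsync import (SpeechSimParams, generate_speech_pair, rate_series,
                      EmbeddingParams, crqa_metrics)

sp = generate_speech_pair(SpeechSimParams(duration_s=480, matching_c=0.7,
                                          seed=42))
ra = rate_series(sp.events_a, (0, 480))
rb = rate_series(sp.events_b, (0, 480))
print(crqa_metrics(ra, rb, EmbeddingParams(radius=0.5)).as_dict())
# {'RR': 0.072, 'DET': 0.916, 'L': 6.398, 'LMAX': 76.0,
#  'T2': 60.413, 'ENTR': 2.48}
```

With strong rate matching, 7.2% of state pairs recur and 92% of
recurrences form repeated sequences of mean length ~6.4 samples
(~2 s at 3 Hz).

## Command line

`dyadsync` exposes `simulate`, `motion`, `speech`, `wlcc`, `crqa`,
`surrogate`, `predict` and `run-all` subcommands; `run-all` simulates
(or ingests) a study, writes the tidy real + virtual metrics table,
per-condition lag-profile and CRQA figures, prediction JSON and a full
provenance log:

```
dyadsync run-all --seed 1 --out out/
```

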