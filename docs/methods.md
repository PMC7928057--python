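# Methods

## The system being modelled

Two DC motors pull the facial skin at one site through wires and tabs, one
vertically and one horizontally. Because the coupling is a wire, each motor
can only pull: all commanded forces are non-negative. Stimulus intensity is
controlled in force rather than position so that the delivered force is
consistent across participants with different tissue compliance. Force
control is realized as current control: motor force is linear in winding
current (F = k_f · I with k_f the lumped force constant, N/A), so the
target force is converted to a target current by the inverse motor model,
and a discrete PID controller corrects the error between target and sensed
current at a 100 Hz loop rate. Timing between the two channels is therefore
quantized to 10 ms control ticks.

## Stimulus model

A "sinusoidal pulse" that must stay non-negative is realized as one period
of a raised cosine,

    p(t) = peak · (1 − cos(2π f t)) / 2,   t ∈ [0, 1/f],

with f = 6 Hz and peak = 2 N by default: duration 1/6 s ≈ 167 ms, a single
maximum at mid-pulse, zero at both ends. A lagged pair places two identical
pulses on a common time base with the vertical onset leading by `lag` ms
(trailing for negative lags). Lags must be integer multiples of the control
interval; the design's ±10 ms conditions are exactly one loop tick. The
trace is padded with 200 ms of pre-silence and 300 ms of post-silence —
values not dictated by the experimental protocol, chosen so the largest
±120 ms lag fits with margin and onsets never sit at the trace boundary.
The full design crosses 14 lags (±10…±120 ms) with 15 repetitions in a
seeded uniform random permutation (210 trials).

## Control loop and plant

Per channel and per 10 ms step, with r the clipped target current and y the
sensed current (true current plus Gaussian sensing noise):

1. error e = r − y; PID drive = k_p·e + k_i·∫e dt + k_d·Δe/Δt, with a
   backward-Euler integral (the current step is included), first-difference
   derivative, no derivative filter, and anti-windup clamping the integral
   term to the motor's current limit;
2. plant input u = r + drive (feedforward plus feedback; a `feedforward`
   flag switches to PID-only drive), clipped to [0, I_max];
3. the current follows first-order electrical dynamics
   i ← α·i + (1−α)(u − d), α = exp(−Δt/τ_e), clipped to [0, I_max].

The skin load enters as the disturbance current d. The skin spring (k_s,
N/m) acts in series with the wire/tab coupling stiffness (k_c, N/m):
quasi-statically the skin absorbs the fraction β = k_s/(k_s + k_c) of the
produced current-equivalent force, and the damper adds a term proportional
to the current's rate of change:

    d = β·i + (c / (k_s + k_c)) · di/dt.

This divider form was chosen over integrating the mass–spring–damper ODE
because it makes the loaded attenuation strictly and smoothly monotone in
skin stiffness — the qualitative property of interest — while a literal
quasi-static spring (x = F/k) yields a reaction force independent of k. The
`moving_mass` field is validated but unused by this quasi-static plant.
β = 0 (stiffness = damping = 0) is the unloaded bench condition.

Defaults: k_f = 1 N/A, R = 2.1 Ω, τ_e = 1 ms, I_max = 4 A (the real motor's
constants are not published; nothing downstream depends on these beyond the
stated invariants), k_s = 300 N/m, c = 2 N·s/m, k_c = 500 N/m for a
skin-like load. PID gains k_p = 0.5, k_i = 2 s⁻¹, k_d = 0 were tuned once
in the unloaded noiseless simulation to ≤ 5% peak tracking error on the 2 N
pulse (measured: −0.8%). Note the discrete loop with the fast electrical
pole has an effective closed-loop pole at −k_p, so k_p < 1 is a hard
stability limit at this loop rate. Sensing noise sd defaults to 0.03 A,
calibrated so a single trial's onset-lag estimate has ≈ 1.5 ms standard
deviation under the default load (measured 1.56 ms over 300 trials).

## Lag verification

Both channels of a trial are up-sampled from 100 Hz to 1000 Hz by linear
interpolation followed by a zero-phase moving average (11 samples = 11 ms,
reflected boundaries — wide enough to suppress sensing noise, narrow enough
to move the 6 Hz pulse's onset by < 1 ms and its peak by < 0.5%). The onset
is the first sample strictly exceeding 10% of that trace's own maximum
(earliest-sample tie-break); the relative threshold makes onsets invariant
to amplitude attenuation, which is why the loaded device still reports
correct lags. The per-trial lag is onset(horizontal) − onset(vertical) in
ms, positive = vertical first, matching the commanded-lag convention. Lags
are averaged per condition (mean ± sd/√n) and the commanded vs measured
condition means are summarized by a Pearson correlation with its two-sided
p and regression line. The correlation is computed on the 14 condition
means; a per-trial (210-point) variant is available via
`condition_means`/`correlate_lags` composition but the condition-mean form
is the canonical summary.

## TOJ analysis

P(vertical first | lag t) is modelled as the two-parameter logistic
1/(1 + exp(−(t − μ)/s)). With only 15 trials per lag, lapse/guess
parameters are not identifiable and are omitted (the synthetic responder
supports a lapse for robustness studies). The default fit maximizes the
Bernoulli likelihood of the raw responses (L-BFGS-B, deterministic start:
μ₀ at the interpolated 50% crossing of the proportions, s₀ = lag range / 8,
bounds μ ∈ [−1000, 1000] ms, s ∈ [1, 500] ms); a least-squares-on-
proportions mode is provided for parity with analyses that fit averaged
probabilities. Complete separation does not abort: s lands on its lower
bound and the fit is flagged `at_bound`. PSE = μ; JND = s·ln 3, identical
to half the 25–75% lag span (the numeric inversion `jnd_from_curve` checks
this identity). Group inference is a one-sample t-test of the
per-participant PSEs against zero; the tail is a mandatory argument and is
recorded in every report — there is no silent default direction. The
degenerate sd = 0, mean = 0 case returns p = 0.5 with a flag. A single
planned test needs no multiplicity correction.

## Synthetic data

The responder is the generative twin of the analysis model: response ~
Bernoulli(lapse/2 + (1 − lapse)·logistic((lag − μ)/s)). Defaults are the
evaluation experiment's group values (μ = −18.37 ms, JND = 25.15 ms,
3 participants), so recovery studies run under the study's own conditions.
Cohorts draw per-participant (μ, JND) from normals around the defaults
(JND truncated > 0); the default between-participant sds of 12.5 and
3.9 ms are √3 × the published standard errors — a calibration that makes
simulated group SEs resemble the reported ones, not a published quantity.
What the generator deliberately omits: reaction times, learning or fatigue
across trials, lapse asymmetries, and any non-logistic response structure —
so passing recovery tests show the pipeline is consistent and unbiased
under its own model, not that human data follow a logistic.

## Problem sizes and numerical choices

The evaluation script simulates one full 210-trial recording set (the
device arm) and 200 replicate three-participant cohorts of 210 trials each
(the perceptual arm), completing in a few seconds; these sizes match the
original design while giving the recovery medians ≈ 0.1 ms Monte-Carlo
resolution. All randomness flows from explicit integer seeds through
numpy's PCG64 generator; per-trial and per-participant seeds are derived
deterministically so runs are byte-reproducible. CSVs are comma-separated
UTF-8 with LF endings and a leading `#` provenance comment (package
version, config hash, seed). Optimizer tolerances: 1e-10 on the likelihood
objective, 1e-12 root-finding tolerance in the curve inversion.

## Known limitations

- The plant is phenomenological: it reproduces the qualitative signatures
  (attenuation under load, preserved timing, noise-limited onset jitter),
  not a specific motor's transients. Loaded attenuation is therefore
  asserted as a strict inequality, never as a quantitative match.
- Exactly two channels are implemented; the data model (one `ForceTrace`
  per channel) does not preclude more, but nothing beyond two is tested.
- The psychometric family and fitting criterion of the original analysis
  are not published; both implemented modes satisfy the same recovery
  invariants, and reported tolerances absorb the difference.
- Real-time constraints, hardware I/O and firmware are out of scope.
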