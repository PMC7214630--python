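# Methods

## The problem

During functional electrical stimulation the recording electrodes see, on
top of the µV-level voluntary EMG, stimulation responses that are orders of
magnitude stronger: the direct artifact (current spill-over into the
amplifier), the M-wave (compound muscle action potential), late reflex
responses (H-reflex, F-wave) some tens of ms after each pulse, plus mains
hum and motion artifacts. Estimating the user's voluntary muscle
contraction (VMC) from this mixture, robustly enough to drive stimulation
proportionally, is the core signal-processing problem this package models.

## Recorded-signal model (`signal_synth`)

Sampling is 2000 Hz with one pulse per 60 ms, so the signal is organized in
bins of 120 samples; the VMC envelope lives at the 16.667 Hz bin rate.

* **Voluntary EMG** is white Gaussian noise band-passed to 20–450 Hz (the
  conventional surface-EMG band; a 4th-order Butterworth), normalized to
  unit stationary SD via the filter's impulse-response norm, then scaled
  per bin by the envelope. This makes the pooled per-bin SD converge to
  the envelope value, which is the property the estimator's calibration
  relies on. Real EMG has a non-flat spectrum, amplitude-dependent
  spectral shifts and motor-unit structure; none of that is modeled, so
  passing tests demonstrate correctness of the processing chain, not
  fidelity to any participant's EMG.
* **Stimulation responses** are per-mA templates anchored at the pulse
  sample: a biphasic double-exponential artifact confined to samples 0–19
  (so ideal blanking removes it) and a damped-sinusoid M-wave over samples
  5–45 (deliberately extending past the first blanking window, leaving
  cancellation to the comb). Template amplitudes (300 and 120 µV/mA peak)
  are plausible placeholders — no published µV values exist for this
  device — and are exposed as configuration. Linear scaling with current
  is assumed; recruitment nonlinearity is out of scope of the recorded-
  signal model.
* **Pulse-to-pulse jitter** is a multiplicative Gaussian factor
  (default SD 2 %) shared by artifact and M-wave; it is the
  non-stationary residue the comb cannot cancel and therefore the origin
  of feedback leakage.
* **Reflexes** occur per pulse with probability 0.05, amplitude
  N(0, 20 µV), centered at sample 80 with ±8-sample support and ±3 samples
  of latency jitter — matching the purpose of the second blanking window.
* **Hum** is a 5 µV, 50 Hz sinusoid with random phase. At a 60 ms bin
  length 50 Hz is exactly bin-periodic (3 cycles/bin), so the comb removes
  it; this is a genuine property of the 60 ms inter-stimulus interval.
* **Motion artifacts** are Poisson-timed (0.2 events/s) raised-cosine
  transients of 10–50 ms and Gaussian amplitude (SD 50 µV).
* **ADC**: rounding to the 2¹⁶-level grid over ±5000 µV (input-referred;
  the 60 dB amplifier gain is folded into the µV scale) with saturation.

## Estimation chain (`vmc_estimator`)

Band-pass → bins → comb → blanking → ARV → smoothing.

* **Band-pass** 16–500 Hz, one Butterworth biquad (2 poles), causal
  (`sosfilt`), −3 dB exactly at the corners. A `bandpass_enabled=False`
  switch exists so the digital stages can be analyzed in isolation: the
  IIR filter smears any time-confined contamination across the whole bin,
  so the *bit-exact* blanking-immunity and comb-annihilation properties
  hold for the chain after the filter; with the filter on they hold
  asymptotically.
* **Comb**: output bin k = bin k − bin k−1; bin 0 is defined as zero (no
  predecessor), so bin-periodic inputs are annihilated from bin 1 onward.
  The alternative (pass bin 0 through) was rejected to keep annihilation
  exact from the first output. The comb is applied to full bins and the
  ARV then ignores blanked samples — equivalent to blanking first, since
  blanked samples never enter the average.
* **Blanking** [0, 20) and [70, 90): "around sample 80" is realized as the
  symmetric 20-sample window; both windows are configuration. Blanking is
  exclusion from the average (divisor 80), not zero-filling.
* **ARV** = mean |·| over the 80 retained samples. For Gaussian input of
  SD σ its expectation is σ·√(2/π); the comb difference of two nearly
  independent bins doubles the variance, so a clean envelope A reads
  A·√2·√(2/π) ≈ 1.128·A. The estimator reports the uncorrected value, as
  the device does; `expected_arv_factor` provides the calibration factor
  (including the band-pass power loss over the EMG band, ≈ 0.92 in
  amplitude) for anyone who wants envelope units.
* **Smoothing**: v_k = α·a_k + (1−α)·v_{k−1} with α = 1 − e^(−Δt/τ),
  Δt = 60 ms, v₋₁ = 0. τ defaults to 1 s, read as the time constant of
  the "1 s default cutoff" of the device's variable low-pass.

## Controller (`controller`)

The PWL law is the minimal three-segment form consistent with the three
named parameters: I = min(I_max, g·max(0, v − v_offset)). It is
nondecreasing, g-Lipschitz and bounded by [0, I_max]. Button steps
(offset 0.5 µV, gain ×1.1, maximum 1 mA, clamps 0–100 µV, 10⁻³–10³ mA/µV,
1–60 mA) are design choices — the physical device's steps are not
documented — and are module constants. Full-on detection requires the
command at ≥ 99 % of I_max for *every* bin of a 2 s window while the true
envelope is at rest; the strict all-bins rule makes detection sensitive to
under-smoothed leakage fluctuations, which is why latch-up analyses are run
at the device-default τ = 1 s.

## Closed loop and stability (`closed_loop`)

The command computed from bin k drives the pulse of bin k+1 (one-bin
actuation delay — the causal ordering of a real-time device). Voluntary
EMG and ambient noise are command-independent and pre-generated; the
per-pulse response is injected bin by bin. The incremental filter/comb/
smoother states are propagated so that with a silent artifact model the
loop reproduces open-loop estimation bit for bit.

**Leakage** λ is *measured*, not assumed: the estimator runs on a zero-EMG
trace at constant probe current and the steady-state estimate is divided by
the probe. λ = 0 for jitter-free responses confined to blanked windows;
with jitter it is proportional to jitter SD and template amplitude.
`calibrated_leakage_model` exploits that linearity: it measures a jittered
reference model once (2000 bins, fixed internal seed) and scales the
templates to hit a requested λ.

**Latch-up criterion.** At zero offset the unsaturated fixed point of
v ← λ·min(I_max, g·v) is unstable iff g·λ > 1: the estimate then grows
until the command saturates and stimulation no longer stops when the user
relaxes. This derivation is the package's own small-signal analysis and is
tested only against the simulation. Stability scenarios use a 1 s
voluntary burst followed by rest: a resting loop at exactly zero state has
nothing to amplify, and in practice latch-up manifests when the user
relaxes after driving the device. The stability map brackets the g = 1/λ
boundary within one grid step; grid points adjacent to the boundary are
where simulation and the idealized iteration may legitimately disagree
(stochastic leakage, finite run length).

**Tracking error** compares the command against the PWL map of the
envelope scaled by `expected_arv_factor` and smoothed by the same IIR,
skipping the first 5τ as transient.

## Outcome scoring (`outcomes`)

IPPA: phase score = mean over items of importance × difficulty (1–25);
follow-up keeps baseline importances; change = baseline − follow-up
(−20…20). QUEST: eight 1–5 items; total = mean of item means. Cohort
statistics: paired Wilcoxon signed-rank (zeros dropped, tie-corrected
normal approximation with continuity correction); paired effect size
mean(change)/SD(change) (sample SD, n−1); a participant counts as a large
individual effect when change ÷ cohort SD of changes > 0.8 — this
definition is inferred, and reproduces the published count only with the
published (rounded) SD, which `cohort_summary` accepts as `sd_reference`.

**Known data inconsistency.** The shipped 27-row cohort table's published
summary row (mean change 4.6, SD 3.5) does not match recomputation from
its own rows (≈ 4.42, ≈ 2.66), and four rows (N12, S21, S22, S27) have
change values that disagree with pre − fu beyond 1-decimal rounding (N12
and S22 by 0.2–0.3). The package surfaces the recomputed and published
summaries side by side and does not force agreement.

**Synthetic cohorts** (`make_synthetic_cohort`) draw importances and
baseline difficulties uniformly on 1–5; follow-up difficulty drops to 1
with a probability chosen so the expected importance-weighted change equals
the target exactly (a uniform item has mean maximal change 6; targets
above 6 blend in maximal items with change 20; negative targets mirror the
construction). Seven items per record keep the cohort-mean Monte-Carlo
error small (≈ 0.1 at n = 500 for a 4.6 target). The logistic regressions
relating usefulness to scores are not implemented: their only published
outputs are p-values.

## Problem sizes and numerical choices

Monte-Carlo tests use 500-bin (30 s) traces, 3000-bin ARV samples and
n = 500 cohorts; stability grids use 5 leakages × 4 gains with ~10 s runs
per point — sizes chosen so each property is measured well inside its
stated tolerance while the whole suite runs in seconds. Seeds are fixed
everywhere; every generator accepts an integer seed, a `SeedSequence` or a
`Generator`. Degenerate inputs are defined rather than left to chance:
empty retained sets and empty item lists raise configuration/validation
errors, a single QUEST respondent yields flagged-undefined SDs, an
all-zero-change cohort reports effect size NaN and Wilcoxon p = 1.

## Limitations

Muscle force, fatigue, recruitment nonlinearity and grip biomechanics are
out of scope; the loop closes over the *recorded signal* only. Electrode
impedance, amplifier circuitry and multi-channel operation are not modeled.
The stability map is a property surface of the model, not a reproduction of
any participant's device settings, for which no quantitative leakage or
gain data were published.
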