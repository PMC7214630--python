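"""Closed-loop simulation of myoelectrically controlled stimulation.

The generator, estimator and controller are coupled bin by bin: the command
computed from bin k drives the stimulation pulse of bin k+1 (one 60 ms
actuation delay).  Because each stimulation pulse leaves a residue in the
VMC estimate — quantified here as a *leakage* λ in µV of estimate per mA of
stimulation — the loop contains a positive feedback path.  At zero offset
the unsaturated fixed point v = λ·g·v shows that a loop gain g·λ ≥ 1 makes
rest unstable: the command grows until it saturates at the maximum and the
device latches into a full-on state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import sosfilt, sosfilt_zi

from .controller import DeviceConfig, detect_full_on, pwl_map
from .errors import ConfigurationError, ShapeError
from .signal_synth import (
    BIN_LEN,
    BIN_RATE,
    ArtifactModel,
    SignalTrace,
    StimSchedule,
    VmcEnvelope,
    ambient_noise,
    bin_response,
    inject_responses,
    synthesize_emg,
)
from .vmc_estimator import (
    EstimatorConfig,
    arv,
    design_bandpass,
    estimate_vmc,
    expected_arv_factor,
    smooth,
)

#: Default latch-up detection window: 2 s of rest at maximum output.
LATCH_WINDOW_BINS = 33


@dataclass(frozen=True)
class LoopTrace:
    """Per-bin record of one closed-loop run."""

    envelope: np.ndarray      # true VMC, µV
    vmc: np.ndarray           # estimate, µV
    arv_raw: np.ndarray       # pre-smoothing ARV, µV
    command: np.ndarray       # stimulation command, mA
    latched: bool
    signal: SignalTrace       # the synthesized recorded signal
    device: DeviceConfig
    estimator: EstimatorConfig

    @property
    def n_bins(self) -> int:
        return len(self.command)


def run_closed_loop(envelope: VmcEnvelope, model: ArtifactModel,
                    device: DeviceConfig, estimator: EstimatorConfig,
                    seed, initial_command: float = 0.0,
                    latch_window: int = LATCH_WINDOW_BINS) -> LoopTrace:
    """Simulate the full feedback loop over an envelope scenario.

    The clean voluntary EMG and the ambient noise are independent of the
    commands and are generated up front; the per-pulse stimulation response
    of bin k is driven by the command computed from bin k−1.  With a silent
    artifact model the loop reduces bit-exactly to open-loop estimation of
    the clean EMG.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(
        seed, np.random.SeedSequence) else seed
    emg_ss, noise_ss = ss.spawn(2)
    emg = synthesize_emg(envelope, emg_ss)
    rng = np.random.default_rng(noise_ss)
    n_bins = envelope.n_bins
    ambient = ambient_noise(n_bins, model, rng)

    sos = design_bandpass(estimator)
    zi = sosfilt_zi(sos) * 0.0  # zero initial state, as in batch sosfilt
    mask = estimator.retained_mask
    alpha = estimator.alpha

    samples = np.empty(n_bins * BIN_LEN)
    vmc = np.empty(n_bins)
    arv_raw = np.empty(n_bins)
    cmd = np.empty(n_bins)
    prev_filtered_bin = np.zeros(BIN_LEN)
    v = 0.0
    current = float(initial_command)

    for k in range(n_bins):
        sl = slice(k * BIN_LEN, (k + 1) * BIN_LEN)
        raw = emg.samples[sl] + ambient[sl] + bin_response(current, model, rng)
        samples[sl] = raw
        if estimator.bandpass_enabled:
            filtered, zi = sosfilt(sos, raw, zi=zi)
        else:
            filtered = raw
        combed = (filtered - prev_filtered_bin) if estimator.comb_enabled else filtered
        if estimator.comb_enabled and k == 0:
            combed = np.zeros(BIN_LEN)
        prev_filtered_bin = filtered
        a = arv(combed, mask)
        v = alpha * a + (1.0 - alpha) * v
        arv_raw[k] = a
        vmc[k] = v
        current = pwl_map(v, device)
        cmd[k] = current

    latched = detect_full_on(cmd, device, window=min(latch_window, n_bins),
                             envelope=envelope.values)
    return LoopTrace(envelope=envelope.values.copy(), vmc=vmc, arv_raw=arv_raw,
                     command=cmd, latched=latched,
                     signal=SignalTrace(samples=samples),
                     device=device, estimator=estimator)


# ---------------------------------------------------------------------------
# Leakage
# ---------------------------------------------------------------------------

def measure_leakage(model: ArtifactModel, estimator: EstimatorConfig,
                    probe_mA: float, n_bins: int, seed) -> float:
    """Steady-state estimator residue per mA of constant stimulation.

    Runs the estimator open loop on a zero-EMG trace stimulated at a
    constant probe current and divides the steady-state estimate by the
    probe.  Zero for a jitter-free, reflex-free model whose responses are
    confined to the blanked windows; dominated by pulse-to-pulse jitter
    otherwise.
    """
    if probe_mA <= 0:
        raise ConfigurationError("probe_mA must be positive")
    envelope = VmcEnvelope(values=np.zeros(n_bins), duration=n_bins / BIN_RATE)
    silent = SignalTrace(samples=np.zeros(n_bins * BIN_LEN))
    schedule = StimSchedule(amplitudes=np.full(n_bins, probe_mA))
    trace = inject_responses(silent, schedule, model, seed)
    est = estimate_vmc(trace, estimator)
    n_skip = min(n_bins - 1, int(np.ceil(10 * estimator.tau * BIN_RATE)))
    return float(np.mean(est.values[n_skip:]) / probe_mA)


def calibrated_leakage_model(leakage: float, estimator: EstimatorConfig | None = None,
                             jitter_sd: float = 0.2, n_bins: int = 2000,
                             calibration_seed: int = 321) -> ArtifactModel:
    """Build an ArtifactModel whose measured leakage is ``leakage`` µV/mA.

    Starts from jittered default artifact/M-wave templates (no reflexes,
    hum or motion), measures the leakage once, and scales the templates
    linearly — leakage is proportional to template amplitude.
    """
    if leakage < 0:
        raise ConfigurationError("leakage must be non-negative")
    estimator = estimator or EstimatorConfig()
    base = ArtifactModel(jitter_sd=jitter_sd, reflex_prob=0.0, reflex_amp_sd=0.0,
                         hum_amp=0.0, motion_rate=0.0, motion_amp=0.0)
    if leakage == 0.0:
        return replace(base, artifact_template=np.zeros(1),
                       mwave_template=np.zeros(1), jitter_sd=0.0)
    lam0 = measure_leakage(base, estimator, probe_mA=20.0, n_bins=n_bins,
                           seed=calibration_seed)
    scale = leakage / lam0
    return replace(base, artifact_template=base.artifact_template * scale,
                   mwave_template=base.mwave_template * scale)


# ---------------------------------------------------------------------------
# Stability analysis
# ---------------------------------------------------------------------------

def small_signal_fixed_point(gain: float, leakage: float, max_stim: float,
                             v0: float = 0.1, n_iter: int = 500,
                             full_on_frac: float = 0.99) -> bool:
    """Iterate v ← λ·min(max_stim, g·v) from a small perturbation.

    Returns True when the iteration saturates (latch-up), which happens
    exactly when g·λ > 1 for any positive start; contraction to zero
    otherwise.  This is the zero-offset small-signal picture of the loop.
    """
    v = v0
    cmd = 0.0
    for _ in range(n_iter):
        cmd = min(max_stim, gain * v)
        v = leakage * cmd
    return cmd >= full_on_frac * max_stim


def _kick_envelope(rest_s: float = 9.0, kick_s: float = 1.0,
                   kick_level: float = 10.0) -> VmcEnvelope:
    """A short voluntary burst followed by rest.

    Latch-up manifests when the user relaxes after driving the device; the
    burst seeds the loop, the trailing rest reveals whether the feedback
    sustains the output.
    """
    n_kick = int(kick_s * BIN_RATE)
    n_rest = int(rest_s * BIN_RATE)
    values = np.concatenate([np.full(n_kick, kick_level), np.zeros(n_rest)])
    return VmcEnvelope(values=values, duration=(n_kick + n_rest) / BIN_RATE)


def stability_map(gains, leakages, device: DeviceConfig,
                  estimator: EstimatorConfig, seed,
                  rest_s: float = 9.0) -> list[dict]:
    """Latch-up flags over a (gain, leakage) grid at rest, zero offset.

    Each grid point runs one closed-loop simulation: a 1 s voluntary burst
    followed by rest.  Returns records with keys gain, leakage, latched.
    The empirical latch boundary brackets the analytic criterion g·λ = 1.
    """
    gains = list(gains)
    leakages = list(leakages)
    if not gains or not leakages:
        raise ConfigurationError("gains and leakages must be nonempty")
    ss = np.random.SeedSequence(seed)
    records = []
    for lam in leakages:
        model = calibrated_leakage_model(lam, estimator)
        for g in gains:
            dev = replace(device, gain=g, offset=0.0)
            env = _kick_envelope(rest_s=rest_s)
            trace = run_closed_loop(env, model, dev, estimator, ss.spawn(1)[0])
            records.append({"gain": float(g), "leakage": float(lam),
                            "latched": bool(trace.latched)})
    return records


def tracking_error(trace: LoopTrace, target: VmcEnvelope) -> float:
    """RMS distance (mA) between the command and the ideal mapped target.

    The ideal command is the PWL map of the target envelope scaled by the
    estimator's expected reading per µV of envelope and passed through the
    same first-order smoother; the first 5τ of bins are skipped as the
    settling transient.
    """
    if trace.n_bins != target.n_bins:
        raise ShapeError("trace and target have different bin counts")
    k_arv = expected_arv_factor(trace.estimator)
    ideal_vmc = smooth(target.values * k_arv, trace.estimator).values
    ideal_cmd = pwl_map(ideal_vmc, trace.device)
    n_skip = int(np.ceil(5 * trace.estimator.tau * BIN_RATE))
    if n_skip >= trace.n_bins:
        raise ShapeError("trace shorter than the settling transient (5 tau)")
    diff = trace.command[n_skip:] - ideal_cmd[n_skip:]
    return float(np.sqrt(np.mean(diff ** 2)))
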