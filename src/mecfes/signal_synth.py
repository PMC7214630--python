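"""Synthetic recorded-signal generation for myoelectrically controlled FES.

The recorded signal at the wrist-extensor electrodes is modelled as the sum of

* voluntary surface EMG — band-limited Gaussian noise whose per-bin standard
  deviation follows a latent voluntary-muscle-contraction (VMC) envelope,
* per-pulse stimulation responses — a direct stimulation artifact plus the
  compound muscle action potential (M-wave), both quasi-stationary templates
  scaled linearly by stimulation current,
* randomly occurring late reflex responses (H-reflex / F-wave) near 40 ms
  after each pulse,
* 50 Hz mains hum, Poisson-timed motion-artifact transients, and 16-bit
  ADC quantization.

Sampling is 2000 Hz with one stimulation pulse every 60 ms, so the signal is
organised in inter-stimulus bins of 120 samples.  All amplitudes are in µV
referred to the amplifier input; stimulation currents are in mA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ShapeError

#: Sampling rate of the recorded signal, Hz.
FS = 2000.0
#: Samples per inter-stimulus interval (60 ms at 2000 Hz).
BIN_LEN = 120
#: Bin (and stimulation) rate, Hz.
BIN_RATE = FS / BIN_LEN
#: Inter-stimulus interval, s.
BIN_DT = BIN_LEN / FS

#: Default synthetic surface-EMG band, Hz.
EMG_BAND = (20.0, 450.0)

RngLike = "int | np.random.SeedSequence | np.random.Generator"


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VmcEnvelope:
    """Latent voluntary-contraction amplitude, one value per 60 ms bin.

    ``values[k]`` is the target RMS amplitude (µV) of the voluntary EMG in
    bin ``k``; ``duration`` is the scenario length in seconds.
    """

    values: np.ndarray
    duration: float

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ShapeError("envelope must be one-dimensional")
        if np.any(values < 0):
            raise ConfigurationError("envelope values must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SignalTrace:
    """Uniformly sampled biopotential series (µV at 2000 Hz).

    The sample count must be a whole number of 120-sample bins.
    """

    samples: np.ndarray

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ShapeError("trace must be one-dimensional")
        if len(samples) % BIN_LEN != 0:
            raise ShapeError(
                f"sample count {len(samples)} is not a multiple of {BIN_LEN}"
            )

    @property
    def n_bins(self) -> int:
        return len(self.samples) // BIN_LEN

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / FS


@dataclass(frozen=True)
class StimSchedule:
    """Per-bin stimulation pulse amplitudes (mA), one pulse per 60 ms bin."""

    amplitudes: np.ndarray
    pulse_offset: int = 0

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", amps)
        if np.any(amps < 0):
            raise ConfigurationError("stimulation amplitudes must be non-negative")
        if not 0 <= self.pulse_offset < BIN_LEN:
            raise ConfigurationError("pulse_offset must lie within a bin")

    @property
    def n_bins(self) -> int:
        return len(self.amplitudes)


def _default_artifact_template() -> np.ndarray:
    """Biphasic double-exponential confined to samples 0-19 (µV per mA)."""
    t = np.arange(20, dtype=float)
    w = np.exp(-t / 2.0) - 0.6 * np.exp(-t / 6.0)
    return 300.0 * w / np.max(np.abs(w))


def _default_mwave_template() -> np.ndarray:
    """Damped sinusoid over samples 5-45 (µV per mA): the M-wave."""
    w = np.zeros(46)
    t = np.arange(41, dtype=float)
    w[5:] = np.sin(2 * np.pi * t / 20.0) * np.exp(-t / 12.0)
    return 120.0 * w / np.max(np.abs(w))


def _default_reflex_template() -> np.ndarray:
    """Late-response waveform centered at sample 80 with ±8-sample support."""
    w = np.zeros(89)
    t = np.arange(-8, 9, dtype=float)
    w[72:89] = np.sin(2 * np.pi * t / 10.0) * np.cos(np.pi * t / 16.0) ** 2
    peak = np.max(np.abs(w))
    return w / peak


@dataclass(frozen=True)
class ArtifactModel:
    """Parameters of everything in the recording that is not voluntary EMG.

    Templates are per-sample waveforms anchored at the pulse sample and
    scaled linearly by stimulation current; ``jitter_sd`` is the fractional
    pulse-to-pulse variability of the template amplitude (the non-stationary
    residue the comb filter cannot cancel).
    """

    artifact_template: np.ndarray = field(default_factory=_default_artifact_template)
    mwave_template: np.ndarray = field(default_factory=_default_mwave_template)
    jitter_sd: float = 0.02
    reflex_prob: float = 0.05
    reflex_template: np.ndarray = field(default_factory=_default_reflex_template)
    reflex_amp_sd: float = 20.0
    reflex_latency_jitter: int = 3
    hum_amp: float = 5.0
    motion_rate: float = 0.2
    motion_amp: float = 50.0
    adc_bits: int = 16
    adc_range: float = 5000.0

    def __post_init__(self):
        for name in ("artifact_template", "mwave_template", "reflex_template"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if len(arr) > BIN_LEN:
                raise ConfigurationError(f"{name} longer than one bin ({BIN_LEN})")
        if not 0.0 <= self.reflex_prob <= 1.0:
            raise ConfigurationError("reflex_prob must be in [0, 1]")
        if self.adc_bits != 16:
            raise ConfigurationError("the device ADC is 16 bit")
        if self.adc_range <= 0:
            raise ConfigurationError("adc_range must be positive")
        if self.jitter_sd < 0 or self.reflex_amp_sd < 0:
            raise ConfigurationError("spread parameters must be non-negative")
        if self.motion_rate < 0 or self.motion_amp < 0 or self.hum_amp < 0:
            raise ConfigurationError("noise levels must be non-negative")

    @classmethod
    def silent(cls) -> "ArtifactModel":
        """No contamination at all: the generator becomes the identity."""
        return cls(
            artifact_template=np.zeros(1),
            mwave_template=np.zeros(1),
            jitter_sd=0.0,
            reflex_prob=0.0,
            reflex_amp_sd=0.0,
            hum_amp=0.0,
            motion_rate=0.0,
            motion_amp=0.0,
        )

    @classmethod
    def ideal(cls) -> "ArtifactModel":
        """Perfectly suppressible stimulation responses.

        The only response is a jitter-free artifact confined to the first
        blanking window, so blanking plus the comb removes it exactly.
        """
        return cls(
            mwave_template=np.zeros(1),
            jitter_sd=0.0,
            reflex_prob=0.0,
            reflex_amp_sd=0.0,
            hum_amp=0.0,
            motion_rate=0.0,
            motion_amp=0.0,
        )


# ---------------------------------------------------------------------------
# Envelope scenarios
# ---------------------------------------------------------------------------

_PROFILES = ("rest", "step", "ramp", "sinusoid")
#: Frequency of the sinusoidal tracking profile, Hz.
SINUSOID_HZ = 0.5


def make_envelope(profile: str, duration: float, level: float, seed=0) -> VmcEnvelope:
    """Build a named VMC envelope scenario.

    rest: identically zero. step: zero for the first half, ``level`` for the
    second. ramp: linear 0 → ``level``. sinusoid: ``level/2 · (1 + sin)`` at
    0.25 Hz, mimicking slow volitional wrist-extension tracking.  ``seed`` is
    accepted for interface uniformity; all profiles are deterministic.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if level < 0:
        raise ConfigurationError("level must be non-negative")
    if profile not in _PROFILES:
        raise ConfigurationError(
            f"unknown profile {profile!r}; expected one of {_PROFILES}"
        )
    n = int(duration * BIN_RATE)
    t = np.arange(n) * BIN_DT
    if profile == "rest":
        values = np.zeros(n)
    elif profile == "step":
        values = np.where(np.arange(n) < n // 2, 0.0, level)
    elif profile == "ramp":
        values = np.linspace(0.0, level, n)
    else:  # sinusoid
        values = 0.5 * level * (1.0 + np.sin(2 * np.pi * SINUSOID_HZ * t))
    return VmcEnvelope(values=values, duration=duration)


# ---------------------------------------------------------------------------
# Voluntary EMG
# ---------------------------------------------------------------------------

def emg_band_sos(band=EMG_BAND, order: int = 4):
    """Second-order sections of the synthesis band filter (Butterworth)."""
    from scipy.signal import butter

    return butter(order, band, btype="bandpass", fs=FS, output="sos")


def synthesize_emg(envelope: VmcEnvelope, seed, band=EMG_BAND) -> SignalTrace:
    """Generate clean voluntary EMG following a VMC envelope.

    White Gaussian noise is band-pass filtered to the surface-EMG band,
    normalised to unit stationary standard deviation, then scaled per bin by
    the envelope.  A zero envelope therefore yields an exactly zero trace,
    and the pooled per-bin sample SD converges to the envelope value.
    """
    from scipy.signal import sosfilt

    rng = _rng(seed)
    n = envelope.n_bins * BIN_LEN
    if n == 0:
        return SignalTrace(samples=np.zeros(0))
    warmup = 1024
    white = rng.standard_normal(n + warmup)
    sos = emg_band_sos(band)
    shaped = sosfilt(sos, white)[warmup:]
    # stationary SD of unit white noise through the filter = ||h||_2
    impulse = np.zeros(4096)
    impulse[0] = 1.0
    h = sosfilt(sos, impulse)
    shaped = shaped / np.sqrt(np.sum(h * h))
    scale = np.repeat(envelope.values, BIN_LEN)
    return SignalTrace(samples=shaped * scale)


# ---------------------------------------------------------------------------
# Stimulation responses and ambient noise
# ---------------------------------------------------------------------------

def _place(template: np.ndarray, offset: int) -> np.ndarray:
    """Template anchored at `offset` within a 120-sample bin, truncated."""
    out = np.zeros(BIN_LEN)
    end = min(BIN_LEN, offset + len(template))
    out[offset:end] = template[: end - offset]
    return out


def bin_response(amp_mA: float, model: ArtifactModel, rng: np.random.Generator,
                 pulse_offset: int = 0) -> np.ndarray:
    """One bin of stimulation response for a pulse of ``amp_mA``.

    Direct artifact and M-wave scale linearly with current and share a
    multiplicative pulse-to-pulse jitter; a late reflex occurs with
    probability ``reflex_prob`` at sample 80 ± latency jitter.  The random
    stream is consumed identically for every bin so that traces are
    reproducible bin-for-bin.
    """
    out = np.zeros(BIN_LEN)
    jitter = rng.normal(0.0, model.jitter_sd) if model.jitter_sd > 0 else 0.0
    if amp_mA > 0:
        stationary = _place(model.artifact_template, pulse_offset) + _place(
            model.mwave_template, pulse_offset
        )
        out += amp_mA * (1.0 + jitter) * stationary
    if model.reflex_prob > 0 and rng.random() < model.reflex_prob:
        shift = int(rng.integers(-model.reflex_latency_jitter,
                                 model.reflex_latency_jitter + 1))
        amp = rng.normal(0.0, model.reflex_amp_sd)
        tmpl = model.reflex_template
        dst0, src0 = max(0, shift), max(0, -shift)
        length = min(BIN_LEN - dst0, len(tmpl) - src0)
        if length > 0:
            out[dst0:dst0 + length] += amp * tmpl[src0:src0 + length]
    return out


def ambient_noise(n_bins: int, model: ArtifactModel, rng: np.random.Generator) -> np.ndarray:
    """Mains hum and motion-artifact transients, independent of stimulation."""
    n = n_bins * BIN_LEN
    out = np.zeros(n)
    if model.hum_amp > 0:
        phase = rng.uniform(0.0, 2 * np.pi)
        t = np.arange(n) / FS
        out += model.hum_amp * np.sin(2 * np.pi * 50.0 * t + phase)
    if model.motion_rate > 0 and model.motion_amp > 0 and n > 0:
        duration = n / FS
        n_events = rng.poisson(model.motion_rate * duration)
        for _ in range(n_events):
            center = rng.uniform(0.0, duration)
            width_s = rng.uniform(0.010, 0.050)
            amp = model.motion_amp * rng.standard_normal()
            half = int(width_s * FS / 2)
            c = int(center * FS)
            lo, hi = max(0, c - half), min(n, c + half + 1)
            k = np.arange(lo, hi) - c
            out[lo:hi] += amp * 0.5 * (1 + np.cos(np.pi * k / max(half, 1)))
    return out


def inject_responses(emg: SignalTrace, schedule: StimSchedule,
                     model: ArtifactModel, seed) -> SignalTrace:
    """Add stimulation responses, reflexes, hum and motion to a clean trace.

    Purely additive: with a zero-amplitude schedule and a silent model the
    output equals the input bit for bit.
    """
    if emg.n_bins != schedule.n_bins:
        raise ShapeError(
            f"trace has {emg.n_bins} bins but schedule has {schedule.n_bins}"
        )
    rng = _rng(seed)
    out = emg.samples.copy()
    for k, amp in enumerate(schedule.amplitudes):
        out[k * BIN_LEN:(k + 1) * BIN_LEN] += bin_response(
            amp, model, rng, schedule.pulse_offset
        )
    out += ambient_noise(emg.n_bins, model, rng)
    return SignalTrace(samples=out)


def adc_quantize(trace: SignalTrace, model: ArtifactModel) -> SignalTrace:
    """Round to the 16-bit grid over ±adc_range, saturating out-of-range values."""
    step = 2.0 * model.adc_range / 2 ** model.adc_bits
    q = np.round(trace.samples / step) * step
    return SignalTrace(samples=np.clip(q, -model.adc_range, model.adc_range))
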