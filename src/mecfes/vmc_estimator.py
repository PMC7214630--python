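"""Estimation of voluntary muscle contraction (VMC) during stimulation.

The estimation chain mirrors the device firmware:

1. second-order band-pass filter, 16–500 Hz;
2. segmentation into 120-sample bins, one per 60 ms inter-stimulus interval;
3. first-order comb filter across bins (subtract the previous bin), placing
   notches at multiples of the 16.667 Hz stimulation rate — this cancels the
   quasi-stationary part of the stimulation responses;
4. two blanking windows, samples [0, 20) for the direct artifact and
   [70, 90) for late H-reflex / F-wave responses, excluded from the average;
5. average rectified value (ARV) over the 80 retained samples of each bin;
6. first-order IIR low-pass smoothing of the per-bin ARV series.

The smoothed series is the VMC estimate, in µV, at the 16.667 Hz bin rate.

Note on calibration: for stochastic EMG the comb stage subtracts an
independent bin and therefore inflates the ARV by √2.  The estimator
reports the uncorrected ARV, exactly as the device does; the expected
reading for a clean envelope A is A·√2·√(2/π) times the band-pass power
factor (see :func:`expected_arv_factor`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfilt

from .errors import ConfigurationError, ShapeError
from .signal_synth import BIN_DT, BIN_LEN, EMG_BAND, FS, SignalTrace


@dataclass(frozen=True)
class EstimatorConfig:
    """Parameters of the VMC estimation chain.

    ``blank1``/``blank2`` are half-open sample ranges within a bin; ``tau``
    is the time constant (s) of the final first-order smoother.  The second
    blanking window is a symmetric 20-sample window centered on sample 80,
    where late reflex responses typically fall.  ``bandpass_enabled`` exists
    for analysis of the digital stages in isolation.
    """

    band_low: float = 16.0
    band_high: float = 500.0
    bin_len: int = BIN_LEN
    blank1: tuple = (0, 20)
    blank2: tuple = (70, 90)
    comb_enabled: bool = True
    tau: float = 1.0
    bandpass_enabled: bool = True

    def __post_init__(self):
        if self.bin_len != BIN_LEN:
            raise ConfigurationError(f"bin_len must be {BIN_LEN}")
        for lo, hi in (self.blank1, self.blank2):
            if not (0 <= lo <= hi <= BIN_LEN):
                raise ConfigurationError("blanking ranges must lie within a bin")
        a, b = sorted([self.blank1, self.blank2])
        if a[1] > b[0]:
            raise ConfigurationError("blanking ranges must be disjoint")
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")
        if not 0 < self.band_low < self.band_high:
            raise ConfigurationError("band edges must satisfy 0 < low < high")

    @property
    def retained_mask(self) -> np.ndarray:
        """Boolean mask of the samples kept for the ARV (True = retained)."""
        mask = np.ones(BIN_LEN, dtype=bool)
        mask[self.blank1[0]:self.blank1[1]] = False
        mask[self.blank2[0]:self.blank2[1]] = False
        return mask

    @property
    def alpha(self) -> float:
        """Per-bin smoothing coefficient, exact exponential discretization."""
        return 1.0 - float(np.exp(-BIN_DT / self.tau))


@dataclass(frozen=True)
class VmcEstimate:
    """Per-bin VMC estimate (µV at the 16.667 Hz bin rate)."""

    values: np.ndarray
    arv_raw: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "arv_raw", np.asarray(self.arv_raw, dtype=float))
        if len(self.values) != len(self.arv_raw):
            raise ShapeError("smoothed and raw series must have equal length")

    @property
    def n_bins(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def design_bandpass(config: EstimatorConfig):
    """Second-order sections of the front-end band-pass (2-pole Butterworth)."""
    return butter(1, [config.band_low, config.band_high], btype="bandpass",
                  fs=FS, output="sos")


def bandpass(trace: SignalTrace, config: EstimatorConfig) -> SignalTrace:
    """Apply the 16–500 Hz second-order band-pass filter (causal)."""
    if len(trace.samples) == 0:
        raise ShapeError("trace is empty")
    if not config.bandpass_enabled:
        return trace
    sos = design_bandpass(config)
    return SignalTrace(samples=sosfilt(sos, trace.samples))


def segment_bins(trace: SignalTrace) -> np.ndarray:
    """Reshape a trace into an (n_bins, 120) array of inter-stimulus bins."""
    n = len(trace.samples)
    if n % BIN_LEN != 0:
        raise ShapeError(f"sample count {n} is not a multiple of {BIN_LEN}")
    return trace.samples.reshape(-1, BIN_LEN)


def comb_filter(bins: np.ndarray, enabled: bool = True) -> np.ndarray:
    """First-order comb across bins: output bin k = bin k − bin k−1.

    Bin 0 has no predecessor and is defined as zero, so any exactly
    bin-periodic input is annihilated from bin 1 onward.
    """
    bins = np.atleast_2d(np.asarray(bins, dtype=float))
    if bins.shape[0] < 1:
        raise ShapeError("need at least one bin")
    if not enabled:
        return bins.copy()
    out = np.zeros_like(bins)
    out[1:] = bins[1:] - bins[:-1]
    return out


def apply_blanking(bin_samples: np.ndarray, config: EstimatorConfig) -> np.ndarray:
    """Samples of one bin that survive both blanking windows (80 of 120)."""
    bin_samples = np.asarray(bin_samples, dtype=float)
    if bin_samples.shape[-1] != BIN_LEN:
        raise ShapeError(f"bin must have {BIN_LEN} samples")
    return bin_samples[..., config.retained_mask]


def arv(bin_samples: np.ndarray, retained_mask: np.ndarray) -> float:
    """Average rectified value over the retained samples of one bin."""
    retained_mask = np.asarray(retained_mask, dtype=bool)
    if not retained_mask.any():
        raise ConfigurationError("blanking retains no samples")
    return float(np.mean(np.abs(np.asarray(bin_samples, dtype=float)[retained_mask])))


def smooth(arv_series: np.ndarray, config: EstimatorConfig) -> VmcEstimate:
    """First-order IIR low-pass of the ARV series.

    v_k = α·a_k + (1−α)·v_{k−1} with α = 1 − exp(−Δt/τ), Δt = 60 ms and
    v_{−1} = 0.  Unity DC gain; a unit step reaches 1 − e⁻¹ after τ seconds.
    """
    a = np.asarray(arv_series, dtype=float)
    alpha = config.alpha
    out = np.empty_like(a)
    v = 0.0
    for k in range(len(a)):
        v = alpha * a[k] + (1.0 - alpha) * v
        out[k] = v
    return VmcEstimate(values=out, arv_raw=a.copy())


def estimate_vmc(trace: SignalTrace, config: EstimatorConfig | None = None) -> VmcEstimate:
    """Full estimation chain: band-pass → bins → comb → blanking → ARV → smooth."""
    config = config or EstimatorConfig()
    filtered = bandpass(trace, config)
    bins = segment_bins(filtered)
    combed = comb_filter(bins, config.comb_enabled)
    mask = config.retained_mask
    # per-bin reduction (not a 2-D axis reduce) so the incremental
    # closed-loop path reproduces the result bit for bit
    arvs = np.array([arv(b, mask) for b in combed])
    return smooth(arvs, config)


# ---------------------------------------------------------------------------
# Calibration helpers
# ---------------------------------------------------------------------------

def bandpass_power_factor(config: EstimatorConfig, band=EMG_BAND,
                          syn_order: int = 4, n_freq: int = 4096) -> float:
    """RMS gain of the front-end band-pass for synthetic-band EMG.

    Computed in the frequency domain from the designed transfer functions:
    the synthetic EMG spectrum (synthesis band filter applied to white
    noise) weighted by the estimator band-pass, relative to the unfiltered
    spectrum.  Equals 1 when the band-pass stage is disabled.
    """
    if not config.bandpass_enabled:
        return 1.0
    from scipy.signal import sosfreqz

    from .signal_synth import emg_band_sos

    w, h_est = sosfreqz(design_bandpass(config), worN=n_freq, fs=FS)
    _, h_syn = sosfreqz(emg_band_sos(band, syn_order), worN=n_freq, fs=FS)
    p_syn = np.abs(h_syn) ** 2
    num = np.trapezoid(p_syn * np.abs(h_est) ** 2, w)
    den = np.trapezoid(p_syn, w)
    return float(np.sqrt(num / den))


def expected_arv_factor(config: EstimatorConfig, band=EMG_BAND) -> float:
    """Expected estimator reading per µV of clean-EMG envelope.

    Gaussian rectification gives √(2/π); the comb difference of independent
    bins inflates the SD by √2; the band-pass removes a little in-band power.
    """
    factor = float(np.sqrt(2.0 / np.pi))
    if config.comb_enabled:
        factor *= float(np.sqrt(2.0))
    return factor * bandpass_power_factor(config, band)
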