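"""Proportional stimulation controller and device user interface model.

The VMC estimate drives the stimulation current through a piecewise-linear
(PWL) law with three user-adjustable parameters: an offset (the VMC level
at which stimulation starts), a gain (mA of stimulation per µV of VMC) and
a maximum stimulation level.  The physical device is adjusted with three
buttons — a mode button (short press: pause/active toggle; long press:
cycle through parameter-adjust modes) and plus/minus buttons — with a
buzzer for acoustic feedback, surrogated here by log records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError

logger = logging.getLogger("mecfes.controller")

#: Adjustment step sizes and clamp ranges for the three key parameters.
OFFSET_STEP_UV = 0.5
OFFSET_RANGE_UV = (0.0, 100.0)
GAIN_FACTOR = 1.1          # plus/minus multiply/divide (10% steps)
GAIN_RANGE = (1e-3, 1e3)   # mA/µV
MAX_STIM_STEP_MA = 1.0
MAX_STIM_RANGE_MA = (1.0, 60.0)

_ADJUST_CYCLE = ("none", "offset", "gain", "max_stim")
_EVENTS = ("short_mode", "long_mode", "plus", "minus")


@dataclass(frozen=True)
class DeviceConfig:
    """Controller parameter set: offset (µV), gain (mA/µV), maximum (mA)."""

    offset: float = 2.0
    gain: float = 2.0
    max_stim: float = 30.0
    tau: float = 1.0

    def __post_init__(self):
        if self.offset < 0:
            raise ConfigurationError("offset must be non-negative")
        if self.gain < 0:
            raise ConfigurationError("gain must be non-negative")
        if self.max_stim <= 0:
            raise ConfigurationError("max_stim must be positive")
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")


@dataclass(frozen=True)
class DeviceState:
    """Operating mode, currently selected adjust parameter, and parameters."""

    mode: str = "active"
    adjust: str = "none"
    config: DeviceConfig = DeviceConfig()

    def __post_init__(self):
        if self.mode not in ("paused", "active"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.adjust not in _ADJUST_CYCLE:
            raise ConfigurationError(f"unknown adjust target {self.adjust!r}")


def pwl_map(vmc, config: DeviceConfig):
    """Piecewise-linear VMC → stimulation map.

    min(max_stim, gain · max(0, vmc − offset)): zero below the offset,
    linear above it, saturating at the maximum stimulation level.
    Accepts scalars or arrays.
    """
    vmc = np.asarray(vmc, dtype=float)
    out = np.minimum(config.max_stim,
                     config.gain * np.maximum(0.0, vmc - config.offset))
    return float(out) if out.ndim == 0 else out


def command(vmc: float, state: DeviceState) -> float:
    """Commanded stimulation for the current device state (0 when paused)."""
    if state.mode == "paused":
        return 0.0
    return pwl_map(vmc, state.config)


def step_buttons(state: DeviceState, event: str) -> DeviceState:
    """Advance the button state machine by one event.

    short_mode toggles paused/active; long_mode cycles the adjust target
    none → offset → gain → max_stim → none; plus/minus nudge the selected
    parameter by its step, clamped to its valid range.  Every transition is
    logged (the physical device beeps).
    """
    if event not in _EVENTS:
        raise ConfigurationError(f"unknown button event {event!r}")
    if event == "short_mode":
        new = replace(state, mode="paused" if state.mode == "active" else "active")
        logger.info("mode toggled -> %s", new.mode)
        return new
    if event == "long_mode":
        idx = _ADJUST_CYCLE.index(state.adjust)
        new = replace(state, adjust=_ADJUST_CYCLE[(idx + 1) % len(_ADJUST_CYCLE)])
        logger.info("adjust target -> %s", new.adjust)
        return new
    # plus / minus
    if state.adjust == "none":
        logger.warning("plus/minus pressed with no parameter selected; ignored")
        return state
    sign = 1.0 if event == "plus" else -1.0
    cfg = state.config
    if state.adjust == "offset":
        value = float(np.clip(cfg.offset + sign * OFFSET_STEP_UV, *OFFSET_RANGE_UV))
        cfg = replace(cfg, offset=value)
    elif state.adjust == "gain":
        factor = GAIN_FACTOR if event == "plus" else 1.0 / GAIN_FACTOR
        value = float(np.clip(cfg.gain * factor, *GAIN_RANGE))
        cfg = replace(cfg, gain=value)
    else:  # max_stim
        value = float(np.clip(cfg.max_stim + sign * MAX_STIM_STEP_MA,
                              *MAX_STIM_RANGE_MA))
        cfg = replace(cfg, max_stim=value)
    logger.info("%s adjusted to %g", state.adjust, value)
    return replace(state, config=cfg)


def detect_full_on(stim_series, config: DeviceConfig, window: int,
                   envelope=None, full_on_frac: float = 0.99) -> bool:
    """Detect the latch-up (full-on) failure state.

    True iff the commanded stimulation stayed at the maximum (within
    ``full_on_frac``) for all of the last ``window`` bins while the true VMC
    envelope was zero there — i.e. stimulation the user is not driving.
    ``envelope`` defaults to rest (all zero).
    """
    if window < 1:
        raise ConfigurationError("window must be at least one bin")
    stim = np.asarray(stim_series, dtype=float)
    if len(stim) < window:
        return False
    tail = stim[-window:]
    if envelope is not None:
        env = np.asarray(envelope, dtype=float)
        if np.any(env[-window:] > 0):
            return False
    return bool(np.all(tail >= full_on_frac * config.max_stim))
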