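"""Plain-text table readers/writers and run-configuration handling.

All tables are comma-separated with a mandatory header row, written with
6 significant digits.  The run configuration is a YAML document with
``scenario``, ``model``, ``estimator`` and ``device`` blocks plus a seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .controller import DeviceConfig
from .errors import ConfigurationError, ParseError, ShapeError
from .signal_synth import BIN_LEN, FS, ArtifactModel, SignalTrace, StimSchedule
from .vmc_estimator import EstimatorConfig, VmcEstimate

logger = logging.getLogger("mecfes.io")

FLOAT_FORMAT = "%.6g"


def _read_table(path, columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    for col in columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()]
        if len(bad):
            # +2: one for the header row, one for 1-based numbering
            raise ParseError(f"{path}: non-numeric value in column {col!r} "
                             f"at line {bad[0] + 2}")
        df[col] = values
    return df


def write_signal(trace: SignalTrace, path) -> None:
    """Write a trace as a (time_s, amplitude_uV) table, one row per sample."""
    df = pd.DataFrame({"time_s": trace.times, "amplitude_uV": trace.samples})
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_signal(path) -> SignalTrace:
    df = _read_table(path, ("time_s", "amplitude_uV"))
    n = len(df)
    if n % BIN_LEN != 0:
        raise ShapeError(f"{path}: {n} samples is not a multiple of {BIN_LEN}")
    return SignalTrace(samples=df["amplitude_uV"].to_numpy(dtype=float))


def write_schedule(schedule: StimSchedule, path) -> None:
    df = pd.DataFrame({"bin_index": np.arange(schedule.n_bins),
                       "amplitude_mA": schedule.amplitudes})
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_schedule(path) -> StimSchedule:
    df = _read_table(path, ("bin_index", "amplitude_mA"))
    return StimSchedule(amplitudes=df["amplitude_mA"].to_numpy(dtype=float))


def write_estimate(estimate: VmcEstimate, path) -> None:
    """Write a VMC estimate as a (bin_index, time_s, arv_uV, vmc_uV) table."""
    idx = np.arange(estimate.n_bins)
    df = pd.DataFrame({"bin_index": idx, "time_s": idx * BIN_LEN / FS,
                       "arv_uV": estimate.arv_raw, "vmc_uV": estimate.values})
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_estimate(path) -> VmcEstimate:
    df = _read_table(path, ("bin_index", "arv_uV", "vmc_uV"))
    return VmcEstimate(values=df["vmc_uV"].to_numpy(dtype=float),
                       arv_raw=df["arv_uV"].to_numpy(dtype=float))


def write_loop_trace(trace, path) -> None:
    idx = np.arange(trace.n_bins)
    df = pd.DataFrame({"bin_index": idx, "time_s": idx * BIN_LEN / FS,
                       "envelope_uV": trace.envelope, "arv_uV": trace.arv_raw,
                       "vmc_uV": trace.vmc, "command_mA": trace.command})
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_stability_map(records, path) -> None:
    pd.DataFrame(records).to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_SCENARIO = {"profile": "step", "duration_s": 12.0, "level_uV": 10.0,
                    "stim_mA": 0.0, "quantize": False}


def load_run_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    return doc


def scenario_from_config(doc: dict) -> dict:
    scenario = dict(DEFAULT_SCENARIO)
    scenario.update(doc.get("scenario", {}))
    return scenario


def model_from_config(doc: dict) -> ArtifactModel:
    block = dict(doc.get("model", {}))
    preset = block.pop("preset", None)
    if preset is not None:
        if preset not in ("default", "silent", "ideal"):
            raise ConfigurationError(f"unknown model preset {preset!r}")
        if block:
            raise ConfigurationError("model preset cannot be combined with fields")
        return {"default": ArtifactModel, "silent": ArtifactModel.silent,
                "ideal": ArtifactModel.ideal}[preset]()
    try:
        return ArtifactModel(**block)
    except TypeError as exc:
        raise ConfigurationError(f"model block: {exc}") from exc


def estimator_from_config(doc: dict) -> EstimatorConfig:
    block = doc.get("estimator", {})
    mapping = {"tau_s": "tau", "band_low_hz": "band_low", "band_high_hz": "band_high"}
    kwargs = {mapping.get(k, k): v for k, v in block.items()}
    for key in ("blank1", "blank2"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    try:
        return EstimatorConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"estimator block: {exc}") from exc


def device_from_config(doc: dict) -> DeviceConfig:
    block = doc.get("device", {})
    mapping = {"offset_uV": "offset", "gain_mA_per_uV": "gain",
               "max_stim_mA": "max_stim", "tau_s": "tau"}
    kwargs = {mapping.get(k, k): v for k, v in block.items()}
    try:
        return DeviceConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"device block: {exc}") from exc
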