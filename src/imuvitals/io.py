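"""CSV / YAML persistence, pipeline configuration, and run logging.

All time series travel as plain headered CSV (comma separator, dot
decimal), with time expressed in seconds from recording start; mechanical
and reference streams are assumed synchronized at t = 0, which the
simulator guarantees.  The configuration object mirrors every constant of
the processing chain so a run log can echo the exact settings used.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import (
    GroundTruth,
    InertialRecording,
    PiecewiseLinear,
    PostureSegment,
    ReferenceRecording,
    SubjectProtocol,
)

__all__ = [
    "PipelineConfig",
    "load_config",
    "save_config",
    "read_recording",
    "write_recording",
    "read_reference",
    "write_reference",
    "read_ground_truth",
    "write_ground_truth",
    "read_protocol",
    "write_protocol",
    "get_logger",
    "log_config",
    "InertialRecording",
    "ReferenceRecording",
    "GroundTruth",
]

_FLOAT_FMT = "%.12g"  # round-trips doubles to far better than 1e-9 relative


@dataclass
class PipelineConfig:
    """Every constant of the HR/RR extraction pipeline.

    Defaults follow the published processing chain: analysis axes z
    (accelerometer) and y (gyroscope); cardiac wavelet reconstruction band
    10-40 Hz; 40-sample RMS envelope; first-order Butterworth band-passes
    at 0.7-3 Hz (cardiac) and 0.1-0.7 Hz (respiratory); six sliding
    windows 5-55 s stepped by 1 s; PSD grid fixed at 0.01/60 Hz (0.166
    mHz, i.e. 0.01 bpm) for every window length; Bland-Altman limits of
    agreement at 1.96 SD.
    """

    acc_axis: str = "z"
    gyr_axis: str = "y"
    cardiac_recon_band: tuple = (10.0, 40.0)   # Hz
    envelope_window: int = 40                  # samples
    cardiac_band: tuple = (0.7, 3.0)           # Hz
    resp_band: tuple = (0.1, 0.7)              # Hz
    filter_order: int = 1
    window_lengths: tuple = (5, 15, 25, 35, 45, 55)  # s
    step: float = 1.0                          # s
    psd_resolution: float = 0.01 / 60.0        # Hz
    loa_multiplier: float = 1.96

    def __post_init__(self):
        for name in ("cardiac_recon_band", "cardiac_band", "resp_band"):
            lo, hi = getattr(self, name)
            if not 0 <= lo < hi:
                raise ValueError(f"{name} must satisfy 0 <= low < high, got ({lo}, {hi})")
            setattr(self, name, (float(lo), float(hi)))
        self.window_lengths = tuple(sorted(float(w) for w in self.window_lengths))
        if self.step <= 0 or self.step > min(self.window_lengths):
            raise ValueError("step must be positive and not exceed the shortest window")
        if self.psd_resolution <= 0:
            raise ValueError("psd_resolution must be positive")
        if self.envelope_window < 1:
            raise ValueError("envelope_window must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# CSV time series

_IMU_COLUMNS = ["time_s", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]


def _read_csv(path, required: list) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: file contains no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for c in required:
        bad = df.index[df[c].isna()]
        if len(bad):
            raise ValueError(f"{path}: column {c!r} has NaN at row {bad[0]}")
    return df


def _check_uniform_time(t: np.ndarray, path) -> float:
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0))
        raise ValueError(f"{path}: non-monotonic time at row {row + 1}")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 0.5 * med):
        row = int(np.argmax(np.abs(dt - med) > 0.5 * med))
        raise ValueError(f"{path}: non-uniform sampling at row {row + 1}")
    fs = 1.0 / med
    # timestamps are serialized with finite precision; snap to the integer
    # rate they encode so window sample counts stay exact across streams
    if abs(fs - round(fs)) < 1e-3 * fs:
        fs = float(round(fs))
    return fs


def write_recording(rec: InertialRecording, path) -> None:
    df = pd.DataFrame({"time_s": rec.times})
    for i, ax in enumerate(("x", "y", "z")):
        df[f"acc_{ax}"] = rec.acc[:, i]
    for i, ax in enumerate(("x", "y", "z")):
        df[f"gyr_{ax}"] = rec.gyr[:, i]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_recording(path) -> InertialRecording:
    df = _read_csv(path, _IMU_COLUMNS)
    t = df["time_s"].to_numpy(float)
    fs = _check_uniform_time(t, path)
    acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy(float)
    gyr = df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(float)
    return InertialRecording(times=t, acc=acc, gyr=gyr, fs=fs)


def write_reference(ref: ReferenceRecording, ecg_path, resp_path) -> None:
    t_ecg = np.arange(ref.ecg.size) / ref.fs_ecg
    pd.DataFrame({"time_s": t_ecg, "ecg": ref.ecg}).to_csv(
        ecg_path, index=False, float_format=_FLOAT_FMT)
    t_resp = np.arange(ref.resp.size) / ref.fs_resp
    pd.DataFrame({"time_s": t_resp, "resp": ref.resp}).to_csv(
        resp_path, index=False, float_format=_FLOAT_FMT)


def read_reference(ecg_path, resp_path) -> ReferenceRecording:
    ecg_df = _read_csv(ecg_path, ["time_s", "ecg"])
    fs_ecg = _check_uniform_time(ecg_df["time_s"].to_numpy(float), ecg_path)
    resp_df = _read_csv(resp_path, ["time_s", "resp"])
    fs_resp = _check_uniform_time(resp_df["time_s"].to_numpy(float), resp_path)
    return ReferenceRecording(
        ecg=ecg_df["ecg"].to_numpy(float), fs_ecg=fs_ecg,
        resp=resp_df["resp"].to_numpy(float), fs_resp=fs_resp)


def write_ground_truth(gt: GroundTruth, path) -> None:
    pd.DataFrame({
        "time_s": gt.times,
        "hr_bpm": gt.hr_true,
        "rr_brpm": gt.rr_true,
        "apnea": gt.apnea_flag.astype(int),
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_ground_truth(path) -> GroundTruth:
    df = _read_csv(path, ["time_s", "hr_bpm", "rr_brpm", "apnea"])
    return GroundTruth(
        times=df["time_s"].to_numpy(float),
        hr_true=df["hr_bpm"].to_numpy(float),
        rr_true=df["rr_brpm"].to_numpy(float),
        apnea_flag=df["apnea"].to_numpy(int).astype(bool),
    )


# ---------------------------------------------------------------------------
# protocol serialization


def write_protocol(protocol: SubjectProtocol, path) -> None:
    d = {
        "seed": int(protocol.seed),
        "segments": [[s.posture, float(s.duration)] for s in protocol.segments],
        "hr_trajectory": {"times": protocol.hr_trajectory.times.tolist(),
                          "values": protocol.hr_trajectory.values.tolist()},
        "rr_trajectory": {"times": protocol.rr_trajectory.times.tolist(),
                          "values": protocol.rr_trajectory.values.tolist()},
        "apnea_intervals": [[float(a), float(b)] for a, b in protocol.apnea_intervals],
        "noise_sd_per_posture": {k: float(v) for k, v in protocol.noise_sd_per_posture.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_protocol(path) -> SubjectProtocol:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return SubjectProtocol(
        segments=[PostureSegment(p, dur) for p, dur in d["segments"]],
        hr_trajectory=PiecewiseLinear(np.array(d["hr_trajectory"]["times"]),
                                      np.array(d["hr_trajectory"]["values"])),
        rr_trajectory=PiecewiseLinear(np.array(d["rr_trajectory"]["times"]),
                                      np.array(d["rr_trajectory"]["values"])),
        apnea_intervals=[tuple(iv) for iv in d["apnea_intervals"]],
        noise_sd_per_posture=d["noise_sd_per_posture"],
        seed=d["seed"],
    )


# ---------------------------------------------------------------------------
# logging


def get_logger(name: str = "imuvitals", logfile=None) -> logging.Logger:
    """Logger writing ``timestamp level message`` lines to stderr (and
    optionally to a file)."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(fmt)
        logger.addHandler(h)
        logger.setLevel(logging.INFO)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    return logger


def log_config(config: PipelineConfig, logger: logging.Logger | None = None) -> None:
    """Echo every constant actually used, one line per field."""
    logger = logger or get_logger()
    for k, v in sorted(config.to_dict().items()):
        logger.info("config %s=%s", k, v)
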