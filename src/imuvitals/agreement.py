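"""Bland-Altman and mean-absolute-error agreement statistics.

Mechanical (IMU-derived) and reference rate series built with the same
window length share their window centres one-for-one; after dropping
points flagged invalid on either side, agreement between the two methods
is summarized by the Bland-Altman mean of differences (MOD), the limits of
agreement MOD +/- 1.96 x SD of the differences (sample SD, n-1
denominator), and the mean absolute error (MAE), grouped by vital x
sensor x posture x window length, with a per-subject MAE breakdown.

All sliding windows are pooled into a single Bland-Altman population per
group; no repeated-measures correction is applied for the strong serial
correlation of overlapping windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .spectral import RateSeries

__all__ = [
    "PairedEstimates",
    "BlandAltman",
    "AgreementReport",
    "pair_series",
    "bland_altman",
    "mae",
    "build_report",
]


class BlandAltman(NamedTuple):
    mod: float
    loa_low: float
    loa_high: float


@dataclass
class PairedEstimates:
    """Mechanical estimates matched 1:1 with reference estimates."""

    window_centers: np.ndarray
    est: np.ndarray   # mechanical, bpm / BrPM
    ref: np.ndarray   # reference, same units
    vital: str = ""       # hr | rr
    sensor: str = ""      # acc | gyr
    posture: str = ""
    window_length: float = float("nan")
    subject: str = ""
    n_excluded: int = 0   # invalid-flagged points dropped pairwise

    def __post_init__(self):
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        self.est = np.asarray(self.est, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        if not (self.window_centers.size == self.est.size == self.ref.size):
            raise ValueError("paired columns must have equal length")

    def __len__(self):
        return self.est.size


def pair_series(est: RateSeries, ref: RateSeries, **labels) -> PairedEstimates:
    """Match a mechanical series with its reference, excluding pairwise any
    point flagged invalid on either side.  The two series must come from
    identically windowed signals."""
    if len(est) != len(ref) or not np.allclose(est.window_centers, ref.window_centers):
        raise ValueError("series were not built with identical windows")
    if est.window_length != ref.window_length:
        raise ValueError("series have different window lengths")
    keep = est.valid & ref.valid
    merged = {
        "vital": est.meta.get("vital", ""),
        "sensor": est.source,
        "posture": est.meta.get("posture", ""),
        "subject": est.meta.get("subject", ""),
    }
    merged.update(labels)
    return PairedEstimates(
        window_centers=est.window_centers[keep],
        est=est.rates[keep],
        ref=ref.rates[keep],
        window_length=est.window_length,
        n_excluded=int((~keep).sum()),
        **merged,
    )


def bland_altman(pairs: PairedEstimates, loa_multiplier: float = 1.96) -> BlandAltman:
    """Mean of differences (est - ref) and 95% limits of agreement."""
    if len(pairs) < 2:
        raise ValueError("Bland-Altman needs at least two valid pairs")
    d = pairs.est - pairs.ref
    mod = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(mod, mod - loa_multiplier * sd, mod + loa_multiplier * sd)


def mae(pairs: PairedEstimates) -> float:
    """Mean absolute error between the two methods."""
    if len(pairs) < 1:
        raise ValueError("MAE needs at least one valid pair")
    return float(np.mean(np.abs(pairs.est - pairs.ref)))


def _pool(group: list) -> PairedEstimates:
    first = group[0]
    return PairedEstimates(
        window_centers=np.concatenate([p.window_centers for p in group]),
        est=np.concatenate([p.est for p in group]),
        ref=np.concatenate([p.ref for p in group]),
        vital=first.vital, sensor=first.sensor, posture=first.posture,
        window_length=first.window_length,
        subject="all",
        n_excluded=sum(p.n_excluded for p in group),
    )


@dataclass
class AgreementReport:
    """Tidy agreement tables.

    ``summary`` holds one row per metric and (vital, sensor, posture,
    window) group pooled over subjects; ``per_subject`` holds the MAE of
    each subject separately.
    """

    summary: pd.DataFrame
    per_subject: pd.DataFrame

    COLUMNS = ["metric", "vital", "sensor", "posture", "window_s", "subject", "value", "n"]

    def to_csv(self, path) -> None:
        tidy = pd.concat([self.summary, self.per_subject], ignore_index=True)
        tidy.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "AgreementReport":
        tidy = pd.read_csv(path)
        pooled = tidy["subject"] == "all"
        return cls(summary=tidy[pooled].reset_index(drop=True),
                   per_subject=tidy[~pooled].reset_index(drop=True))

    def lookup(self, metric: str, **labels) -> pd.DataFrame:
        df = self.summary if labels.get("subject", "all") == "all" else self.per_subject
        out = df[df["metric"] == metric]
        for k, v in labels.items():
            out = out[out[k] == v]
        return out


def build_report(all_pairs: list, loa_multiplier: float = 1.96) -> AgreementReport:
    """Aggregate paired estimates into the study's agreement report:
    MOD / LOA / MAE per (vital, sensor, posture, window length) pooled over
    subjects, plus a per-subject MAE table.  Row order is deterministic."""
    if not all_pairs:
        raise ValueError("no paired estimates supplied")

    groups: dict = {}
    for p in all_pairs:
        key = (p.vital, p.sensor, p.posture, p.window_length)
        groups.setdefault(key, []).append(p)

    summary_rows, subject_rows = [], []
    for key in sorted(groups, key=lambda k: (k[0], k[1], k[2], k[3])):
        vital, sensor, posture, window = key
        members = sorted(groups[key], key=lambda p: p.subject)
        pooled = _pool(members)
        n = len(pooled)
        base = dict(vital=vital, sensor=sensor, posture=posture,
                    window_s=window, subject="all", n=n)
        if n >= 2:
            ba = bland_altman(pooled, loa_multiplier)
            summary_rows += [
                {**base, "metric": "mod", "value": ba.mod},
                {**base, "metric": "loa_low", "value": ba.loa_low},
                {**base, "metric": "loa_high", "value": ba.loa_high},
            ]
        if n >= 1:
            summary_rows.append({**base, "metric": "mae", "value": mae(pooled)})
        summary_rows.append({**base, "metric": "n_excluded",
                             "value": float(pooled.n_excluded)})
        for p in members:
            if len(p) >= 1:
                subject_rows.append({
                    "metric": "mae", "vital": vital, "sensor": sensor,
                    "posture": posture, "window_s": window,
                    "subject": p.subject, "value": mae(p), "n": len(p),
                })

    cols = AgreementReport.COLUMNS
    summary = pd.DataFrame(summary_rows)[cols] if summary_rows else pd.DataFrame(columns=cols)
    per_subject = pd.DataFrame(subject_rows)[cols] if subject_rows else pd.DataFrame(columns=cols)
    return AgreementReport(summary=summary, per_subject=per_subject)
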