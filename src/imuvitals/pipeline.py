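"""End-to-end study orchestration.

Replicates the study design in silico: simulate a cohort of subjects, run
the cardiac and respiratory chains on both sensors for every posture
segment and window length, pair each mechanical rate series with its
reference, and build the agreement report.
"""

from __future__ import annotations

from dataclasses import dataclass


from . import agreement as agr
from . import preprocess as pre
from . import spectral as spec
from .io import PipelineConfig, get_logger
from .synthetic import (
    GroundTruth,
    InertialRecording,
    ReferenceRecording,
    SubjectProtocol,
    default_protocol,
    synthesize_mechanical,
    synthesize_reference,
)

__all__ = [
    "SubjectData",
    "simulate_cohort",
    "slice_recording",
    "slice_reference",
    "extract_subject_rates",
    "pair_all",
    "run_study",
]

logger = get_logger()


@dataclass
class SubjectData:
    subject_id: str
    protocol: SubjectProtocol
    recording: InertialRecording
    reference: ReferenceRecording
    truth: GroundTruth


def simulate_cohort(n_subjects: int, seed: int, **protocol_kwargs) -> list:
    """Simulate ``n_subjects`` subjects with seeds ``seed, seed+1, ...``."""
    cohort = []
    for i in range(n_subjects):
        protocol = default_protocol(seed + i, **protocol_kwargs)
        rec, truth = synthesize_mechanical(protocol)
        ref = synthesize_reference(protocol)
        cohort.append(SubjectData(f"S{i + 1:02d}", protocol, rec, ref, truth))
    return cohort


def slice_recording(rec: InertialRecording, t0: float, t1: float) -> InertialRecording:
    i0, i1 = int(round(t0 * rec.fs)), int(round(t1 * rec.fs))
    return InertialRecording(times=rec.times[i0:i1] - rec.times[i0],
                             acc=rec.acc[i0:i1], gyr=rec.gyr[i0:i1], fs=rec.fs)


def slice_reference(ref: ReferenceRecording, t0: float, t1: float) -> ReferenceRecording:
    e0, e1 = int(round(t0 * ref.fs_ecg)), int(round(t1 * ref.fs_ecg))
    r0, r1 = int(round(t0 * ref.fs_resp)), int(round(t1 * ref.fs_resp))
    return ReferenceRecording(ecg=ref.ecg[e0:e1], fs_ecg=ref.fs_ecg,
                              resp=ref.resp[r0:r1], fs_resp=ref.fs_resp)


def extract_subject_rates(subj: SubjectData, config: PipelineConfig | None = None,
                          windows=None, sensors=("acc", "gyr")) -> list:
    """All rate series for one subject: per posture segment, per window
    length, both vitals, each sensor plus the reference.  Windows longer
    than a segment are skipped with a warning."""
    config = config or PipelineConfig()
    windows = config.window_lengths if windows is None else tuple(windows)
    series = []
    for posture, t0, t1 in subj.protocol.segment_bounds():
        rec = slice_recording(subj.recording, t0, t1)
        ref = slice_reference(subj.reference, t0, t1)
        seg_dur = rec.duration
        chains = {"hr": {}, "rr": {}}
        for sensor in sensors:
            chains["hr"][sensor] = pre.cardiac_preprocess(rec, config, sensor)
            chains["rr"][sensor] = pre.respiratory_preprocess(rec, config, sensor)
        chains["hr"]["reference"] = pre.reference_preprocess(ref, "cardiac", config)
        chains["rr"]["reference"] = pre.reference_preprocess(ref, "respiratory", config)
        bands = {"hr": config.cardiac_band, "rr": config.resp_band}
        # raw respiration amplitude gates RR validity: breath-hold windows
        # have no breathing oscillation and are flagged invalid on all sources
        raw_resp = pre.Signal1D(ref.resp, ref.fs_resp, label="ref_resp_raw")
        for length in windows:
            if length > seg_dur + 1e-9:
                logger.warning("skipping %s s window: %s segment of %s lasts only %.6g s",
                               length, posture, subj.subject_id, seg_dur)
                continue
            for vital, by_source in chains.items():
                for source, sig in by_source.items():
                    series.append(spec.extract_rate_series(
                        sig, bands[vital], length, config, source=source,
                        meta={"vital": vital, "posture": posture,
                              "subject": subj.subject_id},
                        validity_signal=raw_resp if vital == "rr" else None))
    return series


def pair_all(series: list) -> list:
    """Pair each mechanical rate series with the reference series of the
    same (subject, vital, posture, window length)."""
    refs, mech = {}, []
    for rs in series:
        key = (rs.meta.get("subject"), rs.meta.get("vital"),
               rs.meta.get("posture"), rs.window_length)
        if rs.source == "reference":
            refs[key] = rs
        else:
            mech.append((key, rs))
    pairs = []
    for key, rs in mech:
        ref = refs.get(key)
        if ref is None:
            raise ValueError(f"no reference series for group {key}")
        pairs.append(agr.pair_series(rs, ref))
    return pairs


def run_study(n_subjects: int = 11, seed: int = 0,
              config: PipelineConfig | None = None, windows=None,
              sensors=("acc", "gyr"), **protocol_kwargs):
    """Simulate, extract and evaluate in one call.

    Returns ``(report, series, cohort)``.  Deterministic for fixed
    arguments and seed.
    """
    config = config or PipelineConfig()
    cohort = simulate_cohort(n_subjects, seed, **protocol_kwargs)
    series = []
    for subj in cohort:
        series.extend(extract_subject_rates(subj, config, windows, sensors))
    pairs = pair_all(series)
    report = agr.build_report(pairs, loa_multiplier=config.loa_multiplier)
    return report, series, cohort
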