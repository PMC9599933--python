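"""Seeded synthetic cardiorespiratory IMU recordings.

Generates the mechanical signals a chest-worn inertial sensor sees —
heartbeat-locked high-frequency vibration packets (the seismocardiogram /
gyrocardiogram) riding on a slow respiratory oscillation — together with
synchronized reference waveforms (an ECG-like spike train and a respiration
belt trace) and a 1 Hz ground-truth table of the instantaneous heart and
respiratory rates that produced them.

The generator models exactly the statistical structure the spectral
estimation pipeline relies on:

* cardiac energy confined to the 10–40 Hz band (Gaussian-windowed 20 Hz
  carrier packets, one per beat, ~120 ms long);
* respiratory energy confined to 0.1–0.7 Hz (a sinusoid at the
  instantaneous breathing rate, silenced during breath-holds);
* posture-dependent broadband sensor noise (lying < sitting < standing);
* a protocol of consecutive at-rest posture segments, each ~2 min and
  ending with a 20 s voluntary apnea.

It does not attempt realistic intra-beat waveform morphology (no
mitral/aortic fiducial peaks) nor ambulatory motion artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "PiecewiseLinear",
    "PostureSegment",
    "SubjectProtocol",
    "GroundTruth",
    "InertialRecording",
    "ReferenceRecording",
    "beat_times_from_hr",
    "default_protocol",
    "synthesize_mechanical",
    "synthesize_reference",
    "DEFAULT_NOISE_SD",
    "POSTURES",
]

POSTURES = ("sitting", "standing", "lying")

#: Broadband noise standard deviation per posture, in units of the cardiac
#: packet amplitude (1.0).  Chosen to reproduce the qualitative ordering of
#: signal quality across postures: lying is quietest, standing noisiest.
DEFAULT_NOISE_SD = {"lying": 0.05, "sitting": 0.10, "standing": 0.30}

HR_RANGE = (42.0, 180.0)  # bpm, inside the 0.7-3 Hz cardiac band
RR_RANGE = (6.0, 42.0)    # BrPM, inside the 0.1-0.7 Hz respiratory band

_CARRIER_HZ = 20.0        # cardiac packet carrier, centre of the 10-40 Hz band
_PACKET_SIGMA_S = 0.022   # Gaussian envelope width: keeps >=95% of packet
                          # power inside 10-40 Hz at the 20 Hz carrier
_PACKET_HALF_S = 0.060    # hard support +-60 ms: packet duration 120 ms
_APNEA_RAMP_S = 0.5       # half-cosine on/off ramp placed inside the apnea
_CROSS_AXIS_GAIN = 0.3    # attenuation of the non-analysis axes


@dataclass(frozen=True)
class PiecewiseLinear:
    """Piecewise-linear trajectory, callable at arbitrary times.

    Outside the breakpoint range the trajectory is clamped to the end
    values, so a single breakpoint yields a constant.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if t.size == 0:
            raise ValueError("trajectory needs at least one breakpoint")
        if np.any(np.diff(t) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @classmethod
    def constant(cls, value: float) -> "PiecewiseLinear":
        return cls(np.array([0.0]), np.array([float(value)]))

    def __call__(self, t):
        return np.interp(t, self.times, self.values)


@dataclass(frozen=True)
class PostureSegment:
    posture: str
    duration: float  # s

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"segment duration must be > 0, got {self.duration}")


@dataclass
class SubjectProtocol:
    """Generative ground truth for one synthetic subject.

    segments
        Ordered posture segments (label, duration in s).
    hr_trajectory, rr_trajectory
        Instantaneous heart rate (bpm) and respiratory rate (BrPM) over the
        whole recording.
    apnea_intervals
        (start, end) in s where the respiratory oscillation amplitude is
        zero (voluntary breath-hold).
    noise_sd_per_posture
        Broadband sensor-noise SD per posture, in signal units.
    seed
        Master seed: identical (protocol, seed) reproduces every sample.
    """

    segments: list
    hr_trajectory: PiecewiseLinear
    rr_trajectory: PiecewiseLinear
    apnea_intervals: list = field(default_factory=list)
    noise_sd_per_posture: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    seed: int = 0

    def __post_init__(self):
        self.segments = [
            s if isinstance(s, PostureSegment) else PostureSegment(*s)
            for s in self.segments
        ]
        self.validate()

    # -- derived quantities ------------------------------------------------

    @property
    def duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def segment_bounds(self):
        """[(posture, t_start, t_end)] in recording time."""
        out, t0 = [], 0.0
        for s in self.segments:
            out.append((s.posture, t0, t0 + s.duration))
            t0 += s.duration
        return out

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one posture segment")
        dur = self.duration
        grid = np.linspace(0.0, dur, max(int(dur) + 1, 2))
        hr = self.hr_trajectory(grid)
        rr = self.rr_trajectory(grid)
        if np.any(hr < HR_RANGE[0]) or np.any(hr > HR_RANGE[1]):
            raise ValueError(f"hr_trajectory must stay within {HR_RANGE} bpm")
        if np.any(rr < RR_RANGE[0]) or np.any(rr > RR_RANGE[1]):
            raise ValueError(f"rr_trajectory must stay within {RR_RANGE} BrPM")
        for a, b in self.apnea_intervals:
            if not (0.0 <= a < b <= dur + 1e-9):
                raise ValueError(f"apnea interval ({a}, {b}) outside [0, {dur}]")
        for s in self.segments:
            if s.posture not in self.noise_sd_per_posture:
                raise ValueError(f"no noise SD configured for posture {s.posture!r}")
        for p, sd in self.noise_sd_per_posture.items():
            if sd < 0:
                raise ValueError(f"noise SD for {p!r} must be >= 0")

    # -- seeded randomness -------------------------------------------------

    def _streams(self) -> dict:
        """Independent, order-insensitive random streams for this subject."""
        children = SeedSequence(self.seed).spawn(4)
        return {
            "traits": default_rng(children[0]),
            "phase": default_rng(children[1]),
            "mech_noise": default_rng(children[2]),
            "ref_noise": default_rng(children[3]),
        }

    def _phases(self):
        """(cardiac phase fraction in [0,1), respiratory phase in [0,2pi))."""
        rng = self._streams()["phase"]
        return rng.uniform(0.0, 1.0), rng.uniform(0.0, 2.0 * np.pi)

    def beat_times(self) -> np.ndarray:
        """Beat instants shared by the mechanical and reference simulations."""
        u, _ = self._phases()
        return beat_times_from_hr(self.hr_trajectory, self.duration, phase=u)


@dataclass
class GroundTruth:
    """1 Hz samples of the generative trajectories, for parameter recovery."""

    times: np.ndarray       # s
    hr_true: np.ndarray     # bpm
    rr_true: np.ndarray     # BrPM
    apnea_flag: np.ndarray  # bool

    def __post_init__(self):
        n = len(self.times)
        if not (len(self.hr_true) == len(self.rr_true) == len(self.apnea_flag) == n):
            raise ValueError("ground-truth channels must have equal length")


# Recording containers live conceptually with I/O but are defined here so the
# generator has no circular dependency; io re-exports them.

@dataclass
class InertialRecording:
    """Tri-axial accelerometer + gyroscope channels at a uniform rate."""

    times: np.ndarray  # s
    acc: np.ndarray    # (N, 3), axes x, y, z
    gyr: np.ndarray    # (N, 3), axes x, y, z
    fs: float          # Hz

    AXES = ("x", "y", "z")

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        n = self.times.size
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise ValueError("acc and gyr must be (N, 3) arrays matching times")
        if self.fs <= 80.0:
            raise ValueError("sampling rate must exceed 80 Hz to cover 10-40 Hz")
        if n >= 2:
            dt = np.diff(self.times)
            if np.any(np.abs(dt - 1.0 / self.fs) > 0.5 / self.fs):
                raise ValueError("timestamps are not uniform at the stated rate")

    @property
    def duration(self) -> float:
        return self.times.size / self.fs

    def channel(self, sensor: str, axis: str) -> np.ndarray:
        sensor = sensor.lower()
        if axis not in self.AXES:
            raise KeyError(f"unknown axis {axis!r}; expected one of {self.AXES}")
        arr = {"acc": self.acc, "gyr": self.gyr}.get(sensor)
        if arr is None:
            raise KeyError(f"unknown sensor {sensor!r}; expected 'acc' or 'gyr'")
        return arr[:, self.AXES.index(axis)]


@dataclass
class ReferenceRecording:
    """Gold-standard ECG-like and respiration waveforms, each at native rate."""

    ecg: np.ndarray
    fs_ecg: float
    resp: np.ndarray
    fs_resp: float

    def __post_init__(self):
        if self.fs_ecg <= 0 or self.fs_resp <= 0:
            raise ValueError("reference sampling rates must be positive")
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.resp = np.asarray(self.resp, dtype=float)


# ---------------------------------------------------------------------------
# beat timing


def beat_times_from_hr(hr_trajectory, duration: float, phase: float | None = None,
                       rng: Generator | None = None, dt: float = 0.002) -> np.ndarray:
    """Beat instants of a heart beating at time-varying rate ``hr(t)`` bpm.

    The cumulative beat count is the integral of HR(t)/60; beats fall where
    it crosses ``phase + k`` for integer k, so consecutive intervals equal
    60/HR evaluated along the trajectory.  ``phase`` is the fractional-beat
    offset in [0, 1); when None it is drawn from ``rng`` (or a fresh
    generator), which places the first beat uniformly in [0, 60/HR(0)).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if phase is None:
        phase = (rng or default_rng()).uniform(0.0, 1.0)
    if not 0.0 <= phase < 1.0:
        raise ValueError("phase must lie in [0, 1)")
    hr = hr_trajectory if callable(hr_trajectory) else PiecewiseLinear.constant(hr_trajectory)
    grid = np.arange(0.0, duration + dt, dt)
    rate = np.asarray(hr(grid), dtype=float)
    if np.any(rate <= 0):
        raise ValueError("heart-rate trajectory must be positive everywhere")
    beats_cum = cumulative_trapezoid(rate / 60.0, grid, initial=0.0)
    total = beats_cum[-1]
    if phase > total:
        return np.empty(0)
    ks = phase + np.arange(int(np.floor(total - phase)) + 1)
    t = np.interp(ks, beats_cum, grid)
    return t[t < duration]


# ---------------------------------------------------------------------------
# default study protocol


def default_protocol(seed: int, postures=POSTURES, segment_duration: float = 120.0,
                     apnea_duration: float = 20.0, noise_sd: dict | None = None,
                     hr_trajectory: PiecewiseLinear | None = None,
                     rr_trajectory: PiecewiseLinear | None = None) -> SubjectProtocol:
    """The study protocol: consecutive ~2 min at-rest posture segments, each
    ending with a 20 s breath-hold.

    Per-subject HR and RR trajectories are slow seeded sinusoids sampled to
    1 s piecewise-linear tables: HR stays within 60-80 bpm (baseline
    66-74, swing 4-6, period 60-120 s) and RR within 9-21 BrPM (baseline
    12-18, swing 1.5-3, period 45-90 s) — normocardic, eupneic adults at
    rest.
    """
    segments = [PostureSegment(p, segment_duration) for p in postures]
    duration = segment_duration * len(postures)
    traits = default_rng(SeedSequence(seed).spawn(4)[0])

    tgrid = np.arange(0.0, duration + 1.0, 1.0)
    if hr_trajectory is None:
        base = traits.uniform(66.0, 74.0)
        amp = traits.uniform(4.0, 6.0)
        period = traits.uniform(60.0, 120.0)
        phi = traits.uniform(0.0, 2.0 * np.pi)
        hr_trajectory = PiecewiseLinear(tgrid, base + amp * np.sin(2 * np.pi * tgrid / period + phi))
    if rr_trajectory is None:
        base = traits.uniform(12.0, 18.0)
        amp = traits.uniform(1.5, 3.0)
        period = traits.uniform(45.0, 90.0)
        phi = traits.uniform(0.0, 2.0 * np.pi)
        rr_trajectory = PiecewiseLinear(tgrid, base + amp * np.sin(2 * np.pi * tgrid / period + phi))

    apnea = []
    if apnea_duration > 0:
        t0 = 0.0
        for s in segments:
            apnea.append((t0 + s.duration - apnea_duration, t0 + s.duration))
            t0 += s.duration

    return SubjectProtocol(
        segments=segments,
        hr_trajectory=hr_trajectory,
        rr_trajectory=rr_trajectory,
        apnea_intervals=apnea,
        noise_sd_per_posture=dict(DEFAULT_NOISE_SD if noise_sd is None else noise_sd),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# waveform builders


def _apnea_envelope(t: np.ndarray, intervals) -> np.ndarray:
    """Amplitude envelope: 1 during breathing, 0 inside apnea, with a short
    half-cosine ramp placed just inside each interval so breathing segments
    are untouched and the interval interior is exactly flat."""
    env = np.ones_like(t)
    for a, b in intervals:
        ramp = min(_APNEA_RAMP_S, 0.5 * (b - a))
        m = (t >= a) & (t < a + ramp)
        env[m] = 0.5 * (1.0 + np.cos(np.pi * (t[m] - a) / ramp))
        env[(t >= a + ramp) & (t <= b - ramp)] = 0.0
        m = (t > b - ramp) & (t <= b)
        env[m] = 0.5 * (1.0 - np.cos(np.pi * (t[m] - (b - ramp)) / ramp))
    return env


def _respiratory_wave(protocol: SubjectProtocol, t: np.ndarray, phi0: float) -> np.ndarray:
    rr = protocol.rr_trajectory(t)
    phase = 2.0 * np.pi * cumulative_trapezoid(rr / 60.0, t, initial=0.0) + phi0
    return np.sin(phase) * _apnea_envelope(t, protocol.apnea_intervals)


def _cardiac_packets(t: np.ndarray, beats: np.ndarray, fs: float) -> np.ndarray:
    """One Gaussian-windowed 20 Hz packet per beat, 120 ms support."""
    x = np.zeros_like(t)
    half = int(np.ceil(_PACKET_HALF_S * fs))
    n = t.size
    for tb in beats:
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        tau = t[lo:hi] - tb
        x[lo:hi] += np.cos(2 * np.pi * _CARRIER_HZ * tau) * np.exp(-0.5 * (tau / _PACKET_SIGMA_S) ** 2)
    return x


def _noise_sd_per_sample(protocol: SubjectProtocol, t: np.ndarray) -> np.ndarray:
    sd = np.empty_like(t)
    for posture, a, b in protocol.segment_bounds():
        sd[(t >= a) & (t < b)] = protocol.noise_sd_per_posture[posture]
    # last sample may sit exactly at the end of the final segment
    sd[t >= protocol.segment_bounds()[-1][2]] = protocol.noise_sd_per_posture[protocol.segments[-1].posture]
    return sd


#: component amplitudes (cardiac, respiratory) of the analysis channels
_PRIMARY_AMPLITUDES = {"acc_z": (1.0, 0.8), "gyr_y": (0.9, 1.0)}


def synthesize_mechanical(protocol: SubjectProtocol, fs: float = 120.0,
                          cardiac_amplitude: float = 1.0,
                          respiratory_amplitude: float = 1.0):
    """Simulate the six IMU channels plus the 1 Hz ground-truth table.

    The analysis channels (accelerometer z, gyroscope y) carry the
    full-amplitude cardiac packet train and respiratory oscillation; the
    remaining axes carry 0.3x attenuated copies.  Every channel receives
    independent Gaussian noise whose SD follows the posture of the current
    segment.  Identical (protocol, seed) yields bit-identical output.

    Returns ``(InertialRecording, GroundTruth)``.
    """
    protocol.validate()
    if fs <= 80.0:
        raise ValueError("fs must exceed 80 Hz so the 10-40 Hz band is sampled")
    n = int(round(protocol.duration * fs))
    t = np.arange(n) / fs

    _, phi_resp = protocol._phases()
    beats = protocol.beat_times()
    card = cardiac_amplitude * _cardiac_packets(t, beats, fs)
    resp = respiratory_amplitude * _respiratory_wave(protocol, t, phi_resp)
    sd = _noise_sd_per_sample(protocol, t)
    rng = protocol._streams()["mech_noise"]

    def make(channel: str) -> np.ndarray:
        if channel in _PRIMARY_AMPLITUDES:
            ac, ar = _PRIMARY_AMPLITUDES[channel]
        else:
            sensor = channel.split("_")[0]
            primary = "acc_z" if sensor == "acc" else "gyr_y"
            ac, ar = (_CROSS_AXIS_GAIN * a for a in _PRIMARY_AMPLITUDES[primary])
        return ac * card + ar * resp + sd * rng.standard_normal(n)

    acc = np.column_stack([make(f"acc_{ax}") for ax in ("x", "y", "z")])
    gyr = np.column_stack([make(f"gyr_{ax}") for ax in ("x", "y", "z")])
    rec = InertialRecording(times=t, acc=acc, gyr=gyr, fs=float(fs))

    gt_times = np.arange(0.0, np.floor(protocol.duration))
    apnea = np.zeros(gt_times.size, dtype=bool)
    for a, b in protocol.apnea_intervals:
        apnea |= (gt_times >= a) & (gt_times < b)
    truth = GroundTruth(
        times=gt_times,
        hr_true=protocol.hr_trajectory(gt_times),
        rr_true=protocol.rr_trajectory(gt_times),
        apnea_flag=apnea,
    )
    return rec, truth


def synthesize_reference(protocol: SubjectProtocol, fs_ecg: float = 250.0,
                         fs_resp: float = 25.0, ecg_noise_sd: float = 0.0,
                         resp_noise_sd: float = 0.0) -> ReferenceRecording:
    """Simulate the reference system: an ECG-like train of sharp R-wave
    spikes (sigma 8 ms) at the same beat instants as the mechanical
    simulation, and a smooth respiration trace that goes flat during apnea.
    Noise is off by default (the reference is treated as gold standard)."""
    protocol.validate()
    dur = protocol.duration
    beats = protocol.beat_times()

    n_ecg = int(round(dur * fs_ecg))
    t_ecg = np.arange(n_ecg) / fs_ecg
    ecg = np.zeros(n_ecg)
    sigma = 0.008
    half = int(np.ceil(4.0 * sigma * fs_ecg))
    for tb in beats:
        c = int(round(tb * fs_ecg))
        lo, hi = max(0, c - half), min(n_ecg, c + half + 1)
        tau = t_ecg[lo:hi] - tb
        ecg[lo:hi] += np.exp(-0.5 * (tau / sigma) ** 2)

    n_resp = int(round(dur * fs_resp))
    t_resp = np.arange(n_resp) / fs_resp
    _, phi_resp = protocol._phases()
    resp = _respiratory_wave(protocol, t_resp, phi_resp)

    if ecg_noise_sd > 0 or resp_noise_sd > 0:
        rng = protocol._streams()["ref_noise"]
        if ecg_noise_sd > 0:
            ecg = ecg + ecg_noise_sd * rng.standard_normal(n_ecg)
        if resp_noise_sd > 0:
            resp = resp + resp_noise_sd * rng.standard_normal(n_resp)

    return ReferenceRecording(ecg=ecg, fs_ecg=float(fs_ecg),
                              resp=resp, fs_resp=float(fs_resp))
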