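"""Sliding-window dominant-frequency rate estimation.

The preprocessed signal is cut into L-second windows advanced 1 s at a
time.  Each window gets a single-segment Welch power spectral density
(Hamming taper over the full window, 0% overlap — i.e. a modified
periodogram) evaluated on a frequency grid with a *fixed* spacing of
0.01/60 Hz (~0.166 mHz, 0.01 bpm), independent of the window length and of
the stream's sampling rate.  That constant resolution is what makes
estimates from 5 s and 55 s windows, and from 120/250/25 Hz streams,
directly comparable.  The rate is 60 x the frequency of the largest PSD
peak inside the physiological band.

The fixed grid is mathematically the zero-padded DFT with
NFFT = round(fs / resolution) (720,000 points at 120 Hz).  Rather than
materializing such transforms per window, in-band estimation uses the
chirp-z transform (``scipy.signal.ZoomFFT``) to evaluate exactly the same
DFT bins restricted to the band of interest; ``welch_psd`` with
``band=None`` exposes the full-grid path, and the two agree bin for bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import PipelineConfig
from .preprocess import Signal1D

__all__ = [
    "PsdEstimate",
    "RateSeries",
    "Segment",
    "segment_windows",
    "welch_psd",
    "dominant_rate",
    "extract_rate_series",
    "write_rate_series",
    "read_rate_series",
]

#: in-band power below this fraction of total window power flags the
#: estimate invalid (e.g. a reference respiration window inside an apnea)
POWER_FLOOR_FRACTION = 1e-6


@dataclass
class PsdEstimate:
    """One-sided PSD on a uniform grid of spacing ``resolution`` Hz."""

    frequencies: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency and power grids must match")


@dataclass
class Segment:
    center: float  # s, window centre in recording time
    values: np.ndarray
    fs: float


@dataclass
class RateSeries:
    """HR (bpm) or RR (BrPM) estimates at 1 s update intervals."""

    window_centers: np.ndarray  # s
    rates: np.ndarray           # bpm / BrPM; NaN where invalid
    valid: np.ndarray           # bool
    window_length: float        # s
    band: tuple                 # Hz
    source: str = ""            # e.g. acc, gyr, reference
    meta: dict = field(default_factory=dict)  # vital, posture, subject, ...

    def __post_init__(self):
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.window_centers) == len(self.rates) == len(self.valid)):
            raise ValueError("rate-series columns must have equal length")

    def __len__(self):
        return self.window_centers.size


def segment_windows(sig: Signal1D, length: float, step: float = 1.0) -> list:
    """Cut a T-second signal into fully contained L-second windows advanced
    by ``step`` s; for integer-second T, L and 1 s step this yields
    T - L + 1 windows."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = len(sig)
    n_win = int(round(length * sig.fs))
    if n_win < 1 or n_win > n:
        raise ValueError(f"window of {length} s does not fit a {n / sig.fs:.6g} s signal")
    n_step = step * sig.fs
    count = int(np.floor((n - n_win) / n_step + 1e-9)) + 1
    out = []
    for k in range(count):
        start = int(round(k * n_step))
        out.append(Segment(center=k * step + length / 2.0,
                           values=sig.values[start:start + n_win],
                           fs=sig.fs))
    return out


# cache of ZoomFFT transforms and tapers keyed by grid geometry
_zoom_cache: dict = {}
_window_cache: dict = {}


def _hamming(n: int) -> np.ndarray:
    w = _window_cache.get(n)
    if w is None:
        w = sps.get_window("hamming", n)
        if len(_window_cache) > 64:
            _window_cache.clear()
        _window_cache[n] = w
    return w


def _band_bins(band, resolution: float):
    lo, hi = band
    k0 = int(np.ceil(lo / resolution - 1e-9))
    k1 = int(np.floor(hi / resolution + 1e-9))
    if k1 < k0:
        raise ValueError(f"band {band} contains no grid points at resolution {resolution}")
    return k0, k1


def welch_psd(values, fs: float, resolution: float | None = None,
              band=None) -> PsdEstimate:
    """Single-segment Welch PSD on the fixed-resolution grid.

    With ``band=None`` the full one-sided grid (spacing ``fs/NFFT`` with
    ``NFFT = round(fs/resolution)``) is returned via ``scipy.signal.welch``.
    With a ``(f_lo, f_hi)`` band, only the grid bins inside the band are
    evaluated, through a chirp-z transform that reproduces the zero-padded
    DFT bins exactly.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty segment")
    if resolution is None:
        resolution = PipelineConfig().psd_resolution
    nfft = int(round(fs / resolution))
    if nfft < n:
        raise ValueError(
            f"resolution {resolution} Hz is coarser than the segment's native "
            f"{fs / n:.6g} Hz; zero padding can only refine the grid")

    if band is None:
        freqs, power = sps.welch(x, fs=fs, window="hamming", nperseg=n,
                                 noverlap=0, nfft=nfft, detrend="constant")
        return PsdEstimate(freqs, power, resolution=fs / nfft)

    k0, k1 = _band_bins(band, resolution)
    m = k1 - k0 + 1
    key = (n, float(fs), float(resolution), k0, m)
    zoom = _zoom_cache.get(key)
    if zoom is None:
        f1 = k0 * resolution
        f2 = f1 + m * resolution
        zoom = sps.ZoomFFT(n, [f1, f2], m, fs=fs, endpoint=False)
        if len(_zoom_cache) > 64:
            _zoom_cache.clear()
        _zoom_cache[key] = zoom
    w = _hamming(n)
    xd = (x - x.mean()) * w
    spec = zoom(xd)
    power = (np.abs(spec) ** 2) * (2.0 / (fs * np.sum(w**2)))
    freqs = (k0 + np.arange(m)) * resolution
    return PsdEstimate(freqs, power, resolution=resolution)


def dominant_rate(psd: PsdEstimate, band) -> float:
    """60 x the in-band frequency of maximum power; ties and the argmax both
    resolve to the lowest qualifying frequency.  Returns NaN when the band
    holds no power (flagged-invalid estimate)."""
    lo, hi = band
    mask = (psd.frequencies >= lo - 1e-12) & (psd.frequencies <= hi + 1e-12)
    if not np.any(mask):
        raise ValueError(f"band {band} does not intersect the frequency grid")
    p = psd.power[mask]
    if np.all(p <= 0):
        return float("nan")
    f = psd.frequencies[mask]
    return 60.0 * float(f[int(np.argmax(p))])


def extract_rate_series(sig: Signal1D, band, window_length: float,
                        config: PipelineConfig | None = None, source: str = "",
                        meta: dict | None = None,
                        validity_signal: Signal1D | None = None) -> RateSeries:
    """Run the window -> PSD -> peak chain over a whole signal.

    Windows with no oscillation to measure are flagged invalid and carry
    NaN; downstream agreement statistics exclude them pairwise.  Two gates
    apply: a window of ``sig`` whose total (or in-band) power is zero, and
    — when ``validity_signal`` is given (the raw, unfiltered reference
    respiration trace) — any window in which that raw signal's power falls
    below ``POWER_FLOOR_FRACTION`` of its whole-recording power.  The
    latter catches breath-hold windows, where the band-pass filter's own
    ringing would otherwise masquerade as signal.
    """
    config = config or PipelineConfig()
    res = config.psd_resolution
    segments = segment_windows(sig, window_length, config.step)
    centers = np.array([s.center for s in segments])
    rates = np.full(centers.size, np.nan)
    valid = np.zeros(centers.size, dtype=bool)

    amplitude_ok = np.ones(centers.size, dtype=bool)
    if validity_signal is not None:
        vsegs = segment_windows(validity_signal, window_length, config.step)
        if len(vsegs) != len(segments):
            raise ValueError("validity signal does not span the same duration")
        v = validity_signal.values
        v_total = float(np.mean((v - v.mean()) ** 2))
        for i, vs in enumerate(vsegs):
            p = float(np.mean((vs.values - vs.values.mean()) ** 2))
            amplitude_ok[i] = p > POWER_FLOOR_FRACTION * v_total

    for i, seg in enumerate(segments):
        if not amplitude_ok[i]:
            continue
        x = seg.values
        total = float(np.mean((x - x.mean()) ** 2))
        if total <= 0.0:
            continue
        psd = welch_psd(x, sig.fs, res, band=band)
        band_power = float(psd.power.sum()) * res
        if band_power <= POWER_FLOOR_FRACTION * total:
            continue
        r = dominant_rate(psd, band)
        if np.isfinite(r):
            rates[i] = r
            valid[i] = True
    return RateSeries(centers, rates, valid, window_length=float(window_length),
                      band=(float(band[0]), float(band[1])), source=source,
                      meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# persistence: CSV with `# key=value` metadata header lines


def write_rate_series(rs: RateSeries, path) -> None:
    meta = {
        "window_length_s": rs.window_length,
        "band_hz": f"{rs.band[0]}-{rs.band[1]}",
        "source": rs.source,
        **{k: v for k, v in sorted(rs.meta.items())},
    }
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df = pd.DataFrame({
            "window_center_s": rs.window_centers,
            "rate": rs.rates,
            "valid": rs.valid.astype(int),
        })
        df.to_csv(fh, index=False, float_format="%.12g")


def read_rate_series(path) -> RateSeries:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    lo, _, hi = meta.pop("band_hz", "0-0").partition("-")
    return RateSeries(
        window_centers=df["window_center_s"].to_numpy(float),
        rates=df["rate"].to_numpy(float),
        valid=df["valid"].to_numpy(int).astype(bool),
        window_length=float(meta.pop("window_length_s", "nan")),
        band=(float(lo), float(hi)),
        source=meta.pop("source", ""),
        meta=meta,
    )
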