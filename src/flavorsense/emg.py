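"""Submental-EMG swallow detection and per-swallow features.

The detector is a hybrid of the Teager-Kaiser energy operator (TKEO) and a
discrete wavelet transform: after DC removal, a fifth-order 25-400 Hz
Butterworth bandpass and a mains notch, the TKEO sharpens burst onsets, a
sym4 multilevel decomposition keeps only the slow approximation (the burst
envelope), and a sliding RMS yields the detection envelope. Bursts are
maximal suprathreshold runs; each burst peaking within 4000 ms of a sip cue
is a *cued* swallow (first burst per cue), everything else *spontaneous*.

All filtering is zero-phase (forward-backward) so that peak latencies, which
are reported features, carry no filter delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .core import Marker, Recording, ms_to_samples

CUE_WINDOW_MS = 4000.0  # a swallow within [cue, cue + 4000 ms) is cued


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass or notch specification, applied zero-phase."""

    kind: str = "bandpass_butterworth"
    order: int = 5
    low_hz: float = 25.0
    high_hz: float = 400.0
    center_hz: float = 50.0
    q: float = 30.0
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.kind == "bandpass_butterworth":
            if not 0 < self.low_hz < self.high_hz:
                raise ValueError("need 0 < low < high")
            if self.high_hz >= fs / 2:
                raise ValueError(f"high cutoff {self.high_hz} Hz >= Nyquist ({fs / 2} Hz)")
        elif self.kind == "notch":
            if self.center_hz >= fs / 2:
                raise ValueError("notch frequency above Nyquist")
        else:
            raise ValueError(f"unknown filter kind {self.kind!r}")


@dataclass(frozen=True)
class BurstInterval:
    """Maximal suprathreshold run of the detection envelope, half-open."""

    start: int
    end: int
    peak_sample: int
    peak_value: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("start must be < end")
        if not self.start <= self.peak_sample < self.end:
            raise ValueError("peak must lie inside [start, end)")


@dataclass(frozen=True)
class SwallowEvent:
    peak_sample: int
    klass: str  # "cued" | "spontaneous"
    block: int
    cue_sample: int | None = None
    peak_latency_ms: float | None = None
    peak_amplitude_uv: float = 0.0
    auc_uv_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.klass not in ("cued", "spontaneous"):
            raise ValueError(f"class must be cued|spontaneous, got {self.klass!r}")
        if self.klass == "cued":
            if self.cue_sample is None:
                raise ValueError("cued swallow requires a cue")
            if not (self.peak_latency_ms is not None and 0 <= self.peak_latency_ms < CUE_WINDOW_MS):
                raise ValueError("cued latency must lie in [0, 4000) ms")


def remove_dc(x: np.ndarray) -> np.ndarray:
    """Subtract the sample mean (DC offset)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    return x - x.mean()


def bandpass(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth bandpass (default 5th order, 25-400 Hz)."""
    spec = spec or FilterSpec()
    spec.validate(fs)
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def notch(x: np.ndarray, fs: float, f0: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at the mains frequency."""
    if f0 >= fs / 2:
        raise ValueError("notch frequency above Nyquist")
    b, a = sps.iirnotch(f0, q, fs=fs)
    return sps.filtfilt(b, a, x)


def tkeo(x: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy operator, psi[n] = x[n]^2 - x[n-1]*x[n+1].

    Endpoints take the nearest interior value so the length is preserved.
    For a sinusoid A*sin(Omega*n) the interior output is the constant
    A^2 * sin^2(Omega).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("TKEO needs at least 3 samples")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def dwt_envelope(x: np.ndarray, wavelet: str = "sym4", level: int = 4) -> np.ndarray:
    """Low-frequency envelope via multilevel DWT approximation.

    Decomposes with the sym4 mother wavelet and reconstructs from the
    approximation coefficients alone (detail bands zeroed), which at 1 kHz
    and level 4 keeps envelope content below roughly fs / 2^(level+1) Hz.
    """
    x = np.asarray(x, dtype=np.float64)
    max_level = pywt.dwt_max_level(len(x), pywt.Wavelet(wavelet).dec_len)
    if level > max_level:
        raise ValueError(f"level {level} too deep for signal length {len(x)} (max {max_level})")
    coeffs = pywt.wavedec(x, wavelet, level=level)
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    rec = pywt.waverec(coeffs, wavelet)
    return rec[: len(x)]


def rms_envelope(x: np.ndarray, fs: float, window_ms: float = 50.0, step_ms: float = 10.0) -> np.ndarray:
    """Sliding-window RMS, resampled back to the input length.

    The RMS is evaluated every ``step_ms`` over centred windows of
    ``window_ms`` and linearly interpolated to one value per input sample.
    """
    x = np.asarray(x, dtype=np.float64)
    win = max(int(round(window_ms * fs / 1000.0)), 1)
    step = max(int(round(step_ms * fs / 1000.0)), 1)
    if win > x.size:
        raise ValueError("RMS window longer than signal")
    sq = np.concatenate([[0.0], np.cumsum(x * x)])
    centers = np.arange(0, x.size, step)
    lo = np.clip(centers - win // 2, 0, x.size)
    hi = np.clip(lo + win, 0, x.size)
    lo = hi - np.minimum(win, hi)  # keep full window near the right edge
    vals = np.sqrt((sq[hi] - sq[lo]) / np.maximum(hi - lo, 1))
    return np.interp(np.arange(x.size), centers, vals)


def detect_bursts(
    envelope: np.ndarray,
    threshold: float,
    fs: float,
    min_duration_ms: float = 200.0,
    min_gap_ms: float = 200.0,
) -> list[BurstInterval]:
    """Maximal runs of envelope > threshold, merged across short gaps.

    Runs separated by less than ``min_gap_ms`` are merged; merged runs
    shorter than ``min_duration_ms`` are discarded. The burst peak is the
    argmax of the envelope within the run (earliest sample on ties).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    env = np.asarray(envelope, dtype=np.float64)
    above = env > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(env.size)

    min_gap = ms_to_samples(min_gap_ms, fs)
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_dur = ms_to_samples(min_duration_ms, fs)
    bursts = []
    for s, e in merged:
        if e - s < min_dur:
            continue
        peak = s + int(np.argmax(env[s:e]))
        bursts.append(BurstInterval(start=s, end=e, peak_sample=peak, peak_value=float(env[peak])))
    return bursts


def auto_threshold(envelope: np.ndarray, k: float = 5.0) -> float:
    """Median + k * MAD of the envelope (automated stand-in for the manual
    per-block visual threshold)."""
    env = np.asarray(envelope, dtype=np.float64)
    med = float(np.median(env))
    mad = float(np.median(np.abs(env - med)))
    return med + k * mad if mad > 0 else med + k * max(env.std(), 1e-12)


def classify_swallows(
    bursts: list[BurstInterval],
    cue_samples: np.ndarray,
    fs: float,
    block: int,
) -> list[SwallowEvent]:
    """Assign each burst to exactly one class.

    A burst peaking in ``[cue, cue + 4000 ms)`` is cued if it is the first
    such burst for that cue; later bursts in the same window, and all bursts
    outside every cue window (including every rest-block burst), are
    spontaneous. When adjacent cue windows could both claim a burst the
    earlier cue wins.
    """
    cue_samples = np.sort(np.asarray(cue_samples, dtype=int))
    window = ms_to_samples(CUE_WINDOW_MS, fs)
    events: list[SwallowEvent] = []
    claimed: set[int] = set()
    for b in sorted(bursts, key=lambda b: b.peak_sample):
        cue: int | None = None
        for c in cue_samples:  # earlier cue claims the burst
            if c <= b.peak_sample < c + window:
                cue = int(c)
                break
            if c > b.peak_sample:
                break
        if cue is not None and cue not in claimed:
            claimed.add(cue)
            lat = (b.peak_sample - cue) * 1000.0 / fs
            events.append(
                SwallowEvent(
                    peak_sample=b.peak_sample,
                    klass="cued",
                    block=block,
                    cue_sample=cue,
                    peak_latency_ms=lat,
                    peak_amplitude_uv=b.peak_value,
                )
            )
        else:
            events.append(
                SwallowEvent(
                    peak_sample=b.peak_sample,
                    klass="spontaneous",
                    block=block,
                    peak_amplitude_uv=b.peak_value,
                )
            )
    return events


def swallow_features(
    envelope: np.ndarray,
    burst: BurstInterval,
    fs: float,
    cue_sample: int | None = None,
) -> tuple[float | None, float, float]:
    """(peak latency ms, peak amplitude µV, AUC µV·ms) for one burst.

    AUC is the trapezoidal integral of the envelope over ``[start, end)``.
    """
    if burst.end > envelope.size:
        raise ValueError("burst outside envelope bounds")
    seg = np.asarray(envelope[burst.start : burst.end], dtype=np.float64)
    auc = float(np.trapezoid(seg)) * 1000.0 / fs
    amp = float(envelope[burst.peak_sample])
    lat = None if cue_sample is None else (burst.peak_sample - cue_sample) * 1000.0 / fs
    return lat, amp, auc


@dataclass(frozen=True)
class SwallowDetectionConfig:
    bandpass: FilterSpec = FilterSpec()
    notch_hz: float = 50.0
    notch_q: float = 30.0
    wavelet: str = "sym4"
    dwt_level: int = 4
    rms_window_ms: float = 50.0
    rms_step_ms: float = 10.0
    threshold_k_mad: float = 5.0
    manual_threshold: float | None = None
    min_duration_ms: float = 200.0
    min_gap_ms: float = 200.0
    montage: str = "bipolar"  # or "first", "mean"
    features_on: str = "rms"  # or "dwt": feature source signal


def emg_trace(recording: Recording, montage: str = "bipolar") -> np.ndarray:
    """Single analysis trace from the two submental electrodes."""
    idx = recording.channels_with_role("EMG")
    if not idx:
        raise ValueError("no EMG channels in recording")
    if montage == "bipolar" and len(idx) >= 2:
        return recording.data[idx[0]] - recording.data[idx[1]]
    if montage == "mean":
        return recording.data[idx].mean(axis=0)
    return recording.data[idx[0]]


def detection_envelope(x: np.ndarray, fs: float, cfg: SwallowDetectionConfig) -> np.ndarray:
    """Filters -> TKEO -> DWT approximation -> RMS."""
    y = remove_dc(x)
    y = bandpass(y, fs, cfg.bandpass)
    y = notch(y, fs, cfg.notch_hz, cfg.notch_q)
    y = tkeo(y)
    y = dwt_envelope(y, cfg.wavelet, cfg.dwt_level)
    y = np.abs(y)
    src = rms_envelope(y, fs, cfg.rms_window_ms, cfg.rms_step_ms)
    return src


def detect_swallows(
    recording: Recording, cfg: SwallowDetectionConfig | None = None
) -> pd.DataFrame:
    """Full per-block swallow detection on a session recording.

    Returns a DataFrame with columns block, class, cue_sample, peak_sample
    (session-absolute), peak_latency_ms, peak_amplitude_uv, auc_uv_ms.
    """
    from .core import block_bounds, slice_block

    cfg = cfg or SwallowDetectionConfig()
    rows: list[dict] = []
    for block in range(1, 8):
        try:
            start, _ = block_bounds(recording, block)
        except KeyError:
            continue
        sub = slice_block(recording, block)
        x = emg_trace(sub, cfg.montage)
        env = detection_envelope(x, sub.fs, cfg)
        thr = cfg.manual_threshold or auto_threshold(env, cfg.threshold_k_mad)
        bursts = detect_bursts(env, thr, sub.fs, cfg.min_duration_ms, cfg.min_gap_ms)
        cues = np.array([m.sample for m in sub.markers_with_label("sip_cue")], dtype=int)
        events = classify_swallows(bursts, cues, sub.fs, block)
        by_peak = {b.peak_sample: b for b in bursts}
        for ev in events:
            b = by_peak[ev.peak_sample]
            lat, amp, auc = swallow_features(env, b, sub.fs, ev.cue_sample)
            rows.append(
                {
                    "block": block,
                    "class": ev.klass,
                    "cue_sample": -1 if ev.cue_sample is None else ev.cue_sample + start,
                    "peak_sample": ev.peak_sample + start,
                    "peak_latency_ms": np.nan if lat is None else lat,
                    "peak_amplitude_uv": amp,
                    "auc_uv_ms": auc,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "block", "class", "cue_sample", "peak_sample",
            "peak_latency_ms", "peak_amplitude_uv", "auc_uv_ms",
        ],
    )
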