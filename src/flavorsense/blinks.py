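"""Eye-blink detection on frontal channels and per-block blink rate.

Candidate blinks are maximal runs where the 1-20 Hz filtered signal exceeds
the block mean by more than 1.5 standard deviations. Candidates must match a
prototypical rounded "tent" (raised cosine) by Pearson correlation and clear
a signal-to-noise floor; the per-block rate is taken from whichever frontal
channel (Fp1, Fp2, AF7, AF8) retains the most accepted blinks.

Absolute rates depend on the correlation and SNR thresholds, which are
deliberately conservative; within-session *differences* between blocks are
the quantity of interest, not the absolute blinks/min.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import FRONTAL_CHANNELS, Recording, slice_block


@dataclass(frozen=True)
class BlinkConfig:
    low_hz: float = 1.0
    high_hz: float = 20.0
    candidate_sd_factor: float = 1.5
    tent_duration_ms: float = 300.0
    context_ms: float = 100.0
    corr_min: float = 0.90
    snr_min: float = 2.0
    min_candidate_ms: float = 50.0


@dataclass
class BlinkCandidate:
    """One suprathreshold interval on one channel, half-open samples."""

    start: int
    end: int
    channel: str
    peak_sample: int = 0
    tent_correlation: float = 0.0
    snr: float = 0.0
    accepted: bool = False


@dataclass(frozen=True)
class BlockBlinkRate:
    block: int
    rate_per_min: float
    n_blinks: int
    channel_used: str
    duration_min: float
    reliable: bool = True


def blink_bandpass(x: np.ndarray, fs: float, low: float = 1.0, high: float = 20.0) -> np.ndarray:
    """Zero-phase 1-20 Hz bandpass for blink detection."""
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} too low for a {high} Hz blink band")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def candidate_intervals(
    x: np.ndarray,
    fs: float,
    sd_factor: float = 1.5,
    channel: str = "",
    split_peaks: bool = True,
) -> list[BlinkCandidate]:
    """Maximal runs with x strictly above mean + sd_factor * sd.

    Mean and SD are taken over the whole (block) signal. A zero-variance
    signal yields no candidates. With ``split_peaks`` (default), a run that
    contains several prominent maxima — two blinks close enough for their
    suprathreshold intervals to fuse — is split at the valley between
    adjacent peaks, so each blink is scored separately.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < fs:
        raise ValueError("need at least 1 s of signal")
    sd = x.std()
    if sd == 0:
        return []
    thr = x.mean() + sd_factor * sd
    above = x > thr  # strict inequality at the boundary
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(x.size)
    out = []
    for s, e in zip(starts, ends):
        spans = [(s, e)]
        if split_peaks and e - s >= 3:
            seg = x[s:e]
            # secondary peaks must stand well clear of the noise floor
            peaks, _ = sps.find_peaks(seg, prominence=1.5 * sd)
            if len(peaks) > 1:
                spans = []
                prev = 0
                for a, b in zip(peaks[:-1], peaks[1:]):
                    cut = a + int(np.argmin(seg[a:b]))
                    spans.append((s + prev, s + cut))
                    prev = cut
                spans.append((s + prev, e))
        for ss, ee in spans:
            peak = ss + int(np.argmax(x[ss:ee]))
            out.append(BlinkCandidate(start=ss, end=ee, channel=channel, peak_sample=peak))
    return out


def raised_cosine(n: int) -> np.ndarray:
    """Blink prototype of length n, peak 1 at the midpoint."""
    t = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / n))


def fit_tent(
    x: np.ndarray, candidate: BlinkCandidate, fs: float, context_ms: float = 100.0
) -> float:
    """Pearson correlation of the candidate (with context) and the prototype.

    The raised-cosine prototype is rescaled to the extended segment length.
    Zero-variance segments return 0.
    """
    if candidate.end - candidate.start < 5:
        raise ValueError("candidate interval too short to fit")
    ctx = int(round(context_ms * fs / 1000.0))
    lo = max(candidate.start - ctx, 0)
    hi = min(candidate.end + ctx, len(x))
    seg = np.asarray(x[lo:hi], dtype=np.float64)
    proto = raised_cosine(len(seg))
    if seg.std() == 0 or proto.std() == 0:
        return 0.0
    return float(np.corrcoef(seg, proto)[0, 1])


def reject_low_snr(
    candidates: list[BlinkCandidate],
    x: np.ndarray,
    snr_min: float = 2.0,
    corr_min: float = 0.90,
) -> list[BlinkCandidate]:
    """Flag candidates accepted iff SNR and tent correlation clear thresholds.

    SNR = candidate peak amplitude / SD of the signal outside all candidate
    intervals (the noise floor estimate).
    """
    x = np.asarray(x, dtype=np.float64)
    outside = np.ones(x.size, dtype=bool)
    for c in candidates:
        outside[c.start : c.end] = False
    if not outside.any():
        raise ValueError("no samples outside candidate intervals to estimate noise")
    noise_sd = x[outside].std()
    out = []
    for c in candidates:
        snr = float(x[c.peak_sample] / noise_sd) if noise_sd > 0 else np.inf
        accepted = snr >= snr_min and c.tent_correlation >= corr_min
        out.append(replace(c, snr=snr, accepted=bool(accepted)))
    return out


def select_best_channel(counts: dict[str, int]) -> str:
    """Channel with the most accepted blinks; ties go to the earlier entry of
    (Fp1, Fp2, AF7, AF8)."""
    if not counts:
        raise ValueError("no channels with blink counts")
    order = {ch: i for i, ch in enumerate(FRONTAL_CHANNELS)}
    return max(counts, key=lambda ch: (counts[ch], -order.get(ch, len(order))))


def detect_blinks_channel(
    x: np.ndarray, fs: float, cfg: BlinkConfig, channel: str = ""
) -> list[BlinkCandidate]:
    """bandpass -> candidates -> tent fit -> SNR/correlation acceptance."""
    y = blink_bandpass(x, fs, cfg.low_hz, cfg.high_hz)
    cands = candidate_intervals(y, fs, cfg.candidate_sd_factor, channel)
    min_len = max(int(round(cfg.min_candidate_ms * fs / 1000.0)), 5)
    cands = [c for c in cands if c.end - c.start >= min_len]
    if not cands:
        return []
    for c in cands:
        c.tent_correlation = fit_tent(y, c, fs, cfg.context_ms)
    return reject_low_snr(cands, y, cfg.snr_min, cfg.corr_min)


def blink_rate_per_block(
    recording: Recording, cfg: BlinkConfig | None = None
) -> list[BlockBlinkRate]:
    """Per-block blinks/min from the best frontal channel.

    Blocks shorter than 3 minutes are still computed but flagged unreliable
    (rates are conventionally averaged over intervals of at least 3-5 min).
    """
    cfg = cfg or BlinkConfig()
    present = [ch for ch in FRONTAL_CHANNELS if ch in recording.channel_labels]
    if not present:
        raise ValueError("no frontal channels (Fp1/Fp2/AF7/AF8) in recording")
    rates = []
    for block in range(1, 8):
        try:
            sub = slice_block(recording, block)
        except KeyError:
            continue
        counts: dict[str, int] = {}
        for ch in present:
            accepted = [
                c for c in detect_blinks_channel(sub.get_channel(ch), sub.fs, cfg, ch)
                if c.accepted
            ]
            counts[ch] = len(accepted)
        best = select_best_channel(counts)
        dur_min = sub.duration_s / 60.0
        rates.append(
            BlockBlinkRate(
                block=block,
                rate_per_min=counts[best] / dur_min,
                n_blinks=counts[best],
                channel_used=best,
                duration_min=dur_min,
                reliable=dur_min >= 3.0,
            )
        )
    return rates


def blink_rates_frame(rates: list[BlockBlinkRate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "block": [r.block for r in rates],
            "channel_used": [r.channel_used for r in rates],
            "n_blinks": [r.n_blinks for r in rates],
            "duration_min": [r.duration_min for r in rates],
            "rate_per_min": [r.rate_per_min for r in rates],
            "reliable": [r.reliable for r in rates],
        }
    )
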