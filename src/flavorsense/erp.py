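"""Swallow-locked ERP construction: filter, re-reference, epoch, reject, average.

EEG is bandpassed to 1-50 Hz, re-referenced (average reference by default),
and epoched from -2000 to +1999 ms around each swallow peak. Artifactual
epochs are rejected by two semi-automated criteria: improbable data (joint
log-probability of each epoch under the per-channel empirical amplitude
distribution) and abnormal kurtosis, each z-scored across epochs with local
(per-channel) and global exceedance thresholds. Accepted epochs are averaged
per condition.

Eye-artifact pruning by ICA is a pluggable external stage: a precomputed
mixing/unmixing pair plus an exclusion list can be applied after epoching,
but no decomposition is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

from .core import Recording

EPOCH_WINDOW_MS = (-2000.0, 2000.0)  # half-open: covers -2000 .. +1999 ms at 1 kHz


@dataclass
class EpochSet:
    """Epochs x channels x time tensor with labels and a rejection mask."""

    data: np.ndarray  # (n_epochs, n_channels, n_times), µV
    fs: float
    channel_labels: tuple[str, ...]
    times_ms: np.ndarray  # (n_times,)
    labels: pd.DataFrame  # per-epoch: participant, location, block, peak_sample
    rejected: np.ndarray = field(default=None)  # bool (n_epochs,)
    reasons: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[0], dtype=bool)
        if not self.reasons:
            self.reasons = [[] for _ in range(self.data.shape[0])]
        if len(self.rejected) != self.data.shape[0]:
            raise ValueError("mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def reject(self, mask: np.ndarray, reason: str) -> None:
        """Mark epochs rejected, appending the reason code."""
        for i in np.flatnonzero(mask):
            if not self.rejected[i]:
                self.rejected[i] = True
            self.reasons[i].append(reason)

    def accepted_data(self) -> np.ndarray:
        return self.data[~self.rejected]


@dataclass(frozen=True)
class ERP:
    """Condition-average waveform, channels x time."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    times_ms: np.ndarray
    n_epochs: int
    condition: dict

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("an ERP needs at least one epoch")


def eeg_bandpass(
    recording: Recording, low: float = 1.0, high: float = 50.0, order: int = 6
) -> Recording:
    """Zero-phase 1-50 Hz bandpass applied to EEG channels only.

    Order 6 keeps the forward-backward gain below 0.1 one fifth of an octave
    above the 50 Hz edge, so mains and stimulator harmonics do not leak into
    the epochs.
    """
    idx = recording.channels_with_role("EEG")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    data = recording.data.copy()
    if idx:
        data[idx] = sps.sosfiltfilt(sos, data[idx], axis=1)
    return Recording(
        data=data,
        fs=recording.fs,
        channel_labels=recording.channel_labels,
        channel_roles=recording.channel_roles,
        markers=recording.markers,
    )


def rereference(recording: Recording, scheme: str = "average") -> Recording:
    """Re-reference EEG channels.

    ``average``: subtract the per-sample mean over EEG channels (channel sum
    becomes zero at every sample). ``channel:<label>``: subtract that
    channel's signal.
    """
    idx = recording.channels_with_role("EEG")
    data = recording.data.copy()
    if scheme == "average":
        data[idx] -= data[idx].mean(axis=0, keepdims=True)
    elif scheme.startswith("channel:"):
        label = scheme.split(":", 1)[1]
        ref = recording.get_channel(label)  # KeyError if absent
        data[idx] -= ref[None, :]
    else:
        raise ValueError(f"unknown reference scheme {scheme!r}")
    return Recording(
        data=data,
        fs=recording.fs,
        channel_labels=recording.channel_labels,
        channel_roles=recording.channel_roles,
        markers=recording.markers,
    )


def epoch(
    recording: Recording,
    peak_samples: np.ndarray,
    labels: pd.DataFrame | None = None,
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
    channels: list[str] | None = None,
) -> EpochSet:
    """Cut peak-locked epochs over the half-open window ``[t0, t1) ms``.

    Peaks closer than the window half-width to either recording edge are
    dropped with reason ``edge``; their rows never enter the tensor but are
    counted in the retention bookkeeping via the returned labels.
    """
    fs = recording.fs
    pre = int(np.floor(window_ms[0] * fs / 1000.0))
    post = int(np.floor(window_ms[1] * fs / 1000.0))
    n_times = post - pre
    if channels is None:
        idx = recording.channels_with_role("EEG")
    else:
        idx = [recording.channel_index(c) for c in channels]
    chans = tuple(recording.channel_labels[i] for i in idx)
    times = (np.arange(pre, post) * 1000.0 / fs)

    peak_samples = np.asarray(peak_samples, dtype=int)
    keep, dropped = [], 0
    for p in peak_samples:
        if p + pre < 0 or p + post > recording.n_samples:
            dropped += 1
        else:
            keep.append(int(p))
    data = np.empty((len(keep), len(idx), n_times))
    for k, p in enumerate(keep):
        data[k] = recording.data[idx, p + pre : p + post]

    if labels is None:
        lab = pd.DataFrame({"peak_sample": keep})
    else:
        labels = labels.reset_index(drop=True)
        mask = [int(p) in set(keep) for p in peak_samples]
        lab = labels[mask].reset_index(drop=True)
        lab["peak_sample"] = keep
    es = EpochSet(
        data=data, fs=fs, channel_labels=chans, times_ms=times, labels=lab
    )
    es.n_dropped_edge = dropped
    return es


def _zscore_across_epochs(scores: np.ndarray) -> np.ndarray:
    """z-score per column (channel) across epochs; zero-variance -> zeros."""
    mu = scores.mean(axis=0, keepdims=True)
    sd = scores.std(axis=0, keepdims=True)
    out = np.zeros_like(scores)
    nz = sd[0] > 0
    out[:, nz] = (scores[:, nz] - mu[:, nz]) / sd[:, nz]
    return out


def _fd_bins(x: np.ndarray) -> np.ndarray:
    """Freedman-Diaconis bin edges (deterministic, scale-adaptive)."""
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        return np.linspace(x.min() - 1e-9, x.max() + 1e-9, 11)
    width = 2 * iqr / np.cbrt(x.size)
    n_bins = max(int(np.ceil((x.max() - x.min()) / width)), 10)
    return np.linspace(x.min(), x.max(), min(n_bins, 1000) + 1)


def joint_probability_scores(epochs: np.ndarray) -> np.ndarray:
    """Per epoch x channel: mean log-probability of the epoch's samples under
    the channel's empirical (histogram) amplitude distribution."""
    n_ep, n_ch, _ = epochs.shape
    scores = np.empty((n_ep, n_ch))
    for ch in range(n_ch):
        pooled = epochs[:, ch, :].ravel()
        edges = _fd_bins(pooled)
        hist, _ = np.histogram(pooled, bins=edges)
        p = hist / hist.sum()
        logp = np.log(np.clip(p, 1e-12, None))
        which = np.clip(np.digitize(epochs[:, ch, :], edges) - 1, 0, len(p) - 1)
        scores[:, ch] = logp[which].mean(axis=1)
    return scores


def joint_probability_reject(
    epochs: EpochSet, local_z: float = 5.0, global_z: float = 3.0, min_epochs: int = 10
) -> np.ndarray:
    """Reject improbable epochs.

    Each epoch's summed log-probability is z-scored across epochs per
    channel; an epoch is rejected when any channel's |z| exceeds ``local_z``
    or the channel-aggregate |z| exceeds ``global_z``. With fewer than
    ``min_epochs`` epochs the mask accepts everything.
    """
    if epochs.n_epochs < min_epochs:
        return np.zeros(epochs.n_epochs, dtype=bool)
    scores = joint_probability_scores(epochs.data)
    z = _zscore_across_epochs(scores)
    agg = _zscore_across_epochs(scores.mean(axis=1, keepdims=True))[:, 0]
    mask = (np.abs(z) > local_z).any(axis=1) | (np.abs(agg) > global_z)
    epochs.reject(mask, "jointprob")
    return mask


def kurtosis_reject(
    epochs: EpochSet, local_z: float = 5.0, global_z: float = 3.0, min_epochs: int = 10
) -> np.ndarray:
    """Reject epochs with abnormal excess kurtosis.

    Constant (zero-variance) epoch-channels have undefined kurtosis; such
    epochs are rejected with reason ``degenerate``.
    """
    if epochs.n_epochs < min_epochs:
        return np.zeros(epochs.n_epochs, dtype=bool)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # constant epochs trigger a precision warning; they are caught and
        # rejected as degenerate below
        warnings.simplefilter("ignore", RuntimeWarning)
        k = sstats.kurtosis(epochs.data, axis=2, fisher=True, bias=True)
    degenerate = ~np.isfinite(k) | (epochs.data.std(axis=2) == 0)
    deg_mask = degenerate.any(axis=1)
    k = np.where(np.isfinite(k), k, 0.0)
    z = _zscore_across_epochs(k)
    agg = _zscore_across_epochs(k.mean(axis=1, keepdims=True))[:, 0]
    mask = (np.abs(z) > local_z).any(axis=1) | (np.abs(agg) > global_z)
    epochs.reject(mask & ~deg_mask, "kurtosis")
    epochs.reject(deg_mask, "degenerate")
    return mask | deg_mask


def apply_ica_pruning(
    epochs: EpochSet, mixing: np.ndarray, unmixing: np.ndarray, exclude: list[int]
) -> EpochSet:
    """Apply a precomputed ICA decomposition, zeroing the excluded components.

    The decomposition itself (the unmixing matrix) must come from an external
    tool; this stage only projects it out, honoring the convention that
    pruning happens after epoching.
    """
    keep = np.ones(unmixing.shape[0], dtype=bool)
    keep[list(exclude)] = False
    proj = mixing[:, keep] @ unmixing[keep, :]
    epochs.data = np.einsum("ij,ejt->eit", proj, epochs.data)
    return epochs


def average_erp(epochs: EpochSet, by: list[str] | None = None) -> list[ERP]:
    """Arithmetic mean of accepted epochs, grouped by label columns."""
    acc = ~epochs.rejected
    if by:
        groups = epochs.labels[acc].groupby(by, sort=True).groups
        if not groups:
            raise ValueError(f"no accepted epochs for grouping {by}")
        out = []
        for key, rows in groups.items():
            sel = np.asarray(rows, dtype=int)
            if sel.size == 0:
                raise ValueError(f"empty group {key}")
            key_t = key if isinstance(key, tuple) else (key,)
            out.append(
                ERP(
                    data=epochs.data[sel].mean(axis=0),
                    fs=epochs.fs,
                    channel_labels=epochs.channel_labels,
                    times_ms=epochs.times_ms,
                    n_epochs=sel.size,
                    condition=dict(zip(by, key_t)),
                )
            )
        return out
    if not acc.any():
        raise ValueError("no accepted epochs to average")
    return [
        ERP(
            data=epochs.data[acc].mean(axis=0),
            fs=epochs.fs,
            channel_labels=epochs.channel_labels,
            times_ms=epochs.times_ms,
            n_epochs=int(acc.sum()),
            condition={},
        )
    ]


def save_epochs(epochs: EpochSet, path) -> None:
    """Store an EpochSet in an HDF5 container (/epochs group)."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("epochs")
        g.create_dataset("data", data=epochs.data)
        g.attrs["fs"] = float(epochs.fs)
        sdt = h5py.string_dtype(encoding="utf-8")
        g.create_dataset("channel_labels", data=np.array(epochs.channel_labels, dtype=sdt))
        g.create_dataset("times_ms", data=epochs.times_ms)
        g.create_dataset("rejected", data=epochs.rejected.astype(np.int8))
        g.create_dataset(
            "reasons",
            data=np.array([";".join(r) for r in epochs.reasons], dtype=sdt),
        )
        lab = f.create_group("labels")
        for col in epochs.labels.columns:
            vals = epochs.labels[col].to_numpy()
            if vals.dtype.kind in "OU":
                vals = np.array([str(v) for v in vals], dtype=sdt)
            lab.create_dataset(str(col), data=vals)


def load_epochs(path) -> EpochSet:
    """Read an EpochSet written by :func:`save_epochs`."""
    import h5py

    with h5py.File(path, "r") as f:
        g = f["epochs"]
        dec = lambda s: s.decode() if isinstance(s, bytes) else s
        labels = pd.DataFrame(
            {
                k: [dec(v) for v in ds[()]] if ds[()].dtype.kind in "OS" else ds[()]
                for k, ds in f["labels"].items()
            }
        )
        es = EpochSet(
            data=g["data"][()],
            fs=float(g.attrs["fs"]),
            channel_labels=tuple(dec(s) for s in g["channel_labels"][()]),
            times_ms=g["times_ms"][()],
            labels=labels,
            rejected=g["rejected"][()].astype(bool),
            reasons=[
                dec(s).split(";") if dec(s) else [] for s in g["reasons"][()]
            ],
        )
    return es


def retention_report(total: int, rejected_by_reason: dict[str, int]) -> pd.DataFrame:
    """Bookkeeping row: total, rejected per reason, retained, retained %.

    The retained percentage is rounded to one decimal (e.g. 4969 of 5837
    registered swallow trials -> 85.1).
    """
    rejected = sum(rejected_by_reason.values())
    retained = total - rejected
    row = {"total": total}
    row.update({f"rejected_{k}": v for k, v in sorted(rejected_by_reason.items())})
    row["retained"] = retained
    row["retained_pct"] = round(100.0 * retained / total, 1) if total else np.nan
    return pd.DataFrame([row])


def epochset_retention(epochs: EpochSet, n_dropped_edge: int = 0) -> pd.DataFrame:
    """Retention report for an EpochSet (edge-dropped peaks included)."""
    reasons: dict[str, int] = {}
    if n_dropped_edge or getattr(epochs, "n_dropped_edge", 0):
        reasons["edge"] = n_dropped_edge or epochs.n_dropped_edge
    for rl in epochs.reasons:
        if rl:
            reasons[rl[0]] = reasons.get(rl[0], 0) + 1
    total = epochs.n_epochs + reasons.get("edge", 0)
    return retention_report(total, reasons)
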