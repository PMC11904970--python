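"""Core domain types shared by every pipeline stage.

The common substrate is a :class:`Recording`: a channels x samples matrix in
microvolts with a sampling rate, per-channel labels and roles, and an ordered
marker table. Sessions follow a fixed seven-block timeline: five-minute rest
blocks and two ten-minute sipping blocks (#2 and #5), with auricular nerve
stimulation (tVNS) active during blocks #4-#6.

Conventions
-----------
* Sample indexing is 0-based; every interval is half-open ``[start, end)``.
* Times in the API are milliseconds relative to a named marker; conversion
  to samples rounds toward negative infinity (``floor``).
* Amplitudes are microvolts throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MARKER_LABELS = frozenset(
    {"block_start", "block_end", "sip_cue", "tvns_on", "tvns_off", "swallow_peak"}
)

LOCATIONS = ("sham", "C", "T", "CT")

#: Counterbalancing of stimulation location over the four sessions
#: (Williams design, balanced for first-order carryover).
WILLIAMS_ORDERS = (
    ("sham", "CT", "C", "T"),
    ("CT", "T", "sham", "C"),
    ("T", "C", "CT", "sham"),
    ("C", "sham", "T", "CT"),
)

CHANNEL_ROLES = frozenset({"EEG", "EMG", "REF", "GND"})

#: Frontal channels used for eye-blink detection, in tie-break precedence order.
FRONTAL_CHANNELS = ("Fp1", "Fp2", "AF7", "AF8")


def ms_to_samples(ms: float, fs: float) -> int:
    """Convert milliseconds to a sample index, rounding toward -inf."""
    return math.floor(ms * fs / 1000.0)


@dataclass(frozen=True)
class Marker:
    """A time-stamped event in a recording.

    ``sample`` is a 0-based index into the signal; ``block`` is the 1-7 block
    the marker belongs to, or ``None`` for markers outside the block timeline.
    """

    label: str
    sample: int
    block: int | None = None

    def __post_init__(self) -> None:
        if self.label not in MARKER_LABELS:
            raise ValueError(f"unknown marker label {self.label!r}")
        if self.sample < 0:
            raise ValueError(f"marker sample must be >= 0, got {self.sample}")
        if self.block is not None and not 1 <= self.block <= 7:
            raise ValueError(f"block must be in 1..7, got {self.block}")


@dataclass(frozen=True)
class SessionMeta:
    """Identity of one recording session of the four-location crossover."""

    participant_id: str
    location: str
    session_order: int

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}, got {self.location!r}")
        if not 1 <= self.session_order <= 4:
            raise ValueError(f"session_order must be in 1..4, got {self.session_order}")


@dataclass(frozen=True)
class BlockSpec:
    """One block of the seven-block session timeline."""

    index: int
    kind: str
    tvns_state: str
    nominal_duration: float

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 7:
            raise ValueError(f"block index must be in 1..7, got {self.index}")
        if self.kind not in ("rest", "sipping"):
            raise ValueError(f"kind must be rest|sipping, got {self.kind!r}")
        if self.tvns_state not in ("off", "on"):
            raise ValueError(f"tvns_state must be off|on, got {self.tvns_state!r}")
        if self.nominal_duration <= 0:
            raise ValueError("nominal_duration must be positive")


def default_block_specs(rest_s: float = 300.0, sipping_s: float = 600.0) -> tuple[BlockSpec, ...]:
    """The study timeline: blocks 2 and 5 are sipping, stimulation on in 4-6."""
    specs = []
    for i in range(1, 8):
        kind = "sipping" if i in (2, 5) else "rest"
        state = "on" if 4 <= i <= 6 else "off"
        dur = sipping_s if kind == "sipping" else rest_s
        specs.append(BlockSpec(index=i, kind=kind, tvns_state=state, nominal_duration=dur))
    return tuple(specs)


def validate_block_specs(specs: Sequence[BlockSpec]) -> None:
    if len(specs) != 7:
        raise ValueError(f"expected 7 block specs, got {len(specs)}")
    for i, s in enumerate(specs, start=1):
        if s.index != i:
            raise ValueError("block specs must be ordered 1..7")
        want_kind = "sipping" if i in (2, 5) else "rest"
        if s.kind != want_kind:
            raise ValueError(f"block {i} must be {want_kind}")
        want_state = "on" if 4 <= i <= 6 else "off"
        if s.tvns_state != want_state:
            raise ValueError(f"block {i} must have tvns_state={want_state}")


@dataclass
class Recording:
    """Multichannel signal (channels x samples, µV) plus markers.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz (the study recorded at 1000 Hz).
    channel_labels
        Ordered channel names, one per row of ``data``.
    channel_roles
        Per-channel role, each in ``{"EEG", "EMG", "REF", "GND"}``.
    markers
        Ordered event markers with 0-based sample indices.
    """

    data: np.ndarray
    fs: float = 1000.0
    channel_labels: tuple[str, ...] = ()
    channel_roles: tuple[str, ...] = ()
    markers: tuple[Marker, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_labels = tuple(self.channel_labels)
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError("one role per channel required")
        for r in self.channel_roles:
            if r not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {r!r}")
        self.markers = tuple(self.markers)
        n = self.n_samples
        for m in self.markers:
            if not 0 <= m.sample < n:
                raise ValueError(
                    f"marker {m.label!r} at sample {m.sample} outside [0, {n})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def channels_with_role(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == role]

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def markers_with_label(self, label: str) -> list[Marker]:
        return [m for m in self.markers if m.label == label]

    def markers_frame(self) -> pd.DataFrame:
        """Marker table as a DataFrame with columns label, sample, block."""
        return pd.DataFrame(
            {
                "label": [m.label for m in self.markers],
                "sample": [m.sample for m in self.markers],
                "block": [m.block if m.block is not None else -1 for m in self.markers],
            }
        )


def block_bounds(recording: Recording, block: int) -> tuple[int, int]:
    """Sample span ``[start, end)`` of one block from its boundary markers."""
    starts = [m for m in recording.markers if m.label == "block_start" and m.block == block]
    ends = [m for m in recording.markers if m.label == "block_end" and m.block == block]
    if not starts or not ends:
        raise KeyError(f"block {block} markers absent from recording")
    start, end = starts[0].sample, ends[0].sample
    if start >= end:
        raise ValueError(f"block {block} has non-positive span [{start}, {end})")
    return start, end


def slice_block(recording: Recording, block: int) -> Recording:
    """Extract one block as a sub-recording.

    Markers inside ``[start, end)`` are kept and re-indexed relative to the
    slice start; the interval is half-open, so a marker at the block-end
    sample is excluded.
    """
    start, end = block_bounds(recording, block)
    markers = tuple(
        replace(m, sample=m.sample - start)
        for m in recording.markers
        if start <= m.sample < end
    )
    return Recording(
        data=recording.data[:, start:end].copy(),
        fs=recording.fs,
        channel_labels=recording.channel_labels,
        channel_roles=recording.channel_roles,
        markers=markers,
    )


def export_markers_csv(recording: Recording, path) -> None:
    """Write the marker table as CSV with columns label, sample, block."""
    recording.markers_frame().to_csv(path, index=False)
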