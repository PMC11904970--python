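"""Readers and writers: HDF5 session container and BrainVision import.

The native on-disk format of the pipeline is a self-describing HDF5 container
with three groups::

    /signal   data (channels x samples, float64 µV), fs, labels, roles
    /markers  label, sample, block (block -1 where absent)
    /meta     participant_id, location, session_order

BrainVision (.vhdr/.vmrk/.eeg) is supported read-only, since that is what the
amplifier writes; the pipeline never emits it. Annotation descriptions are
mapped to the pipeline's marker vocabulary through a caller-supplied
dictionary because marker naming is site-specific.
"""

from __future__ import annotations

import os
from typing import Mapping

import h5py
import numpy as np

from .core import MARKER_LABELS, Marker, Recording, SessionMeta

_STR = h5py.string_dtype(encoding="utf-8")


def write_session(recording: Recording, meta: SessionMeta, path) -> None:
    """Write a recording and its session metadata to an HDF5 container.

    NaNs in the data are preserved verbatim. ``read_session`` restores data,
    fs, labels, roles and markers bit-exactly.
    """
    with h5py.File(path, "w") as f:
        sig = f.create_group("signal")
        sig.create_dataset("data", data=recording.data)
        sig.attrs["fs"] = float(recording.fs)
        sig.attrs["unit"] = "uV"
        sig.create_dataset("labels", data=np.array(recording.channel_labels, dtype=_STR))
        sig.create_dataset("roles", data=np.array(recording.channel_roles, dtype=_STR))

        mk = f.create_group("markers")
        mk.create_dataset(
            "label", data=np.array([m.label for m in recording.markers], dtype=_STR)
        )
        mk.create_dataset(
            "sample", data=np.array([m.sample for m in recording.markers], dtype=np.int64)
        )
        mk.create_dataset(
            "block",
            data=np.array(
                [m.block if m.block is not None else -1 for m in recording.markers],
                dtype=np.int64,
            ),
        )

        mt = f.create_group("meta")
        mt.attrs["participant_id"] = meta.participant_id
        mt.attrs["location"] = meta.location
        mt.attrs["session_order"] = int(meta.session_order)


def read_session(path) -> tuple[Recording, SessionMeta]:
    """Read a session container written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        sig = f["signal"]
        data = sig["data"][()]
        fs = float(sig.attrs["fs"])
        labels = tuple(s.decode() if isinstance(s, bytes) else s for s in sig["labels"][()])
        roles = tuple(s.decode() if isinstance(s, bytes) else s for s in sig["roles"][()])
        mk = f["markers"]
        mlabels = [s.decode() if isinstance(s, bytes) else s for s in mk["label"][()]]
        msamples = mk["sample"][()]
        mblocks = mk["block"][()]
        markers = tuple(
            Marker(label=l, sample=int(s), block=None if b < 0 else int(b))
            for l, s, b in zip(mlabels, msamples, mblocks)
        )
        mt = f["meta"]
        meta = SessionMeta(
            participant_id=str(mt.attrs["participant_id"]),
            location=str(mt.attrs["location"]),
            session_order=int(mt.attrs["session_order"]),
        )
    return (
        Recording(data=data, fs=fs, channel_labels=labels, channel_roles=roles, markers=markers),
        meta,
    )


def _parse_vmrk_markers(
    vmrk_path: str,
    marker_map: Mapping[str, str] | None,
    n_samples: int,
) -> tuple[Marker, ...]:
    """Extract the ``[Marker Infos]`` table of a .vmrk file.

    Each entry is ``Mk<N>=<Type>,<Description>,<Position>,<Size>,<Channel>``
    with Position a 1-based data-point index. Descriptions are mapped to the
    pipeline vocabulary; unmapped descriptions (``New Segment`` etc.) are
    dropped.
    """
    import configparser

    parser = configparser.ConfigParser(strict=False)
    parser.optionxform = str  # marker keys are case-sensitive
    with open(vmrk_path, encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    # strip the "Brain Vision Data Exchange Marker File" banner line(s)
    lines = [l for l in text.splitlines() if not l.startswith(("Brain Vision", ";"))]
    parser.read_string("\n".join(lines))
    if "Marker Infos" not in parser:
        return ()

    markers: list[Marker] = []
    for key, value in parser["Marker Infos"].items():
        if not key.startswith("Mk"):
            continue
        fields = value.split(",")
        if len(fields) < 3:
            continue
        desc = fields[1]
        block: int | None = None
        if marker_map is not None:
            if desc not in marker_map:
                continue
            label = marker_map[desc]
        else:
            core = desc.split("/")[-1]  # tolerate "Stimulus/..." style prefixes
            if ":" in core:
                label, _, blk = core.partition(":")
                block = int(blk)
            else:
                label = core
            if label not in MARKER_LABELS:
                continue
        sample = int(fields[2]) - 1  # .vmrk positions are 1-based
        if not 0 <= sample < n_samples:
            raise ValueError(
                f"marker {label!r} at sample {sample} outside [0, {n_samples})"
            )
        markers.append(Marker(label=label, sample=sample, block=block))

    markers.sort(key=lambda m: m.sample)
    return tuple(markers)


def read_brainvision(
    header_path,
    marker_map: Mapping[str, str] | None = None,
    emg_channels: tuple[str, ...] = (),
) -> Recording:
    """Read a BrainVision recording into a :class:`Recording`.

    Parameters
    ----------
    header_path
        Path to the ``.vhdr`` header; the companion ``.vmrk`` and binary data
        file must sit next to it.
    marker_map
        Maps annotation descriptions to the pipeline's marker labels
        (``block_start``, ``sip_cue``, ...). Descriptions not in the map are
        dropped. By default, descriptions that already match the pipeline
        vocabulary (optionally suffixed ``:<block>``) are taken as-is.
    emg_channels
        Channel labels to assign the EMG role; all other data channels are
        treated as EEG.
    """
    import mne

    header_path = os.fspath(header_path)
    if not os.path.exists(header_path):
        raise FileNotFoundError(f"header file not found: {header_path}")
    base = header_path[: -len(".vhdr")] if header_path.endswith(".vhdr") else header_path
    for ext in (".vmrk", ".eeg"):
        companion = base + ext
        if not os.path.exists(companion):
            raise FileNotFoundError(
                f"BrainVision companion file missing: {os.path.basename(companion)}"
            )

    try:
        raw = mne.io.read_raw_brainvision(header_path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - dialect-specific
        raise ValueError(f"unsupported BrainVision dialect: {exc}") from exc

    data_uv = raw.get_data() * 1e6  # mne loads volts
    fs = float(raw.info["sfreq"])
    labels = tuple(raw.ch_names)
    roles = tuple("EMG" if l in emg_channels else "EEG" for l in labels)

    # Marker positions come straight from the .vmrk table rather than from the
    # imported annotations: annotation onsets are float seconds (lossy at odd
    # rates) and out-of-range entries are silently dropped on import, whereas
    # the contract here is an explicit range error.
    markers = _parse_vmrk_markers(base + ".vmrk", marker_map, n_samples=data_uv.shape[1])
    return Recording(
        data=data_uv, fs=fs, channel_labels=labels, channel_roles=roles, markers=tuple(markers)
    )
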