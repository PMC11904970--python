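"""Shared fixtures: small recordings and reduced-scale simulated sessions."""

from __future__ import annotations

import numpy as np
import pytest

from flavorsense.core import Marker, Recording, SessionMeta
from flavorsense.simulate import SimConfig, simulate_session


@pytest.fixture
def tiny_recording() -> Recording:
    """Two channels, 10 000 samples, one block-like marker pair."""
    rng = np.random.default_rng(0)
    markers = (
        Marker("block_start", 1000, 1),
        Marker("sip_cue", 1000, 1),
        Marker("sip_cue", 2500, 1),
        Marker("block_end", 4000, 1),
    )
    return Recording(
        data=rng.standard_normal((2, 10_000)),
        fs=1000.0,
        channel_labels=("Cz", "EMGsub1"),
        channel_roles=("EEG", "EMG"),
        markers=markers,
    )


@pytest.fixture(scope="session")
def small_session():
    """Full 7-block timeline at reduced rate/channels; session-scoped because
    simulation dominates test runtime."""
    cfg = SimConfig(seed=42, n_eeg_channels=4, fs=250)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def emg_session():
    """Full-rate session for the swallow detector (needs the 25-400 Hz band)."""
    cfg = SimConfig(seed=11, n_eeg_channels=4, fs=1000)
    return simulate_session(cfg)


def write_brainvision_fixture(
    directory,
    data_uv: np.ndarray,
    fs: float,
    labels: list[str],
    markers: list[tuple[str, int]],
    stem: str = "fixture",
):
    """Write a minimal multiplexed IEEE_FLOAT_32 BrainVision trio.

    Marker positions are written 1-based, as the format specifies.
    """
    directory = str(directory)
    n_ch, n_samp = data_uv.shape
    with open(f"{directory}/{stem}.vhdr", "w") as f:
        f.write("Brain Vision Data Exchange Header File Version 1.0\n")
        f.write("[Common Infos]\n")
        f.write(f"DataFile={stem}.eeg\nMarkerFile={stem}.vmrk\n")
        f.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        f.write(f"NumberOfChannels={n_ch}\n")
        f.write(f"SamplingInterval={1e6 / fs:.0f}\n")
        f.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n")
        f.write("[Channel Infos]\n")
        for i, lab in enumerate(labels, 1):
            f.write(f"Ch{i}={lab},,1,µV\n")
    with open(f"{directory}/{stem}.vmrk", "w") as f:
        f.write("Brain Vision Data Exchange Marker File, Version 1.0\n")
        f.write("[Common Infos]\n")
        f.write(f"DataFile={stem}.eeg\n")
        f.write("[Marker Infos]\n")
        f.write("Mk1=New Segment,,1,1,0,00000000000000000000\n")
        for k, (desc, sample) in enumerate(markers, 2):
            f.write(f"Mk{k}=Stimulus,{desc},{sample + 1},1,0\n")
    data_uv.astype("<f4").T.tofile(f"{directory}/{stem}.eeg")
    return f"{directory}/{stem}.vhdr"
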