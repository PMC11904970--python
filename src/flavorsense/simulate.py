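"""Seeded synthetic sessions with the recording structure the analysis assumes.

A simulated session reproduces the seven-block timeline of the study design:
five-minute rest blocks and two ten-minute sipping blocks (#2 and #5), with
auricular stimulation active during blocks #4-#6 on a 30 s on / 30 s off duty
cycle. Each sipping block carries 10 cue cycles of five sip cues; cue cycles
occupy the *off* half-cycles of the duty cycle so that no cue ever falls
inside an on period (antisynchronization), and the same placement is used in
the unstimulated sipping block for symmetry.

Signals are built additively:

* EEG channels: 1/f (pink) background noise, blink "tents" on the frontal
  channels, a swallow-locked potential template at every injected swallow
  peak, and a 25 Hz biphasic pulse-train artifact during on half-cycles.
* EMG channels: white background noise plus amplitude-modulated broadband
  bursts, one per cue (truncated-normal latency) plus Poisson spontaneous
  bursts, injected with opposite polarity on the two submental electrodes so
  the bipolar montage recovers the full burst.

Every injected event is exported as ground truth, which is what makes each
downstream detector testable without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    FRONTAL_CHANNELS,
    LOCATIONS,
    WILLIAMS_ORDERS,
    BlockSpec,
    Marker,
    Recording,
    SessionMeta,
    default_block_specs,
    validate_block_specs,
)

# 64-channel cap montage (10-20 extension); frontal blink channels first so
# reduced-channel simulations keep them.
EEG_CHANNEL_NAMES: tuple[str, ...] = (
    "Fp1", "Fp2", "AF7", "AF8", "AF3", "AF4", "Fz", "F1", "F2", "F3", "F4",
    "F5", "F6", "F7", "F8", "FC1", "FC2", "FC3", "FC4", "FC5", "FC6", "FT7",
    "FT8", "Cz", "C1", "C2", "C3", "C4", "C5", "C6", "T7", "T8", "CP1",
    "CP2", "CP3", "CP4", "CP5", "CP6", "TP7", "TP8", "Pz", "P1", "P2", "P3",
    "P4", "P5", "P6", "P7", "P8", "PO3", "PO4", "PO7", "PO8", "POz", "Oz",
    "O1", "O2", "AFz", "F9", "CPz", "TP9", "TP10", "PO9", "PO10",
)

EMG_CHANNEL_NAMES: tuple[str, ...] = ("EMGsub1", "EMGsub2")


@dataclass(frozen=True)
class TvnsConfig:
    """Stimulator settings: 25 Hz biphasic pulses, 30 s on / 30 s off."""

    pulse_rate_hz: float = 25.0
    pulse_width_us: float = 250.0
    duty_on_s: float = 30.0
    duty_off_s: float = 30.0
    artifact_amplitude_uv: float = 20.0


@dataclass(frozen=True)
class CueScheduleConfig:
    cycles_per_sipping_block: int = 10
    sips_per_cycle: int = 5
    cycle_length_s: float = 30.0
    jitter_s: float = 0.0


@dataclass(frozen=True)
class SwallowModelConfig:
    """Cued swallows follow each cue with truncated-normal latency."""

    cued_latency_mean_ms: float = 1000.0
    cued_latency_sd_ms: float = 300.0
    spontaneous_rate_per_min: float = 1.0
    burst_duration_ms: float = 800.0
    burst_amplitude_uv: float = 30.0


@dataclass(frozen=True)
class ErpModelConfig:
    """Swallow-locked potential: topography x raised-cosine time course."""

    peak_latency_ms: float = 500.0
    duration_ms: float = 200.0
    amplitude_uv: float = 5.0
    #: per-(location, block) amplitude scaling; "*" wildcards allowed
    condition_scaling: Mapping[tuple[str, object], float] = field(default_factory=dict)


@dataclass(frozen=True)
class BlinkModelConfig:
    """Blink rate per block (blinks/min) and the tent waveform."""

    rate_per_block: tuple[float, ...] = (15.0, 20.0, 15.0, 15.0, 20.0, 15.0, 15.0)
    tent_duration_ms: float = 300.0
    amplitude_uv: float = 150.0
    #: relative blink amplitude on the four frontal channels
    channel_gains: tuple[float, ...] = (1.0, 0.95, 0.7, 0.65)


@dataclass(frozen=True)
class NoiseConfig:
    pink_exponent: float = 1.0
    eeg_sd_uv: float = 10.0
    emg_sd_uv: float = 2.0


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_eeg_channels: int = 64
    fs: float = 1000.0
    block_specs: tuple[BlockSpec, ...] = field(default_factory=default_block_specs)
    tvns: TvnsConfig = field(default_factory=TvnsConfig)
    cues: CueScheduleConfig = field(default_factory=CueScheduleConfig)
    swallow: SwallowModelConfig = field(default_factory=SwallowModelConfig)
    erp: ErpModelConfig = field(default_factory=ErpModelConfig)
    blink: BlinkModelConfig = field(default_factory=BlinkModelConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        validate_block_specs(self.block_specs)
        if not 4 <= self.n_eeg_channels <= len(EEG_CHANNEL_NAMES):
            raise ValueError(
                f"n_eeg_channels must be in 4..{len(EEG_CHANNEL_NAMES)} "
                "(the four frontal blink channels are mandatory)"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.blink.rate_per_block) != 7:
            raise ValueError("blink rate_per_block must have 7 entries")


@dataclass
class GroundTruth:
    """Everything injected into a simulated session.

    ``swallows``: sample, class, block, cue_sample, amplitude_uv, auc_uv_ms.
    ``blinks``: sample, channel, block.
    ``erp_events``: sample, block, amplitude_uv.
    ``cues``: sample, block.
    """

    swallows: pd.DataFrame
    blinks: pd.DataFrame
    erp_events: pd.DataFrame
    cues: pd.DataFrame


def block_offsets(config: SimConfig) -> list[tuple[int, int]]:
    """Sample span [start, end) of each block, concatenated without gaps."""
    spans = []
    cursor = 0
    for spec in config.block_specs:
        n = int(round(spec.nominal_duration * config.fs))
        spans.append((cursor, cursor + n))
        cursor += n
    return spans


def _duty_on(config: SimConfig, block: BlockSpec, t_in_block_s: float) -> bool:
    """Whether the stimulator is in an on half-cycle at a block-relative time."""
    if block.tvns_state != "on":
        return False
    period = config.tvns.duty_on_s + config.tvns.duty_off_s
    return (t_in_block_s % period) < config.tvns.duty_on_s


def make_cue_schedule(config: SimConfig) -> tuple[Marker, ...]:
    """Sip-cue markers for both sipping blocks.

    Cue cycles occupy the off half-cycles of the 30 s on / 30 s off duty
    cycle (offsets 30-60 s, 90-120 s, ... from block start), so 10 cycles
    tile a 600 s sipping block and no cue can coincide with stimulation in
    the tVNS-on block. Within a cycle the cues are evenly spaced with a
    half-step margin: offsets (j + 1/2) * cycle_length / sips_per_cycle.
    """
    cc = config.cues
    period = config.tvns.duty_on_s + config.tvns.duty_off_s
    markers: list[Marker] = []
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0E]))
    for (start, end), spec in zip(block_offsets(config), config.block_specs):
        if spec.kind != "sipping":
            continue
        needed = cc.cycles_per_sipping_block * period
        if needed > spec.nominal_duration + 1e-9:
            raise ValueError(
                f"{cc.cycles_per_sipping_block} cue cycles need {needed:.0f} s "
                f"but block {spec.index} lasts {spec.nominal_duration:.0f} s"
            )
        for c in range(cc.cycles_per_sipping_block):
            window_start_s = c * period + config.tvns.duty_on_s
            for j in range(cc.sips_per_cycle):
                offset_s = (j + 0.5) * cc.cycle_length_s / cc.sips_per_cycle
                if cc.jitter_s > 0:
                    offset_s += rng.uniform(-cc.jitter_s, cc.jitter_s)
                t_s = window_start_s + offset_s
                sample = start + int(np.floor(t_s * config.fs))
                if not start <= sample < end:
                    raise ValueError("cue jitter pushed a cue outside its block")
                markers.append(Marker(label="sip_cue", sample=sample, block=spec.index))
    return tuple(markers)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, sd: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping, normalised to the target SD."""
    from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

    m = next_fast_len(n)  # awkward lengths make the FFT quadratic-ish
    white = rng.standard_normal(m)
    spec = rfft(white)
    freqs = rfftfreq(m)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    x = irfft(spec * scale, m)[:n]
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _raised_cosine(n: int) -> np.ndarray:
    """Tent prototype: 0.5 * (1 - cos(2*pi*t/D)), peak 1 at the midpoint."""
    t = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / n))


def _add_at(signal: np.ndarray, start: int, waveform: np.ndarray) -> None:
    """Add a waveform to a 1-D signal, clipping at the edges."""
    lo = max(start, 0)
    hi = min(start + len(waveform), len(signal))
    if hi > lo:
        signal[lo:hi] += waveform[lo - start : hi - start]


def _condition_scale(
    scaling: Mapping[tuple[str, object], float], location: str, block: int
) -> float:
    for key in ((location, block), (location, "*"), ("*", block), ("*", "*")):
        if key in scaling:
            return float(scaling[key])
    return 1.0


def simulate_session(
    config: SimConfig,
    meta: SessionMeta | None = None,
) -> tuple[Recording, SessionMeta, GroundTruth]:
    """Render one synthetic session. Deterministic given ``config.seed``."""
    if meta is None:
        meta = SessionMeta(participant_id="sim01", location="sham", session_order=1)
    fs = config.fs
    spans = block_offsets(config)
    # one padding sample so the final block_end marker (= end of block 7,
    # half-open) is itself a valid sample index
    n_total = spans[-1][1] + 1
    n_eeg = config.n_eeg_channels
    n_ch = n_eeg + 2

    labels = EEG_CHANNEL_NAMES[:n_eeg] + EMG_CHANNEL_NAMES
    roles = ("EEG",) * n_eeg + ("EMG",) * 2

    ss = np.random.SeedSequence([config.seed, 0x5E55])
    rng_noise, rng_blink, rng_swallow = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    data = np.empty((n_ch, n_total), dtype=np.float64)
    for ch in range(n_eeg):
        data[ch] = _pink_noise(
            rng_noise, n_total, config.noise.pink_exponent, config.noise.eeg_sd_uv
        )
    for ch in range(n_eeg, n_ch):
        data[ch] = rng_noise.standard_normal(n_total) * config.noise.emg_sd_uv

    markers: list[Marker] = []
    for (start, end), spec in zip(spans, config.block_specs):
        markers.append(Marker("block_start", start, spec.index))
        markers.append(Marker("block_end", end, spec.index))

    cue_markers = make_cue_schedule(config)
    markers.extend(cue_markers)
    cues_df = pd.DataFrame(
        {"sample": [m.sample for m in cue_markers], "block": [m.block for m in cue_markers]}
    )

    # --- stimulation duty-cycle markers and pulse-train artifact ------------
    period_s = config.tvns.duty_on_s + config.tvns.duty_off_s
    for (start, end), spec in zip(spans, config.block_specs):
        if spec.tvns_state != "on":
            continue
        n_cycles = int(np.ceil((end - start) / fs / period_s))
        for c in range(n_cycles):
            on_s = start + int(round(c * period_s * fs))
            off_s = start + int(round((c * period_s + config.tvns.duty_on_s) * fs))
            if on_s < end:
                markers.append(Marker("tvns_on", on_s, spec.index))
            if off_s < end:
                markers.append(Marker("tvns_off", off_s, spec.index))
            # biphasic pulses at pulse_rate during the on half-cycle
            amp = config.tvns.artifact_amplitude_uv
            if amp > 0:
                step = fs / config.tvns.pulse_rate_hz
                n_pulses = int(config.tvns.duty_on_s * config.tvns.pulse_rate_hz)
                pulse_starts = on_s + np.round(np.arange(n_pulses) * step).astype(int)
                pulse_starts = pulse_starts[(pulse_starts + 1 < min(off_s, end))]
                # 250 µs biphasic pulse is under-resolved at 1 kHz: render as
                # a +/- sample pair so only duty-cycle timing is meaningful
                data[:n_eeg, pulse_starts] += amp
                data[:n_eeg, pulse_starts + 1] -= amp

    # --- blinks -------------------------------------------------------------
    tent_n = max(int(round(config.blink.tent_duration_ms * fs / 1000.0)), 3)
    tent = _raised_cosine(tent_n)
    frontal_idx = [labels.index(ch) for ch in FRONTAL_CHANNELS]
    blink_rows: list[dict] = []
    for (start, end), spec in zip(spans, config.block_specs):
        rate = config.blink.rate_per_block[spec.index - 1]
        dur_min = (end - start) / fs / 60.0
        n_blinks = rng_blink.poisson(rate * dur_min)
        if n_blinks == 0:
            continue
        peaks = np.sort(
            rng_blink.integers(start + tent_n, end - tent_n, size=n_blinks)
        )
        for p in peaks:
            gain_jitter = rng_blink.lognormal(mean=0.0, sigma=0.15)
            for idx, g in zip(frontal_idx, config.blink.channel_gains):
                _add_at(
                    data[idx],
                    int(p) - tent_n // 2,
                    tent * config.blink.amplitude_uv * g * gain_jitter,
                )
            blink_rows.append(
                {"sample": int(p), "channel": "Fp1", "block": spec.index}
            )

    # --- swallows (EMG bursts) ----------------------------------------------
    sw = config.swallow
    burst_n = max(int(round(sw.burst_duration_ms * fs / 1000.0)), 5)
    burst_env = _raised_cosine(burst_n)
    emg1, emg2 = n_eeg, n_eeg + 1
    swallow_rows: list[dict] = []

    def inject_burst(peak_sample: int, block: int, cue_sample: int | None) -> None:
        carrier = rng_swallow.standard_normal(burst_n)
        # normalise so the rectified-envelope peak is ~burst_amplitude
        carrier /= max(np.abs(carrier).mean() * 1.2533, 1e-12)  # E|N(0,1)| = sqrt(2/pi)
        wave = burst_env * carrier * sw.burst_amplitude_uv
        start = peak_sample - burst_n // 2
        _add_at(data[emg1], start, 0.5 * wave)
        _add_at(data[emg2], start, -0.5 * wave)
        env_uv = burst_env * sw.burst_amplitude_uv
        auc = float(np.trapezoid(env_uv)) * 1000.0 / fs  # µV·ms
        swallow_rows.append(
            {
                "sample": int(peak_sample),
                "class": "cued" if cue_sample is not None else "spontaneous",
                "block": block,
                "cue_sample": -1 if cue_sample is None else int(cue_sample),
                "amplitude_uv": sw.burst_amplitude_uv,
                "auc_uv_ms": auc,
            }
        )

    for m in cue_markers:
        while True:
            lat_ms = rng_swallow.normal(sw.cued_latency_mean_ms, sw.cued_latency_sd_ms)
            if 0.0 <= lat_ms < 4000.0:
                break
        peak = m.sample + int(np.floor(lat_ms * fs / 1000.0))
        inject_burst(peak, m.block, m.sample)

    occupied = np.array(sorted(r["sample"] for r in swallow_rows), dtype=int)
    rate_hz = sw.spontaneous_rate_per_min / 60.0
    n_spont = rng_swallow.poisson(rate_hz * n_total / fs)
    cand = np.sort(rng_swallow.integers(burst_n, n_total - burst_n, size=n_spont))
    for p in cand:
        if occupied.size and np.min(np.abs(occupied - p)) < 2 * burst_n:
            continue  # avoid overlapping an existing burst
        block = next(
            spec.index
            for (start, end), spec in zip(spans, config.block_specs)
            if start <= p < end
        )
        inject_burst(int(p), block, None)
        occupied = np.append(occupied, p)

    # --- swallow-locked potential -------------------------------------------
    erp = config.erp
    erp_rows: list[dict] = []
    if erp.amplitude_uv != 0 and swallow_rows:
        erp_n = max(int(round(erp.duration_ms * fs / 1000.0)), 3)
        course = _raised_cosine(erp_n)
        # smooth dipole-like topography over the cap, strongest mid-list
        chan_pos = np.linspace(-1.0, 1.0, n_eeg)
        topo = np.exp(-((chan_pos - 0.2) ** 2) / 0.5)
        for row in swallow_rows:
            amp = erp.amplitude_uv * _condition_scale(
                erp.condition_scaling, meta.location, row["block"]
            )
            onset = row["sample"] + int(
                np.floor((erp.peak_latency_ms - erp.duration_ms / 2.0) * fs / 1000.0)
            )
            wave = course * amp
            lo = max(onset, 0)
            hi = min(onset + erp_n, n_total)
            if hi > lo:
                data[:n_eeg, lo:hi] += topo[:, None] * wave[lo - onset : hi - onset]
            erp_rows.append(
                {"sample": row["sample"], "block": row["block"], "amplitude_uv": amp}
            )

    markers.sort(key=lambda m: (m.sample, m.label))
    recording = Recording(
        data=data, fs=fs, channel_labels=labels, channel_roles=roles, markers=tuple(markers)
    )
    truth = GroundTruth(
        swallows=pd.DataFrame(
            swallow_rows,
            columns=["sample", "class", "block", "cue_sample", "amplitude_uv", "auc_uv_ms"],
        ).sort_values("sample", ignore_index=True),
        blinks=pd.DataFrame(blink_rows, columns=["sample", "channel", "block"]),
        erp_events=pd.DataFrame(erp_rows, columns=["sample", "block", "amplitude_uv"]),
        cues=cues_df,
    )
    return recording, meta, truth


EffectMap = Mapping[str, Mapping[tuple[str, object], float]]


def simulate_cohort(
    config: SimConfig,
    n_participants: int,
    locations: Sequence[str] = LOCATIONS,
    effect_map: EffectMap | None = None,
    participant_sd: Mapping[str, float] | None = None,
) -> Iterator[tuple[Recording, SessionMeta, GroundTruth]]:
    """Yield one session per participant x location, lazily.

    Session order is counterbalanced with the four Williams orders, assigned
    round-robin so each order is used ``floor(n/4)`` or ``ceil(n/4)`` times.
    Per-participant random effects (multiplicative, lognormal) perturb blink
    rate and burst amplitude; ``effect_map`` injects condition effects, e.g.
    ``{"blink_rate": {("*", 2): 2.0}}`` doubles the blink rate in block 2.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    for loc in locations:
        if loc not in LOCATIONS:
            raise ValueError(f"unknown location {loc!r}")
    effect_map = effect_map or {}
    sd = {"blink_rate": 0.1, "burst_amplitude": 0.1}
    if participant_sd:
        sd.update(participant_sd)

    for p in range(n_participants):
        order = WILLIAMS_ORDERS[p % len(WILLIAMS_ORDERS)]
        p_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFACE, p]))
        blink_re = p_rng.lognormal(0.0, sd["blink_rate"])
        amp_re = p_rng.lognormal(0.0, sd["burst_amplitude"])
        for s_idx, loc in enumerate(order, start=1):
            if loc not in locations:
                continue
            session_seed = int(
                np.random.SeedSequence([config.seed, p, s_idx]).generate_state(1)[0]
                % (2**31)
            )
            blink_scales = tuple(
                config.blink.rate_per_block[b - 1]
                * blink_re
                * _condition_scale(effect_map.get("blink_rate", {}), loc, b)
                for b in range(1, 8)
            )
            burst_amp = (
                config.swallow.burst_amplitude_uv
                * amp_re
                * _condition_scale(effect_map.get("burst_amplitude", {}), loc, "*")
            )
            erp_amp = config.erp.amplitude_uv * _condition_scale(
                effect_map.get("erp_amplitude", {}), loc, "*"
            )
            session_cfg = replace(
                config,
                seed=session_seed,
                blink=replace(config.blink, rate_per_block=blink_scales),
                swallow=replace(config.swallow, burst_amplitude_uv=burst_amp),
                erp=replace(config.erp, amplitude_uv=erp_amp),
            )
            meta = SessionMeta(
                participant_id=f"sim{p + 1:02d}", location=loc, session_order=s_idx
            )
            yield simulate_session(session_cfg, meta=meta)
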