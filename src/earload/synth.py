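"""Synthetic task-EEG generator.

Produces event schedules for an N-back working-memory task and a mental
arithmetic task, and continuous multi-channel EEG realizing configurable
condition effects: per-band power scaling by difficulty level, P100/P300
event-related potentials with system-dependent amplitude, eye-blink
transients with a fixed spatial pattern, 1/f background activity and
intermittent sinusoidal line noise.

The generator exists so that every downstream stage (preprocessing,
spectral/temporal features, permutation statistics, classification) can be
validated against known ground truth. The signal model is deliberately
simple — independent narrowband Gaussian oscillators per channel, no
volume conduction or cortical geometry — which is sufficient for the
band-power and ERP effects the analysis targets.

Default designs: the N-back task runs 4 sessions of 6 two-minute blocks
(48 letter stimuli per block, 500 ms on screen, 2000 ms inter-stimulus
interval, 16 of 48 targets); the arithmetic task runs 2 sessions of 15
one-minute blocks, 5 difficulty levels given 3 times per session. In both
tasks each level appears once before any level repeats and no level occurs
twice in a row; a 20 s rest follows each block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import fft as sfft

from .containers import (
    Channel,
    EventStream,
    Montage,
    Recording,
    STIMULUS_KINDS,
)

__all__ = [
    "TaskDesign",
    "EffectProfile",
    "DesignError",
    "make_nback_schedule",
    "make_arithmetic_schedule",
    "synthesize_recording",
    "default_montage",
    "CHANNEL_SUBSETS",
    "CANONICAL_BANDS",
    "Montage",
    "Channel",
    "EventStream",
]


class DesignError(ValueError):
    """Raised when a task design cannot be scheduled."""


# canonical neural-oscillation bands (Hz): delta through high gamma
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta1": (13.0, 19.0),
    "beta2": (20.0, 30.0),
    "gamma1": (30.0, 50.0),
    "gamma2": (50.0, 100.0),
}

# 12-channel subsets used for statistics and classification, plus the
# two-channel in-ear vs occipital comparison sets
CHANNEL_SUBSETS: dict[str, list[str]] = {
    "cap12": ["Cz", "Fz", "Pz", "Fpz", "O2", "O1", "F4", "C4", "P4", "P3", "C3", "F3"],
    "ear12": ["L1", "L2", "L3", "L6", "L7", "R1", "R2", "R3", "R6", "R7", "E1", "E2"],
    "cap2": ["O1", "O2"],
    "ear2": ["E1", "E2"],
}

# small onset offsets keeping event onsets strictly increasing where task
# timing would otherwise produce ties (block_start vs first stimulus,
# block_end vs rest onset)
_STIM_LEAD = 0.01
_REST_LAG = 0.001


@dataclass(frozen=True)
class TaskDesign:
    """Parameters of one task schedule; see module docstring for defaults."""

    task_id: str  # "nback" | "arithmetic"
    n_sessions: int
    blocks_per_session: int
    block_duration: float  # s
    levels: tuple
    repeats_per_session: int
    stimulus_duration: float = 0.0  # s, nback only
    isi: float = 0.0  # s, nback only
    stimuli_per_block: int = 0  # nback only
    target_fraction: float = 0.0  # nback only
    rest_duration: float = 20.0  # s

    def __post_init__(self) -> None:
        if self.task_id not in ("nback", "arithmetic"):
            raise DesignError(f"unknown task_id {self.task_id!r}")
        if self.repeats_per_session * len(self.levels) != self.blocks_per_session:
            raise DesignError(
                "repeats_per_session x n_levels must equal blocks_per_session "
                f"({self.repeats_per_session} x {len(self.levels)} != "
                f"{self.blocks_per_session})"
            )
        if len(set(self.levels)) != len(self.levels):
            raise DesignError("levels must be unique")
        if len(self.levels) < 2:
            raise DesignError("need at least two levels for the no-repeat constraint")
        if self.task_id == "nback":
            needed = self.stimuli_per_block * (self.stimulus_duration + self.isi)
            if needed > self.block_duration + 1e-9:
                raise DesignError(
                    f"stimuli need {needed:.1f}s but block lasts "
                    f"{self.block_duration:.1f}s"
                )
            if not (0.0 <= self.target_fraction <= 1.0):
                raise DesignError("target_fraction must be in [0, 1]")

    @property
    def n_targets_per_block(self) -> int:
        return int(round(self.target_fraction * self.stimuli_per_block))

    @classmethod
    def nback_default(cls) -> "TaskDesign":
        return cls(
            task_id="nback",
            n_sessions=4,
            blocks_per_session=6,
            block_duration=120.0,
            levels=(0, 1, 2),
            repeats_per_session=2,
            stimulus_duration=0.5,
            isi=2.0,
            stimuli_per_block=48,
            target_fraction=0.33,
            rest_duration=20.0,
        )

    @classmethod
    def arithmetic_default(cls) -> "TaskDesign":
        return cls(
            task_id="arithmetic",
            n_sessions=2,
            blocks_per_session=15,
            block_duration=60.0,
            levels=(1, 2, 3, 4, 5),
            repeats_per_session=3,
            rest_duration=20.0,
        )


def _session_level_order(design: TaskDesign, rng: np.random.Generator) -> list:
    """Level order for one session: a concatenation of rounds, each a
    permutation of the level set (so every level appears once before any
    repeats), with no level twice in a row across round boundaries.
    Rejection sampling with bounded retries."""
    levels = list(design.levels)
    for _ in range(1000):
        order: list = []
        ok = True
        for _ in range(design.repeats_per_session):
            perm = list(rng.permutation(len(levels)))
            round_levels = [levels[i] for i in perm]
            if order and round_levels[0] == order[-1]:
                ok = False
                break
            order.extend(round_levels)
        if ok:
            return order
    raise DesignError("could not sample a level order satisfying constraints")


def _block_timeline(design: TaskDesign, rng: np.random.Generator):
    """Yield (session, block, level, start_s) with rests between blocks and
    a rest-length gap between sessions. A short pre-roll before the first
    block keeps pre-stimulus epoch windows inside the recording."""
    t = 5.0
    for s in range(1, design.n_sessions + 1):
        order = _session_level_order(design, rng)
        for b, level in enumerate(order, start=1):
            yield s, b, level, t
            t += design.block_duration + design.rest_duration
        t += design.rest_duration  # inter-session gap


def make_nback_schedule(design: TaskDesign, seed: int) -> EventStream:
    """Generate the full N-back event stream.

    Per block: exactly ``stimuli_per_block`` stimulus events at the fixed
    stimulus-onset asynchrony, of which exactly
    ``round(target_fraction * stimuli_per_block)`` are targets.
    Deterministic for a fixed seed.
    """
    if design.task_id != "nback":
        raise DesignError("make_nback_schedule requires an nback design")
    rng = np.random.default_rng(seed)
    soa = design.stimulus_duration + design.isi
    rows = []
    for s, b, level, t0 in _block_timeline(design, rng):
        t1 = t0 + design.block_duration
        rows.append((t0, 0.0, s, b, level, "block_start"))
        targets = set(
            rng.choice(design.stimuli_per_block, design.n_targets_per_block, replace=False)
        )
        for i in range(design.stimuli_per_block):
            kind = "stimulus_target" if i in targets else "stimulus_nontarget"
            rows.append((t0 + _STIM_LEAD + i * soa, design.stimulus_duration, s, b, level, kind))
        rows.append((t1, 0.0, s, b, level, "block_end"))
        rows.append((t1 + _REST_LAG, design.rest_duration, s, b, level, "rest"))
    frame = pd.DataFrame(rows, columns=["onset_s", "duration_s", "session", "block", "level", "kind"])
    return EventStream(frame)


def make_arithmetic_schedule(design: TaskDesign, seed: int) -> EventStream:
    """Generate the arithmetic event stream: block_start/block_end events
    delimiting each block (problem presentations are self-paced and not
    modeled), with rests between blocks."""
    if design.task_id != "arithmetic":
        raise DesignError("make_arithmetic_schedule requires an arithmetic design")
    rng = np.random.default_rng(seed)
    rows = []
    for s, b, level, t0 in _block_timeline(design, rng):
        t1 = t0 + design.block_duration
        rows.append((t0, 0.0, s, b, level, "block_start"))
        rows.append((t1, 0.0, s, b, level, "block_end"))
        rows.append((t1 + _REST_LAG, design.rest_duration, s, b, level, "rest"))
    frame = pd.DataFrame(rows, columns=["onset_s", "duration_s", "session", "block", "level", "kind"])
    return EventStream(frame)


def default_montage(sampling_rate: float = 500.0) -> Montage:
    """Concurrent cap + ear montage: 12 scalp channels (10-20 names), two
    sub-ocular EOG channels, 10 around-ear cEEGrid channels (L*/R*) and two
    in-ear channels (E1/E2). Signals are generated in a common reference."""
    channels = [Channel(n, "cap", "scalp") for n in CHANNEL_SUBSETS["cap12"]]
    channels += [Channel(n, "cap", "eog") for n in ("EOG1", "EOG2")]
    channels += [
        Channel(n, "ear", "around_ear")
        for n in ("L1", "L2", "L3", "L6", "L7", "R1", "R2", "R3", "R6", "R7")
    ]
    channels += [Channel(n, "ear", "in_ear") for n in ("E1", "E2")]
    return Montage(channels, sampling_rate)


def _flat_gains(levels) -> dict:
    return {lv: {b: 1.0 for b in CANONICAL_BANDS} for lv in levels}


@dataclass
class EffectProfile:
    """Ground-truth condition effects injected by the generator.

    ``band_gain[level][band]`` multiplies the *power* of that oscillator
    band during blocks of that level (1.0 = no effect).
    ``erp_amplitude[level][component]`` is the peak amplitude in uV of the
    P100/P300 templates added at each stimulus onset; ``system_gain``
    scales ERP amplitude per recording system (ear < cap by default).

    ``osc_bands`` is the oscillator partition (name -> (low, high) Hz);
    it defaults to the seven canonical bands but may be any disjoint
    set, allowing narrowband condition effects. ``osc_std`` gives each
    band's oscillator amplitude on top of the background's own in-band
    share (bands absent from the map get the background share only).
    ``amplitude_modulation_std`` is the sigma of a slow log-normal
    amplitude modulation applied independently per channel and band
    (~4 s correlation), emulating arousal-linked band-power
    co-fluctuation; it produces the heavy-tailed epoch-power
    distributions characteristic of real EEG.
    """

    band_gain: dict
    erp_amplitude: dict
    system_gain: dict = field(default_factory=lambda: {"cap": 1.0, "ear": 0.4})
    blink_rate: float = 15.0  # events / minute
    blink_amplitude: float = 120.0  # uV at the EOG channels
    line_noise_freq: float = 50.0  # Hz
    line_noise_amplitude: float = 2.0  # uV
    background_exponent: float = 1.0  # 1/f slope of the broadband background
    background_std: float = 8.0  # uV
    amplitude_modulation_std: float = 0.4
    osc_bands: dict = field(default_factory=lambda: dict(CANONICAL_BANDS))
    osc_std: dict = field(
        default_factory=lambda: {
            "delta": 2.5,
            "theta": 2.5,
            "alpha": 4.0,
            "beta1": 1.5,
            "beta2": 1.2,
            "gamma1": 0.9,
            "gamma2": 0.7,
        }
    )

    def __post_init__(self) -> None:
        for lv, gains in self.band_gain.items():
            for band, g in gains.items():
                if band not in self.osc_bands:
                    raise ValueError(f"unknown band {band!r} in band_gain")
                if g <= 0:
                    raise ValueError(f"band_gain[{lv}][{band}] must be > 0")
        if self.amplitude_modulation_std < 0:
            raise ValueError("amplitude_modulation_std must be >= 0")
        for g in self.system_gain.values():
            if g <= 0:
                raise ValueError("system gains must be > 0")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be >= 0")

    @classmethod
    def nback_default(cls) -> "EffectProfile":
        """Working-memory load effects: power below 20 Hz decreases with
        load (strongest over alpha), high-beta/gamma power increases;
        P300 amplitude decreases with load."""
        high = {
            "delta": 0.85,
            "theta": 0.80,
            "alpha": 0.60,
            "beta1": 0.85,
            "beta2": 1.15,
            "gamma1": 1.30,
            "gamma2": 1.30,
        }
        mid = {b: math.sqrt(g) for b, g in high.items()}
        return cls(
            band_gain={0: {b: 1.0 for b in CANONICAL_BANDS}, 1: mid, 2: high},
            erp_amplitude={
                0: {"P100": 5.0, "P300": 8.0},
                1: {"P100": 5.0, "P300": 6.0},
                2: {"P100": 5.0, "P300": 4.0},
            },
        )

    @classmethod
    def nback_narrowband(cls) -> "EffectProfile":
        """Working-memory effects with subject-like narrowband structure.

        The discriminative effects sit in ~2 Hz sub-band oscillators (the
        two halves of the alpha band plus narrow slices of three gamma
        ranges, two of them above 45 Hz), each with its own slow amplitude
        modulation, and with heterogeneous signs at fine frequency scale
        (net alpha suppression, net gamma enhancement). This is the
        realistic regime in which fine spectral resolution and a high
        cut-off frequency pay off: coarse band features partially cancel
        the alternating fine structure, and low cut-offs discard the
        high-gamma effects.
        """
        osc_bands = {
            "delta": (1.0, 3.0), "theta": (4.0, 7.0),
            "alpha_lo": (8.0, 10.0), "alpha_hi": (10.0, 12.0),
            "beta1": (13.0, 19.0), "beta2": (20.0, 30.0),
            "g30_46": (30.0, 46.0), "g50_60": (50.0, 60.0),
            "g70_80": (70.0, 80.0), "g95_100": (95.0, 100.0),
        }
        units = []
        for lo in (46, 48, *range(60, 70, 2), *range(80, 95, 2)):
            name = f"g{lo}"
            osc_bands[name] = (float(lo), min(float(lo + 2), 95.0))
            units.append(name)
        osc_std = {
            "delta": 2.5, "theta": 2.5, "alpha_lo": 2.8, "alpha_hi": 2.8,
            "beta1": 1.5, "beta2": 1.2,
            **{b: 0.3 for b in osc_bands if b.startswith("g")},
        }
        high = {"alpha_lo": 0.55, "alpha_hi": 1.1}
        high.update({u: (1.7 if i % 2 == 0 else 0.6) for i, u in enumerate(units)})
        gains = {lv: {b: 1.0 for b in osc_bands} for lv in (0, 1, 2)}
        for b, g in high.items():
            gains[1][b] = math.sqrt(g)
            gains[2][b] = g
        return cls(
            band_gain=gains,
            erp_amplitude={
                0: {"P100": 5.0, "P300": 8.0},
                1: {"P100": 5.0, "P300": 6.0},
                2: {"P100": 5.0, "P300": 4.0},
            },
            osc_bands=osc_bands,
            osc_std=osc_std,
        )

    @classmethod
    def arithmetic_default(cls) -> "EffectProfile":
        """Cognitive-workload effects: broadband power increase with
        difficulty level across the whole spectrum."""
        gains = {
            lv: {b: 1.0 + 0.07 * (lv - 1) for b in CANONICAL_BANDS} for lv in (1, 2, 3, 4, 5)
        }
        return cls(band_gain=gains, erp_amplitude={lv: {"P100": 0.0, "P300": 0.0} for lv in gains})

    @classmethod
    def null(cls, levels) -> "EffectProfile":
        """No condition effect, no ERPs, no blinks, no line noise, and no
        slow amplitude modulation.

        Disabling the modulation makes epochs exchangeable across blocks,
        which trial-level permutation tests require; with block-wise
        condition assignment and slow power fluctuations such tests are
        intrinsically anticonservative (on real data too).
        """
        return cls(
            band_gain=_flat_gains(levels),
            erp_amplitude={lv: {"P100": 0.0, "P300": 0.0} for lv in levels},
            blink_rate=0.0,
            line_noise_amplitude=0.0,
            amplitude_modulation_std=0.0,
        )


# blink spatial weight by channel name, falling back to role
_BLINK_NAME_WEIGHTS = {
    "Fpz": 0.7, "Fz": 0.5, "F3": 0.45, "F4": 0.45, "Cz": 0.3, "C3": 0.25, "C4": 0.25,
}
_BLINK_ROLE_WEIGHTS = {"eog": 1.0, "scalp": 0.15, "around_ear": 0.12, "in_ear": 0.08}
_LINE_ROLE_WEIGHTS = {"in_ear": 1.0, "around_ear": 0.6, "scalp": 0.2, "eog": 0.2}


def _slow_lognormal_envelope(
    rng: np.random.Generator, n: int, fs: float, sigma: float, knot_s: float = 4.0
) -> np.ndarray:
    """Slow multiplicative amplitude envelope with E[a^2] ~= 1: exp of a
    piecewise-linear Gaussian walk with ``knot_s``-second knots."""
    if sigma == 0:
        return np.ones(n)
    n_knots = int(n / fs / knot_s) + 2
    knots = rng.standard_normal(n_knots)
    t = np.arange(n) / fs / knot_s
    s = np.interp(t, np.arange(n_knots), knots)
    # linear interpolation shrinks the variance; compensate empirically
    sd = s.std()
    if sd > 0:
        s = s / sd
    return np.exp(sigma * s - sigma**2)


def _channel_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float, bands: dict
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, float]]:
    """Background + per-band noise for one channel.

    The 1/f background is notched over the canonical bands; each band's
    oscillator is unit-variance noise with the 1/f spectral shape inside
    its band, so the band carries ALL in-band power and a configured
    band-power gain is recovered exactly by epoch band-power ratios.
    Returns ``(background, oscillators, bg_frac)`` where ``bg_frac[band]``
    is the share of total background variance the notch removed from that
    band (used to restore it through the oscillator amplitude).

    All components come from independent white noise in one batched FFT
    (float32 internally, padded to a fast length).
    """
    m = sfft.next_fast_len(n)
    bands = list(bands.items())
    white = rng.standard_normal((1 + len(bands), m), dtype=np.float32)
    spec = sfft.rfft(white, axis=1)
    f = sfft.rfftfreq(m, 1.0 / fs)
    shape = np.zeros_like(f, dtype=np.float32)
    shape[1:] = f[1:].astype(np.float32) ** (-exponent / 2.0)
    nyq = fs / 2.0
    power = shape.astype(float) ** 2
    total_power = power[1:].sum()
    masks, bg_frac = {}, {}
    in_any = np.zeros_like(f, dtype=bool)
    for name, (lo, hi) in bands:
        mask = (f >= lo) & (f <= min(hi, 0.99 * nyq))
        masks[name] = mask
        bg_frac[name] = float(power[mask].sum() / total_power)
        in_any |= mask
    spec[0] *= np.where(in_any, 0.0, shape)
    for i, (name, _) in enumerate(bands, start=1):
        spec[i] *= np.where(masks[name], shape, 0.0)
    x = sfft.irfft(spec, m, axis=1)[:, :n]
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    x /= sd
    background = x[0].astype(float)
    oscillators = {name: x[i].astype(float) for i, (name, _) in enumerate(bands, start=1)}
    return background, oscillators, bg_frac


def _erp_template(fs: float, p100: float, p300: float, duration: float = 0.8) -> np.ndarray:
    """P100 + P300 waveform sampled at fs, starting at stimulus onset."""
    t = np.arange(int(round(duration * fs))) / fs
    return p100 * np.exp(-0.5 * ((t - 0.10) / 0.02) ** 2) + p300 * np.exp(
        -0.5 * ((t - 0.35) / 0.08) ** 2
    )


def _blink_template(fs: float) -> np.ndarray:
    """400 ms biphasic blink waveform with unit positive peak."""
    t = np.arange(int(round(0.4 * fs))) / fs
    w = np.exp(-0.5 * ((t - 0.15) / 0.05) ** 2) - 0.25 * np.exp(-0.5 * ((t - 0.30) / 0.07) ** 2)
    return w / w.max()


def synthesize_recording(
    events: EventStream,
    montage: Optional[Montage] = None,
    effect: Optional[EffectProfile] = None,
    seed: int = 0,
) -> Recording:
    """Render a continuous synthetic EEG recording for an event schedule.

    Signal model per channel: 1/f background + one narrowband Gaussian
    oscillator per canonical band whose power inside a block is scaled by
    ``effect.band_gain[level][band]``, + ERP template at each stimulus
    onset (scaled by level and recording system), + rank-one blink
    transients strongest on EOG/frontal channels, + sinusoidal line noise.
    Fully reproducible given ``seed``; known blink/ERP ground truth is
    attached to ``Recording.ground_truth``.
    """
    if len(events) == 0:
        raise ValueError("empty event stream")
    if montage is None:
        montage = default_montage()
    if effect is None:
        raise ValueError("an EffectProfile is required")

    blocks = events.block_intervals()
    for lv in blocks["level"].unique():
        if lv not in effect.band_gain:
            raise ValueError(f"level {lv!r} missing from EffectProfile.band_gain")
        if lv not in effect.erp_amplitude:
            raise ValueError(f"level {lv!r} missing from EffectProfile.erp_amplitude")

    fs = montage.sampling_rate
    n = int(math.ceil((events.duration + 1.0) * fs))
    rng = np.random.default_rng(seed)
    nyq = fs / 2.0

    # per-band power-gain envelope over time (shared across channels)
    envelopes = {}
    for band in effect.osc_bands:
        env = np.ones(n)
        for (_, _), row in blocks.iterrows():
            i0 = int(round(row["start_s"] * fs))
            i1 = min(int(round(row["end_s"] * fs)), n)
            env[i0:i1] = effect.band_gain[row["level"]].get(band, 1.0)
        envelopes[band] = np.sqrt(env)  # power factor -> amplitude factor

    data = np.empty((len(montage.channels), n))
    for ci in range(len(montage.channels)):
        background, oscillators, bg_frac = _channel_noise(
            rng, n, fs, effect.background_exponent, effect.osc_bands
        )
        x = effect.background_std * background
        for band in effect.osc_bands:
            # band amplitude restores the notched background share so the
            # grand PSD keeps its 1/f profile at unit gain
            amp = math.sqrt(
                effect.osc_std.get(band, 0.0) ** 2 + bg_frac[band] * effect.background_std**2
            )
            mod = _slow_lognormal_envelope(rng, n, fs, effect.amplitude_modulation_std)
            x += amp * mod * envelopes[band] * oscillators[band]
        data[ci] = x

    # ERPs: added to all non-EOG channels, scaled per recording system
    stim = events.stimuli()
    erp_truth = {}
    if len(stim):
        templates = {
            lv: _erp_template(fs, amp.get("P100", 0.0), amp.get("P300", 0.0))
            for lv, amp in effect.erp_amplitude.items()
        }
        erp_truth = {lv: tpl.copy() for lv, tpl in templates.items()}
        sys_gain = np.array(
            [
                0.0 if c.role == "eog" else effect.system_gain[c.system]
                for c in montage.channels
            ]
        )
        for _, ev in stim.iterrows():
            tpl = templates[ev["level"]]
            i0 = int(round(ev["onset_s"] * fs))
            i1 = min(i0 + len(tpl), n)
            data[:, i0:i1] += sys_gain[:, None] * tpl[: i1 - i0]

    # blinks: rank-one spatial pattern, Poisson-distributed onsets
    w = np.array(
        [
            _BLINK_NAME_WEIGHTS.get(c.name, _BLINK_ROLE_WEIGHTS[c.role])
            for c in montage.channels
        ]
    )
    blink_course = np.zeros(n)
    if effect.blink_rate > 0:
        n_blinks = rng.poisson(effect.blink_rate * events.duration / 60.0)
        tpl = _blink_template(fs)
        onsets = np.sort(rng.uniform(0, events.duration - 0.5, n_blinks))
        for t0 in onsets:
            i0 = int(round(t0 * fs))
            i1 = min(i0 + len(tpl), n)
            # amplitude jitter keeps blinks from being perfectly stereotyped
            blink_course[i0:i1] += effect.blink_amplitude * rng.uniform(0.7, 1.3) * tpl[: i1 - i0]
        data += w[:, None] * blink_course[None, :]

    # intermittent sinusoidal interference, strongest on in-ear channels
    if effect.line_noise_amplitude > 0:
        lw = np.array([_LINE_ROLE_WEIGHTS[c.role] for c in montage.channels])
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        data += effect.line_noise_amplitude * lw[:, None] * np.sin(
            2 * np.pi * effect.line_noise_freq * t + phase
        )[None, :]

    truth = {
        "blink_timecourse": blink_course,
        "blink_pattern": w / np.linalg.norm(w),
        "erp_templates": erp_truth,
    }
    return Recording(
        data=data, sampling_rate=fs, montage=montage, events=events, ground_truth=truth
    )
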