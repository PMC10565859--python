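"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package: times are in seconds, signal
amplitudes in microvolts, sample indexing is 0-based, and all sample
windows are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "Montage",
    "EventStream",
    "Recording",
    "EpochSet",
    "FeatureMatrix",
]

SYSTEMS = ("cap", "ear")
ROLES = ("scalp", "around_ear", "in_ear", "eog")

#: event kinds carried by an EventStream
EVENT_KINDS = (
    "stimulus_target",
    "stimulus_nontarget",
    "block_start",
    "block_end",
    "rest",
)
STIMULUS_KINDS = ("stimulus_target", "stimulus_nontarget")

EVENT_COLUMNS = ["onset_s", "duration_s", "session", "block", "level", "kind"]


@dataclass(frozen=True)
class Channel:
    """One electrode: name, recording system, functional role, reference."""

    name: str
    system: str  # "cap" | "ear"
    role: str  # "scalp" | "around_ear" | "in_ear" | "eog"
    reference_name: str = "nose"

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown system {self.system!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class Montage:
    """Electrode layout plus the native sampling rate of the amplifier."""

    channels: list[Channel]
    sampling_rate: float = 500.0

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        valid = set(names) | {"nose"}
        for c in self.channels:
            if c.reference_name not in valid:
                raise ValueError(
                    f"reference {c.reference_name!r} of channel {c.name!r} "
                    "is not a channel name or 'nose'"
                )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def roles(self) -> list[str]:
        return [c.role for c in self.channels]

    @property
    def systems(self) -> list[str]:
        return [c.system for c in self.channels]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, names: Sequence[str]) -> "Montage":
        by_name = {c.name: c for c in self.channels}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise KeyError(f"channels not in montage: {missing}")
        return Montage([by_name[n] for n in names], self.sampling_rate)


class EventStream:
    """Ordered timed markers (stimuli, block boundaries, rests).

    Wraps a DataFrame with columns ``onset_s, duration_s, session, block,
    level, kind``. Onsets are strictly increasing; stimulus events lie
    within their block's ``[start, end)`` interval.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"event frame missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)[EVENT_COLUMNS]
        if validate:
            self._validate()

    def _validate(self) -> None:
        onsets = self.frame["onset_s"].to_numpy(float)
        if len(onsets) and not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        bad = ~self.frame["kind"].isin(EVENT_KINDS)
        if bad.any():
            raise ValueError(
                f"unknown event kinds: {sorted(self.frame.loc[bad, 'kind'].unique())}"
            )
        # every stimulus falls inside its block interval
        blocks = self.block_intervals()
        stim = self.stimuli()
        for _, ev in stim.iterrows():
            key = (ev["session"], ev["block"])
            if key not in blocks.index:
                raise ValueError(f"stimulus without block interval: {key}")
            start, end = blocks.loc[key, ["start_s", "end_s"]]
            if not (start <= ev["onset_s"] < end):
                raise ValueError(
                    f"stimulus at {ev['onset_s']:.3f}s outside block {key}"
                )

    def __len__(self) -> int:
        return len(self.frame)

    def stimuli(self) -> pd.DataFrame:
        return self.frame[self.frame["kind"].isin(STIMULUS_KINDS)]

    def block_intervals(self) -> pd.DataFrame:
        """One row per (session, block): start_s, end_s, level."""
        starts = self.frame[self.frame["kind"] == "block_start"]
        ends = self.frame[self.frame["kind"] == "block_end"]
        s = starts.set_index(["session", "block"])
        e = ends.set_index(["session", "block"])
        out = pd.DataFrame(
            {
                "start_s": s["onset_s"],
                "end_s": e["onset_s"].reindex(s.index),
                "level": s["level"],
            }
        )
        if out["end_s"].isna().any():
            raise ValueError("block_start without matching block_end")
        return out

    @property
    def duration(self) -> float:
        if not len(self.frame):
            return 0.0
        last = self.frame.iloc[-1]
        return float(last["onset_s"] + last["duration_s"])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventStream":
        return cls(pd.read_csv(path, sep="\t"))

    def __eq__(self, other) -> bool:
        return isinstance(other, EventStream) and self.frame.equals(other.frame)


@dataclass
class Recording:
    """Continuous multi-channel signal with channel metadata and events.

    ``data`` is channels x samples in microvolts. ``ground_truth`` is an
    optional dict populated by the synthetic generator (known blink
    time-course/pattern, ERP templates) used only for validation.
    """

    data: np.ndarray
    sampling_rate: float
    montage: Montage
    events: EventStream
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.montage.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{len(self.montage.channels)} channels"
            )
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, data: np.ndarray, sampling_rate: Optional[float] = None) -> "Recording":
        return Recording(
            data=data,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            montage=self.montage,
            events=self.events,
            ground_truth=self.ground_truth,
        )

    def pick(self, names: Sequence[str]) -> "Recording":
        idx = [self.montage.index(n) for n in names]
        return Recording(
            data=self.data[idx],
            sampling_rate=self.sampling_rate,
            montage=self.montage.subset(names),
            events=self.events,
            ground_truth=self.ground_truth,
        )


@dataclass
class EpochSet:
    """Trials x channels x samples with per-trial condition labels."""

    data: np.ndarray
    sampling_rate: float
    window: tuple[float, float]
    labels: np.ndarray
    block_ids: np.ndarray
    session_ids: np.ndarray
    channel_names: list[str]
    channel_roles: Optional[list[str]] = None
    baseline: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.block_ids = np.asarray(self.block_ids)
        self.session_ids = np.asarray(self.session_ids)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.block_ids) == len(self.session_ids) == n):
            raise ValueError("per-trial metadata length mismatch")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length mismatch")
        if self.baseline is not None:
            b0, b1 = self.baseline
            w0, w1 = self.window
            if not (w0 <= b0 < b1 <= w1):
                raise ValueError("baseline must lie within the epoch window")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.sampling_rate

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            sampling_rate=self.sampling_rate,
            window=self.window,
            labels=self.labels[mask],
            block_ids=self.block_ids[mask],
            session_ids=self.session_ids[mask],
            channel_names=list(self.channel_names),
            channel_roles=None if self.channel_roles is None else list(self.channel_roles),
            baseline=self.baseline,
        )

    def select_channels(self, names: Sequence[str]) -> "EpochSet":
        idx = [self.channel_names.index(n) for n in names]
        return EpochSet(
            data=self.data[:, idx],
            sampling_rate=self.sampling_rate,
            window=self.window,
            labels=self.labels,
            block_ids=self.block_ids,
            session_ids=self.session_ids,
            channel_names=[self.channel_names[i] for i in idx],
            channel_roles=None
            if self.channel_roles is None
            else [self.channel_roles[i] for i in idx],
            baseline=self.baseline,
        )


@dataclass
class FeatureMatrix:
    """Trials x named features with per-trial labels.

    ``descriptors`` holds one ``(channel, feature_label)`` pair per column,
    e.g. ``("Pz", "alpha")`` or ``("E1", "t300ms")``.
    """

    values: np.ndarray
    descriptors: list[tuple[str, str]]
    labels: np.ndarray
    model_id: str
    subject_id: str = "s01"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be trials x features")
        if self.values.shape[1] != len(self.descriptors):
            raise ValueError("descriptor count must equal feature count")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels length must equal trial count")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaNs")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [f"{ch}:{label}" for ch, label in self.descriptors]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "label", self.labels)
        return df
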