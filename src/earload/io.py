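"""On-disk formats.

Recordings and epoch sets are stored as a flat binary matrix container: a
little-endian float32 ``.dat`` file in C order plus a ``.json`` sidecar
with shape, sampling rate and channel metadata; events travel as TSV.
Feature matrices are TSV (one row per trial, columns named
``channel:feature``) with a JSON sidecar. EDF recordings can be read when
mne is installed; there is no EDF writer.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Channel, EpochSet, EventStream, FeatureMatrix, Montage, Recording

__all__ = [
    "save_recording",
    "load_recording",
    "save_epochs",
    "load_epochs",
    "save_features",
    "load_features",
    "read_edf",
    "sha256_file",
]


def _montage_meta(m: Montage) -> dict:
    return {
        "sampling_rate": m.sampling_rate,
        "channels": [
            {"name": c.name, "system": c.system, "role": c.role, "reference_name": c.reference_name}
            for c in m.channels
        ],
    }


def _montage_from_meta(meta: dict) -> Montage:
    return Montage(
        [Channel(c["name"], c["system"], c["role"], c["reference_name"]) for c in meta["channels"]],
        meta["sampling_rate"],
    )


def save_recording(rec: Recording, stem: str | Path) -> list[Path]:
    """Write ``<stem>.dat`` (float32 channels x samples), ``<stem>.json``
    and ``<stem>.events.tsv``; returns the written paths."""
    stem = Path(stem)
    dat = stem.with_suffix(".dat")
    rec.data.astype("<f4").tofile(dat)
    meta = {
        "kind": "recording",
        "dtype": "<f4",
        "order": "C",
        "shape": list(rec.data.shape),
        "units": "uV",
        "montage": _montage_meta(rec.montage),
        "sampling_rate": rec.sampling_rate,
    }
    js = stem.with_suffix(".json")
    js.write_text(json.dumps(meta, indent=1))
    ev = stem.with_suffix(".events.tsv")
    rec.events.to_tsv(ev)
    return [dat, js, ev]


def load_recording(stem: str | Path) -> Recording:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    if meta.get("kind") != "recording":
        raise ValueError(f"{stem}: sidecar is not a recording container")
    data = np.fromfile(stem.with_suffix(".dat"), dtype=meta["dtype"]).reshape(meta["shape"])
    events = EventStream.from_tsv(stem.with_suffix(".events.tsv"))
    return Recording(
        data=data.astype(float),
        sampling_rate=meta["sampling_rate"],
        montage=_montage_from_meta(meta["montage"]),
        events=events,
    )


def save_epochs(ep: EpochSet, stem: str | Path) -> list[Path]:
    stem = Path(stem)
    dat = stem.with_suffix(".dat")
    ep.data.astype("<f4").tofile(dat)
    meta = {
        "kind": "epochs",
        "dtype": "<f4",
        "order": "C",
        "shape": list(ep.data.shape),
        "units": "uV",
        "sampling_rate": ep.sampling_rate,
        "window": list(ep.window),
        "baseline": None if ep.baseline is None else list(ep.baseline),
        "labels": [_py(v) for v in ep.labels],
        "block_ids": [_py(v) for v in ep.block_ids],
        "session_ids": [_py(v) for v in ep.session_ids],
        "channel_names": list(ep.channel_names),
        "channel_roles": ep.channel_roles,
    }
    js = stem.with_suffix(".json")
    js.write_text(json.dumps(meta, indent=1))
    return [dat, js]


def _py(v):
    return v.item() if isinstance(v, np.generic) else v


def load_epochs(stem: str | Path) -> EpochSet:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    if meta.get("kind") != "epochs":
        raise ValueError(f"{stem}: sidecar is not an epochs container")
    data = np.fromfile(stem.with_suffix(".dat"), dtype=meta["dtype"]).reshape(meta["shape"])
    return EpochSet(
        data=data.astype(float),
        sampling_rate=meta["sampling_rate"],
        window=tuple(meta["window"]),
        baseline=None if meta["baseline"] is None else tuple(meta["baseline"]),
        labels=np.asarray(meta["labels"]),
        block_ids=np.asarray(meta["block_ids"]),
        session_ids=np.asarray(meta["session_ids"]),
        channel_names=meta["channel_names"],
        channel_roles=meta["channel_roles"],
    )


def save_features(fm: FeatureMatrix, stem: str | Path) -> list[Path]:
    stem = Path(stem)
    tsv = stem.with_suffix(".tsv")
    fm.to_frame().to_csv(tsv, sep="\t", index=False)
    js = stem.with_suffix(".json")
    js.write_text(
        json.dumps({"kind": "features", "model_id": fm.model_id, "subject_id": fm.subject_id})
    )
    return [tsv, js]


def load_features(stem: str | Path) -> FeatureMatrix:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    if meta.get("kind") != "features":
        raise ValueError(f"{stem}: sidecar is not a features container")
    df = pd.read_csv(stem.with_suffix(".tsv"), sep="\t")
    labels = df.pop("label").to_numpy()
    descriptors = [tuple(c.split(":", 1)) for c in df.columns]
    return FeatureMatrix(
        values=df.to_numpy(float),
        descriptors=descriptors,
        labels=labels,
        model_id=meta["model_id"],
        subject_id=meta["subject_id"],
    )


def read_edf(path: str | Path, montage: Montage) -> Recording:
    """Read a continuous EDF recording (requires mne); EDF annotations of
    the form ``kind/session/block/level`` become the event stream."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    rows = []
    for onset, duration, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        parts = desc.split("/")
        if len(parts) != 4:
            continue
        kind, session, block, level = parts
        rows.append((float(onset), float(duration), int(session), int(block), _maybe_int(level), kind))
    frame = pd.DataFrame(
        rows, columns=["onset_s", "duration_s", "session", "block", "level", "kind"]
    )
    return Recording(
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        montage=montage,
        events=EventStream(frame),
    )


def _maybe_int(s: str):
    try:
        return int(s)
    except ValueError:
        return s


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
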