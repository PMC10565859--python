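import numpy as np
import pytest

from earload.containers import EpochSet
from earload.pipeline import preprocess_subject
from earload.synth import (
    EffectProfile,
    TaskDesign,
    default_montage,
    make_arithmetic_schedule,
    make_nback_schedule,
    synthesize_recording,
    CANONICAL_BANDS,
)


def small_arith_design(n_blocks_per_session=4, levels=(1, 2), block_duration=60.0):
    """Reduced block-design for fast unit tests (not the study conditions)."""
    return TaskDesign(
        task_id="arithmetic",
        n_sessions=2,
        blocks_per_session=n_blocks_per_session,
        block_duration=block_duration,
        levels=levels,
        repeats_per_session=n_blocks_per_session // len(levels),
        rest_duration=20.0,
    )


def small_montage(n_scalp=4):
    m = default_montage()
    names = [c.name for c in m.channels if c.role == "scalp"][:n_scalp]
    names += ["EOG1", "EOG2", "E1", "E2"]
    return m.subset(names)


def make_epochs(data, fs=256.0, labels=None, window_start=0.0, roles=None, names=None):
    """EpochSet straight from an array, for feature/stat unit tests."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    return EpochSet(
        data=data,
        sampling_rate=fs,
        window=(window_start, window_start + data.shape[2] / fs),
        labels=np.zeros(n, dtype=int) if labels is None else np.asarray(labels),
        block_ids=np.zeros(n, dtype=int),
        session_ids=np.zeros(n, dtype=int),
        channel_names=[f"ch{i}" for i in range(data.shape[1])] if names is None else list(names),
        channel_roles=roles,
    )


@pytest.fixture(scope="session")
def accept_effect():
    return EffectProfile.nback_narrowband()


@pytest.fixture(scope="session")
def nback_recording(accept_effect):
    """One full-scale synthetic N-back subject (default design)."""
    events = make_nback_schedule(TaskDesign.nback_default(), seed=101)
    return synthesize_recording(events, default_montage(), accept_effect, seed=102)


@pytest.fixture(scope="session")
def nback_epochs(nback_recording):
    """Preprocessed stimulus-locked epochs plus reports for that subject."""
    ep, rejection, blink = preprocess_subject(nback_recording, "nback")
    return ep, rejection, blink


@pytest.fixture(scope="session")
def arithmetic_epochs():
    """Preprocessed fixed-window epochs for a full-scale arithmetic subject."""
    events = make_arithmetic_schedule(TaskDesign.arithmetic_default(), seed=201)
    rec = synthesize_recording(
        events, default_montage(), EffectProfile.arithmetic_default(), seed=202
    )
    return preprocess_subject(rec, "arithmetic")
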