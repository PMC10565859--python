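"""ERP-based temporal features and spectral-temporal fusion (N-back only).

Temporal features are the low-passed (20 Hz), 100 Hz-resampled signal
amplitudes from 0 to 1000 ms after stimulus onset, sampled every 10 ms —
100 features per channel. The fusion model concatenates these with the
1 Hz spectral bins for 200 features per channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import EpochSet, FeatureMatrix

__all__ = ["TemporalFeatureSpec", "erp_features", "fuse_features", "moving_average"]


@dataclass(frozen=True)
class TemporalFeatureSpec:
    window: tuple[float, float] = (0.0, 1.0)
    step: float = 0.010  # s
    lowpass: float = 20.0  # Hz
    rate: float = 100.0  # Hz
    smoothing_points: int = 4  # display-only moving average

    def __post_init__(self) -> None:
        n = (self.window[1] - self.window[0]) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window length must be a multiple of step")

    @property
    def n_per_channel(self) -> int:
        return int(round((self.window[1] - self.window[0]) / self.step))


def erp_features(
    ep: EpochSet, spec: TemporalFeatureSpec | None = None, subject_id: str = "s01"
) -> FeatureMatrix:
    """Amplitude-over-time features from stimulus-locked epochs.

    Per channel: zero-phase low-pass at ``spec.lowpass``, polyphase
    resampling to ``spec.rate``, then amplitudes at 0, 10, ..., 990 ms.
    """
    if spec is None:
        spec = TemporalFeatureSpec()
    w0, w1 = ep.window
    if w0 > spec.window[0] + 1e-9 or w1 < spec.window[1] - 1e-9:
        raise ValueError(
            f"epoch window {ep.window} does not cover the feature window {spec.window}"
        )
    sos = signal.butter(4, spec.lowpass, btype="lowpass", fs=ep.sampling_rate, output="sos")
    filt = signal.sosfiltfilt(sos, ep.data, axis=2)
    frac = Fraction(spec.rate / ep.sampling_rate).limit_denominator(1000)
    res = signal.resample_poly(filt, frac.numerator, frac.denominator, axis=2)
    # index of t = spec.window[0] on the resampled grid
    i0 = int(round((spec.window[0] - w0) * spec.rate))
    idx = i0 + np.arange(spec.n_per_channel) * int(round(spec.step * spec.rate))
    if idx[-1] >= res.shape[2]:
        raise ValueError("resampled epoch too short for the feature window")
    feats = res[:, :, idx]  # trials x channels x timepoints
    values = feats.reshape(ep.n_trials, -1)
    times_ms = (spec.window[0] + np.arange(spec.n_per_channel) * spec.step) * 1000
    descriptors = [
        (ch, f"t{int(round(t))}ms") for ch in ep.channel_names for t in times_ms
    ]
    return FeatureMatrix(
        values=values,
        descriptors=descriptors,
        labels=ep.labels,
        model_id="temporal",
        subject_id=subject_id,
    )


def fuse_features(spectral: FeatureMatrix, temporal: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of spectral and temporal features for the
    same trials; trial order and labels are preserved unchanged."""
    if spectral.n_trials != temporal.n_trials:
        raise ValueError(
            f"trial mismatch: {spectral.n_trials} spectral vs {temporal.n_trials} temporal"
        )
    if spectral.subject_id != temporal.subject_id:
        raise ValueError("feature matrices come from different subjects")
    if not np.array_equal(spectral.labels, temporal.labels):
        raise ValueError("per-trial labels differ between the two matrices")
    return FeatureMatrix(
        values=np.hstack([spectral.values, temporal.values]),
        descriptors=list(spectral.descriptors) + list(temporal.descriptors),
        labels=spectral.labels,
        model_id="fusion",
        subject_id=spectral.subject_id,
    )


def moving_average(waveform: np.ndarray, points: int = 4) -> np.ndarray:
    """Centered running mean with shrinking edge windows (display
    smoothing for grand-average ERP traces). Output length equals input
    length; for an even ``points`` the window extends one sample further
    to the left."""
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("moving_average expects a 1-D waveform")
    n = waveform.shape[-1]
    if n < points:
        raise ValueError("waveform shorter than the smoothing window")
    left = points // 2
    right = points - left - 1
    c = np.cumsum(np.concatenate([[0.0], waveform]))
    out = np.empty_like(waveform, dtype=float)
    for i in range(n):
        a = max(0, i - left)
        b = min(n, i + right + 1)
        out[i] = (c[b] - c[a]) / (b - a)
    return out
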