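"""Per-epoch power spectral density and band-power feature models.

PSDs are one-sided Hann-windowed periodograms on the epoch's native
frequency grid (0.5 Hz for 2 s epochs at 256 Hz). Six binning models
aggregate the grid into features, at cut-off frequencies of 45, 80 or
100 Hz:

- ``bin05``  — every native 0.5 Hz bin (200 features/channel at 100 Hz)
- ``bin1``   — 1 Hz bins centered on 1..cutoff Hz (100/channel)
- ``mixed5`` — delta/theta/alpha bands plus 5 Hz bins over 13-cutoff Hz
  (21/channel at 100 Hz)
- ``band12`` — delta..beta2 plus 10 Hz gamma bins (12/channel at 100 Hz)
- ``band7``  — the seven canonical oscillation bands
- ``band5``  — delta, theta, alpha, beta 13-30, gamma 30-cutoff

Band features are the *mean* PSD over the band's native bins, which keeps
bands of unequal width comparable; every statistic downstream is invariant
to this monotone choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EpochSet, FeatureMatrix

__all__ = [
    "BinningScheme",
    "FeatureMatrix",
    "MODEL_IDS",
    "CUTOFFS",
    "periodogram_psd",
    "make_scheme",
    "band_power",
    "normalize_p90",
]

MODEL_IDS = ("bin05", "bin1", "mixed5", "band12", "band7", "band5")
CUTOFFS = (45.0, 80.0, 100.0)

# printed feature counts per channel at the 100 Hz cut-off
COUNTS_AT_100 = {"bin05": 200, "bin1": 100, "mixed5": 21, "band12": 12, "band7": 7, "band5": 5}

_NAMED = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta1": (13.0, 19.0),
    "beta2": (20.0, 30.0),
}


@dataclass(frozen=True)
class Band:
    """One frequency band; bounds in Hz with inclusivity flags."""

    label: str
    low: float
    high: float
    incl_low: bool = True
    incl_high: bool = True

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        lo = freqs >= self.low - 1e-9 if self.incl_low else freqs > self.low + 1e-9
        hi = freqs <= self.high + 1e-9 if self.incl_high else freqs < self.high - 1e-9
        return lo & hi


@dataclass(frozen=True)
class BinningScheme:
    model_id: str
    cutoff: float
    bands: tuple[Band, ...]

    @property
    def n_features_per_channel(self) -> int:
        return len(self.bands)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]


def periodogram_psd(ep: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-window periodogram per trial and channel.

    Returns ``(psd, freqs)`` with ``psd`` of shape trials x channels x
    n_freqs in uV^2/Hz; the integral of the PSD over frequency equals the
    mean square of the window-compensated signal (scipy density scaling).
    Epoch length is uniform by construction of :class:`EpochSet`; a 2 s
    epoch at 256 Hz yields the native 0.5 Hz grid.
    """
    freqs, psd = signal.periodogram(
        ep.data, fs=ep.sampling_rate, window="hann", axis=2, scaling="density"
    )
    return psd, freqs


def _steps(
    start: float, width: float, cutoff: float, label_fmt: str, first_incl_low: bool = True
) -> list[Band]:
    """Adjacent width-Hz bands from ``start`` to ``cutoff``, half-open
    except the last (closed at the cutoff); final band truncated. The
    first band's low edge can be made exclusive when it abuts a closed
    named band."""
    bands = []
    s = start
    while s < cutoff - 1e-9:
        e = min(s + width, cutoff)
        last = e >= cutoff - 1e-9
        incl_low = first_incl_low if s == start else True
        bands.append(
            Band(label_fmt.format(low=int(s), high=int(e)), s, e, incl_low=incl_low, incl_high=last)
        )
        s += width
    return bands


def make_scheme(model_id: str, cutoff: float) -> BinningScheme:
    """Build the exact band edges for one feature model at one cut-off."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    if cutoff not in CUTOFFS:
        raise ValueError(f"cutoff must be one of {CUTOFFS}, got {cutoff}")
    if model_id == "band7" and cutoff == 45.0:
        raise ValueError(
            "band7 at a 45 Hz cut-off is disallowed: it would carry the same "
            "features as the mixed5 (5 Hz) model"
        )

    named = [Band(k, lo, hi) for k, (lo, hi) in _NAMED.items()]
    delta, theta, alpha, beta1, beta2 = named

    if model_id == "bin05":
        grid = np.arange(0.5, cutoff + 1e-9, 0.5)
        bands = tuple(Band(f"{f:g}Hz", f, f) for f in grid)
    elif model_id == "bin1":
        # 1 Hz bins centered on the integers 1..cutoff, each averaging the
        # two native 0.5 Hz bins at k-0.5 and k
        bands = tuple(Band(f"{k}Hz", k - 0.5, float(k)) for k in range(1, int(cutoff) + 1))
    elif model_id == "mixed5":
        bands = tuple([delta, theta, alpha] + _steps(13.0, 5.0, cutoff, "{low}-{high}Hz"))
    elif model_id == "band12":
        bands = tuple(
            [delta, theta, alpha, beta1, beta2]
            + _steps(30.0, 10.0, cutoff, "gamma{low}-{high}", first_incl_low=False)
        )
    elif model_id == "band7":
        bands = tuple(
            [delta, theta, alpha, beta1, beta2,
             Band("gamma1", 30.0, 50.0, incl_low=False),
             Band("gamma2", 50.0, cutoff, incl_low=False)]
        )
    else:  # band5
        bands = tuple(
            [delta, theta, alpha, Band("beta", 13.0, 30.0),
             Band("gamma", 30.0, cutoff, incl_low=False)]
        )

    scheme = BinningScheme(model_id=model_id, cutoff=cutoff, bands=bands)
    if cutoff == 100.0 and len(bands) != COUNTS_AT_100[model_id]:
        raise AssertionError(
            f"{model_id} at 100 Hz built {len(bands)} bands, expected {COUNTS_AT_100[model_id]}"
        )
    return scheme


def band_power(
    psd: np.ndarray,
    freqs: np.ndarray,
    scheme: BinningScheme,
    channel_names: list[str],
    labels: np.ndarray,
    model_id: str | None = None,
    subject_id: str = "s01",
) -> FeatureMatrix:
    """Aggregate a trials x channels x freqs PSD into band features.

    Each feature is the mean PSD over the band's native-resolution bins;
    channel blocks are concatenated (all bands of channel 1, then channel
    2, ...).
    """
    psd = np.asarray(psd)
    if psd.ndim != 3 or psd.shape[1] != len(channel_names):
        raise ValueError("psd must be trials x channels x freqs matching channel_names")
    if freqs.max() < scheme.cutoff - 1e-9:
        raise ValueError(
            f"PSD grid ends at {freqs.max():g} Hz, below scheme cutoff {scheme.cutoff:g} Hz"
        )
    masks = []
    for band in scheme.bands:
        m = band.mask(freqs)
        if not m.any():
            raise ValueError(f"band {band.label} selects no PSD bins")
        masks.append(m)
    per_band = np.stack([psd[:, :, m].mean(axis=2) for m in masks], axis=2)
    n_trials = psd.shape[0]
    values = per_band.reshape(n_trials, -1)  # channel-major: ch0 bands, ch1 bands, ...
    descriptors = [(ch, band.label) for ch in channel_names for band in scheme.bands]
    return FeatureMatrix(
        values=values,
        descriptors=descriptors,
        labels=labels,
        model_id=model_id or f"{scheme.model_id}@{scheme.cutoff:g}",
        subject_id=subject_id,
    )


def normalize_p90(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Divide by the 90th percentile along ``axis`` (linear interpolation
    between order statistics), so the normalized 90th percentile is 1.

    Used for cross-subject band-power summaries: each subject-band is
    scaled independently before pooling.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[axis] < 10:
        raise ValueError("need at least 10 values per subject-band to normalize")
    p90 = np.percentile(values, 90, axis=axis, keepdims=True)
    if np.any(p90 <= 0):
        raise ValueError("degenerate input: non-positive 90th percentile")
    return values / p90
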