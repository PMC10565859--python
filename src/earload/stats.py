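"""Permutation statistics, FDR correction and cross-subject heatmaps.

Condition comparisons use a label-permutation test on the difference of
condition means. The null distribution is built by shuffling pooled
condition labels (5,000 permutations by default) and the observed
statistic is standardized against it to give a signed z-score: positive z
means the more demanding condition has the higher value. Significance at
level alpha uses the one-tailed normal threshold on |z|, so alpha = 0.01
corresponds to |z| > 2.3262 and alpha = 0.001 to |z| > 3.0902.

Per subject, p-values over all (channel x frequency-bin) cells are
corrected with the Benjamini-Hochberg step-up procedure; cross-subject
heatmaps count, per cell, how many subjects show an FDR-corrected
significant difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "SubjectHeatmap",
    "permutation_z",
    "permutation_z_cells",
    "fdr_adjust",
    "subject_heatmap",
    "band_summary",
    "z_threshold",
]


def z_threshold(alpha: float) -> float:
    """|z| significance threshold for the one-tailed convention:
    Phi^-1(1 - alpha); 2.3262 at alpha=0.01, 3.0902 at alpha=0.001."""
    return float(sps.norm.ppf(1.0 - alpha))


@dataclass
class PermutationResult:
    observed: float
    z: float
    p: float
    n_perm: int

    def significant(self, alpha: float = 0.01) -> bool:
        return abs(self.z) > z_threshold(alpha)


def _null_stats(
    pooled: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null distribution of mean(b) - mean(a) under label shuffling.

    ``pooled`` is (n_a + n_b) x cells; returns n_perm x cells. Labels are
    permuted without replacement, shared across cells.
    """
    n = pooled.shape[0]
    n_b = n - n_a
    total = pooled.sum(axis=0)
    # each permutation: pick which rows are "a"; 0/1 indicator rows keep
    # the per-permutation sums a single BLAS matmul
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_a]
    indicator = np.zeros((n_perm, n))
    np.put_along_axis(indicator, idx, 1.0, axis=1)
    sums_a = indicator @ pooled  # n_perm x cells
    sums_b = total[None, :] - sums_a
    return sums_b / n_b - sums_a / n_a


def permutation_z(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 5000,
    seed: Optional[int] = None,
) -> PermutationResult:
    """Permutation test of mean(b) - mean(a); b is the more demanding
    condition, so positive z means higher values under higher load."""
    a = np.asarray(a, dtype=float).reshape(-1, 1)
    b = np.asarray(b, dtype=float).reshape(-1, 1)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per condition")
    rng = np.random.default_rng(seed)
    observed = float(b.mean() - a.mean())
    null = _null_stats(np.vstack([a, b]), len(a), n_perm, rng)[:, 0]
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate data: permutation null has zero spread")
    z = (observed - null.mean()) / sd
    p = float(sps.norm.sf(abs(z)))
    return PermutationResult(observed=observed, z=float(z), p=max(p, np.finfo(float).tiny), n_perm=n_perm)


def permutation_z_cells(
    a: np.ndarray, b: np.ndarray, n_perm: int = 5000, seed: Optional[int] = None
) -> np.ndarray:
    """Vectorized permutation z-scores over many cells at once.

    ``a`` and ``b`` are trials x cells for the two conditions (the cell
    axis may represent channel x frequency-bin pairs, flattened). The same
    label permutations are shared across cells. Returns z per cell.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("cell count mismatch between conditions")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 trials per condition")
    rng = np.random.default_rng(seed)
    observed = b.mean(axis=0) - a.mean(axis=0)
    null = _null_stats(np.vstack([a, b]), len(a), n_perm, rng)
    sd = null.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("degenerate data: zero-spread permutation null in some cell")
    return (observed - null.mean(axis=0)) / sd


def fdr_adjust(p_values: Sequence[float], alpha: float = 0.01) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up decisions at level ``alpha``.

    Returns ``(reject, realized_threshold)`` where the realized threshold
    is the largest p-value still declared significant (0.0 when none is).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold


@dataclass
class SubjectHeatmap:
    """Cross-subject significance counts per (channel x cell)."""

    counts: np.ndarray  # channels x cells, int
    alpha: float
    n_subjects: int
    per_subject_thresholds: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts.min() < 0 or self.counts.max() > self.n_subjects:
            raise ValueError("counts must lie in [0, n_subjects]")


def subject_heatmap(z_matrices: Sequence[np.ndarray], alpha: float = 0.01) -> SubjectHeatmap:
    """Sum per-subject FDR-corrected significance maps.

    For each subject: convert the signed z matrix (channels x cells) to
    one-tailed p-values, BH-adjust across all of that subject's cells at
    ``alpha``, binarize, then sum the binary maps cell-wise.
    """
    if not len(z_matrices):
        raise ValueError("no subjects given")
    shape = np.asarray(z_matrices[0]).shape
    counts = np.zeros(shape, dtype=int)
    thresholds = []
    for z in z_matrices:
        z = np.asarray(z, dtype=float)
        if z.shape != shape:
            raise ValueError(f"shape mismatch: {z.shape} vs {shape}")
        p = sps.norm.sf(np.abs(z)).ravel()
        p = np.maximum(p, np.finfo(float).tiny)
        reject, thr = fdr_adjust(p, alpha=alpha)
        counts += reject.reshape(shape).astype(int)
        thresholds.append(thr)
    return SubjectHeatmap(
        counts=counts,
        alpha=alpha,
        n_subjects=len(z_matrices),
        per_subject_thresholds=thresholds,
    )


def band_summary(
    norm_low: np.ndarray,
    norm_high: np.ndarray,
    band_labels: Sequence[str],
    n_perm: int = 5000,
    seed: Optional[int] = None,
    whisker: float = 2.5,
    clip: float = 2.5,
) -> pd.DataFrame:
    """Boxplot-style distribution summary of normalized band powers.

    ``norm_low``/``norm_high`` are trials x bands of 90th-percentile
    normalized powers for the less/more demanding condition. Whiskers
    extend ``whisker`` x IQR beyond the quartiles; values above ``clip``
    are flagged as extreme outliers and reported clipped for display. A
    permutation z-score (high vs low) is attached per band.
    """
    norm_low = np.atleast_2d(np.asarray(norm_low, dtype=float))
    norm_high = np.atleast_2d(np.asarray(norm_high, dtype=float))
    if norm_low.shape[1] != len(band_labels) or norm_high.shape[1] != len(band_labels):
        raise ValueError("band count mismatch")
    z = permutation_z_cells(norm_low, norm_high, n_perm=n_perm, seed=seed)
    rows = []
    for j, label in enumerate(band_labels):
        for cond, vals in (("low", norm_low[:, j]), ("high", norm_high[:, j])):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo_w = vals[vals >= q1 - whisker * iqr].min()
            hi_w = vals[vals <= q3 + whisker * iqr].max()
            outliers = vals[(vals < lo_w) | (vals > hi_w)]
            rows.append(
                {
                    "band": label,
                    "condition": cond,
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "whisker_low": lo_w,
                    "whisker_high": hi_w,
                    "n_outliers": int(len(outliers)),
                    "n_extreme": int((vals > clip).sum()),
                    "display_max": float(min(vals.max(), clip)),
                    "z": float(z[j]),
                }
            )
    return pd.DataFrame(rows)
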