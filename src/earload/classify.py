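"""Step-wise linear discriminant analysis (swLDA) with fixed-partition
cross-validation and binomial chance-level calibration.

The classifier is the classical swLDA of the single-trial EEG/BCI
literature: class labels are coded -1/+1 and regressed on the features by
ordinary least squares; features enter the model by forward inclusion
(partial-F p-value < p_in, default 0.1) and leave by backward elimination
(partial p > p_out, default 0.15). Requiring p_in < p_out prevents
add/remove cycling: a feature admitted at p < p_in cannot immediately
qualify for removal, and each accepted step strictly decreases the
residual sum of squares over a finite lattice of subsets; a ``max_steps``
cap guards the loop regardless.

Cross-validation uses a frozen trial-to-fold assignment (deterministic
round-robin) so that every feature model of a subject is scored on
identical splits. The chance level follows the binomial inversion of
Combrisson & Jerbi: the smallest accuracy k/n whose probability under
guessing is at most alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SWLDAModel",
    "CVResult",
    "swlda_train",
    "swlda_predict",
    "assign_folds",
    "crossvalidate",
    "chance_level",
    "compare_models",
]


@dataclass
class SWLDAModel:
    selected: list[int]
    weights: np.ndarray
    threshold: float  # decision threshold on the discriminant score
    feature_means: np.ndarray  # training means of the selected features
    classes: np.ndarray  # classes[0] -> score below threshold, classes[1] above
    p_in: float
    p_out: float
    selection_trace: list[tuple[int, str, int, float]] = field(default_factory=list)
    majority_class: Optional[object] = None  # set when no feature passed p_in

    @property
    def is_empty(self) -> bool:
        return len(self.selected) == 0

    def to_dict(self) -> dict:
        return {
            "selected": [int(i) for i in self.selected],
            "weights": [float(w) for w in self.weights],
            "threshold": float(self.threshold),
            "p_in": self.p_in,
            "p_out": self.p_out,
            "trace": [
                {"step": s, "action": a, "feature": int(j), "p": float(p)}
                for s, a, j, p in self.selection_trace
            ],
        }


def _partial_p_included(G: np.ndarray, yc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partial-F p-value of each included feature in the regression of yc
    on G (both centered), plus the coefficient vector."""
    n, k = G.shape
    gram = G.T @ G
    gram_inv = np.linalg.pinv(gram)
    w = gram_inv @ (G.T @ yc)
    resid = yc - G @ w
    df = n - k - 1  # intercept absorbed by centering
    if df <= 0:
        return np.ones(k), w
    sigma2 = float(resid @ resid) / df
    diag = np.clip(np.diag(gram_inv), np.finfo(float).tiny, None)
    if sigma2 <= 0:  # perfect fit: every retained feature maximally significant
        return np.full(k, np.finfo(float).tiny), w
    F = w**2 / (sigma2 * diag)
    return sps.f.sf(F, 1, df), w


def swlda_train(
    X: np.ndarray,
    y: Sequence,
    p_in: float = 0.1,
    p_out: float = 0.15,
    max_steps: int = 60,
) -> SWLDAModel:
    """Fit an swLDA model by forward inclusion / backward elimination.

    At each forward step the candidate with the smallest partial-F
    p-value enters if p < p_in; after every inclusion, any retained
    feature whose partial p exceeds p_out is removed (largest first).
    Constant or collinear candidates are skipped, not fatal. If no
    feature passes p_in at the first step the model is empty and predicts
    the majority class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be trials x features")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {len(classes)}")
    if len(y) != X.shape[0]:
        raise ValueError("label count mismatch")
    if X.shape[0] <= 2:
        raise ValueError("need more than 2 trials")
    if not p_in < p_out:
        raise ValueError("p_in must be below p_out (guards selection cycling)")

    n, p = X.shape
    yv = np.where(y == classes[1], 1.0, -1.0)
    xm = X.mean(axis=0)
    Xc = X - xm
    yc = yv - yv.mean()

    selected: list[int] = []
    trace: list[tuple[int, str, int, float]] = []
    step = 0
    guard = 0
    while len([t for t in trace if t[1] == "add"]) < max_steps:
        guard += 1
        if guard > 10 * max_steps:
            break
        # --- forward: best candidate by partial F given current selection
        if selected:
            Q, _ = np.linalg.qr(Xc[:, selected])
            Z = Xc - Q @ (Q.T @ Xc)
            r = yc - Q @ (Q.T @ yc)
        else:
            Z = Xc
            r = yc
        sse = float(r @ r)
        d = np.einsum("ij,ij->j", Z, Z)
        scale = float(np.einsum("ij,ij->j", Xc, Xc).max())
        valid = d > 1e-12 * max(scale, 1.0)
        valid[selected] = False
        if not valid.any() or sse <= 0:
            break
        c = Z.T @ r
        delta = np.zeros(p)
        delta[valid] = c[valid] ** 2 / d[valid]
        sse_new = sse - delta
        df2 = n - (len(selected) + 1) - 1
        if df2 <= 0:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(sse_new > 0, delta / (sse_new / df2), np.inf)
        pvals = np.where(valid, sps.f.sf(F, 1, df2), 1.1)
        j = int(np.argmin(pvals))
        if pvals[j] >= p_in:
            break
        selected.append(j)
        step += 1
        trace.append((step, "add", j, float(pvals[j])))
        # --- backward: drop redundant features until all partial p <= p_out
        while len(selected) > 1:
            pv, _ = _partial_p_included(Xc[:, selected], yc)
            worst = int(np.argmax(pv))
            if pv[worst] <= p_out:
                break
            step += 1
            trace.append((step, "remove", selected[worst], float(pv[worst])))
            selected.pop(worst)

    if not selected:
        counts = [(y == cl).sum() for cl in classes]
        return SWLDAModel(
            selected=[],
            weights=np.zeros(0),
            threshold=0.0,
            feature_means=np.zeros(0),
            classes=classes,
            p_in=p_in,
            p_out=p_out,
            selection_trace=trace,
            majority_class=classes[int(np.argmax(counts))],
        )

    G = Xc[:, selected]
    w, *_ = np.linalg.lstsq(G, yc, rcond=None)
    scores = G @ w
    thr = 0.5 * (scores[yv > 0].mean() + scores[yv < 0].mean())
    return SWLDAModel(
        selected=list(selected),
        weights=w,
        threshold=float(thr),
        feature_means=xm[selected],
        classes=classes,
        p_in=p_in,
        p_out=p_out,
        selection_trace=trace,
    )


def swlda_predict(model: SWLDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and discriminant scores for new trials."""
    X = np.asarray(X, dtype=float)
    if model.is_empty:
        labels = np.full(X.shape[0], model.majority_class)
        return labels, np.zeros(X.shape[0])
    if X.shape[1] <= max(model.selected):
        raise ValueError("X does not carry the training feature space")
    scores = (X[:, model.selected] - model.feature_means) @ model.weights
    labels = np.where(scores > model.threshold, model.classes[1], model.classes[0])
    return labels, scores


def assign_folds(n_trials: int, k: int = 10) -> np.ndarray:
    """Deterministic round-robin partition: trial i -> fold (i mod k) + 1.

    Frozen across feature models so that every model of a subject is
    evaluated on byte-identical splits.
    """
    if n_trials < k:
        raise ValueError(f"need at least {k} trials for {k} folds")
    return np.arange(n_trials) % k + 1


@dataclass
class CVResult:
    fold_accuracies: list[float]  # percent, per evaluated fold
    partition: np.ndarray
    chance_threshold: float  # percent
    n_features_final: float  # mean selected-feature count over folds
    excluded_folds: list[int] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def above_chance(self) -> bool:
        return self.mean_accuracy > self.chance_threshold


def crossvalidate(
    X: np.ndarray,
    y: Sequence,
    partition: Optional[np.ndarray] = None,
    p_in: float = 0.1,
    p_out: float = 0.15,
    max_steps: int = 60,
    chance_alpha: float = 0.001,
) -> CVResult:
    """k-fold cross-validation of swLDA on a frozen partition.

    Each fold is held out once; folds whose training split lacks a class
    are excluded from the mean and flagged. Accuracy is percent correct.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if partition is None:
        partition = assign_folds(len(y))
    partition = np.asarray(partition)
    if len(partition) != len(y):
        raise ValueError("partition length mismatch")
    folds = np.unique(partition)
    accs, n_feats, excluded = [], [], []
    for fold in folds:
        test = partition == fold
        train = ~test
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 1:
            excluded.append(int(fold))
            continue
        model = swlda_train(X[train], y[train], p_in=p_in, p_out=p_out, max_steps=max_steps)
        pred, _ = swlda_predict(model, X[test])
        accs.append(100.0 * float(np.mean(pred == y[test])))
        n_feats.append(len(model.selected))
    if not accs:
        raise ValueError("no fold could be evaluated")
    return CVResult(
        fold_accuracies=accs,
        partition=partition,
        chance_threshold=chance_level(len(y), 2, chance_alpha),
        n_features_final=float(np.mean(n_feats)),
        excluded_folds=excluded,
    )


def chance_level(n_trials: int, n_classes: int = 2, alpha: float = 0.001) -> float:
    """Binomial chance-level threshold in percent.

    Binomial inversion at confidence 1 - alpha: the threshold accuracy is
    k/n with k the (1 - alpha) quantile of Binomial(n, 1/n_classes), so a
    guesser exceeds it with probability at most alpha. 500 two-class
    trials at alpha = 0.001 give 57%.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    k = int(sps.binom.ppf(1.0 - alpha, n_trials, 1.0 / n_classes))
    k = min(k, n_trials)
    return 100.0 * k / n_trials


@dataclass
class PairedComparison:
    t: float
    p: float
    significant: bool


def compare_models(
    acc_a: Sequence[float], acc_b: Sequence[float], alpha: float = 0.001
) -> PairedComparison:
    """Two-sided paired t-test on per-(subject, fold) accuracies."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired accuracy arrays must have equal length")
    if np.var(a - b) == 0:
        raise ValueError("zero variance of paired differences; t-test undefined")
    t, p = sps.ttest_rel(a, b)
    return PairedComparison(t=float(t), p=float(p), significant=bool(p < alpha))
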