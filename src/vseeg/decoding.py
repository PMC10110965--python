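"""Time-resolved multivariate decoding of stimulus novelty (OLD vs NEW).

At every timepoint the multichannel sample vector is the feature set; a
standardized L2-penalized logistic regression (L-BFGS-B) is scored with
ROC-AUC under stratified 20-fold cross-validation.  Standardization parameters
are fit on each training fold only (no leakage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .containers import EpochArray

__all__ = ["StandardizationParams", "standardize_fit", "standardize_apply",
           "LinearDecoder", "fit_logistic", "auc", "FoldAssignment",
           "make_folds", "DecodingScores", "decode_timecourse", "pool",
           "ROILabeling", "subset_roi", "ROI_VOCABULARY"]

ROI_VOCABULARY = ("Hc", "ACC", "ITG", "F", "Ins-Op", "P", "T", "O")


# ---------------------------------------------------------------- scaling

@dataclass
class StandardizationParams:
    mean: np.ndarray
    sd: np.ndarray
    keep: np.ndarray          # boolean mask of non-constant columns


def standardize_fit(X_train: np.ndarray) -> StandardizationParams:
    """Per-column mean/SD on training data; zero-variance columns are
    flagged (with a warning) and excluded downstream."""
    X = np.asarray(X_train, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {np.count_nonzero(~keep)} constant column(s)")
    return StandardizationParams(mean, sd, keep)


def standardize_apply(params: StandardizationParams, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    out = (X[:, params.keep] - params.mean[params.keep]) / params.sd[params.keep]
    return out


# ---------------------------------------------------------------- classifier

@dataclass
class LinearDecoder:
    weights: np.ndarray
    intercept: float
    standardization: StandardizationParams | None
    l2: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        if self.standardization is not None:
            X = standardize_apply(self.standardization, X)
        return X @ self.weights + self.intercept


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    l2: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    standardization: StandardizationParams | None = None,
) -> LinearDecoder:
    """L2-penalized logistic regression via L-BFGS-B.

    Minimizes sum_i log(1 + exp(-s_i (x_i.w + b))) + l2/2 ||w||^2 with
    s in {-1, +1}; the intercept is not penalized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    s = np.where(y == classes[1], 1.0, -1.0)
    n, d = X.shape

    def loss_grad(theta):
        w, b = theta[:d], theta[d]
        z = s * (X @ w + b)
        loss = np.sum(np.logaddexp(0.0, -z)) + 0.5 * l2 * (w @ w)
        # d/dz log(1+e^-z) = -sigmoid(-z)
        g = -s / (1.0 + np.exp(z))
        grad = np.concatenate([X.T @ g + l2 * w, [g.sum()]])
        return loss, grad

    res = minimize(loss_grad, np.zeros(d + 1), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": tol, "ftol": 0.0})
    return LinearDecoder(res.x[:d], float(res.x[d]), standardization, l2)


def auc(decision_values: np.ndarray, labels: np.ndarray) -> float:
    """ROC-AUC by the Mann-Whitney midrank formula (ties count 1/2)."""
    v = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    pos = y == np.max(y)
    n_pos = int(pos.sum())
    n_neg = v.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes required")
    ranks = rankdata(v)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------- folds

@dataclass
class FoldAssignment:
    fold_of_trial: np.ndarray
    n_folds: int
    seed: int

    def split(self):
        for f in range(self.n_folds):
            test = np.flatnonzero(self.fold_of_trial == f)
            train = np.flatnonzero(self.fold_of_trial != f)
            yield train, test


def make_folds(labels: np.ndarray, n_folds: int = 20, seed: int = 0) -> FoldAssignment:
    """Seeded stratified fold assignment; every fold holds both classes."""
    y = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < n_folds:
        raise ValueError(
            f"too few trials per class ({counts.min()}) for {n_folds} folds; "
            "reduce n_folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of_trial = np.empty(y.size, dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        fold_of_trial[test] = f
    return FoldAssignment(fold_of_trial, n_folds, seed)


# ---------------------------------------------------------------- timecourse

@dataclass
class DecodingScores:
    """ROC-AUC per fold and timepoint."""

    scores: np.ndarray           # (n_folds, n_timepoints)
    times: np.ndarray
    space: str
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("AUC scores must lie in [0, 1]")
        if self.scores.shape != (self.n_folds, self.times.size):
            raise ValueError("scores shape must be (n_folds, n_timepoints)")

    def fold_mean(self) -> np.ndarray:
        return self.scores.mean(axis=0)


def decode_timecourse(
    ep: EpochArray,
    n_folds: int = 20,
    l2: float = 1.0,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    time_window_s: tuple[float, float] | None = None,
    return_patterns: bool = False,
):
    """Per-timepoint cross-validated decoding of OLD vs NEW.

    ``time_window_s`` restricts decoding to a time range (scores/times then
    cover only that range).  With ``return_patterns`` the fold-averaged Haufe
    activation pattern per timepoint is returned alongside the scores.
    """
    y = ep.y()
    if ep.n_trials < 2 * n_folds:
        raise ValueError("too few trials; reduce n_folds")
    folds = make_folds(ep.labels, n_folds=n_folds, seed=seed)
    times = ep.times
    t_idx = np.arange(times.size)
    if time_window_s is not None:
        t_idx = t_idx[(times >= time_window_s[0]) & (times <= time_window_s[1])]
        if t_idx.size == 0:
            raise ValueError("time window contains no samples")
    scores = np.empty((n_folds, t_idx.size))
    patterns = np.zeros((ep.n_channels, t_idx.size)) if return_patterns else None
    splits = list(folds.split())
    for j, t in enumerate(t_idx):
        Xt = ep.data[:, :, t]
        ref_pattern = None
        for f, (train, test) in enumerate(splits):
            params = standardize_fit(Xt[train])
            Xtr = standardize_apply(params, Xt[train])
            dec = fit_logistic(Xtr, y[train], l2=l2, tol=tol,
                               max_iter=max_iter, standardization=params)
            scores[f, j] = auc(dec.decision(Xt[test]), y[test])
            if return_patterns:
                from .patterns import activation_pattern
                a = np.zeros(ep.n_channels)
                a[params.keep] = activation_pattern(dec.weights, Xtr)
                if ref_pattern is None:
                    ref_pattern = a
                elif a @ ref_pattern < 0:      # sign-align folds before averaging
                    a = -a
                patterns[:, j] += a / n_folds
    result = DecodingScores(scores, times[t_idx], ep.space, n_folds, seed)
    if return_patterns:
        return result, patterns
    return result


# ---------------------------------------------------------------- pooling / ROI

def pool(eps: list[EpochArray]) -> EpochArray:
    """Channel-wise concatenation across modalities/spaces.

    Each input is scaled to unit mean channel variance first, so microvolt
    scale differences between scalp and SEEG do not dominate the pooled
    feature space.
    """
    if len(eps) < 2:
        raise ValueError("pooling needs at least two inputs")
    ref = eps[0]
    for other in eps[1:]:
        if other.n_trials != ref.n_trials or \
                not np.array_equal(other.labels, ref.labels) or \
                other.n_samples != ref.n_samples or \
                abs(other.fs - ref.fs) > 1e-9 or \
                other.first_sample != ref.first_sample:
            raise ValueError("pooled inputs must share trials, labels and time axis")
    blocks, ids = [], []
    for ep in eps:
        scale = np.sqrt(np.mean(ep.data.var(axis=(0, 2))))
        blocks.append(ep.data / scale if scale > 0 else ep.data)
        ids.extend(f"{ep.space}:{ch}" for ch in ep.channel_ids)
    return replace(ref, data=np.concatenate(blocks, axis=1),
                   channel_ids=ids, space="pooled")


@dataclass
class ROILabeling:
    """Channel-to-region mapping over a declared label vocabulary."""

    labels: dict[str, str]
    vocabulary: tuple[str, ...] = ROI_VOCABULARY

    def __post_init__(self) -> None:
        bad = set(self.labels.values()) - set(self.vocabulary)
        if bad:
            raise ValueError(f"labels outside vocabulary: {bad}")

    def channels(self, label: str) -> list[str]:
        return [ch for ch, lab in self.labels.items() if lab == label]


def subset_roi(ep: EpochArray, roi: ROILabeling, label: str) -> EpochArray:
    """Restrict epochs to channels carrying the given region label."""
    if label not in roi.vocabulary:
        raise ValueError(f"unknown ROI label {label!r}")
    wanted = set(roi.channels(label))
    idx = [i for i, ch in enumerate(ep.channel_ids) if ch in wanted]
    if not idx:
        raise ValueError(f"no channels labeled {label!r}")
    return ep.select_channels(np.array(idx), space=f"roi:{label}")
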