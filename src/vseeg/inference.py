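"""One-sample cluster-based sign-flip permutation test on fold scores.

Per-timepoint one-sample t statistics of (score - chance) across folds are
thresholded at the one-sided t quantile; contiguous suprathreshold runs form
clusters whose mass (summed t) is compared against the permutation null of the
maximal cluster mass under random per-fold sign flips.  When the fold count
permits, the sign-flip space is enumerated exhaustively.

Caveat: cross-validation folds share training data and are not strictly
independent samples; the test treats them as exchangeable, as is common
practice for fold-score inference, and this assumption is echoed in every
report.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["Cluster", "ClusterTestResult", "cluster_permutation_onesample",
           "significant_intervals", "EXCHANGEABILITY_NOTE"]

EXCHANGEABILITY_NOTE = (
    "fold scores share training data and are treated as exchangeable samples")


@dataclass(frozen=True)
class Cluster:
    start: int            # first timepoint index
    end: int              # last timepoint index, inclusive
    mass: float           # sum of suprathreshold t values
    p_value: float


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    threshold: float
    n_permutations: int
    seed: int
    alternative: str
    exact: bool
    note: str = EXCHANGEABILITY_NOTE

    def __post_init__(self) -> None:
        for c in self.clusters:
            if not (0.0 < c.p_value <= 1.0):
                raise ValueError("cluster p-values must lie in (0, 1]")
            if c.mass <= 0:
                raise ValueError("cluster mass must be positive")
        starts = [c.start for c in self.clusters]
        if starts != sorted(starts):
            raise ValueError("clusters must be ordered")


def _t_stats(dev: np.ndarray) -> np.ndarray:
    """One-sample t across axis 0 (folds); zero-variance columns give t=0."""
    n = dev.shape[0]
    mean = dev.mean(axis=0)
    sd = dev.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def _find_clusters(t: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    above = t > threshold
    clusters = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            clusters.append((start, i - 1, float(t[start:i].sum())))
            start = None
    if start is not None:
        clusters.append((start, t.size - 1, float(t[start:].sum())))
    return clusters


def _max_cluster_mass(tmat: np.ndarray, threshold: float) -> np.ndarray:
    """Row-wise maximal cluster mass of suprathreshold runs (vectorized).

    Requires threshold > 0 so that masses accumulate monotonically.
    """
    if threshold <= 0:
        return np.array([
            max((m for _, _, m in _find_clusters(row, threshold)), default=0.0)
            for row in tmat])
    above = tmat > threshold
    contrib = np.where(above, tmat, 0.0)
    cs = np.cumsum(contrib, axis=1)
    # cumsum value at the most recent sub-threshold position (0 before any)
    resets = np.where(above, 0.0, cs)
    floor = np.maximum.accumulate(resets, axis=1)
    seg = np.where(above, cs - floor, 0.0)
    return seg.max(axis=1)


def _sign_flips(n_folds: int, n_perm: int, seed: int) -> tuple[np.ndarray, bool]:
    if 2 ** n_folds <= n_perm:
        flips = np.array(list(itertools.product((1.0, -1.0), repeat=n_folds)))
        return flips, True
    rng = np.random.default_rng(seed)
    flips = rng.choice([1.0, -1.0], size=(n_perm, n_folds))
    return flips, False


def cluster_permutation_onesample(
    scores: np.ndarray,
    mu0: float = 0.5,
    forming_p: float = 0.05,
    n_perm: int = 1024,
    seed: int = 0,
    alternative: str = "greater",
) -> ClusterTestResult:
    """Cluster permutation test of fold scores against chance.

    Parameters
    ----------
    scores : ndarray (n_folds, n_timepoints)
    mu0 : float
        Chance level (0.5 for ROC-AUC).
    forming_p : float
        One-sided tail probability defining the cluster-forming t threshold.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n_folds, n_t = scores.shape
    if n_folds < 3:
        raise ValueError("need at least 3 folds")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    dev = scores - mu0
    if alternative == "less":
        dev = -dev
    threshold = float(stats.t.ppf(1.0 - forming_p, df=n_folds - 1))
    flips, exact = _sign_flips(n_folds, n_perm, seed)
    n_eff = flips.shape[0]
    # the observed statistic goes through the identical vectorized path as
    # the null (prepended identity row), so the p > 0 guarantee holds even
    # in numerically degenerate (near-zero variance) columns
    rows = np.vstack([np.ones((1, n_folds)), flips])
    # sign flips leave per-column sum of squares invariant; only means move
    ss = np.sum(dev ** 2, axis=0)
    means = rows @ dev / n_folds
    var = np.maximum((ss[None, :] - n_folds * means ** 2) / (n_folds - 1), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmat = means / np.sqrt(var / n_folds)
    tmat = np.where(np.isnan(tmat), 0.0, tmat)       # 0/0 -> no evidence
    t_obs = tmat[0]
    observed = _find_clusters(t_obs, threshold)
    null_max = _max_cluster_mass(tmat[1:], threshold)
    clusters = []
    for start, end, mass in observed:
        if exact:
            p = float(np.mean(null_max >= mass - 1e-12))
        else:
            p = float((1 + np.sum(null_max >= mass - 1e-12)) / (1 + n_eff))
        clusters.append(Cluster(start, end, mass, p))
    return ClusterTestResult(clusters, threshold, n_eff, seed, alternative, exact)


def significant_intervals(
    res: ClusterTestResult,
    alpha: float = 0.05,
    time_axis: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """Start/end times (seconds) of clusters with p < alpha."""
    out = []
    for c in res.clusters:
        if c.p_value < alpha:
            if time_axis is None:
                out.append((float(c.start), float(c.end)))
            else:
                t = np.asarray(time_axis, dtype=float)
                if c.end >= t.size:
                    raise ValueError("time axis shorter than tested timepoints")
                out.append((float(t[c.start]), float(t[c.end])))
    return out
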