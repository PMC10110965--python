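"""Activation patterns: interpretable encoding directions from decoder weights.

A linear decoder's weights are not directly interpretable — a channel can
receive a large weight purely to cancel correlated noise.  The corresponding
activation pattern a = Cov(X) w / (w' Cov(X) w) is: it is the forward
projection of the decoded latent signal onto the channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["activation_pattern", "PatternTimeline", "pattern_timeline"]


def activation_pattern(weights: np.ndarray, X_train: np.ndarray) -> np.ndarray:
    """Pattern a = Sigma_X w / (w' Sigma_X w) for a single decision function.

    ``X_train`` must be the (standardized) data the decoder was fitted on;
    its row covariance supplies Sigma_X.  The direction of a is invariant to
    positive rescaling of X.
    """
    w = np.asarray(weights, dtype=float)
    if np.allclose(w, 0.0):
        raise ValueError("zero weight vector: pattern undefined")
    X = np.asarray(X_train, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    Xc = X - X.mean(axis=0, keepdims=True)
    cov_w = Xc.T @ (Xc @ w) / (X.shape[0] - 1)     # Sigma_X w without forming Sigma
    denom = w @ cov_w
    if denom <= 0:
        raise ValueError("degenerate training covariance")
    return cov_w / denom


@dataclass
class PatternTimeline:
    """Channel x time-bin summary of activation patterns."""

    values: np.ndarray          # (n_channels, n_bins)
    bin_edges_s: np.ndarray     # (n_bins + 1,)
    statistic: str
    channel_ids: list[str] | None = None

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def pattern_timeline(
    patterns: np.ndarray,
    times: np.ndarray,
    bin_s: float = 0.2,
    statistic: str = "signed-mean",
    channel_ids: list[str] | None = None,
) -> PatternTimeline:
    """Average patterns (channels x timepoints) into fixed-width time bins.

    ``statistic`` is ``"signed-mean"`` (mean of values) or
    ``"mean-magnitude"`` (mean of absolute values).  The last, possibly
    partial, bin is included.  For display stability the sign of the whole
    timeline is fixed so that the channel with the largest absolute value in
    the peak bin is positive (signed-mean only).
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    if statistic not in ("signed-mean", "mean-magnitude"):
        raise ValueError(f"unknown statistic {statistic!r}")
    P = np.atleast_2d(np.asarray(patterns, dtype=float))
    t = np.asarray(times, dtype=float)
    if P.shape[1] != t.size:
        raise ValueError("patterns and times disagree in length")
    dt = np.diff(t)
    if t.size > 1 and not np.allclose(dt, dt[0]):
        raise ValueError("time axis must be uniform")
    duration = t[-1] - t[0]
    n_bins = max(1, int(np.ceil(duration / bin_s - 1e-9)))
    edges = t[0] + bin_s * np.arange(n_bins + 1)
    idx = np.minimum(((t - t[0]) / bin_s).astype(int), n_bins - 1)
    vals = np.zeros((P.shape[0], n_bins))
    for b in range(n_bins):
        cols = idx == b
        if cols.any():
            block = P[:, cols]
            vals[:, b] = np.abs(block).mean(axis=1) if statistic == "mean-magnitude" \
                else block.mean(axis=1)
    if statistic == "signed-mean" and vals.size:
        peak_bin = np.argmax(np.abs(vals).max(axis=0))
        peak_ch = np.argmax(np.abs(vals[:, peak_bin]))
        if vals[peak_ch, peak_bin] < 0:
            vals = -vals
    return PatternTimeline(vals, edges, statistic, channel_ids)
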