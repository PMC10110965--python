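"""SOBI blind source separation.

Second-order blind identification: whiten at lag zero, then find the
orthogonal rotation that jointly diagonalizes a set of symmetrized time-lagged
covariance matrices (Jacobi/Givens sweeps).  Works because temporally
correlated sources with distinct autocorrelations share no lagged
cross-covariance.  No dimensionality reduction: component count equals channel
count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import EpochArray

__all__ = ["UnmixingModel", "lagged_covariance", "joint_diagonalize", "sobi",
           "amari_index"]


@dataclass
class UnmixingModel:
    whitener: np.ndarray
    rotation: np.ndarray
    mixing: np.ndarray
    unmixing: np.ndarray
    lags: list[int]

    def __post_init__(self) -> None:
        resid = self.unmixing @ self.mixing - np.eye(self.mixing.shape[1])
        if np.max(np.abs(resid)) > 1e-8:
            raise ValueError("unmixing x mixing deviates from identity")
        VtV = self.rotation.T @ self.rotation - np.eye(self.rotation.shape[0])
        if np.max(np.abs(VtV)) > 1e-10:
            raise ValueError("rotation is not orthonormal")


def lagged_covariance(data: np.ndarray, lag: int) -> np.ndarray:
    """Symmetrized lagged covariance C(tau) = (R(tau) + R(tau)') / 2."""
    X = np.asarray(data, dtype=float)
    n_samples = X.shape[1]
    if lag >= n_samples:
        raise ValueError(f"lag {lag} >= {n_samples} samples")
    X = X - X.mean(axis=1, keepdims=True)
    R = X[:, : n_samples - lag] @ X[:, lag:].T / (n_samples - lag)
    return (R + R.T) / 2.0


def _off_criterion(mats: np.ndarray) -> float:
    off = 0.0
    for M in mats:
        off += np.sum(M ** 2) - np.sum(np.diag(M) ** 2)
    return float(off)


def joint_diagonalize(
    matrices, tol: float = 1e-9, max_sweeps: int = 100,
) -> np.ndarray:
    """Orthogonal rotation approximately diagonalizing all input matrices.

    Jacobi strategy: for every index pair, the Givens angle minimizing the
    summed squared off-diagonals is the principal direction of the 2x2
    structure matrix G = sum_k h_k h_k' with h_k = (Mpp - Mqq, 2 Mpq).
    Terminates when the largest rotation sine in a sweep drops below ``tol``.
    """
    mats = np.array([np.asarray(M, dtype=float) for M in matrices])
    if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
        raise ValueError("all matrices must be square and same size")
    for M in mats:
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("matrices must be symmetric")
    n = mats.shape[1]
    V = np.eye(n)
    for _ in range(max_sweeps):
        max_s = 0.0
        for p in range(n - 1):
            for q in range(p + 1, n):
                h1 = mats[:, p, p] - mats[:, q, q]
                h2 = 2.0 * mats[:, p, q]
                g11 = h1 @ h1
                g12 = h1 @ h2
                g22 = h2 @ h2
                ton = g11 - g22
                toff = 2.0 * g12
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) < tol:
                    continue
                max_s = max(max_s, abs(s))
                rot_p = c * mats[:, :, p] + s * mats[:, :, q]
                rot_q = -s * mats[:, :, p] + c * mats[:, :, q]
                mats[:, :, p], mats[:, :, q] = rot_p, rot_q
                rot_p = c * mats[:, p, :] + s * mats[:, q, :]
                rot_q = -s * mats[:, p, :] + c * mats[:, q, :]
                mats[:, p, :], mats[:, q, :] = rot_p, rot_q
                vp = c * V[:, p] + s * V[:, q]
                vq = -s * V[:, p] + c * V[:, q]
                V[:, p], V[:, q] = vp, vq
        if max_s < tol:
            break
    return V


def sobi(
    ep: EpochArray,
    lags: range | list[int] = range(1, 51),
    eps: float = 0.0,
    tol: float = 1e-9,
    max_sweeps: int = 100,
) -> tuple[UnmixingModel, EpochArray]:
    """SOBI decomposition of epoched data (epochs concatenated along time).

    Returns the model and the component-space epochs (space tag
    ``"component"``); mixing columns are unit-norm, components ordered by
    descending back-projected variance with positive max-abs loading.
    """
    if ep.n_channels < 2:
        raise ValueError("need at least 2 channels")
    lags = list(lags)
    X = ep.data.transpose(1, 0, 2).reshape(ep.n_channels, -1)
    if max(lags) >= X.shape[1]:
        raise ValueError("largest lag exceeds available samples")
    X = X - X.mean(axis=1, keepdims=True)
    C0 = X @ X.T / (X.shape[1] - 1)
    evals, E = np.linalg.eigh(C0)
    if evals.min() <= 0 and eps == 0.0:
        raise np.linalg.LinAlgError(
            "rank-deficient data: whitening failed; pass eps > 0 to regularize")
    evals = evals + eps
    whitener = (E / np.sqrt(evals)).T            # D^-1/2 E'
    Z = whitener @ X
    lagged = [lagged_covariance(Z, lag) for lag in lags]
    V = joint_diagonalize(lagged, tol=tol, max_sweeps=max_sweeps)
    unmix0 = V.T @ whitener
    mix0 = E @ (np.sqrt(evals)[:, None] * V)      # pinv(unmix0)
    norms = np.linalg.norm(mix0, axis=0)
    order = np.argsort(-norms)
    mixing = mix0[:, order] / norms[order]
    unmixing = unmix0[order] * norms[order][:, None]
    signs = np.sign(mixing[np.argmax(np.abs(mixing), axis=0),
                           np.arange(mixing.shape[1])])
    signs[signs == 0] = 1.0
    mixing = mixing * signs
    unmixing = unmixing * signs[:, None]
    model = UnmixingModel(whitener, V, mixing, unmixing, lags)
    comp = np.einsum("kc,tcs->tks", unmixing, ep.data)
    names = [f"IC{k + 1:03d}" for k in range(ep.n_channels)]
    ep_comp = replace(ep, data=comp, channel_ids=names, space="component")
    return model, ep_comp


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant separation error of P = unmixing @ mixing.

    0 means perfect separation (P a scaled permutation); normalized to [0, 1].
    """
    P = np.abs(np.asarray(P, dtype=float))
    n = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * n * (n - 1)))
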