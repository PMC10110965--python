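"""LCMV beamformer: "virtual SEEG" source time courses from scalp epochs.

A spatial filter w at a grid point with forward gain l minimizes output power
w' C w subject to the unit-gain constraint w' l = 1, giving
w = C^-1 l / (l' C^-1 l).  The dipole orientation is chosen to maximize output
power (scalar, max-power beamformer): the eigenvector of the smallest
eigenvalue of L' C^-1 L.  Filters are computed at the grid points nearest the
midpoints of SEEG bipolar pairs, yielding one reconstructed signal per pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .containers import EpochArray
from .forward import HeadModel, LeadField
from .preprocessing import BipolarMap

__all__ = ["SourceGrid", "CovarianceEstimate", "SpatialFilter", "build_grid",
           "estimate_covariance", "lcmv_weights", "map_bipolar_to_grid",
           "reconstruct"]


@dataclass
class SourceGrid:
    """Regular cubic lattice of candidate source locations inside the head."""

    points_mm: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=float)
        if self.points_mm.ndim != 2 or self.points_mm.shape[1] != 3:
            raise ValueError("points must be (n, 3)")

    @property
    def n_points(self) -> int:
        return self.points_mm.shape[0]


@dataclass
class CovarianceEstimate:
    matrix: np.ndarray
    window_s: tuple[float, float]
    shrinkage: float

    def __post_init__(self) -> None:
        C = np.asarray(self.matrix, dtype=float)
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        self.matrix = (C + C.T) / 2.0


@dataclass
class SpatialFilter:
    """Unit-gain spatial filters, one row per target grid point."""

    weights: np.ndarray          # (n_points, n_channels)
    orientations: np.ndarray     # (n_points, 3)
    grid_indices: np.ndarray
    channel_ids: list[str]
    output_names: list[str]


def build_grid(model: HeadModel, spacing_mm: float = 5.0,
               radius_mm: float | None = None) -> SourceGrid:
    """Cubic lattice (including the origin) clipped to the head volume.

    ``radius_mm`` defaults to the model sphere radius; pass a smaller brain
    radius to keep sources away from the surface.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    R = radius_mm if radius_mm is not None else model.sphere_radius_mm
    if R <= 0 or spacing_mm > 2 * R:
        raise ValueError("empty grid: spacing larger than the head")
    n = int(np.floor(R / spacing_mm))
    axis = np.arange(-n, n + 1) * spacing_mm
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= R]
    if pts.size == 0:
        raise ValueError("empty grid: spacing larger than the head")
    return SourceGrid(pts, spacing_mm)


def estimate_covariance(
    ep: EpochArray,
    window_s: tuple[float, float] | None = None,
    shrinkage: float = 0.05,
) -> CovarianceEstimate:
    """Sample covariance over concatenated within-window samples, with
    diagonal loading C <- (1-lam) C + lam mean(diag(C)) I."""
    if ep.n_trials < 2:
        raise ValueError("need at least 2 trials")
    times = ep.times
    if window_s is None:
        window_s = (float(times[0]), float(times[-1]))
    mask = (times >= window_s[0]) & (times <= window_s[1])
    if not mask.any():
        raise ValueError("covariance window outside the epoch")
    X = ep.data[:, :, mask].transpose(1, 0, 2).reshape(ep.n_channels, -1)
    X = X - X.mean(axis=1, keepdims=True)
    C = X @ X.T / (X.shape[1] - 1)
    lam = float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    mu = np.mean(np.diag(C))
    if lam == 0.0 and (mu == 0 or np.linalg.cond(C) > 1e12):
        warnings.warn("covariance is (near-)singular; consider shrinkage > 0")
    C = (1.0 - lam) * C + lam * mu * np.eye(C.shape[0])
    return CovarianceEstimate(C, window_s, lam)


def _lcmv_single(L: np.ndarray, Cinv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weights and orientation for one grid point; L is (channels, 3) or
    (channels,) for a fixed orientation."""
    if L.ndim == 1:
        u = np.array([1.0])
        l = L
    else:
        G = L.T @ Cinv @ L                       # 3x3
        evals, evecs = np.linalg.eigh(G)
        # smallest eigenvalue of G maximizes output power; ignore the null
        # space of a rank-deficient lead field (no gain in that orientation)
        valid = evals > 1e-12 * evals.max()
        if not valid.any():
            raise np.linalg.LinAlgError("lead field has no usable orientation")
        u = evecs[:, np.argmax(valid)]           # first valid = smallest
        if u[np.argmax(np.abs(u))] < 0:
            u = -u
        l = L @ u
    denom = l @ Cinv @ l
    if denom <= 0 or not np.isfinite(denom):
        raise np.linalg.LinAlgError(
            "degenerate LCMV denominator; increase covariance shrinkage")
    w = Cinv @ l / denom
    return w, u


def lcmv_weights(
    leadfield: LeadField,
    cov: CovarianceEstimate,
    point_indices: np.ndarray | None = None,
    output_names: list[str] | None = None,
) -> SpatialFilter:
    """Max-power scalar LCMV filters at the selected grid points."""
    try:
        Cinv = np.linalg.inv(cov.matrix)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular covariance; increase shrinkage") from err
    idx = np.arange(leadfield.n_sources) if point_indices is None \
        else np.asarray(point_indices)
    W = np.empty((idx.size, leadfield.n_channels))
    U = np.empty((idx.size, 3))
    for k, j in enumerate(idx):
        W[k], U[k] = _lcmv_single(leadfield.gain[:, j, :], Cinv)
    names = output_names or [f"src{j:04d}" for j in idx]
    return SpatialFilter(W, U, idx, list(leadfield.channel_ids), names)


def map_bipolar_to_grid(bmap: BipolarMap | np.ndarray, grid: SourceGrid) -> np.ndarray:
    """Grid index nearest each bipolar midpoint; ties -> lowest index.

    Accepts a :class:`BipolarMap` or a bare (n, 3) array of midpoints.
    """
    if grid.n_points == 0:
        raise ValueError("empty grid")
    mids = bmap.midpoints_mm if isinstance(bmap, BipolarMap) else np.atleast_2d(bmap)
    d = cdist(mids, grid.points_mm)
    dmin = d.min(axis=1, keepdims=True)
    # first index within numerical tie tolerance of the minimum
    return np.argmax(d <= dmin + 1e-9, axis=1)


def reconstruct(ep_scalp: EpochArray, filters: SpatialFilter) -> EpochArray:
    """Apply spatial filters to scalp epochs -> source-space EpochArray."""
    if list(ep_scalp.channel_ids) != list(filters.channel_ids):
        raise ValueError("filter channel order does not match epochs")
    data = np.einsum("pc,tcs->tps", filters.weights, ep_scalp.data)
    return replace(
        ep_scalp, data=data, channel_ids=list(filters.output_names),
        space="source",
    )
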