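"""LCMV beamformer: grid, covariance, weights, mapping, reconstruction."""

import numpy as np
import pytest
from scipy.optimize import minimize

from vseeg.beamformer import (SourceGrid, build_grid, estimate_covariance,
                              lcmv_weights, map_bipolar_to_grid, reconstruct)
from vseeg.containers import EpochArray
from vseeg.forward import HeadModel, LeadField, lead_field
from vseeg.geometry import make_geometry
from vseeg.preprocessing import BipolarMap, epoch
from vseeg import default_sources, make_task_schedule, simulate_subject

MODEL = HeadModel()


def _epochs_from_data(data, fs=100.0, first_sample=0):
    n_trials, n_ch, _ = data.shape
    return EpochArray(
        data, fs, first_sample,
        np.array(["OLD", "NEW"] * (n_trials // 2) + ["OLD"] * (n_trials % 2),
                 dtype=object),
        np.ones(n_trials, bool), np.full(n_trials, 0.6), "s",
        [f"c{i}" for i in range(n_ch)], "scalp")


class TestGrid:
    def test_lattice_spacing_is_5mm(self):
        grid = build_grid(MODEL, 5.0, radius_mm=40.0)
        from scipy.spatial.distance import cdist
        d = cdist(grid.points_mm, grid.points_mm)
        np.fill_diagonal(d, np.inf)
        assert abs(d.min() - 5.0) < 1e-9

    def test_all_points_inside_radius(self):
        grid = build_grid(MODEL, 5.0, radius_mm=60.0)
        assert np.all(np.linalg.norm(grid.points_mm, axis=1) <= 60.0)

    def test_point_count_matches_brute_force_enumeration(self):
        spacing, R = 5.0, 80.0
        count = 0
        n = int(R // spacing)
        for i in range(-n, n + 1):        # independent exhaustive enumeration
            for j in range(-n, n + 1):
                for k in range(-n, n + 1):
                    if spacing * np.sqrt(i * i + j * j + k * k) <= R:
                        count += 1
        grid = build_grid(MODEL, spacing, radius_mm=R)
        assert grid.n_points == count

    def test_oversized_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_grid(MODEL, 500.0, radius_mm=80.0)


class TestCovariance:
    def test_white_noise_gives_identity(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((100, 6, 1000))   # 1e5 samples
        cov = estimate_covariance(_epochs_from_data(data), shrinkage=0.0)
        C = cov.matrix
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 0.05
        np.testing.assert_allclose(np.diag(C), 1.0, atol=0.05)

    def test_full_shrinkage_is_spherical(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((10, 4, 50)) * np.arange(1, 5)[None, :, None]
        cov = estimate_covariance(_epochs_from_data(data), shrinkage=1.0)
        C = cov.matrix
        assert np.allclose(C, C[0, 0] * np.eye(4))

    def test_eigenvalue_floor_from_shrinkage(self):
        rng = np.random.default_rng(2)
        data = np.repeat(rng.standard_normal((10, 1, 50)), 4, axis=1)  # rank 1
        cov = estimate_covariance(_epochs_from_data(data), shrinkage=0.05)
        evals = np.linalg.eigvalsh(cov.matrix)
        mu = np.mean(np.diag(cov.matrix))
        assert evals.min() >= 0.05 * mu * (1 - 1e-9)

    def test_singularity_warning_without_shrinkage(self):
        data = np.repeat(np.random.default_rng(3).standard_normal((8, 1, 40)),
                         3, axis=1)
        with pytest.warns(UserWarning):
            estimate_covariance(_epochs_from_data(data), shrinkage=0.0)


def _leadfield_from_matrix(L3):
    """Wrap a (channels, 3) gain as a one-point LeadField."""
    return LeadField(L3[:, None, :], [f"c{i}" for i in range(L3.shape[0])],
                     np.zeros((1, 3)))


class TestLCMV:
    def test_identity_covariance_unit_gain_basis_vector(self):
        # fixed orientation, C = I, l = e1  ->  w = e1
        from vseeg.beamformer import _lcmv_single
        n = 6
        w, _ = _lcmv_single(np.eye(n)[:, 0], np.eye(n))
        np.testing.assert_allclose(w, np.eye(n)[0], atol=1e-12)

    def test_unit_gain_constraint_random_spd(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = 8
            A = rng.standard_normal((n, n))
            C = A @ A.T + n * np.eye(n)
            L = rng.standard_normal((n, 3))
            cov = CovWrap(C)
            filt = lcmv_weights(_leadfield_from_matrix(L), cov)
            l = L @ filt.orientations[0]
            assert abs(filt.weights[0] @ l - 1.0) < 1e-9

    def test_weights_match_constrained_qp_oracle(self):
        """w from the closed form equals the numeric minimizer of w'Cw
        subject to w'l = 1 (8-channel problems)."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = 8
            A = rng.standard_normal((n, n))
            C = A @ A.T + n * np.eye(n)
            L = rng.standard_normal((n, 3))
            filt = lcmv_weights(_leadfield_from_matrix(L), CovWrap(C))
            l = L @ filt.orientations[0]
            res = minimize(lambda w: w @ C @ w, np.ones(n) / (l.sum() or 1.0),
                           constraints=[{"type": "eq",
                                         "fun": lambda w: w @ l - 1.0}],
                           method="SLSQP",
                           options={"maxiter": 500, "ftol": 1e-14})
            np.testing.assert_allclose(filt.weights[0], res.x, atol=1e-6)

    def test_singular_covariance_advises_shrinkage(self):
        L = np.eye(4)[:, :3]
        cov = CovWrap(np.zeros((4, 4)))
        with pytest.raises(np.linalg.LinAlgError):
            lcmv_weights(_leadfield_from_matrix(L), cov)


class CovWrap:
    """Minimal stand-in exposing the CovarianceEstimate interface."""

    def __init__(self, C):
        self.matrix = C
        self.window_s = (0.0, 1.0)
        self.shrinkage = 0.0


class TestMapping:
    grid = SourceGrid(np.array([[0.0, 0, 0], [5.0, 0, 0], [0, 5.0, 0],
                                [5.0, 5.0, 0]]), 5.0)

    def _bmap(self, mids):
        mids = np.atleast_2d(mids)
        return BipolarMap([("a", "b")] * len(mids), mids,
                          [f"p{i}" for i in range(len(mids))])

    def test_exact_midpoint_maps_to_itself(self):
        idx = map_bipolar_to_grid(self._bmap([[5.0, 0, 0]]), self.grid)
        assert idx[0] == 1

    def test_equidistant_tie_takes_lowest_index(self):
        idx = map_bipolar_to_grid(self._bmap([[2.5, 2.5, 0]]), self.grid)
        assert idx[0] == 0

    def test_distance_bound_inside_hull(self):
        model = HeadModel()
        grid = build_grid(model, 5.0, radius_mm=50.0)
        rng = np.random.default_rng(0)
        mids = rng.uniform(-20, 20, size=(50, 3))
        idx = map_bipolar_to_grid(self._bmap(mids), grid)
        d = np.linalg.norm(grid.points_mm[idx] - mids, axis=1)
        assert np.all(d <= np.sqrt(3) / 2 * 5.0 + 1e-9)


class TestReconstruct:
    def test_linearity_and_channel_count(self):
        rng = np.random.default_rng(0)
        ep = _epochs_from_data(rng.standard_normal((6, 5, 20)))
        from vseeg.beamformer import SpatialFilter
        W = rng.standard_normal((3, 5))
        filt = SpatialFilter(W, np.tile([0, 0, 1.0], (3, 1)),
                             np.arange(3), ep.channel_ids, ["a", "b", "c"])
        out = reconstruct(ep, filt)
        assert out.n_channels == 3 and out.space == "source"
        ep2 = _epochs_from_data(2.0 * ep.data)
        np.testing.assert_allclose(reconstruct(ep2, filt).data, 2 * out.data,
                                   rtol=1e-12)

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        ep = _epochs_from_data(rng.standard_normal((6, 5, 20)))
        from vseeg.beamformer import SpatialFilter
        filt = SpatialFilter(np.zeros((2, 5)), np.zeros((2, 3)),
                             np.arange(2), ["x"] * 5, ["a", "b"])
        with pytest.raises(ValueError):
            reconstruct(ep, filt)


class TestSingleSourceRecovery:
    """Forward-simulate a single deep dipole, beamform back at its location."""

    @pytest.fixture(scope="class")
    def recovered(self):
        schedule = make_task_schedule(1, 8, seed=0, inter_block_gap_s=2.0)
        geometry = make_geometry(24, 2, 6, seed=1)
        sources = default_sources(1, seed=5)
        scalp, _, gt = simulate_subject(schedule, geometry, sources,
                                        snr=np.inf, accuracy=1.0, fs=256,
                                        seed=2)
        ep = epoch(scalp, gt.schedule, tmin_s=-0.1, tmax_s=0.9,
                   baseline=None, space="scalp")
        src_pos = gt.source_set.positions
        lf = lead_field(geometry, src_pos, HeadModel(), "scalp")
        cov = estimate_covariance(ep, shrinkage=0.05)
        filt = lcmv_weights(lf, cov)
        out = reconstruct(ep, filt)
        truth = gt.source_set.sources[0].baseline.sample(out.times) + \
            0.5 * gt.source_set.sources[0].differential.sample(out.times)
        return out, truth, ep, gt, geometry, lf

    def test_noiseless_waveform_recovered(self, recovered):
        out, truth, *_ = recovered
        rec = out.data[out.labels == "OLD"][0, 0]
        corr = np.corrcoef(rec, truth)[0, 1]
        assert corr > 0.99

    def test_noiseless_outputs_fully_correlated_everywhere(self, recovered):
        """With a single active source and no noise every filter output is a
        scaled copy of the source waveform — the extreme of leakage."""
        out, truth, ep, gt, geometry, lf = recovered
        src = np.asarray(gt.source_set.positions[0])
        probe = src - 15.0 * src / np.linalg.norm(src)
        lf2 = lead_field(geometry, probe[None, :], HeadModel(), "scalp")
        cov = estimate_covariance(ep, shrinkage=0.05)
        out2 = reconstruct(ep, lcmv_weights(lf2, cov))
        assert abs(np.corrcoef(out2.data[0, 0], truth)[0, 1]) > 0.99

    def test_leakage_decays_with_distance_under_noise(self):
        """At finite SNR, beamformer outputs at probes marching away from the
        source stay correlated with the source waveform but decreasingly so."""
        schedule = make_task_schedule(2, 8, seed=0, inter_block_gap_s=2.0)
        geometry = make_geometry(24, 2, 6, seed=1)
        sources = default_sources(1, seed=5)
        scalp, _, gt = simulate_subject(schedule, geometry, sources,
                                        snr={"scalp": 1.0, "depth": 10.0},
                                        accuracy=1.0, fs=256, seed=9)
        ep = epoch(scalp, gt.schedule, tmin_s=-0.1, tmax_s=0.9,
                   baseline=None, space="scalp")
        src = np.asarray(gt.source_set.positions[0])
        direction = -src / np.linalg.norm(src)
        probes = np.array([src, src + 20 * direction, src + 45 * direction])
        lf3 = lead_field(geometry, probes, HeadModel(), "scalp")
        cov = estimate_covariance(ep, shrinkage=0.05)
        out3 = reconstruct(ep, lcmv_weights(lf3, cov))
        truth = gt.source_set.sources[0].baseline.sample(out3.times)
        evoked = out3.data.mean(axis=0)
        corrs = [abs(np.corrcoef(evoked[i], truth)[0, 1]) for i in range(3)]
        assert corrs[0] > corrs[2]
        assert corrs[1] > corrs[2]

    def test_invariance_to_consistent_channel_reordering(self, recovered):
        out, truth, ep, gt, geometry, lf = recovered
        rng = np.random.default_rng(3)
        perm = rng.permutation(ep.n_channels)
        ep_p = ep.select_channels(perm)
        lf_p = LeadField(lf.gain[perm], [lf.channel_ids[i] for i in perm],
                         lf.source_positions_mm)
        for e, l in [(ep, lf), (ep_p, lf_p)]:
            cov = estimate_covariance(e, shrinkage=0.05)
            filt = lcmv_weights(l, cov)
            filt.channel_ids = list(e.channel_ids)
            rec = reconstruct(e, filt)
            np.testing.assert_allclose(np.abs(rec.data[0, 0]),
                                       np.abs(out.data[0, 0]), atol=1e-6)
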