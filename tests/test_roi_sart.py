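"""SART projector geometry and the ROI-weighted update: hand-checked ray
traces, adjoint consistency, reduction to classic SART at k = 1, and
convergence against a dense least-squares oracle."""

import numpy as np
import pytest

from tempsub import SartState, build_projector, forward_project, sart_iterate


def plain_sart_sweep(W, l_g, measured, v, relax, n_detectors, n_angles):
    """Independent classic SART reference: dense numpy, no ROI factors.

    One angle-sequential sweep of
    v_j += relax * sum_i w_ij (p_i - (Wv)_i / l_g_i) / sum_i w_ij.
    """
    W = np.asarray(W.todense()) if hasattr(W, "todense") else np.asarray(W)
    v = v.copy()
    for a in range(n_angles):
        sl = slice(a * n_detectors, (a + 1) * n_detectors)
        Wb, lg = W[sl], l_g[sl]
        resid = np.zeros(n_detectors)
        hit = lg > 0
        resid[hit] = measured[sl][hit] - (Wb @ v)[hit] / lg[hit]
        den = Wb.sum(axis=0)
        num = Wb.T @ resid
        upd = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        v += relax * upd
    return v


class TestBuildProjector:
    def test_horizontal_ray_through_2x2_top_row(self):
        geom = build_projector(2, [0.0], 2)
        entries = geom.ray_entries(0)  # detector offset -0.5 -> y = 0.5
        assert sorted(((r, c), w) for (r, c), w in entries) == [
            ((0, 0), pytest.approx(1.0)),
            ((0, 1), pytest.approx(1.0)),
        ]
        assert geom.l_v[0] == pytest.approx(2.0)
        assert geom.l_g[0] == pytest.approx(2.0)

    def test_full_grid_roi_gives_unit_k(self):
        geom = build_projector(8, np.linspace(0, np.pi, 6, endpoint=False), 8)
        hit = geom.l_g > 0
        np.testing.assert_allclose(geom.k_roi[hit], 1.0, atol=1e-9)

    def test_half_grid_roi_halves_k_for_horizontal_rays(self):
        roi = np.zeros((4, 4), bool)
        roi[:, :2] = True  # left half
        geom = build_projector(4, [0.0], 4, roi)
        np.testing.assert_allclose(geom.k_roi, 0.5, atol=1e-9)

    def test_k_roi_bounds(self):
        rng = np.random.default_rng(41)
        roi = rng.random((8, 8)) > 0.5
        geom = build_projector(8, np.linspace(0, np.pi, 10, endpoint=False), 12, roi)
        assert (geom.k_roi >= -1e-9).all()
        assert (geom.k_roi <= 1.0 + 1e-9).all()
        assert (geom.l_v <= geom.l_g + 1e-9).all()

    def test_diagonal_ray_lengths_sum_to_chord(self):
        geom = build_projector(4, [np.pi / 4], 6)
        W = np.asarray(geom.weights.todense())
        for i in range(6):
            if geom.l_g[i] > 0:
                assert W[i].sum() == pytest.approx(geom.l_g[i], abs=1e-9)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            build_projector(1, [0.0], 4)
        with pytest.raises(ValueError):
            build_projector(4, [], 4)


class TestForwardAdjoint:
    def test_inner_product_consistency(self):
        """<W v, p> == <v, W^T p> on random instances."""
        rng = np.random.default_rng(43)
        geom = build_projector(6, np.linspace(0, np.pi, 5, endpoint=False), 8)
        W = geom.weights
        for _ in range(5):
            v = rng.random(36)
            p = rng.random(geom.n_rays)
            lhs = float((W @ v) @ p)
            rhs = float(v @ (W.T @ p))
            assert lhs == pytest.approx(rhs, rel=1e-12)


class TestSartIterate:
    @pytest.fixture
    def system8(self):
        n = 8
        geom = build_projector(n, np.linspace(0, np.pi, 18, endpoint=False), n)
        truth = np.zeros((n, n))
        truth[2:6, 2:6] = 1.0
        measured = forward_project(geom, truth)
        return geom, truth.ravel(), measured

    def test_zero_fixed_point(self, system8):
        geom, _, _ = system8
        state = SartState(volume=np.zeros(geom.grid_size**2))
        state = sart_iterate(state, geom, np.zeros(geom.n_rays), n_iter=5)
        np.testing.assert_array_equal(state.volume, 0.0)

    def test_residual_monotone_and_recovers_phantom(self, system8):
        geom, truth, measured = system8
        state = SartState(volume=np.zeros(64), relax=1.0)
        state = sart_iterate(state, geom, measured, n_iter=20)
        rh = state.residual_history
        assert len(rh) == 20
        assert all(rh[i + 1] <= rh[i] + 1e-12 for i in range(19))
        rmse_rec = np.sqrt(np.mean((state.volume - truth) ** 2))
        rmse_zero = np.sqrt(np.mean(truth**2))
        assert rmse_rec < rmse_zero

    def test_matches_dense_least_squares_residual(self, system8):
        """After 20 sweeps the projection residual is within 20% (relative
        to the data norm) of the dense least-squares optimum."""
        geom, truth, measured = system8
        state = sart_iterate(SartState(volume=np.zeros(64)), geom, measured, 20)
        W = np.asarray(geom.weights.todense())
        lg = np.where(geom.l_g > 0, geom.l_g, 1.0)
        A = W / lg[:, None]
        v_ls, *_ = np.linalg.lstsq(A, measured, rcond=None)
        r_sart = np.linalg.norm(A @ state.volume - measured) / np.linalg.norm(measured)
        r_ls = np.linalg.norm(A @ v_ls - measured) / np.linalg.norm(measured)
        assert r_sart <= r_ls + 0.2

    def test_unit_k_reduces_to_plain_sart(self):
        """With a full-grid ROI the update equals classic SART per-voxel."""
        n = 8
        angles = np.linspace(0, np.pi, 10, endpoint=False)
        geom = build_projector(n, angles, n)
        rng = np.random.default_rng(47)
        truth = rng.random((n, n))
        measured = forward_project(geom, truth)
        v0 = rng.random(n * n)

        state = sart_iterate(
            SartState(volume=v0.copy(), relax=0.8), geom, measured, n_iter=1
        )
        ref = plain_sart_sweep(
            geom.weights, geom.l_g, measured, v0.copy(), 0.8, n, len(angles)
        )
        np.testing.assert_allclose(state.volume, ref, atol=1e-9)

    def test_roi_weighted_update_differs_from_plain(self):
        n = 8
        roi = np.zeros((n, n), bool)
        roi[:, : n // 2] = True
        angles = np.linspace(0, np.pi, 10, endpoint=False)
        geom_roi = build_projector(n, angles, n, roi)
        geom_full = build_projector(n, angles, n)
        rng = np.random.default_rng(53)
        truth = rng.random((n, n))
        measured = forward_project(geom_full, truth)
        a = sart_iterate(SartState(volume=np.zeros(n * n)), geom_roi, measured, 1)
        b = sart_iterate(SartState(volume=np.zeros(n * n)), geom_full, measured, 1)
        assert not np.allclose(a.volume, b.volume)

    def test_measured_length_mismatch(self):
        geom = build_projector(4, [0.0], 4)
        with pytest.raises(ValueError, match="rays"):
            sart_iterate(SartState(volume=np.zeros(16)), geom, np.zeros(3))

    def test_relaxation_bounds(self):
        with pytest.raises(ValueError):
            SartState(volume=np.zeros(4), relax=0.0)
        with pytest.raises(ValueError):
            SartState(volume=np.zeros(4), relax=2.5)
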