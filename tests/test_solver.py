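"""The alignment loop: adjoint gradients, fixed points, config, masking,
lift-over. Full-scale recovery runs live in test_acceptance.py."""

import numpy as np
import pytest

from stwarp.geometry import AffineTransform, LandmarkSet
from stwarp.objective import fit_contrast
from stwarp.raster import PointSet, RasterImage
from stwarp.solver import (
    AlignmentResult,
    LabelVolume,
    SolverConfig,
    _Workspace,
    lift_over_labels,
    matching_mask,
    run_lddmm,
    run_lddmm_3d_to_2d,
)
from stwarp.synthetic import VolumeSpec, generate_volume, volume_intensity


def _gauss_image(shape, dx, center, sigma, origin=(0.0, 0.0)):
    axes = [origin[k] + dx * (np.arange(shape[k]) + 0.5) for k in range(2)]
    yy, xx = np.meshgrid(*axes, indexing="ij")
    vals = np.exp(-((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2))
    return RasterImage(vals[None], axes)


@pytest.fixture
def tiny_pair():
    src = _gauss_image((12, 14), 50.0, (300, 350), 160.0)
    tgt = _gauss_image((12, 14), 50.0, (330, 320), 170.0)
    return src, tgt


class TestAdjointGradients:
    """The hand-written adjoint must agree with central finite differences
    of the matching + landmark energy (weights and contrast held fixed)."""

    def test_gradients_match_finite_differences(self, tiny_pair, rng):
        src, tgt = tiny_pair
        cfg = SolverConfig(niter=1, nt=3, a=300.0, sigma_M=0.5, sigma_P=2.0)
        lm = LandmarkSet(
            [[300.0, 350.0], [400.0, 200.0], [200.0, 500.0]],
            [[330.0, 330.0], [390.0, 210.0], [230.0, 480.0]],
        )
        ws = _Workspace(src, tgt, cfg, lm, embed_plane=False)
        Amat = np.array([[1.02, 0.03, 15.0], [-0.02, 0.98, -8.0], [0, 0, 1.0]])
        v = rng.normal(0, 8.0, size=(3, 2) + ws.vgrid_shape)
        w = rng.random(ws.N)
        _, s0 = ws.backward_sample(Amat, v)
        contrast = fit_contrast(s0, ws.J, weights=w, degree=3)
        M, P, gA, gV = ws.energy_and_grads(Amat, v, w, contrast)
        assert M > 0 and P > 0

        def total(Am, vs):
            m, p, _, _ = ws.energy_and_grads(Am, vs, w, contrast)
            return m + p

        eps = 1e-5
        for i in range(2):
            for j in range(3):
                Ap, Am_ = Amat.copy(), Amat.copy()
                Ap[i, j] += eps
                Am_[i, j] -= eps
                fd = (total(Ap, v) - total(Am_, v)) / (2 * eps)
                assert gA[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-8)
        for t, c, i, j in [(0, 0, 5, 6), (1, 1, 3, 9), (2, 0, 8, 2)]:
            vp, vm = v.copy(), v.copy()
            vp[t, c, i, j] += eps
            vm[t, c, i, j] -= eps
            fd = (total(Amat, vp) - total(Amat, vm)) / (2 * eps)
            assert gV[t, c, i, j] == pytest.approx(fd, rel=1e-3, abs=1e-10)


class TestSolverConfig:
    def test_defaults_follow_published_table(self):
        cfg = SolverConfig()
        assert (cfg.dx, cfg.sigma_M, cfg.sigma_R, cfg.sigma_P) == (30.0, 1.0, 5e5, 20.0)
        assert (cfg.sigma_A, cfg.sigma_B, cfg.a, cfg.p) == (5.0, 2.0, 500.0, 2.0)
        assert (cfg.niter, cfg.diffeo_start, cfg.nt) == (5000, 0, 3)
        assert (cfg.ep_L, cfg.ep_T, cfg.ep_V) == (2e-8, 2e-1, 2e3)

    def test_from_dict_accepts_published_names(self):
        cfg = SolverConfig.from_dict(
            {"sigmaM": 0.2, "epV": 50.0, "niter": 10, "T": [1.0, 2.0]}
        )
        assert cfg.sigma_M == 0.2 and cfg.ep_V == 50.0
        assert list(cfg.T0) == [1.0, 2.0]

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError, match="sigmaQ"):
            SolverConfig.from_dict({"sigmaQ": 1.0})

    def test_A_exclusive_with_L_T(self):
        with pytest.raises(ValueError):
            SolverConfig(A0=np.eye(3), T0=[0.0, 0.0])


class TestRunLddmm:
    def test_self_alignment_is_a_fixed_point(self, tiny_pair):
        """Source == target with identity init: the objective never rises
        above its epoch-0 value and the map stays within half a pixel."""
        src, _ = tiny_pair
        cfg = SolverConfig(
            niter=200, A0=np.eye(3), sigma_M=0.2, sigma_B=0.3, sigma_A=0.4,
            ep_L=1e-10, ep_T=1e-3, ep_V=1.0, contrast_degree=1,
        )
        res = run_lddmm(src, src, cfg)
        hist = res.loss_history[:, 3]
        assert hist[-1] <= hist[0] + 1e-12  # exact fixed point up to float noise
        assert np.linalg.norm(res.A.translation) < 25.0  # dx/2
        assert np.abs(res.v.samples).max() < 25.0

    def test_loss_history_is_deterministic(self, tiny_pair):
        src, tgt = tiny_pair
        cfg = SolverConfig(
            niter=40, sigma_M=0.2, sigma_B=0.3, sigma_A=0.4,
            ep_L=1e-10, ep_T=1e-3, ep_V=1.0, contrast_degree=1,
        )
        h1 = run_lddmm(src, tgt, cfg).loss_history
        h2 = run_lddmm(src, tgt, cfg).loss_history
        np.testing.assert_array_equal(h1, h2)

    def test_multichannel_source_rejected(self, tiny_pair):
        src, tgt = tiny_pair
        bad = RasterImage(np.repeat(src.values, 2, axis=0), src.axis_coords)
        with pytest.raises(ValueError, match="single-channel"):
            run_lddmm(bad, tgt, SolverConfig(niter=1))

    def test_nonfinite_abort_names_epoch(self, tiny_pair, monkeypatch):
        """If an energy term ever turns non-finite the solve aborts with
        the epoch index and step-size advice."""
        import stwarp.solver as solver_mod

        src, tgt = tiny_pair
        monkeypatch.setattr(
            solver_mod, "matching_energy", lambda *a, **k: float("nan")
        )
        with pytest.raises(RuntimeError, match="epoch 0"):
            run_lddmm(src, tgt, SolverConfig(niter=5, sigma_M=0.2))

    def test_landmark_initialization_used(self, tiny_pair):
        src, tgt = tiny_pair
        lm = LandmarkSet(
            [[100.0, 100.0], [500.0, 100.0], [100.0, 600.0]],
            [[130.0, 70.0], [530.0, 70.0], [130.0, 570.0]],
        )
        cfg = SolverConfig(niter=1, ep_L=0.0, ep_T=0.0, ep_V=0.0,
                           sigma_M=0.2, contrast_degree=1)
        res = run_lddmm(src, tgt, cfg, landmarks=lm)
        np.testing.assert_allclose(res.A.translation, [30.0, -30.0], atol=1e-8)
        assert res.loss_history[0, 2] >= 0  # landmark term recorded


class TestRun3dTo2d:
    def test_plane_outside_volume_raises(self):
        vs = VolumeSpec(seed=1)
        vol, _ = generate_volume(vs)
        tgt = _gauss_image((10, 10), 50.0, (250, 250), 150.0)
        cfg = SolverConfig(niter=1, T0=[-1e6, 0.0, 0.0])
        with pytest.raises(RuntimeError, match="T0"):
            run_lddmm_3d_to_2d(vol, tgt, cfg)

    def test_affine_only_matches_bruteforce_z_scan(self):
        """With v frozen and only the z-translation free, the solve lands
        within one voxel of the brute-force best-matching slice."""
        vs = VolumeSpec(seed=5)
        vol, _ = generate_volume(vs)
        zax, yax, xax = vol.axis_coords
        z0 = zax[14]
        yy, xx = np.meshgrid(yax, xax, indexing="ij")
        flat = np.stack([np.full(yy.size, z0), yy.ravel(), xx.ravel()], axis=1)
        tgt = RasterImage(
            volume_intensity(vs, flat).reshape((1,) + yy.shape), [yax, xax]
        )
        # brute-force scan: SSD of each z slice against the target
        ssd = [
            float(((vol.values[0, k] - tgt.values[0]) ** 2).sum())
            for k in range(len(zax))
        ]
        z_best = zax[int(np.argmin(ssd))]
        cfg = SolverConfig(
            dx=vs.spacing, niter=300, diffeo_start=10**9, sigma_M=0.1,
            sigma_B=0.5, sigma_A=0.5, contrast_degree=1,
            ep_L=0.0, ep_T=2e-3, T0=[-(z0 + 2 * vs.spacing), 0.0, 0.0],
        )
        res = run_lddmm_3d_to_2d(vol, tgt, cfg)
        assert abs(-res.A.translation[0] - z_best) < vs.spacing


class TestMatchingMask:
    def _result_with_posteriors(self, match_field):
        from stwarp.objective import ContrastModel, MixtureWeights
        from stwarp.geometry import VelocityField

        grid = match_field.shape
        axes = [100.0 * (np.arange(n) + 0.5) for n in grid]
        post = np.stack([match_field, 1 - match_field, np.zeros(grid)])
        return AlignmentResult(
            A=AffineTransform.identity(2),
            v=VelocityField.zeros(axes),
            loss_history=np.zeros((1, 4)),
            W=MixtureWeights(post, [0.0], [1.0]),
            contrast=ContrastModel([[0.0, 1.0]], 1),
            source_axis_coords=axes,
            target_axis_coords=axes,
            config=SolverConfig(niter=1),
        )

    def test_default_threshold_is_085(self):
        import inspect

        from stwarp.solver import matching_mask as mm

        assert inspect.signature(mm).parameters["threshold"].default == 0.85

    def test_all_matching(self):
        res = self._result_with_posteriors(np.ones((5, 6)))
        mask, flags = matching_mask(res, PointSet(np.array([[250.0, 350.0]])))
        assert mask.all() and flags[0]

    def test_threshold_splits_pixels(self):
        field = np.zeros((4, 4))
        field[:, :2] = 0.9
        res = self._result_with_posteriors(field)
        mask, _ = matching_mask(res)
        assert mask[:, :2].all() and not mask[:, 2:].any()

    def test_point_outside_grid_flagged_false(self):
        res = self._result_with_posteriors(np.ones((4, 4)))
        _, flags = matching_mask(res, PointSet(np.array([[5000.0, 5000.0]])))
        assert not flags[0]


class TestLiftOver:
    def _identity_result(self, axes3):
        from stwarp.objective import ContrastModel, MixtureWeights
        from stwarp.geometry import VelocityField

        return AlignmentResult(
            A=AffineTransform.identity(3),
            v=VelocityField.zeros(axes3),
            loss_history=np.zeros((1, 4)),
            W=MixtureWeights.uniform((2, 2)),
            contrast=ContrastModel([[0.0, 1.0]], 1),
            source_axis_coords=axes3,
            target_axis_coords=axes3[1:],
            config=SolverConfig(niter=1),
        )

    def test_identity_reads_voxel_label(self):
        axes = [50.0 * (np.arange(4) + 0.5) for _ in range(3)]
        labels = np.arange(64).reshape(4, 4, 4)
        vol = LabelVolume(labels, axes)
        res = self._identity_result(axes)
        # cell at the (y, x) center of voxel (0, 2, 3): embedded at z = 0,
        # whose nearest z voxel is index 0
        cells = PointSet(np.array([[axes[1][2], axes[2][3]]]))
        got = lift_over_labels(res, vol, cells)
        assert got[0] == labels[0, 2, 3]

    def test_outside_volume_is_background(self):
        axes = [50.0 * (np.arange(4) + 0.5) for _ in range(3)]
        vol = LabelVolume(np.ones((4, 4, 4), dtype=int), axes)
        res = self._identity_result(axes)
        got = lift_over_labels(res, vol, PointSet(np.array([[9e4, 9e4]])))
        assert got[0] == 0

    def test_disjoint_grids_rejected(self):
        axes = [50.0 * (np.arange(4) + 0.5) for _ in range(3)]
        far = [1e6 + a for a in axes]
        vol = LabelVolume(np.ones((4, 4, 4), dtype=int), far)
        res = self._identity_result(axes)
        with pytest.raises(ValueError, match="overlap"):
            lift_over_labels(res, vol, PointSet(np.array([[100.0, 100.0]])))


def test_label_volume_validation():
    axes = [np.arange(3.0)] * 3
    with pytest.raises(ValueError):
        LabelVolume(np.zeros((3, 3, 3)), axes)  # float labels
    with pytest.raises(ValueError):
        LabelVolume(-np.ones((3, 3, 3), dtype=int), axes)
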