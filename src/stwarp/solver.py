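"""Gradient-descent diffeomorphic alignment (2D→2D and 3D→2D) and lift-over.

Each epoch of the solve: (1) integrate the backward flow from the target
pixel centers through A⁻¹ and −v and sample the source there; (2) refit
the polynomial contrast model; (3) one EM sweep of the three-component
Gaussian mixture on the target; (4) evaluate the objective
E = R(v) + M + P; (5) steepest-descent updates — the linear part of A with
step epL, the translation with epT, and (from epoch ``diffeo_start`` on)
the velocity field with epV after converting the raw derivative to a
Sobolev natural gradient.

Gradients are the exact discrete adjoint of the composed forward
computation (interpolation, Euler integration, affine), so the descent
direction matches what reverse-mode automatic differentiation would give
for the identical discretization. The mixture weights and contrast
coefficients are held fixed within each gradient step (EM-in-the-loop).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from ._interp import interp, interp_point_jacobian, interp_vjp_values
from .geometry import (
    AffineTransform,
    LandmarkSet,
    VelocityField,
    fit_affine_landmarks,
    flow_points,
)
from .objective import (
    ContrastModel,
    EnergyWeights,
    MixtureWeights,
    em_update_weights,
    fit_contrast,
    matching_energy,
    operator_symbol,
)
from .raster import PointSet, RasterImage

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "AlignmentResult",
    "LabelVolume",
    "run_lddmm",
    "run_lddmm_3d_to_2d",
    "matching_mask",
    "lift_over_labels",
]

#: Posterior threshold above which a target pixel counts as matched tissue.
MATCHING_THRESHOLD = 0.85

_T1_ALIASES = {
    "sigmaM": "sigma_M",
    "sigmaR": "sigma_R",
    "sigmaP": "sigma_P",
    "sigmaA": "sigma_A",
    "sigmaB": "sigma_B",
    "epL": "ep_L",
    "epT": "ep_T",
    "epV": "ep_V",
    "L": "L0",
    "T": "T0",
    "A": "A0",
}


@dataclass
class SolverConfig:
    """Solver parameters; defaults follow the published tool's defaults.

    σ values weight the objective terms (each enters as 1/(2σ²)) and, for
    σM/σB/σA, serve as the standard deviations of the mixture components.
    a (μm) and p set the Sobolev operator (1 − a²Δ)^p; epL/epT/epV are the
    gradient-descent step sizes of the affine linear part, translation and
    velocity field. ``diffeo_start`` delays the velocity update for
    coarse-to-fine (affine-first) optimization. Either (L0, T0) or A0 may
    initialize the affine — not both.
    """

    dx: float = 30.0
    sigma_M: float = 1.0
    sigma_R: float = 5.0e5
    sigma_P: float = 2.0e1
    sigma_A: float = 5.0
    sigma_B: float = 2.0
    a: float = 500.0
    p: float = 2.0
    niter: int = 5000
    diffeo_start: int = 0
    nt: int = 3
    ep_L: float = 2.0e-8
    ep_T: float = 2.0e-1
    ep_V: float = 2.0e3
    pointsI: Optional[np.ndarray] = None
    pointsJ: Optional[np.ndarray] = None
    muB: Union[None, str, Sequence[float]] = None
    muA: Union[None, str, Sequence[float]] = None
    L0: Optional[np.ndarray] = None
    T0: Optional[np.ndarray] = None
    A0: Optional[np.ndarray] = None
    contrast_degree: int = 3
    seed: Optional[int] = None

    def __post_init__(self):
        if self.A0 is not None and (self.L0 is not None or self.T0 is not None):
            raise ValueError("specify either (L0, T0) or A0, not both")
        for name in ("sigma_M", "sigma_R", "sigma_P", "sigma_A", "sigma_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nt < 1 or self.niter < 0 or self.a <= 0 or self.p < 1:
            raise ValueError("invalid nt/niter/a/p")

    @classmethod
    def from_dict(cls, d: dict) -> "SolverConfig":
        """Build from a config mapping using the published parameter names
        (sigmaM, sigmaR, sigmaP, sigmaA, sigmaB, epL, epT, epV, L, T, A, ...).
        """
        kwargs = {}
        valid = set(cls.__dataclass_fields__)
        for key, val in d.items():
            name = _T1_ALIASES.get(key, key)
            if name not in valid:
                raise KeyError(f"unknown solver config key: {key!r}")
            kwargs[name] = val
        return cls(**kwargs)

    def energy_weights(self) -> EnergyWeights:
        return EnergyWeights(
            self.sigma_M, self.sigma_R, self.sigma_P, self.sigma_A, self.sigma_B
        )


@dataclass
class LabelVolume:
    """3D integer annotation volume on a uniform μm grid; 0 = background."""

    labels: np.ndarray
    axis_coords: Sequence[np.ndarray]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative")
        self.axis_coords = [np.asarray(a, float) for a in self.axis_coords]
        if tuple(len(a) for a in self.axis_coords) != self.labels.shape:
            raise ValueError("axis_coords must match the label grid")


@dataclass
class AlignmentResult:
    """Everything downstream transforms consume: A, v, posteriors, history.

    loss_history has one row per epoch: (R, M, landmark, total).
    """

    A: AffineTransform
    v: VelocityField
    loss_history: np.ndarray
    W: MixtureWeights
    contrast: ContrastModel
    source_axis_coords: Sequence[np.ndarray]
    target_axis_coords: Sequence[np.ndarray]
    config: SolverConfig

    @property
    def d(self) -> int:
        return self.A.d

    def transform_points(self, pts: PointSet) -> PointSet:
        """Map source-space points to target space: x ↦ A·φ₁(x)."""
        coords = flow_points(self.v, pts.coords, direction="forward")
        return pts.with_coords(self.A.apply(coords))

    def pull_back_points(self, coords: np.ndarray) -> np.ndarray:
        """Map target-space coordinates to source space: y ↦ φ₁⁻¹(A⁻¹y)."""
        q = self.A.inverse().apply(np.asarray(coords, float))
        return flow_points(self.v, q, direction="backward")


def _resolve_mu(spec, target_values, which: str):
    """Resolve a muB/muA config entry to (per-channel vector, fixed?)."""
    c = target_values.shape[0]
    if spec is None:
        flat = target_values.reshape(c, -1)
        vec = flat.min(axis=1) if which == "background" else flat.max(axis=1)
        return vec.astype(float), False
    if isinstance(spec, str):
        if spec == "black":
            return np.zeros(c), True
        if spec == "white":
            return np.ones(c), True
        raise ValueError(f"{which} color must be 'black' or 'white'")
    vec = np.broadcast_to(np.atleast_1d(np.asarray(spec, float)), (c,)).copy()
    return vec, True


def _initial_affine(cfg, source, target, lm, d, embed_plane):
    if lm is not None:
        A, _ = fit_affine_landmarks(lm)
        return A
    if cfg.A0 is not None:
        return AffineTransform(np.asarray(cfg.A0, float))
    L = np.eye(d) if cfg.L0 is None else np.asarray(cfg.L0, float)
    if cfg.T0 is not None:
        return AffineTransform.from_linear_translation(L, np.asarray(cfg.T0, float))
    # translation aligning intensity centroids
    def centroid(img):
        w = img.values.sum(axis=0)
        tot = w.sum()
        grid = img.meshgrid()
        if tot <= 0:
            return np.array([a.mean() for a in img.axis_coords])
        return (grid.reshape(img.d, -1) * w.ravel()).sum(axis=1) / tot

    cs = centroid(source)
    ct = centroid(target)
    if embed_plane:
        ct = np.concatenate([[0.0], ct])
    return AffineTransform.from_linear_translation(L, ct - L @ cs)


class _Workspace:
    """Precomputed geometry for one solve; evaluates E and its adjoint grads.

    ``energy_and_grads`` treats the mixture weights and contrast model as
    fixed (EM-in-the-loop) and returns the matching + landmark energies
    together with the exact discrete gradients w.r.t. the affine matrix
    and the raw (covector) gradient w.r.t. the velocity samples. Kept
    separate from the descent loop so the adjoint can be checked against
    finite differences.
    """

    def __init__(self, source, target, cfg, lm, embed_plane):
        d = source.d
        self.d = d
        self.cfg = cfg
        self.lm = lm
        self.source = source
        self.target = target
        c_tgt = target.values.shape[0]
        self.c_tgt = c_tgt
        self.grid_shape = target.grid_shape
        self.N = int(np.prod(self.grid_shape))
        self.J = target.values.reshape(c_tgt, self.N)
        self.cellJ = float(np.prod(target.dx))
        Ygrid = target.meshgrid().reshape(target.d, self.N)
        Y = np.vstack([np.zeros((1, self.N)), Ygrid]) if embed_plane else Ygrid
        self.Yh = np.vstack([Y, np.ones((1, self.N))])
        vax = []
        for ax in source.axis_coords:
            step = ax[1] - ax[0] if len(ax) > 1 else 1.0
            vax.append(np.concatenate([
                ax[0] - step * np.array([2.0, 1.0]),
                ax,
                ax[-1] + step * np.array([1.0, 2.0]),
            ]))
        self.vax = vax
        self.vgrid_shape = tuple(len(a) for a in vax)
        self.cellV = float(np.prod([a[1] - a[0] for a in vax]))
        symbol = operator_symbol(vax, cfg.a, cfg.p)
        self.sym2 = symbol**2
        self.inv_sym2 = symbol**-2.0

    def backward_sample(self, Amat, vsamples):
        """Backward flow of the target pixels; returns (traj, s)."""
        nt = vsamples.shape[0]
        dt = 1.0 / nt
        B = np.linalg.inv(Amat)
        traj = [(B @ self.Yh)[: self.d]]
        for k in range(nt):
            t = nt - 1 - k
            vel = interp(self.vax, vsamples[t], traj[k])
            traj.append(traj[k] - dt * vel)
        s = interp(self.source.axis_coords, self.source.values, traj[nt])[0]
        return traj, s

    def energy_and_grads(self, Amat, vsamples, w_match, contrast,
                         traj=None, s=None):
        """Matching + landmark energy and exact adjoint gradients.

        Returns (M, P, grad_A, grad_v_raw); grad_v_raw is the raw
        derivative (covector) w.r.t. the velocity samples, before Sobolev
        smoothing, and excludes the regularization term (handled in
        closed form by the caller).
        """
        cfg, d, lm = self.cfg, self.d, self.lm
        nt = vsamples.shape[0]
        dt = 1.0 / nt
        B = np.linalg.inv(Amat)
        if traj is None:
            traj, s = self.backward_sample(Amat, vsamples)
        fpred = contrast(s)
        M_val = matching_energy(fpred, self.J, w_match, cfg.sigma_M, self.cellJ)

        dM_dfpred = (self.cellJ / cfg.sigma_M**2) * w_match * (fpred - self.J)
        dM_ds = (dM_dfpred * contrast.derivative(s)).sum(axis=0)
        src_jac = interp_point_jacobian(
            self.source.axis_coords, self.source.values, traj[nt]
        )
        g = src_jac[0] * dM_ds
        grad_v_raw = np.zeros_like(vsamples)
        for k in range(nt - 1, -1, -1):
            t = nt - 1 - k
            grad_v_raw[t] += interp_vjp_values(
                self.vax, traj[k], -dt * g, self.vgrid_shape
            )
            jv = interp_point_jacobian(self.vax, vsamples[t], traj[k])
            g = g - dt * np.einsum("cjn,cn->jn", jv, g)
        Ghat = np.zeros((d + 1, d + 1))
        Ghat[:d] = g @ self.Yh.T
        grad_A = -B.T @ Ghat @ B.T

        P_val = 0.0
        if lm is not None:
            Alin, Atr = Amat[:d, :d], Amat[:d, d]
            lm_traj = [lm.source_pts.T]
            for k in range(nt):
                vel = interp(self.vax, vsamples[k], lm_traj[k])
                lm_traj.append(lm_traj[k] + dt * vel)
            mapped = Alin @ lm_traj[nt] + Atr[:, None]
            resid = mapped - lm.target_pts.T
            P_val = float(np.sum(resid**2) / (2.0 * cfg.sigma_P**2))
            diff = resid / cfg.sigma_P**2
            qh = np.vstack([lm_traj[nt], np.ones((1, lm.m))])
            GP = np.zeros((d + 1, d + 1))
            GP[:d] = diff @ qh.T
            grad_A += GP
            u = Alin.T @ diff
            for k in range(nt - 1, -1, -1):
                grad_v_raw[k] += interp_vjp_values(
                    self.vax, lm_traj[k], dt * u, self.vgrid_shape
                )
                jv = interp_point_jacobian(self.vax, vsamples[k], lm_traj[k])
                u = u + dt * np.einsum("cjn,cn->jn", jv, u)
        return M_val, P_val, grad_A, grad_v_raw


def _solve(source, target, cfg, lm, embed_plane):
    d = source.d
    if source.values.shape[0] != 1:
        raise ValueError(
            "the solver expects a single-channel source (a density raster); "
            "combine channels before solving"
        )
    if embed_plane:
        if d != 3 or target.d != 2:
            raise ValueError("3D→2D alignment needs a 3D source and 2D target")
    elif target.d != d:
        raise ValueError("source and target dimensions must match")
    if lm is not None and lm.d != d:
        raise ValueError("landmark dimension must match the source")

    ew = cfg.energy_weights()
    ws = _Workspace(source, target, cfg, lm, embed_plane)
    nt = cfg.nt
    c_tgt = ws.c_tgt
    grid_shape = ws.grid_shape

    v = VelocityField.zeros(ws.vax, nt=nt, a=cfg.a, p=cfg.p)
    A = _initial_affine(cfg, source, target, lm, d, embed_plane)
    mu_B, fix_B = _resolve_mu(cfg.muB, target.values, "background")
    mu_A, fix_A = _resolve_mu(cfg.muA, target.values, "artifact")
    W = MixtureWeights.uniform(grid_shape, c_tgt)
    W.mu_B, W.mu_A = mu_B, mu_A
    contrast = None
    history = np.zeros((cfg.niter, 4))

    for epoch in range(cfg.niter):
        try:
            # (1) backward flow from the target pixels, sample the source
            traj, s = ws.backward_sample(A.matrix, v.samples)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"singular affine at epoch {epoch}") from err

        # (2) refit contrast with the current matching weights
        w_match = W.matching.reshape(ws.N)
        contrast = fit_contrast(s, ws.J, weights=w_match, degree=cfg.contrast_degree)
        fpred = contrast(s)

        # (3) EM sweep of the mixture on the target intensities
        W = em_update_weights(
            fpred.reshape((c_tgt,) + grid_shape), target.values, ew,
            mu_B=W.mu_B, mu_A=W.mu_A, priors=W.priors,
            fix_mu_B=fix_B, fix_mu_A=fix_A,
        )
        w_match = W.matching.reshape(ws.N)

        # (4) objective and (5) adjoint gradients, W and θ held fixed
        R_val = float(np.sum(_filt(v.samples, ws.sym2) * v.samples) * ws.cellV
                      / (2.0 * cfg.sigma_R**2 * nt))
        M_val, P_val, grad_A, grad_v_raw = ws.energy_and_grads(
            A.matrix, v.samples, w_match, contrast, traj=traj, s=s
        )
        total = R_val + M_val + P_val
        history[epoch] = (R_val, M_val, P_val, total)
        if not np.isfinite(total):
            raise RuntimeError(
                f"non-finite objective at epoch {epoch}; reduce step sizes "
                "(epL/epT/epV) or increase sigma values"
            )

        newL = A.linear - cfg.ep_L * grad_A[:d, :d]
        newT = A.translation - cfg.ep_T * grad_A[:d, d]
        A = AffineTransform.from_linear_translation(newL, newT)

        if epoch >= cfg.diffeo_start:
            nat = _filt(grad_v_raw, ws.inv_sym2)
            nat += (ws.cellV / (cfg.sigma_R**2 * nt)) * v.samples
            v = VelocityField(v.samples - cfg.ep_V * nat, ws.vax, a=cfg.a, p=cfg.p)

        if epoch % 100 == 0:
            logger.debug(
                "epoch %d: R=%.4g M=%.4g P=%.4g total=%.4g",
                epoch, R_val, M_val, P_val, total,
            )

    return AlignmentResult(
        A=A, v=v, loss_history=history, W=W, contrast=contrast,
        source_axis_coords=[a.copy() for a in source.axis_coords],
        target_axis_coords=[a.copy() for a in target.axis_coords],
        config=cfg,
    )


def _filt(samples, symbol):
    axes = tuple(range(samples.ndim - symbol.ndim, samples.ndim))
    return np.real(np.fft.ifftn(np.fft.fftn(samples, axes=axes) * symbol, axes=axes))


def run_lddmm(
    source: RasterImage,
    target: RasterImage,
    cfg: Optional[SolverConfig] = None,
    landmarks: Optional[LandmarkSet] = None,
) -> AlignmentResult:
    """Align a 2D source raster to a 2D target raster.

    When ``landmarks`` are given, the affine is initialized from them by
    least squares and the landmark penalty is added to the objective;
    otherwise the affine starts from cfg.A0 / (L0, T0), or identity linear
    part with a translation aligning the intensity centroids.
    """
    cfg = cfg or SolverConfig()
    if cfg.pointsI is not None and landmarks is None:
        if cfg.pointsJ is None:
            raise ValueError("pointsI given without pointsJ")
        landmarks = LandmarkSet(np.asarray(cfg.pointsI), np.asarray(cfg.pointsJ))
    return _solve(source, target, cfg, landmarks, embed_plane=False)


def run_lddmm_3d_to_2d(
    source_vol: RasterImage,
    target_img: RasterImage,
    cfg: Optional[SolverConfig] = None,
    landmarks: Optional[LandmarkSet] = None,
) -> AlignmentResult:
    """Align a 3D source volume (e.g. an atlas) to a 2D target section.

    The target section is embedded at z = 0 of target space and matched
    against the source sampled along the mapped plane; the solved 4×4
    affine and 3D velocity field accommodate deformations into and out of
    the section plane. The slice depth is absorbed into the affine's
    z-translation, so cfg.T0 should carry a starting z-offset when the
    section is far from the volume center.
    """
    cfg = cfg or SolverConfig()
    # the z=0 plane must land at least partly inside the volume at init
    A_init = _initial_affine(cfg, source_vol, target_img, landmarks, 3, True)
    ys, xs = target_img.axis_coords
    corners = np.array([[0.0, y, x] for y in (ys[0], ys[-1]) for x in (xs[0], xs[-1])])
    mapped = A_init.inverse().apply(corners)
    lo = np.array([a[0] for a in source_vol.axis_coords])
    hi = np.array([a[-1] for a in source_vol.axis_coords])
    if not np.any(np.all((mapped >= lo) & (mapped <= hi), axis=1)):
        raise RuntimeError(
            "the target plane maps entirely outside the source volume at "
            "initialization; provide a better initial translation T0"
        )
    return _solve(source_vol, target_img, cfg, landmarks, embed_plane=True)


def matching_mask(
    result: AlignmentResult,
    points: Optional[PointSet] = None,
    threshold: float = MATCHING_THRESHOLD,
):
    """Mask of target pixels whose matching posterior exceeds ``threshold``.

    Returns (mask, flags): ``mask`` is a boolean array on the target grid
    (True where W_matching > threshold, default 0.85), and ``flags`` marks
    — by nearest-pixel lookup of the transformed coordinates — which of the
    given source-space ``points`` land on matched tissue (None when no
    points are passed). Points mapping outside the target grid are flagged
    False.
    """
    mask = result.W.matching > threshold
    flags = None
    if points is not None:
        mapped = result.transform_points(points).coords
        if result.d == 3 and mapped.shape[1] == 3:
            mapped = mapped[:, 1:]
        axes = result.target_axis_coords
        idx = []
        inside = np.ones(mapped.shape[0], dtype=bool)
        for k, ax in enumerate(axes):
            step = ax[1] - ax[0] if len(ax) > 1 else 1.0
            i = np.round((mapped[:, k] - ax[0]) / step).astype(int)
            inside &= (i >= 0) & (i < len(ax))
            idx.append(np.clip(i, 0, len(ax) - 1))
        flags = mask[tuple(idx)] & inside
    return mask, flags


def lift_over_labels(
    result: AlignmentResult,
    labels: LabelVolume,
    cells: PointSet,
) -> np.ndarray:
    """Annotate 2D cells with atlas labels through a solved 3D→2D alignment.

    Each cell (y, x) is embedded at (0, y, x) in target space, mapped into
    the source volume via A⁻¹ followed by the backward flow, and assigned
    the nearest-voxel label; cells landing outside the volume get 0.
    """
    if result.d != 3:
        raise ValueError("lift-over requires a 3D→2D alignment result")
    if cells.d != 2:
        raise ValueError("cells must be 2D section coordinates")
    src_lo = np.array([a[0] for a in result.source_axis_coords])
    src_hi = np.array([a[-1] for a in result.source_axis_coords])
    lab_lo = np.array([a[0] for a in labels.axis_coords])
    lab_hi = np.array([a[-1] for a in labels.axis_coords])
    if np.any(lab_hi < src_lo) or np.any(lab_lo > src_hi):
        raise ValueError(
            "label volume grid does not overlap the alignment's source grid"
        )
    emb = np.hstack([np.zeros((cells.n, 1)), cells.coords])
    vol_coords = result.pull_back_points(emb)
    out = np.zeros(cells.n, dtype=labels.labels.dtype)
    idx = []
    inside = np.ones(cells.n, dtype=bool)
    for k, ax in enumerate(labels.axis_coords):
        step = ax[1] - ax[0] if len(ax) > 1 else 1.0
        i = np.round((vol_coords[:, k] - ax[0]) / step).astype(int)
        inside &= (i >= 0) & (i < len(ax))
        idx.append(np.clip(i, 0, len(ax) - 1))
    vals = labels.labels[tuple(idx)]
    out[inside] = vals[inside]
    return out
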