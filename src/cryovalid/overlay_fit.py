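"""Likelihood-based rigid-body superposition of density maps.

One map is held static while a moving map is rotated/translated onto it.
Both maps enter as Fourier coefficients; for Gaussian signal and noise the
only terms of the negative log-likelihood that depend on the transformation
are the cross-terms

    C(R, t) = Σ_s w(|s|) · Re[ F₁*(s) · F₂(R s) · phase(s, t) ]

where the per-shell weight ``w`` comes from the off-diagonal of the inverse
2×2 signal+noise covariance of the pair — shells where the maps agree well
count more, shells with no observed correlation count nothing.  The fit
alternates (a) re-estimating the per-shell covariances/weights at the
current alignment with (b) gradient steps on the cross-term, until the
functional stagnates.

Rotations are parameterized by axis–angle vectors; gradients are taken in
the local chart (a small rotation composed onto the current one, so there
are no gimbal issues) and mapped to the axis–angle parameters through the
exact SO(3) right Jacobian.  Rotated Fourier coefficients are resampled by
cubic B-spline interpolation of a zero-padded, recentred coefficient field,
whose analytic gradient is smooth and exact — accurate enough that the
fitted optimum is not biased toward lattice-aligned orientations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .fourier_stats import (
    FourierMap,
    ShellStatistics,
    forward_fft,
    make_shells,
)
from .voxel_io import AtomRecord, VoxelMap

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "FitState",
    "transform_fourier",
    "score_fit",
    "fit_transform",
    "apply_transform_to_atoms",
    "build_soft_mask",
    "extract_masked_region",
]


@dataclass
class RigidTransform:
    """Proper rotation (axis–angle vector, radians·axis) plus translation (Å).

    Applied to a point about a centre c:  x ← R (x − c) + c + t.
    """

    rotvec: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotvec = np.asarray(self.rotvec, dtype=float).reshape(3).copy()
        self.translation = np.asarray(self.translation, dtype=float).reshape(3).copy()

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, translation=(0, 0, 0)) -> "RigidTransform":
        return cls(Rotation.from_matrix(matrix).as_rotvec(), np.asarray(translation))

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_rotvec(self.rotvec).as_matrix()

    @property
    def angle_deg(self) -> float:
        """Rotation angle in degrees."""
        return float(np.degrees(np.linalg.norm(self.rotvec)))

    def inverse(self) -> "RigidTransform":
        """Inverse transform about the same centre."""
        rt = self.matrix.T
        return RigidTransform(-self.rotvec, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``
        (both about the same centre)."""
        r = self.matrix @ other.matrix
        t = self.matrix @ other.translation + self.translation
        return RigidTransform(Rotation.from_matrix(r).as_rotvec(), t)


def apply_transform_to_atoms(
    atoms: list[AtomRecord], transform: RigidTransform, center
) -> list[AtomRecord]:
    """Apply x ← R(x − c) + c + t to every atom position."""
    c = np.asarray(center, dtype=float)
    R = transform.matrix
    t = transform.translation
    out = []
    for a in atoms:
        x = R @ (a.xyz - c) + c + t
        out.append(AtomRecord(tuple(x), a.occupancy, a.b_value, a.element))
    return out


# ---------------------------------------------------------------------------
# interpolation kernels with exact gradients
# ---------------------------------------------------------------------------

def _bspline3_weights(f: np.ndarray):
    """Cubic B-spline weights (and derivatives) for offsets −1..2 around the
    cell fraction ``f`` in [0, 1)."""
    f2 = f * f
    f3 = f2 * f
    w = np.empty((4,) + f.shape)
    w[0] = (1 - f) ** 3 / 6.0
    w[1] = (3 * f3 - 6 * f2 + 4) / 6.0
    w[2] = (-3 * f3 + 3 * f2 + 3 * f + 1) / 6.0
    w[3] = f3 / 6.0
    dw = np.empty_like(w)
    dw[0] = -((1 - f) ** 2) / 2.0
    dw[1] = (3 * f2 - 4 * f) / 2.0
    dw[2] = (-3 * f2 + 2 * f + 1) / 2.0
    dw[3] = f2 / 2.0
    return w, dw


def _bspline3_complex(re: np.ndarray, im: np.ndarray, coords: np.ndarray,
                      want_grad: bool = False):
    """Cubic B-spline interpolation of a complex field stored as two
    prefiltered real cubes (see ``scipy.ndimage.spline_filter``).

    ``coords`` has shape (3, M) in index units; points whose 4³ support
    leaves the array evaluate to 0 (and zero gradient).  Returns complex
    values (M,) and, if requested, the exact analytic gradient (3, M) of
    the interpolant with respect to the index coordinates.
    """
    shape = re.shape
    valid = np.ones(coords.shape[1], dtype=bool)
    for k, n in enumerate(shape):
        valid &= (coords[k] >= 1.0) & (coords[k] <= n - 3.0)
    c = np.where(valid, coords, 2.0)
    i0 = np.floor(c).astype(np.int64)
    f = c - i0
    wx, dwx = _bspline3_weights(f[0])
    wy, dwy = _bspline3_weights(f[1])
    wz, dwz = _bspline3_weights(f[2])

    val = np.zeros(coords.shape[1], dtype=np.complex128)
    grad = np.zeros((3, coords.shape[1]), dtype=np.complex128) if want_grad \
        else None
    for a in range(4):
        ia = i0[0] + a - 1
        for b in range(4):
            ib = i0[1] + b - 1
            wxy = wx[a] * wy[b]
            if want_grad:
                dx_y = dwx[a] * wy[b]
                x_dy = wx[a] * dwy[b]
            for cc in range(4):
                ic = i0[2] + cc - 1
                corner = re[ia, ib, ic] + 1j * im[ia, ib, ic]
                val += corner * (wxy * wz[cc])
                if want_grad:
                    grad[0] += corner * (dx_y * wz[cc])
                    grad[1] += corner * (x_dy * wz[cc])
                    grad[2] += corner * (wxy * dwz[cc])
    val[~valid] = 0.0
    if want_grad:
        grad[:, ~valid] = 0.0
        return val, grad
    return val


def transform_fourier(
    fmap: FourierMap,
    transform: RigidTransform,
    center=None,
    magnification: float = 1.0,
) -> FourierMap:
    """Fourier coefficients of the rigidly moved (optionally magnified) map.

    The moved real-space map is ψ'(x) = ψ(T⁻¹ x) with
    T x = m·R (x − c) + c + t, which in reciprocal space is

        Ψ'(s) = m³ · Ψ(m Rᵀ s) · exp(−2πi s·b),   b = c + t − m R c.

    Coefficients are resampled at the scaled/rotated frequencies by cubic
    spline interpolation on a zero-padded, recentred (pre-phased by
    exp(+2πi s·c)) coefficient field — see
    :class:`~cryovalid.fourier_stats.FourierInterpolator`; points falling
    outside the sampled reciprocal box are set to zero.
    """
    from .fourier_stats import FourierInterpolator

    shape = fmap.shape
    m = float(magnification)
    interp = FourierInterpolator(fmap, center=center)
    sx, sy, sz = fmap.freq_axes()
    S = np.stack(np.meshgrid(sx, sy, sz, indexing="ij"), axis=0).reshape(3, -1)
    out = (m ** 3) * interp.moved(S, transform.matrix, transform.translation, m)
    return FourierMap(out.reshape(shape), fmap.pixel_size, fmap.origin,
                      normalized=fmap.normalized, weighted=fmap.weighted)


# ---------------------------------------------------------------------------
# cross-term model
# ---------------------------------------------------------------------------

def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])


def _maximize_with_restarts(neg_fun, p0: np.ndarray, bounds=None,
                            maxiter: int = 60):
    """L-BFGS-B on a piecewise-smooth objective.

    Trilinear resampling makes the cross-term only piecewise-smooth; the
    Wolfe line search can abort exactly on a lattice-aligned state (e.g. an
    identity start).  If the first solve fails to improve, restart from
    slightly nudged points and keep the best result.
    """
    from scipy.optimize import minimize

    f0 = neg_fun(p0)[0]
    best = None
    for shift in (0.0, 1e-4, -1e-4):
        opt = minimize(neg_fun, p0 + shift, jac=True, method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-14,
                                "gtol": 1e-12})
        if best is None or opt.fun < best.fun:
            best = opt
        if best.fun < f0 - 1e-12 * abs(f0):
            break
    return best


def _so3_right_jacobian(rotvec: np.ndarray) -> np.ndarray:
    """Right Jacobian J_r of the SO(3) exponential map:
    exp([φ + dφ]) ≈ exp([φ]) · exp([J_r(φ) dφ]).  Converts gradients taken
    in the local (body-frame) chart into gradients w.r.t. the absolute
    axis–angle parameters."""
    theta = np.linalg.norm(rotvec)
    K = _skew(rotvec)
    if theta < 1e-8:
        return np.eye(3) - 0.5 * K + K @ K / 6.0
    return (
        np.eye(3)
        - (1.0 - np.cos(theta)) / theta ** 2 * K
        + (theta - np.sin(theta)) / theta ** 3 * (K @ K)
    )


class CrossTerm:
    """Weighted likelihood cross-term between a static and a moving map,
    evaluated on reciprocal points inside a resolution cutoff, with exact
    gradients in the local chart (small rotation δ composed onto the current
    rotation, translation increment).

    The moving map's coefficients are evaluated off-lattice with a cubic
    B-spline on a zero-padded, recentred (pre-phased) field — see
    :class:`~cryovalid.fourier_stats.FourierInterpolator` for why the
    recentring matters — whose analytic gradient is smooth and exact.
    Scoring runs over the static map's (unpadded) reciprocal points inside
    the shell limit.
    """

    def __init__(
        self,
        static: FourierMap,
        moving: FourierMap,
        shells: ShellStatistics,
        center=None,
        pad_factor: int = 3,
    ):
        from scipy import ndimage

        if static.shape != moving.shape:
            raise ValueError("static and moving maps must share a grid")
        self.shape = static.shape
        self.pixel_size = static.pixel_size
        if center is None:
            center = (np.asarray(self.shape) - 1) / 2.0 * self.pixel_size
        self.center = np.asarray(center, dtype=float)
        self.shells = shells

        mask = shells.bin_index >= 0
        self.point_bins = shells.bin_index[mask]
        sx, sy, sz = static.freq_axes()
        Sfull = np.stack(np.meshgrid(sx, sy, sz, indexing="ij"), axis=0)
        self.S = Sfull.reshape(3, -1)[:, mask.ravel()]
        self.F1c = np.conj(static.coeffs[mask])
        self.p1 = np.abs(static.coeffs[mask]) ** 2

        # zero-pad the moving map (finer reciprocal sampling), pre-phase by
        # exp(+2pi i s.c) (recentring removes the fast phase ramp so the
        # coefficient field is smooth), then store as B-spline coefficients
        pad_shape = tuple(pad_factor * n for n in self.shape)
        mv = np.fft.ifftn(moving.coeffs).real
        padded = np.zeros(pad_shape)
        padded[: self.shape[0], : self.shape[1], : self.shape[2]] = mv
        paxes = [np.fft.fftfreq(n, d=p)
                 for n, p in zip(pad_shape, self.pixel_size)]
        pre = np.exp(2j * np.pi * (
            paxes[0][:, None, None] * self.center[0]
            + paxes[1][None, :, None] * self.center[1]
            + paxes[2][None, None, :] * self.center[2]
        ))
        sh = np.fft.fftshift(np.fft.fftn(padded) * pre)
        self._re = ndimage.spline_filter(np.ascontiguousarray(sh.real),
                                         order=3)
        self._im = ndimage.spline_filter(np.ascontiguousarray(sh.imag),
                                         order=3)
        self._s0 = np.array(
            [np.fft.fftshift(f)[0] for f in paxes]
        )
        self._ds = np.array(
            [1.0 / (n * p) for n, p in zip(pad_shape, self.pixel_size)]
        )
        self.weights = np.ones(len(self.F1c))
        self.nbins = shells.nbins

    def _coords(self, q: np.ndarray) -> np.ndarray:
        return (q - self._s0[:, None]) / self._ds[:, None]

    def moved_coeffs(self, R: np.ndarray, t: np.ndarray, m: float = 1.0):
        """Interpolated moving coefficients (with phase) at the cutoff points.

        The m³ Jacobian of a physical magnification is deliberately omitted:
        the likelihood operates on per-shell-normalized coefficients, and a
        uniform scale in the raw cross-term would reward inflating m
        irrespective of alignment.
        """
        q = m * (R.T @ self.S)
        vals = _bspline3_complex(self._re, self._im, self._coords(q))
        return vals * np.exp(-2j * np.pi * (self.S.T @ (self.center + t)))

    def update_weights(self, moved: np.ndarray, eps: float = 1e-2) -> np.ndarray:
        """Per-shell weights from the current alignment.

        Per bin the observed correlation ρ of static vs. moved coefficients
        is formed; the cross-term weight is the (positive) off-diagonal of
        the inverse 2×2 correlation matrix, ρ/(1−ρ²), divided by the
        geometric-mean power so that coefficients enter normalized.  Bins
        with ρ ≤ 0 or too few points get zero weight.
        """
        nb = self.nbins
        bins = self.point_bins
        num = np.bincount(bins, weights=(self.F1c * moved).real, minlength=nb)
        pm = np.bincount(bins, weights=np.abs(moved) ** 2, minlength=nb)
        p1 = np.bincount(bins, weights=self.p1, minlength=nb)
        counts = np.bincount(bins, minlength=nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = num / np.sqrt(p1 * pm)
            wb = np.where(
                (rho > 0) & (counts >= 5),
                rho / (1.0 - np.clip(rho, 0, 1 - eps) ** 2) / np.sqrt(p1 * pm / np.maximum(counts, 1) ** 2),
                0.0,
            )
        wb = np.nan_to_num(wb, nan=0.0, posinf=0.0)
        if not np.any(wb > 0):
            raise ValueError("no shell carries positive correlation: nothing to fit")
        self.weights = wb[bins]
        return wb

    def value(self, R: np.ndarray, t: np.ndarray, m: float = 1.0) -> float:
        """Weighted cross-term Σ w Re[F₁* F₂moved]."""
        moved = self.moved_coeffs(R, t, m)
        return float(np.sum(self.weights * (self.F1c * moved).real))

    def value_grad(self, R: np.ndarray, t: np.ndarray, m: float = 1.0,
                   with_magnification: bool = False):
        """Cross-term and its exact gradient w.r.t. (δ, Δt) in the local
        chart, where the rotation is updated as R·exp([δ]×).  With
        ``with_magnification`` a 7th component, ∂C/∂m, is appended."""
        q = m * (R.T @ self.S)
        vals, gq = _bspline3_complex(self._re, self._im, self._coords(q),
                                      want_grad=True)
        gq = gq / self._ds[:, None]  # d/d(index) -> d/d(frequency)
        phase = np.exp(-2j * np.pi * (self.S.T @ (self.center + t)))
        A = self.F1c * vals * phase
        C = float(np.sum(self.weights * A.real))

        grad = np.zeros(7 if with_magnification else 6)
        wA = self.weights * A
        for k in range(3):
            grad[3 + k] = float(np.sum((wA * (-2j * np.pi * self.S[k])).real))
        # rotation: q(δ) = m exp(−[δ]) u with u = Rᵀ s  ⇒ dq/dδ_k = m (u × e_k)
        # (the pre-phased formulation leaves no other rotation dependence)
        u = R.T @ self.S
        wF1phase = self.weights * self.F1c * phase
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            dq = m * np.cross(u.T, e).T              # (3, M)
            dval = np.sum(gq * dq, axis=0)
            grad[k] = float(np.sum((wF1phase * dval).real))
        if with_magnification:
            # q = m u ⇒ dq/dm = u
            dval_m = np.sum(gq * u, axis=0)
            grad[6] = float(np.sum((wF1phase * dval_m).real))
        return C, grad


def score_fit(
    static: FourierMap,
    moving: FourierMap,
    transform: RigidTransform,
    stats: ShellStatistics,
    center=None,
    magnification: float = 1.0,
) -> tuple[float, float]:
    """Negative log-likelihood (up to transformation-independent terms) and
    cross-term value of the pair at the given transformation."""
    model = CrossTerm(static, moving, stats, center=center)
    moved = model.moved_coeffs(transform.matrix, transform.translation,
                               magnification)
    model.update_weights(moved)
    cross = float(np.sum(model.weights * (model.F1c * moved).real))
    return -cross, cross


@dataclass
class FitState:
    """Result of a rigid-body fit."""

    transform: RigidTransform
    magnification: float
    nll: float
    cross: float
    converged: bool
    iterations: int
    history: list
    fsc_before: np.ndarray | None = None
    fsc_after: np.ndarray | None = None
    shells: ShellStatistics | None = None


def _fsc_points(model: CrossTerm, moved: np.ndarray) -> np.ndarray:
    nb = model.nbins
    bins = model.point_bins
    num = np.bincount(bins, weights=(model.F1c * moved).real, minlength=nb)
    pm = np.bincount(bins, weights=np.abs(moved) ** 2, minlength=nb)
    p1 = np.bincount(bins, weights=model.p1, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.clip(num / np.sqrt(p1 * pm), -1.0, 1.0)


def fit_transform(
    static: VoxelMap,
    moving: VoxelMap,
    init: RigidTransform | None = None,
    resolution: float | None = None,
    max_iter: int = 150,
    magnification: float = 1.0,
    multiresolution: bool = True,
    center=None,
    rel_tol: float = 1e-6,
) -> FitState:
    """Fit the rigid transformation carrying the moving map onto the static.

    Iterates the five-step scheme: per-shell covariances/weights are
    recomputed at the current alignment, the analytic cross-term gradient is
    taken in the local chart, a backtracking line search updates the
    parameters, and the functional change decides convergence
    (|ΔC| < ``rel_tol``·|C|).  With ``multiresolution`` the fit first runs
    with a low-pass at twice the target resolution, then at the target.

    Returns the transform T such that ``transform_fourier(moving, T)``
    matches the static map; if the moving map was produced by applying T₀ to
    the static one, the fitted T is T₀⁻¹ (same rotation angle and
    translation magnitude).
    """
    if not np.allclose(static.pixel_size, moving.pixel_size):
        from .magnification import resample_to_grid
        moving = resample_to_grid(moving, static.shape, static.pixel_size,
                                  static.origin)
    if static.shape != moving.shape:
        raise ValueError("maps must share a grid (resample first)")
    if resolution is None:
        resolution = 3.0 * float(np.max(static.pixel_size))
    nyq = 2.0 * float(np.max(static.pixel_size))
    schedule = [max(2.0 * resolution, nyq), resolution] if multiresolution else [resolution]
    # drop duplicate stages
    sched = []
    for r in schedule:
        if not sched or abs(r - sched[-1]) > 1e-9:
            sched.append(r)

    from scipy.optimize import minimize

    F1 = forward_fft(static)
    F2 = forward_fft(moving)
    state = init if init is not None else RigidTransform.identity()
    p = np.concatenate([state.rotvec, state.translation])
    m = float(magnification)

    history: list[float] = []
    converged = False
    total_iter = 0
    fsc_before = None
    model = None
    for stage, res in enumerate(sched):
        shells = make_shells(static.shape, static.pixel_size, resolution_limit=res)
        model = CrossTerm(F1, F2, shells, center=center)
        if stage == len(sched) - 1:
            init0 = init or RigidTransform.identity()
            fsc_before = _fsc_points(
                model, model.moved_coeffs(init0.matrix, init0.translation, m))
        prev = None
        stage_converged = False
        for it in range(max_iter):
            total_iter += 1
            # step 1/4: covariances -> weights at the current alignment
            R = Rotation.from_rotvec(p[:3]).as_matrix()
            model.update_weights(model.moved_coeffs(R, p[3:], m))

            def neg_cross(q: np.ndarray) -> tuple[float, np.ndarray]:
                Rq = Rotation.from_rotvec(q[:3]).as_matrix()
                C, g_loc = model.value_grad(Rq, q[3:], m)
                g = np.empty(6)
                g[:3] = _so3_right_jacobian(q[:3]).T @ g_loc[:3]
                g[3:] = g_loc[3:]
                return -C, -g

            opt = _maximize_with_restarts(neg_cross, p)
            p = opt.x
            C = -float(opt.fun)
            history.append(C)
            if prev is not None and abs(C - prev) <= rel_tol * max(abs(C), 1e-30):
                stage_converged = True
                break
            prev = C
        converged = stage_converged
    R = Rotation.from_rotvec(p[:3]).as_matrix()
    moved = model.moved_coeffs(R, p[3:], m)
    fsc_after = _fsc_points(model, moved)
    cross = float(np.sum(model.weights * (model.F1c * moved).real))
    final = RigidTransform(p[:3], p[3:])
    if not converged:
        logger.warning("fit did not converge in %d iterations", max_iter)
    return FitState(
        transform=final,
        magnification=m,
        nll=-cross,
        cross=cross,
        converged=converged,
        iterations=total_iter,
        history=history,
        fsc_before=fsc_before,
        fsc_after=fsc_after,
        shells=model.shells,
    )


# ---------------------------------------------------------------------------
# soft masks
# ---------------------------------------------------------------------------

def build_soft_mask(
    vmap: VoxelMap,
    atoms: list[AtomRecord] | None = None,
    center=None,
    radius: float | None = None,
    atom_radius: float = 3.0,
    edge_voxels: float = 3.0,
) -> VoxelMap:
    """A 0–1 mask: union of spheres (per atom, or one explicit sphere) with a
    raised-cosine edge of ``edge_voxels`` voxels."""
    shape = np.asarray(vmap.shape)
    ax = [vmap.origin[k] + np.arange(shape[k]) * vmap.pixel_size[k] for k in range(3)]
    if atoms:
        centers = np.array([a.xyz for a in atoms])
        r = atom_radius
    elif center is not None and radius is not None:
        centers = np.asarray(center, dtype=float).reshape(1, 3)
        r = radius
    else:
        raise ValueError("provide atoms or an explicit sphere (center, radius)")
    d = np.full(vmap.shape, np.inf)
    for cpos in centers:
        dd = np.sqrt(
            (ax[0][:, None, None] - cpos[0]) ** 2
            + (ax[1][None, :, None] - cpos[1]) ** 2
            + (ax[2][None, None, :] - cpos[2]) ** 2
        )
        np.minimum(d, dd, out=d)
    edge = edge_voxels * float(np.max(vmap.pixel_size))
    mask = np.zeros(vmap.shape)
    mask[d <= r] = 1.0
    on_edge = (d > r) & (d < r + edge)
    mask[on_edge] = 0.5 * (1.0 + np.cos(np.pi * (d[on_edge] - r) / edge))
    if not np.any(mask > 0):
        raise ValueError("empty mask: no voxel inside the selection")
    return VoxelMap(mask, vmap.pixel_size, vmap.origin)


def extract_masked_region(
    vmap: VoxelMap,
    atoms: list[AtomRecord] | None = None,
    center=None,
    radius: float | None = None,
    atom_radius: float = 3.0,
    edge_voxels: float = 3.0,
) -> VoxelMap:
    """Multiply the map by a soft mask around the selection (atom spheres or
    an explicit sphere)."""
    mask = build_soft_mask(vmap, atoms=atoms, center=center, radius=radius,
                           atom_radius=atom_radius, edge_voxels=edge_voxels)
    return VoxelMap(vmap.data * mask.data, vmap.pixel_size, vmap.origin)
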