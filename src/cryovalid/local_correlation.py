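"""Voxel-wise local correlation between density maps.

The local correlation at voxel x is a kernel-weighted Pearson correlation:

    CC(x) = cov_m(ψ1, ψ2)(x) / sqrt(var_m(ψ1)(x) · var_m(ψ2)(x))

with local moments taken under a normalized, spherically symmetric kernel
m(x): flat (1/Z) inside radius r0, raised-cosine falloff to zero at r1, and
zero beyond.  Moments are evaluated with circular FFT convolution, so edge
voxels mix density from opposite faces of the periodic grid — pad or mask
maps whose signal reaches the box edge.

Three flavours of correlation map are produced: ``half`` (between half
maps, a local signal-to-noise measure), ``full`` (half converted to the
full-map scale via 2c/(1+c)), and ``map_model`` (between an observed full
map and a model-derived map).  For ``map_model`` to be comparable with
``full``, both inputs must first be normalized per resolution shell and
weighted by the full-map FSC; absent overfitting the map–model correlation
then cannot systematically exceed the full-map correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier_stats import (
    ShellStatistics,
    forward_fft,
    inverse_fft,
    normalize_and_weight,
)
from .voxel_io import AtomRecord, VoxelMap

__all__ = [
    "Kernel",
    "LocalMoments",
    "CorrelationMap",
    "build_kernel",
    "local_moments",
    "cc_from_moments",
    "cc_half_to_full",
    "cc_full_from_halves",
    "cc_map_model",
    "atom_cc",
    "AtomCC",
]


@dataclass(frozen=True)
class Kernel:
    """Soft spherical kernel: flat core of radius ``r0`` (voxels), raised-
    cosine edge reaching zero at ``r1``.  Discrete weights are evaluated at
    voxel centres and normalized so their sum is exactly 1."""

    r0: float
    r1: float
    weights: np.ndarray  # cube of side 2*ceil(r1)+1... trimmed to nonzero extent

    @property
    def radius(self) -> int:
        return (self.weights.shape[0] - 1) // 2


def build_kernel(r0: float, r1: float | None = None) -> Kernel:
    """Build the soft spherical kernel.  ``r1`` defaults to ``r0 + 2``
    (two voxels of cosine edge to soften the mask)."""
    if r1 is None:
        r1 = r0 + 2.0
    if not (0 <= r0 < r1):
        raise ValueError(f"need 0 <= r0 < r1, got r0={r0}, r1={r1}")
    rad = int(np.ceil(r1))
    ax = np.arange(-rad, rad + 1, dtype=float)
    d = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2)
    w = np.zeros_like(d)
    w[d <= r0] = 1.0
    edge = (d > r0) & (d < r1)
    w[edge] = 0.5 * (1.0 + np.cos(np.pi * (d[edge] - r0) / (r1 - r0)))
    total = w.sum()
    if total <= 0:
        raise ValueError("kernel has no support")
    return Kernel(float(r0), float(r1), w / total)


@dataclass
class LocalMoments:
    """Per-voxel kernel-weighted means, variances and covariance."""

    mean1: np.ndarray
    mean2: np.ndarray
    var1: np.ndarray
    var2: np.ndarray
    cov12: np.ndarray


def _kernel_fft(kernel: Kernel, shape: tuple[int, int, int]) -> np.ndarray:
    """FFT of the kernel embedded (wrapped) in a grid of ``shape``."""
    rad = kernel.radius
    if any(2 * rad + 1 > n for n in shape):
        raise ValueError(f"kernel radius {rad} too large for grid {shape}")
    k = np.zeros(shape)
    sl = tuple(np.arange(-rad, rad + 1) % n for n in shape)
    k[np.ix_(*sl)] = kernel.weights
    return np.fft.rfftn(k)


def local_moments(map1: VoxelMap, map2: VoxelMap, kernel: Kernel) -> LocalMoments:
    """Local first and second moments of two maps by circular FFT convolution.

    Identical (to ~1e-6 absolute) to direct windowed weighted sums at every
    voxel; the FFT route evaluates all voxels at once.
    """
    if map1.shape != map2.shape:
        raise ValueError(f"grid mismatch: {map1.shape} vs {map2.shape}")
    a = np.asarray(map1.data, dtype=np.float64)
    b = np.asarray(map2.data, dtype=np.float64)
    kf = _kernel_fft(kernel, a.shape)

    def conv(x: np.ndarray) -> np.ndarray:
        return np.fft.irfftn(np.fft.rfftn(x) * kf, s=x.shape, axes=(0, 1, 2))

    m1 = conv(a)
    m2 = conv(b)
    var1 = np.clip(conv(a * a) - m1 * m1, 0.0, None)
    var2 = np.clip(conv(b * b) - m2 * m2, 0.0, None)
    cov12 = conv(a * b) - m1 * m2
    return LocalMoments(m1, m2, var1, var2, cov12)


@dataclass
class CorrelationMap:
    """Per-voxel correlation values in [−1, 1]; NaN where undefined
    (vanishing local variance).  ``kind`` is 'half', 'full' or 'map_model'."""

    values: np.ndarray
    kind: str
    pixel_size: np.ndarray
    origin: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_voxelmap(self, fill: float = 0.0) -> VoxelMap:
        return VoxelMap(
            np.nan_to_num(self.values, nan=fill), self.pixel_size, self.origin
        )


def cc_from_moments(
    moments: LocalMoments,
    var_floor: float | None = None,
    kind: str = "half",
    pixel_size=1.0,
    origin=(0.0, 0.0, 0.0),
) -> CorrelationMap:
    """Correlation from local moments.  Voxels where either local variance is
    at or below ``var_floor`` are marked missing (NaN).  The default floor is
    1e-12 × the largest local variance, guarding 0/0 in flat solvent."""
    if var_floor is None:
        var_floor = 1e-12 * max(moments.var1.max(), moments.var2.max(), 1e-300)
    good = (moments.var1 > var_floor) & (moments.var2 > var_floor)
    cc = np.full(moments.cov12.shape, np.nan)
    cc[good] = moments.cov12[good] / np.sqrt(moments.var1[good] * moments.var2[good])
    np.clip(cc, -1.0, 1.0, out=cc)
    return CorrelationMap(cc, kind, np.broadcast_to(np.asarray(pixel_size, float), (3,)).copy(),
                          np.asarray(origin, float).copy())


def cc_half_to_full(cc_half: CorrelationMap) -> CorrelationMap:
    """Convert a half-map correlation map to the full-map scale, 2c/(1+c)."""
    if cc_half.kind != "half":
        raise ValueError(f"expected a half-map correlation, got kind={cc_half.kind!r}")
    c = cc_half.values
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2.0 * c / (1.0 + c)
    out = np.where(np.isclose(c, -1.0), np.nan, out)
    return CorrelationMap(out, "full", cc_half.pixel_size, cc_half.origin)


def _weighted_realspace(vmap: VoxelMap, stats: ShellStatistics,
                        total_power: str) -> VoxelMap:
    f = forward_fft(vmap)
    return inverse_fft(normalize_and_weight(f, stats, weight=True,
                                            total_power=total_power))


def cc_full_from_halves(
    half1: VoxelMap,
    half2: VoxelMap,
    stats: ShellStatistics,
    kernel: Kernel,
) -> CorrelationMap:
    """Full-map local correlation from normalized+weighted half maps."""
    w1 = _weighted_realspace(half1, stats, "stats")
    w2 = _weighted_realspace(half2, stats, "stats")
    m = local_moments(w1, w2, kernel)
    cc_h = cc_from_moments(m, kind="half", pixel_size=half1.pixel_size,
                           origin=half1.origin)
    return cc_half_to_full(cc_h)


def cc_map_model(
    fullmap: VoxelMap,
    modelmap: VoxelMap,
    halfstats: ShellStatistics,
    kernel: Kernel,
    assume_weighted: bool = False,
) -> CorrelationMap:
    """Local correlation between an observed full map and a model-derived map.

    Both maps are normalized per shell and weighted by sqrt(full-map FSC)
    derived from the half maps (the model map is normalized against its own
    per-shell power, having no noise component).  Pass ``assume_weighted``
    only if the inputs have already been through that weighting.
    """
    if assume_weighted:
        wf, wm = fullmap, modelmap
    else:
        wf = _weighted_realspace(fullmap, halfstats, "stats")
        wm = _weighted_realspace(modelmap, halfstats, "self")
    m = local_moments(wf, wm, kernel)
    return cc_from_moments(m, kind="map_model", pixel_size=fullmap.pixel_size,
                           origin=fullmap.origin)


@dataclass
class AtomCC:
    """Per-atom interpolated correlation values with validity flags."""

    values: np.ndarray    # NaN where undefined or outside
    inside: np.ndarray    # atom within the interpolatable grid extent
    defined: np.ndarray   # all 8 surrounding voxels carry a defined CC


def atom_cc(cc: CorrelationMap, atoms: list[AtomRecord]) -> AtomCC:
    """Trilinear interpolation of a correlation map at atomic positions.

    Atoms outside the grid are flagged (``inside`` False) rather than
    clamped; atoms whose surrounding voxels include missing values are
    flagged undefined.
    """
    grid = cc.values
    shape = np.asarray(grid.shape)
    n = len(atoms)
    values = np.full(n, np.nan)
    inside = np.zeros(n, dtype=bool)
    defined = np.zeros(n, dtype=bool)
    for i, atom in enumerate(atoms):
        idx = (atom.xyz - cc.origin) / cc.pixel_size
        if np.any(idx < 0) or np.any(idx > shape - 1):
            continue
        inside[i] = True
        i0 = np.minimum(np.floor(idx).astype(int), shape - 2)
        f = idx - i0
        corners = grid[i0[0]:i0[0] + 2, i0[1]:i0[1] + 2, i0[2]:i0[2] + 2]
        if not np.isfinite(corners).all():
            continue
        defined[i] = True
        wx = np.array([1 - f[0], f[0]])
        wy = np.array([1 - f[1], f[1]])
        wz = np.array([1 - f[2], f[2]])
        values[i] = np.einsum("i,j,k,ijk->", wx, wy, wz, corners)
    return AtomCC(values, inside, defined)
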