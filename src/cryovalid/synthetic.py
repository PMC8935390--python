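"""Synthetic fixtures: Gaussian-blob phantoms, half-map pairs with
controlled noise, and rigidly transformed / magnified copies with ground
truth attached.

Everything here is deterministic under its seed.  The transformed-copy
generator works by real-space trilinear resampling — deliberately a
different code path from the Fourier-space route the fitting engine uses,
so parameter-recovery tests are not self-confirming.

Noise is white (flat spectrum): the statistics the package estimates are
per resolution shell, so flat noise exercises them fully while keeping the
analytic expectations simple.  A power-law colored-noise option exists for
stress tests.  The signal-to-noise ratio (SNR) convention is the ratio of
the map's spatial variance to the noise variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .magnification import MagnifiedTransform
from .model_density import DEFAULT_ATOM_PARAMS
from .overlay_fit import RigidTransform
from .voxel_io import AtomRecord, VoxelMap

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "make_half_pair",
    "make_transformed_copy",
    "make_model_for_phantom",
    "default_phantom_spec",
    "noise_sigma_for_snr",
    "add_noise",
]


@dataclass
class PhantomSpec:
    """Recipe for a sum-of-Gaussians phantom.

    ``blobs`` is a list of (center Å, width σ Å, amplitude); the same spec
    and seed always produce a bit-identical map.
    """

    shape: tuple[int, int, int]
    pixel_size: float | tuple[float, float, float]
    blobs: list[tuple[tuple[float, float, float], float, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        extent = np.asarray(self.shape) * np.broadcast_to(
            np.asarray(self.pixel_size, dtype=float), (3,))
        for center, width, _amp in self.blobs:
            if width <= 0:
                raise ValueError(f"blob width must be positive, got {width}")
            if np.any(np.asarray(center) < 0) or np.any(np.asarray(center) >= extent):
                raise ValueError(f"blob center {center} outside grid extent {extent}")


@dataclass
class GroundTruth:
    """What the generator knows: the injected transform, the noise level and
    the clean map (from which per-shell signal power follows)."""

    noise_sigma: float = 0.0
    transform: MagnifiedTransform | None = None
    clean: VoxelMap | None = None
    seed: int = 0

    def signal_power(self, shells) -> np.ndarray:
        """Per-shell mean signal power of the clean map."""
        if self.clean is None:
            raise ValueError("no clean map recorded")
        from .fourier_stats import forward_fft
        return shells.bin_mean(np.abs(forward_fft(self.clean).coeffs) ** 2)

    def noise_power(self) -> float:
        """Per-coefficient noise power of white noise of SD sigma on an
        N-voxel grid under the unnormalized forward DFT: N·sigma²."""
        if self.clean is None:
            raise ValueError("no clean map recorded")
        return float(np.prod(self.clean.shape)) * self.noise_sigma ** 2


def default_phantom_spec(
    shape: int | tuple[int, int, int] = 48,
    pixel_size: float = 1.0,
    n_blobs: int = 14,
    seed: int = 7,
) -> PhantomSpec:
    """An asymmetric multi-blob phantom emulating a globular particle.

    Blob centres are drawn uniformly within ±30% of the box extent around
    the centre and widths in 2–3 Å — density distributed through a
    molecular-envelope-like volume (so orientation is well determined, as
    for a real particle) while Gaussian tails still decay to ~zero at the
    box faces, keeping the periodic-grid analysis free of wrap-around.
    """
    if isinstance(shape, int):
        shape = (shape, shape, shape)
    rng = np.random.default_rng(seed)
    extent = np.asarray(shape) * pixel_size
    blobs = []
    for _ in range(n_blobs):
        center = extent / 2 + rng.uniform(-0.3, 0.3, size=3) * extent
        width = rng.uniform(2.0, 3.0)
        amp = rng.uniform(0.5, 1.0)
        # keep 3 sigma of every tail inside the box: the periodic-grid
        # analysis assumes the density decays to ~zero at the faces
        margin = 3.0 * width
        center = np.clip(center, margin, extent - margin)
        blobs.append((tuple(center), float(width), float(amp)))
    return PhantomSpec(shape, pixel_size, blobs, seed)


def make_phantom(spec: PhantomSpec) -> VoxelMap:
    """Sum of isotropic 3-D Gaussians a·exp(−|x−c|²/2σ²) on the grid."""
    pixel = np.broadcast_to(np.asarray(spec.pixel_size, dtype=float), (3,))
    ax = [np.arange(n) * p for n, p in zip(spec.shape, pixel)]
    data = np.zeros(spec.shape)
    for center, width, amp in spec.blobs:
        c = np.asarray(center, dtype=float)
        r2 = (
            (ax[0][:, None, None] - c[0]) ** 2
            + (ax[1][None, :, None] - c[1]) ** 2
            + (ax[2][None, None, :] - c[2]) ** 2
        )
        data += amp * np.exp(-r2 / (2.0 * width ** 2))
    return VoxelMap(data, pixel)


def noise_sigma_for_snr(vmap: VoxelMap, snr: float) -> float:
    """Noise SD giving the requested variance-ratio SNR for this map."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return float(np.sqrt(np.var(vmap.data) / snr))


def add_noise(vmap: VoxelMap, noise_sigma: float, seed: int,
              colored_alpha: float = 0.0) -> VoxelMap:
    """Map plus Gaussian noise of SD ``noise_sigma``.

    ``colored_alpha`` > 0 shapes the noise spectrum as |s|^(−alpha/2)
    (power-law power spectrum) while keeping the total variance at
    ``noise_sigma²`` — for stress tests only; the default is white.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(vmap.shape)
    if colored_alpha > 0:
        f = np.fft.fftn(noise)
        sx, sy, sz = (np.fft.fftfreq(n, d=p)
                      for n, p in zip(vmap.shape, vmap.pixel_size))
        smag = np.sqrt(sx[:, None, None] ** 2 + sy[None, :, None] ** 2
                       + sz[None, None, :] ** 2)
        smag[0, 0, 0] = smag[smag > 0].min()
        f *= smag ** (-colored_alpha / 2.0)
        noise = np.fft.ifftn(f).real
        noise /= noise.std()
    return VoxelMap(vmap.data + noise_sigma * noise, vmap.pixel_size, vmap.origin)


def make_half_pair(
    vmap: VoxelMap, noise_sigma: float, seed: int
) -> tuple[VoxelMap, VoxelMap, GroundTruth]:
    """Two half maps: the input plus independent white Gaussian noise."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    h1 = add_noise(vmap, noise_sigma, seed)
    h2 = add_noise(vmap, noise_sigma, seed + 1_000_003)
    return h1, h2, GroundTruth(noise_sigma=noise_sigma, clean=vmap.copy(),
                               seed=seed)


def make_transformed_copy(
    vmap: VoxelMap,
    transform: RigidTransform | MagnifiedTransform,
    center=None,
    order: int = 3,
) -> VoxelMap:
    """Copy of the map moved by a (possibly magnified) rigid transform.

    Implements x ← m·R(x−c) + c + t about the grid centre by real-space
    spline resampling (cubic by default) on the periodic grid — a code path
    deliberately independent of the Fourier-space route the fitting engine
    uses.  An identity transform returns the input (spline prefiltering is
    exact at integer sampling positions).
    """
    if isinstance(transform, RigidTransform):
        transform = MagnifiedTransform(rigid=transform)
    if center is None:
        center = vmap.grid_center()
    c_idx = (np.asarray(center, dtype=float) - vmap.origin) / vmap.pixel_size
    R = transform.rigid.matrix
    m = transform.magnification
    t = transform.rigid.translation
    idx = np.indices(vmap.shape).reshape(3, -1).astype(float)
    x = (idx - c_idx[:, None]) * vmap.pixel_size[:, None]
    y = (R.T @ (x - t[:, None])) / m
    src = y / vmap.pixel_size[:, None] + c_idx[:, None]
    data = ndimage.map_coordinates(
        np.asarray(vmap.data, dtype=float), src, order=order, mode="grid-wrap"
    ).reshape(vmap.shape)
    return VoxelMap(data, vmap.pixel_size, vmap.origin)


def make_model_for_phantom(
    spec: PhantomSpec, element: str = "C"
) -> tuple[list[AtomRecord], dict[str, tuple[float, float]]]:
    """Pseudo-atoms (one per blob) whose Gaussian density reproduces the
    phantom, plus the matching element-parameter table for model_to_map.

    A blob of width σ corresponds to B' = 8π²σ²; the atom's B is B' minus
    the element base width, and relative blob amplitudes are encoded in the
    occupancies (scaled so the largest is 1).
    """
    base = DEFAULT_ATOM_PARAMS.get(element, (6.0, 10.0))[1]
    peaks = []
    for center, width, amp in spec.blobs:
        bprime = 8.0 * np.pi ** 2 * width ** 2
        if bprime <= base:
            raise ValueError(f"blob width {width} too narrow for base width {base}")
        # peak density of the atom Gaussian is occ*amp_el*(4pi/B')^{3/2}
        peaks.append((center, bprime, amp / (4.0 * np.pi / bprime) ** 1.5))
    scale = max(p[2] for p in peaks)
    atoms = [
        AtomRecord(position=tuple(center), occupancy=w / scale,
                   b_value=bprime - base, element=element)
        for center, bprime, w in peaks
    ]
    params = {element: (scale, base)}
    return atoms, params
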