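"""Model-derived density maps from atomic records.

Each atom contributes a single isotropic 3-D Gaussian whose spread is its
B value plus a per-element base width:

    ρ_a(x) = occ · amp · (4π / B')^{3/2} · exp(−4π² |x − x_a|² / B'),
    B' = B + base_width  (Å²)

so the atom's Fourier transform is ``occ · amp · exp(−B'|s|²/4)``.  The map
is synthesized in Fourier space (a Gaussian transforms to a Gaussian, so
there are no real-space truncation artifacts) and hard low-pass cut at the
requested resolution.  Amplitudes are a coarse atomic-number proxy — the
correlation machinery needs a plausible model map, not a scattering-factor
tabulation.
"""

from __future__ import annotations

import numpy as np

from .voxel_io import AtomRecord, VoxelMap

__all__ = ["DEFAULT_ATOM_PARAMS", "model_to_map"]

# element -> (amplitude ~ atomic number, base_width added to B, Å²)
DEFAULT_ATOM_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.0, 10.0),
    "C": (6.0, 10.0),
    "N": (7.0, 10.0),
    "O": (8.0, 10.0),
    "P": (15.0, 10.0),
    "S": (16.0, 10.0),
}
_FALLBACK_PARAMS = (6.0, 10.0)


def model_to_map(
    atoms: list[AtomRecord],
    shape: tuple[int, int, int],
    pixel_size,
    resolution: float,
    origin=(0.0, 0.0, 0.0),
    params: dict[str, tuple[float, float]] | None = None,
) -> VoxelMap:
    """Compute a model map on the given grid, band-limited at ``resolution``.

    Atoms must lie inside the grid extent; offenders are reported in the
    error.  The result is linear in atoms and in occupancies.
    """
    pixel_size = np.broadcast_to(np.asarray(pixel_size, dtype=float), (3,)).copy()
    origin = np.asarray(origin, dtype=float)
    if resolution < 2.0 * float(np.max(pixel_size)) - 1e-9:
        raise ValueError(
            f"resolution {resolution} Å is beyond Nyquist for pixels {pixel_size}"
        )
    if params is None:
        params = DEFAULT_ATOM_PARAMS
    extent = np.asarray(shape) * pixel_size
    bad = [
        a for a in atoms
        if np.any(a.xyz < origin) or np.any(a.xyz - origin >= extent)
    ]
    if bad:
        raise ValueError(f"{len(bad)} atoms outside the grid: {bad[:5]}")

    axes = [np.fft.fftfreq(n, d=p) for n, p in zip(shape, pixel_size)]
    s2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    F = np.zeros(shape, dtype=np.complex128)
    for a in atoms:
        amp, base = params.get(a.element, _FALLBACK_PARAMS)
        bprime = a.b_value + base
        gauss = a.occupancy * amp * np.exp(-bprime * s2 / 4.0)
        x = a.xyz - origin
        phase = np.exp(
            -2j * np.pi * (
                axes[0][:, None, None] * x[0]
                + axes[1][None, :, None] * x[1]
                + axes[2][None, None, :] * x[2]
            )
        )
        F += gauss * phase
    F[s2 > (1.0 / resolution) ** 2] = 0.0
    voxel_volume = float(np.prod(pixel_size))
    data = np.fft.ifftn(F).real / voxel_volume
    return VoxelMap(data, pixel_size, origin)
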