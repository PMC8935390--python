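"""Posterior (expected "true") map estimation from N observed maps.

Per resolution shell, the observed maps' Fourier coefficients are modelled
as common signal plus independent noise, summarized by an N×N observed
correlation matrix ρo, a true-signal correlation matrix ρs and a diagonal
matrix of √(full-map FSC) values.  The posterior mean of the normalized
true coefficients is the per-frequency linear map

    ⟨Ft⟩ = ρs · fsc · ρo⁻¹ · Eo

where Eo are the observed coefficients normalized by the per-shell total
(signal+noise) standard deviation.  For N = 1 this collapses to the scalar
Wiener-like weighting ⟨Ft⟩ = √fsc_full · Eo.  Since all matrices are real,
the per-frequency map preserves Hermitian symmetry and the output maps stay
real.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .fourier_stats import (
    FourierMap,
    ShellStatistics,
    estimate_signal_noise,
    fsc as shell_fsc,
)

logger = logging.getLogger(__name__)

__all__ = ["ShellMatrixSet", "build_shell_matrices", "posterior_mean"]

RIDGE_EPS = 1e-4


@dataclass
class ShellMatrixSet:
    """Per-shell N×N correlation matrices and FSC diagonals.

    ``obs_corr`` (ρo) and ``true_corr`` (ρs) are symmetric with unit
    diagonal; ρo is ridge-regularized to keep it invertible.  ``total_sd``
    holds the per-map √(S+σ²) used to normalize coefficients; ``valid``
    flags shells with enough coefficients and positive statistics.
    """

    obs_corr: np.ndarray   # (nbins, N, N)
    true_corr: np.ndarray  # (nbins, N, N)
    fsc_diag: np.ndarray   # (nbins, N) sqrt of full-map FSC, clipped >= 0
    total_sd: np.ndarray   # (nbins, N)
    valid: np.ndarray      # (nbins,)
    shells: ShellStatistics
    per_map_stats: list[ShellStatistics]

    @property
    def n_maps(self) -> int:
        return self.obs_corr.shape[1]


def build_shell_matrices(
    maps: list[tuple[FourierMap, FourierMap, FourierMap]],
    shells: ShellStatistics,
) -> ShellMatrixSet:
    """Build per-shell matrices from (fullmap, half1, half2) triples.

    Diagonals (signal, noise, FSC) come from each map's half pair; the
    cross-map covariances come from the full maps.  Off-diagonal true
    correlations are the observed ones rescaled by
    √((Sᵢᵢ+σᵢ²)(Sⱼⱼ+σⱼ²)/(Sᵢᵢ Sⱼⱼ)), clipped to |ρ| ≤ 1.  Near-singular ρo
    is regularized by a diagonal ridge.
    """
    n = len(maps)
    if n == 0:
        raise ValueError("need at least one (fullmap, half1, half2) triple")
    for full, h1, h2 in maps:
        if full.shape != shells.shape or h1.shape != shells.shape \
                or h2.shape != shells.shape:
            raise ValueError("all maps must share the shells' grid")
    stats = [estimate_signal_noise(h1, h2, shells) for _, h1, h2 in maps]
    nb = shells.nbins

    S = np.stack([st.signal_var for st in stats], axis=1)          # (nb, N)
    # the observed map is the average of the two halves, so its noise
    # variance is half the per-half estimate
    sig2 = np.stack([st.noise_var for st in stats], axis=1) / 2.0
    total = S + sig2
    fsc_full = np.stack(
        [np.nan_to_num(st.fsc_full, nan=0.0) for st in stats], axis=1
    )
    fsc_diag = np.sqrt(np.clip(fsc_full, 0.0, None))

    obs = np.zeros((nb, n, n))
    true = np.zeros((nb, n, n))
    for i in range(n):
        obs[:, i, i] = 1.0
        true[:, i, i] = 1.0
    for i in range(n):
        for j in range(i + 1, n):
            cov = shells.bin_mean(
                (maps[i][0].coeffs * np.conj(maps[j][0].coeffs)).real
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                rho_o = cov / np.sqrt(total[:, i] * total[:, j])
                rho_s = np.where(
                    (S[:, i] > 0) & (S[:, j] > 0),
                    cov / np.sqrt(S[:, i] * S[:, j]),
                    0.0,
                )
            rho_o = np.clip(np.nan_to_num(rho_o, nan=0.0), -1.0, 1.0)
            rho_s = np.clip(np.nan_to_num(rho_s, nan=0.0), -1.0, 1.0)
            obs[:, i, j] = obs[:, j, i] = rho_o
            true[:, i, j] = true[:, j, i] = rho_s
    # ridge regularization keeps rho_o invertible for duplicated maps
    obs = obs + RIDGE_EPS * np.eye(n)[None, :, :]
    obs /= (1.0 + RIDGE_EPS)

    valid = (shells.counts >= 5) & np.all(total > 0, axis=1)
    eigmin = np.linalg.eigvalsh(obs).min(axis=1)
    bad = valid & (eigmin <= 0)
    if np.any(bad):
        logger.warning("%d shells dropped: observed correlation matrix not PSD",
                       int(bad.sum()))
        valid = valid & ~bad
    return ShellMatrixSet(obs, true, fsc_diag, np.sqrt(total), valid,
                          shells, stats)


def posterior_mean(
    maps: list[FourierMap],
    matrices: ShellMatrixSet,
    rescale_to_input: bool = False,
) -> list[FourierMap]:
    """Posterior mean of the normalized true-map coefficients for each input.

    Inputs are the observed full maps in raw units; normalization by the
    per-shell total standard deviation happens internally.  Shells flagged
    invalid contribute zero coefficients.  With ``rescale_to_input`` the
    output is multiplied back by the per-shell signal standard deviation,
    returning maps on roughly the input scale.
    """
    n = matrices.n_maps
    if len(maps) != n:
        raise ValueError(f"expected {n} maps, got {len(maps)}")
    shells = matrices.shells
    for f in maps:
        if f.shape != shells.shape:
            raise ValueError("maps must match the shells' grid")
    nb = shells.nbins

    # per-bin operator  M = rho_s . fsc . rho_o^-1  (acting on Eo vectors)
    M = np.zeros((nb, n, n))
    for b in range(nb):
        if not matrices.valid[b]:
            continue
        try:
            inv = np.linalg.inv(matrices.obs_corr[b])
        except np.linalg.LinAlgError:
            logger.warning("shell %d: singular observed correlation; dropped", b)
            continue
        M[b] = matrices.true_corr[b] @ np.diag(matrices.fsc_diag[b]) @ inv

    bin_index = shells.bin_index
    inside = bin_index >= 0
    binflat = bin_index[inside]
    # normalized coefficients Eo, stacked (N, npoints)
    Eo = np.empty((n, binflat.size), dtype=np.complex128)
    for j, f in enumerate(maps):
        sd = matrices.total_sd[:, j][binflat]
        with np.errstate(invalid="ignore", divide="ignore"):
            Eo[j] = np.where(sd > 0, f.coeffs[inside] / sd, 0.0)
    Mpts = M[binflat]                      # (npoints, N, N)
    Ft = np.einsum("pij,jp->ip", Mpts, Eo)
    if rescale_to_input:
        for j in range(n):
            sig_sd = np.sqrt(matrices.per_map_stats[j].signal_var)[binflat]
            Ft[j] *= sig_sd
    out = []
    for j, f in enumerate(maps):
        coeffs = np.zeros(shells.shape, dtype=np.complex128)
        coeffs[inside] = Ft[j]
        out.append(replace(f, coeffs=coeffs, normalized=not rescale_to_input,
                           weighted=True))
    return out
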