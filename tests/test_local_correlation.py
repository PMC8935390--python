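"""Kernel construction and voxel-wise local correlation."""

import numpy as np
import pytest

from cryovalid.fourier_stats import estimate_signal_noise, forward_fft, make_shells
from cryovalid.local_correlation import (
    atom_cc,
    build_kernel,
    cc_from_moments,
    cc_full_from_halves,
    cc_half_to_full,
    cc_map_model,
    local_moments,
)
from cryovalid.model_density import model_to_map
from cryovalid.synthetic import (
    default_phantom_spec,
    make_half_pair,
    make_model_for_phantom,
    make_phantom,
    noise_sigma_for_snr,
)
from cryovalid.voxel_io import AtomRecord, VoxelMap


class TestKernel:
    def test_sum_is_one(self):
        for r0 in [0.0, 1.0, 2.0, 3.5]:
            k = build_kernel(r0)
            assert k.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_default_edge_two_voxels(self):
        assert build_kernel(3.0).r1 == 5.0

    def test_piecewise_shape(self):
        k = build_kernel(2.0, 4.0)
        rad = k.radius
        center = k.weights[rad, rad, rad]
        # plateau: weight at |x|=2 equals the central weight
        assert k.weights[rad + 2, rad, rad] == pytest.approx(center)
        # zero at and beyond r1
        assert k.weights[rad + 4, rad, rad] == 0.0
        # half the plateau at the midpoint radius (r0+r1)/2 = 3
        assert k.weights[rad + 3, rad, rad] == pytest.approx(center / 2)

    def test_spherical_symmetry(self):
        k = build_kernel(1.5, 3.5)
        rad = k.radius
        w = k.weights
        assert w[rad + 2, rad, rad] == pytest.approx(w[rad, rad + 2, rad])
        assert w[rad, rad + 2, rad] == pytest.approx(w[rad, rad, rad - 2])

    def test_invalid_radii(self):
        with pytest.raises(ValueError):
            build_kernel(3.0, 2.0)


def _brute_force_moments(a, b, kernel):
    """Direct windowed weighted sums at every voxel (circular)."""
    n = a.shape[0]
    rad = kernel.radius
    off = np.arange(-rad, rad + 1)
    w = kernel.weights
    cov = np.empty_like(a)
    v1 = np.empty_like(a)
    v2 = np.empty_like(a)
    for x in range(n):
        for y in range(n):
            for z in range(n):
                ia = a[np.ix_((x + off) % n, (y + off) % n, (z + off) % n)]
                ib = b[np.ix_((x + off) % n, (y + off) % n, (z + off) % n)]
                ma, mb = (w * ia).sum(), (w * ib).sum()
                cov[x, y, z] = (w * ia * ib).sum() - ma * mb
                v1[x, y, z] = (w * ia * ia).sum() - ma * ma
                v2[x, y, z] = (w * ib * ib).sum() - mb * mb
    return cov, v1, v2


class TestLocalMoments:
    def test_matches_brute_force(self, rng):
        a = rng.standard_normal((12, 12, 12))
        b = rng.standard_normal((12, 12, 12))
        k = build_kernel(2.0)
        mom = local_moments(VoxelMap(a, 1.0), VoxelMap(b, 1.0), k)
        cov, v1, v2 = _brute_force_moments(a, b, k)
        np.testing.assert_allclose(mom.cov12, cov, atol=1e-6)
        np.testing.assert_allclose(mom.var1, np.clip(v1, 0, None), atol=1e-6)
        np.testing.assert_allclose(mom.var2, np.clip(v2, 0, None), atol=1e-6)

    def test_constant_maps_zero_moments(self):
        c = VoxelMap(np.full((10, 10, 10), 3.0), 1.0)
        mom = local_moments(c, c, build_kernel(2.0))
        np.testing.assert_allclose(mom.var1, 0.0, atol=1e-12)
        np.testing.assert_allclose(mom.cov12, 0.0, atol=1e-12)

    def test_affine_relation(self, rng):
        a = rng.standard_normal((10, 10, 10))
        b = 2.5 * a + 1.0
        k = build_kernel(2.0)
        mom = local_moments(VoxelMap(a, 1.0), VoxelMap(b, 1.0), k)
        np.testing.assert_allclose(mom.cov12, 2.5 * mom.var1, atol=1e-8)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            local_moments(VoxelMap(np.zeros((8,) * 3), 1.0),
                          VoxelMap(np.zeros((10,) * 3), 1.0),
                          build_kernel(2.0))


class TestCorrelation:
    def test_scaled_map_cc_one(self, phantom32):
        double = VoxelMap(2.0 * phantom32.data, 1.0)
        mom = local_moments(phantom32, double, build_kernel(2.0))
        cc = cc_from_moments(mom)
        np.testing.assert_allclose(cc.values[cc.defined], 1.0, atol=1e-6)

    def test_negated_map_cc_minus_one(self, phantom32):
        neg = VoxelMap(-phantom32.data, 1.0)
        mom = local_moments(phantom32, neg, build_kernel(2.0))
        cc = cc_from_moments(mom)
        np.testing.assert_allclose(cc.values[cc.defined], -1.0, atol=1e-6)

    def test_matches_windowed_pearson(self, rng):
        a = rng.standard_normal((12, 12, 12))
        b = a + 0.5 * rng.standard_normal((12, 12, 12))
        k = build_kernel(2.0)
        cc = cc_from_moments(local_moments(VoxelMap(a, 1.0), VoxelMap(b, 1.0), k))
        cov, v1, v2 = _brute_force_moments(a, b, k)
        expect = cov / np.sqrt(v1 * v2)
        np.testing.assert_allclose(cc.values[cc.defined],
                                   np.clip(expect, -1, 1)[cc.defined],
                                   atol=1e-6)

    @pytest.mark.parametrize("c,expected", [(0.0, 0.0), (1.0, 1.0), (1/3, 0.5)])
    def test_half_to_full_values(self, c, expected):
        from cryovalid.local_correlation import CorrelationMap
        cm = CorrelationMap(np.array([[[c]]]), "half", np.ones(3), np.zeros(3))
        assert cc_half_to_full(cm).values[0, 0, 0] == pytest.approx(expected)

    def test_half_to_full_monotone(self):
        from cryovalid.local_correlation import CorrelationMap
        grid = np.linspace(-0.95, 1.0, 1000).reshape(10, 10, 10)
        cm = CorrelationMap(grid, "half", np.ones(3), np.zeros(3))
        out = cc_half_to_full(cm).values.ravel()
        assert np.all(np.diff(out) > 0)


class TestMapModel:
    @pytest.fixture(scope="class")
    def setup(self):
        spec = default_phantom_spec(48, 1.0)
        ph = make_phantom(spec)
        atoms, params = make_model_for_phantom(spec)
        mm = model_to_map(atoms, ph.shape, ph.pixel_size, 3.0, params=params)
        sigma = noise_sigma_for_snr(ph, 5.0)
        h1, h2, _ = make_half_pair(ph, sigma, seed=9)
        full = VoxelMap((h1.data + h2.data) / 2, ph.pixel_size)
        shells = make_shells(ph.shape, 1.0, resolution_limit=3.0)
        stats = estimate_signal_noise(forward_fft(h1), forward_fft(h2), shells)
        return spec, ph, atoms, params, mm, full, h1, h2, stats

    def test_model_identical_to_map_gives_one(self, setup):
        # identical (already-weighted) inputs correlate to exactly 1;
        # comparing the observed-map and model-map weighting routes on the
        # same array would differ per shell by the noise share
        *_, full, h1, h2, stats = setup
        kern = build_kernel(3.0)
        cc = cc_map_model(full, full.copy(), stats, kern,
                          assume_weighted=True)
        assert np.nanmedian(cc.values) == pytest.approx(1.0, abs=1e-6)

    def test_perfect_model_tracks_ccfull(self, setup):
        spec, ph, atoms, params, mm, full, h1, h2, stats = setup
        kern = build_kernel(4.0)
        ccfull = cc_full_from_halves(h1, h2, stats, kern)
        ccmm = cc_map_model(full, mm, stats, kern)
        d = ccfull.defined & ccmm.defined & (ccfull.values > 0.5)
        ratio = np.median(ccmm.values[d] / ccfull.values[d])
        assert 0.9 <= ratio <= 1.0

    def test_deleted_blob_detected(self, setup):
        spec, ph, atoms, params, mm, full, h1, h2, stats = setup
        kern = build_kernel(4.0)
        mm2 = model_to_map(atoms[1:], ph.shape, ph.pixel_size, 3.0,
                           params=params)
        ccfull = cc_full_from_halves(h1, h2, stats, kern)
        ccmm = cc_map_model(full, mm2, stats, kern)
        idx = tuple(np.round(np.asarray(spec.blobs[0][0])).astype(int))
        assert ccmm.values[idx] < ccfull.values[idx] - 0.2


class TestAtomCC:
    def _cc_map(self, rng):
        from cryovalid.local_correlation import CorrelationMap
        vals = rng.standard_normal((8, 8, 8))
        return CorrelationMap(vals, "full", np.ones(3), np.zeros(3))

    def test_voxel_center_exact(self, rng):
        cc = self._cc_map(rng)
        res = atom_cc(cc, [AtomRecord((2.0, 3.0, 4.0))])
        assert res.values[0] == pytest.approx(cc.values[2, 3, 4])

    def test_midpoint_average(self, rng):
        cc = self._cc_map(rng)
        res = atom_cc(cc, [AtomRecord((2.5, 3.0, 4.0))])
        expect = 0.5 * (cc.values[2, 3, 4] + cc.values[3, 3, 4])
        assert res.values[0] == pytest.approx(expect)

    def test_random_positions_match_oracle(self, rng):
        cc = self._cc_map(rng)
        pos = rng.uniform(0.5, 6.5, size=(10, 3))
        res = atom_cc(cc, [AtomRecord(tuple(p)) for p in pos])
        for i, p in enumerate(pos):
            i0 = np.floor(p).astype(int)
            f = p - i0
            acc = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = ((f[0] if dx else 1 - f[0])
                             * (f[1] if dy else 1 - f[1])
                             * (f[2] if dz else 1 - f[2]))
                        acc += w * cc.values[i0[0] + dx, i0[1] + dy, i0[2] + dz]
            assert res.values[i] == pytest.approx(acc)

    def test_outside_atom_flagged(self, rng):
        cc = self._cc_map(rng)
        res = atom_cc(cc, [AtomRecord((20.0, 1.0, 1.0))])
        assert not res.inside[0]
        assert np.isnan(res.values[0])

    def test_missing_region_flagged(self, rng):
        cc = self._cc_map(rng)
        cc.values[2, 3, 4] = np.nan
        res = atom_cc(cc, [AtomRecord((2.2, 3.2, 4.2))])
        assert res.inside[0] and not res.defined[0]
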