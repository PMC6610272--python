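"""Histogram and GLCM texture features against brute-force enumeration."""

import numpy as np
import pytest

from oracles import (
    all_features_oracle,
    binning_oracle,
    first_order_oracle,
    glcm_features_oracle,
    glcm_oracle,
)
from texsurv.texture import (
    DegenerateGLCMError,
    GLCMatrix,
    TextureConfig,
    build_glcm,
    default_offsets_3d,
    extract_features,
    glcm_features,
    histogram_features,
    quantize,
)
from texsurv.voi import VoxelVolume, make_voi
from conftest import random_voi


def _voi_from(grid, mask=None, spacing=(1.0, 1.0, 1.0)):
    grid = np.asarray(grid, dtype=float)
    volume = VoxelVolume(grid=grid, spacing=spacing)
    mask = np.ones(grid.shape) if mask is None else mask
    return volume, make_voi(volume, mask)


class TestQuantize:
    def test_constant_voi_single_level(self):
        _, voi = _voi_from(np.full((3, 3, 3), 7.0))
        q = quantize(voi, 8)
        assert set(q.levels[q.mask]) == {0}
        assert q.histogram.probabilities[0] == 1.0

    def test_balanced_two_values(self):
        grid = np.zeros((2, 2, 2))
        grid[1] = 1.0
        _, voi = _voi_from(grid)
        q = quantize(voi, 2)
        assert np.allclose(q.histogram.probabilities, [0.5, 0.5])

    def test_matches_per_voxel_binning(self, rng):
        for _ in range(20):
            _, voi = random_voi(rng)
            bins = int(rng.integers(2, 12))
            q = quantize(voi, bins)
            levels, probs = binning_oracle(list(voi.intensities), bins)
            assert np.array_equal(q.levels[q.mask], levels)
            assert np.allclose(q.histogram.probabilities, probs, atol=1e-12)

    def test_rejects_single_bin(self, rng):
        _, voi = random_voi(rng)
        with pytest.raises(ValueError):
            quantize(voi, 1)


class TestHistogramFeatures:
    def test_constant_voi_degenerate(self):
        _, voi = _voi_from(np.full((2, 2, 2), 3.0))
        q = quantize(voi, 16)
        f = histogram_features(q.histogram, voi.intensities)
        assert f["entropy"] == 0.0
        assert f["uniformity"] == 1.0
        assert f["variance"] == 0.0
        assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0
        assert f["degenerate"] == 1.0

    def test_balanced_closed_form(self):
        grid = np.zeros((2, 2, 2))
        grid[1] = 1.0
        _, voi = _voi_from(grid)
        q = quantize(voi, 2)
        f = histogram_features(q.histogram, voi.intensities)
        assert f["entropy"] == pytest.approx(1.0)
        assert f["uniformity"] == pytest.approx(0.5)

    def test_matches_direct_summation(self, rng):
        for _ in range(20):
            _, voi = random_voi(rng)
            bins = int(rng.integers(2, 16))
            q = quantize(voi, bins)
            got = histogram_features(q.histogram, voi.intensities)
            want = first_order_oracle(list(voi.intensities), bins)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k

    def test_entropy_bounded_by_log_bins(self, rng):
        _, voi = random_voi(rng, max_shape=(6, 6, 6))
        for bins in (2, 4, 32):
            f = histogram_features(quantize(voi, bins).histogram, voi.intensities)
            assert 0.0 <= f["entropy"] <= np.log2(bins) + 1e-12


class TestGLCM:
    def test_constant_patch_single_cell(self):
        _, voi = _voi_from(np.full((2, 2, 1), 5.0))
        q = quantize(voi, 4)
        glcm = build_glcm(q, offsets=[(1, 0, 0)])
        assert glcm.matrix[0, 0] == pytest.approx(1.0)

    def test_alternating_strip(self):
        # strip 0,1,0,1 along x: ordered pairs (0,1),(1,0),(0,1); symmetrized
        grid = np.array([0.0, 1.0, 0.0, 1.0]).reshape(4, 1, 1)
        _, voi = _voi_from(grid)
        q = quantize(voi, 2)
        glcm = build_glcm(q, offsets=[(1, 0, 0)], symmetric=True)
        assert glcm.matrix[0, 1] == pytest.approx(0.5)
        assert glcm.matrix[1, 0] == pytest.approx(0.5)
        assert glcm.matrix[0, 0] == glcm.matrix[1, 1] == 0.0

    def test_matches_pair_enumeration(self, rng):
        offsets = default_offsets_3d()
        for _ in range(15):
            _, voi = random_voi(rng, discrete=True)
            bins = int(rng.integers(2, 8))
            q = quantize(voi, bins)
            try:
                glcm = build_glcm(q, offsets)
            except DegenerateGLCMError:
                assert voi.voxel_count == 1 or not _has_neighbour_pair(voi.mask)
                continue
            want = glcm_oracle(q.levels, q.mask, offsets, bins)
            assert np.allclose(glcm.matrix, want, atol=1e-12)

    def test_single_voxel_degenerate(self):
        _, voi = _voi_from(np.array([[[1.0]]]))
        with pytest.raises(DegenerateGLCMError):
            build_glcm(quantize(voi, 2), default_offsets_3d())

    def test_agrees_with_skimage_in_plane(self, rng):
        skimage = pytest.importorskip("skimage.feature")
        img = rng.integers(0, 4, (6, 7)).astype(np.uint8)
        _, voi = _voi_from(img[..., None].astype(float) + 0.0,
                           mask=np.ones((6, 7, 1)))
        q = quantize(voi, 4)
        # min-max over 0..3 with 4 bins is the identity labelling
        glcm = build_glcm(q, offsets=[(0, 1, 0)], symmetric=True)
        ref = skimage.graycomatrix(img, [1], [0], levels=4, symmetric=True,
                                   normed=True)[:, :, 0, 0]
        assert np.allclose(glcm.matrix, ref, atol=1e-12)


class TestGLCMFeatures:
    def test_single_cell_limits(self):
        _, voi = _voi_from(np.full((2, 2, 1), 5.0))
        glcm = build_glcm(quantize(voi, 4), offsets=[(1, 0, 0)])
        f = glcm_features(glcm)
        assert f["angular_second_moment"] == 1.0
        assert f["glcm_entropy"] == 0.0
        assert f["cluster_prominence"] == pytest.approx(0.0)
        assert f["cluster_shade"] == pytest.approx(0.0)

    def test_two_cell_closed_form(self):
        P = np.zeros((2, 2))
        P[0, 1] = P[1, 0] = 0.5
        f = glcm_features(GLCMatrix(2, P, ((1, 0, 0),), True))
        assert f["angular_second_moment"] == pytest.approx(0.5)
        assert f["glcm_entropy"] == pytest.approx(1.0)
        assert f["cluster_shade"] == pytest.approx(0.0)

    def test_matches_direct_summation(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 9))
            M = rng.random((n, n))
            M = M + M.T
            P = M / M.sum()
            got = glcm_features(GLCMatrix(n, P, ((1, 0, 0),), True))
            want = glcm_features_oracle(P)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k


def _has_neighbour_pair(mask):
    idx = list(zip(*np.nonzero(mask)))
    return any(
        max(abs(a - b) for a, b in zip(p, q)) == 1
        and all(abs(a - b) <= 1 for a, b in zip(p, q))
        for p in idx
        for q in idx
        if p != q
    )


class TestExtractFeatures:
    def test_constant_phantom_composition(self):
        volume, voi = _voi_from(np.full((3, 3, 3), 9.0), spacing=(2.0, 1.0, 1.0))
        f = extract_features(volume, voi)
        assert f["entropy"] == 0.0 and f["uniformity"] == 1.0
        assert f["variance"] == 0.0 and f["skewness"] == 0.0 and f["kurtosis"] == 0.0
        assert f["glcm_entropy"] == 0.0 and f["angular_second_moment"] == 1.0
        assert f["cluster_prominence"] == pytest.approx(0.0)
        assert f["cluster_shade"] == pytest.approx(0.0)
        assert f["volume_cm3"] == pytest.approx(27 * 2.0 / 1000.0)

    def test_shift_invariance(self, rng):
        volume, voi = random_voi(rng, max_shape=(5, 5, 5))
        shifted = VoxelVolume(grid=volume.grid + 17.0, spacing=volume.spacing)
        voi2 = make_voi(shifted, voi.mask)
        f1 = extract_features(volume, voi)
        f2 = extract_features(shifted, voi2)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9, abs=1e-9), k

    def test_affine_transform_behaviour(self, rng):
        """Positive-slope affine maps: min-max features invariant; variance
        scales by slope^2; skewness/kurtosis invariant."""
        volume, voi = random_voi(rng, max_shape=(5, 5, 5))
        a, b = 2.5, -4.0
        scaled = VoxelVolume(grid=a * volume.grid + b, spacing=volume.spacing)
        voi2 = make_voi(scaled, voi.mask)
        f1 = extract_features(volume, voi)
        f2 = extract_features(scaled, voi2)
        for k in ("entropy", "uniformity", "skewness", "kurtosis", "glcm_entropy",
                  "angular_second_moment", "cluster_prominence", "cluster_shade"):
            assert f2[k] == pytest.approx(f1[k], rel=1e-9, abs=1e-9), k
        assert f2["variance"] == pytest.approx(a**2 * f1["variance"], rel=1e-9)

    def test_shade_negates_under_intensity_inversion(self, rng):
        for _ in range(10):
            _, voi = random_voi(rng, discrete=True)
            bins = 7
            q = quantize(voi, bins)
            try:
                g1 = build_glcm(q, default_offsets_3d())
            except DegenerateGLCMError:
                continue
            inv = q.levels.copy()
            inv[q.mask] = bins - 1 - inv[q.mask]
            q2 = type(q)(levels=inv, mask=q.mask, bin_count=bins, histogram=q.histogram)
            g2 = build_glcm(q2, default_offsets_3d())
            f1, f2 = glcm_features(g1), glcm_features(g2)
            assert f2["cluster_shade"] == pytest.approx(-f1["cluster_shade"],
                                                        rel=1e-9, abs=1e-9)
            assert f2["cluster_prominence"] == pytest.approx(
                f1["cluster_prominence"], rel=1e-9, abs=1e-9
            )

    def test_noise_has_lower_uniformity_than_smooth(self, rng):
        """i.i.d.-noise phantoms are less homogeneous than smooth gradients
        both in histogram (uniformity) and GLCM (ASM) terms."""
        wins = 0
        for _ in range(20):
            shape = (6, 6, 6)
            noisy = rng.normal(0, 1, shape)
            smooth = np.linspace(0, 1, 6)[:, None, None] * np.ones(shape)
            smooth = smooth + rng.normal(0, 0.01, shape)
            vol_n, voi_n = _voi_from(noisy)
            vol_s, voi_s = _voi_from(smooth)
            fn = extract_features(vol_n, voi_n)
            fs = extract_features(vol_s, voi_s)
            wins += (fn["uniformity"] < fs["uniformity"]) and (
                fn["angular_second_moment"] < fs["angular_second_moment"]
            )
        assert wins == 20


class TestOracleEquivalence:
    def test_all_features_match_enumeration(self, rng):
        """Exhaustive-enumeration agreement on random VOIs within 5x5x5."""
        offsets = default_offsets_3d()
        cfg = TextureConfig(bin_count=6)
        checked = 0
        while checked < 25:
            volume, voi = random_voi(rng)
            if voi.voxel_count < 2 or not _has_neighbour_pair(voi.mask):
                continue
            got = extract_features(volume, voi, cfg)
            want = all_features_oracle(volume.grid, voi.mask, 6, offsets)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k
            checked += 1
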