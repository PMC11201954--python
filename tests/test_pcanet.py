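"""PCANet stages versus a literal loop-transcription oracle, plus contracts.

The oracle functions below re-implement patch sampling, PCA filtering,
convolution, hashing and block histograms as plain nested loops with no
shared code, so any vectorization mistake in the package shows up as a
numeric mismatch.
"""

import numpy as np
import pytest

from mdte import pcanet
from mdte.pcanet import (
    PCANetModel,
    binary_hash,
    block_histograms,
    block_offsets,
    convolve_stage,
    extract_patches,
    fit_pca_filters,
)

# ---------------------------------------------------------------------------
# literal transcription oracle (dense loops, no optimization)
# ---------------------------------------------------------------------------


def naive_patches(img, k1, k2):
    m, n = img.shape
    pt, pl = (k1 - 1) // 2, (k2 - 1) // 2
    pad = np.zeros((m + k1 - 1, n + k2 - 1))
    pad[pt:pt + m, pl:pl + n] = img
    cols = []
    for i in range(m):
        for j in range(n):
            patch = [pad[i + a, j + b] for a in range(k1) for b in range(k2)]
            patch = np.array(patch)
            cols.append(patch - patch.mean())
    return np.array(cols).T


def naive_conv(img, filt):
    m, n = img.shape
    k1, k2 = filt.shape
    pt, pl = (k1 - 1) // 2, (k2 - 1) // 2
    pad = np.zeros((m + k1 - 1, n + k2 - 1))
    pad[pt:pt + m, pl:pl + n] = img
    out = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            acc = 0.0
            for a in range(k1):
                for b in range(k2):
                    acc += pad[i + a, j + b] * filt[a, b]
            out[i, j] = acc
    return out


def naive_hash(maps):
    L2, m, n = maps.shape
    out = np.zeros((m, n), dtype=np.int64)
    for i in range(m):
        for j in range(n):
            val = 0
            for l in range(1, L2 + 1):
                if maps[l - 1, i, j] > 0:
                    val += 2 ** (l - 1)
            out[i, j] = val
    return out


def naive_block_hist(t_map, bh, bw, overlap, n_bins):
    m, n = t_map.shape
    sr = max(1, int(round(bh * (1 - overlap))))
    sc = max(1, int(round(bw * (1 - overlap))))
    rows = list(range(0, m - bh + 1, sr))
    if rows[-1] != m - bh:
        rows.append(m - bh)
    cols = list(range(0, n - bw + 1, sc))
    if cols[-1] != n - bw:
        cols.append(n - bw)
    hists = []
    for r in rows:
        for c in cols:
            h = np.zeros(n_bins, dtype=np.int64)
            for i in range(r, r + bh):
                for j in range(c, c + bw):
                    h[t_map[i, j]] += 1
            hists.append(h)
    return np.concatenate(hists)


def naive_transform(model, img):
    stage1 = [naive_conv(img, model.W1[l]) for l in range(model.L1)]
    feats = []
    for l in range(model.L1):
        stage2 = np.stack([naive_conv(stage1[l], model.W2[q]) for q in range(model.L2)])
        t_map = naive_hash(stage2)
        feats.append(
            naive_block_hist(t_map, model.block_h, model.block_w,
                             model.overlap_ratio, 2 ** model.L2)
        )
    return np.concatenate(feats)


# ---------------------------------------------------------------------------


class TestPatches:
    def test_patch_matrix_shape_and_centering(self, rng):
        img = rng.standard_normal((32, 96))
        P = extract_patches(img, 3, 3)
        assert P.shape == (9, 32 * 96)
        np.testing.assert_allclose(P.sum(axis=0), 0.0, atol=1e-10)

    def test_constant_image_gives_zero_interior_patches(self):
        # border patches see the zero padding, so only interior patches are
        # exactly constant and hence centred to zero
        m = n = 6
        P = extract_patches(np.full((m, n), 3.5), 3, 3)
        interior = [i * n + j for i in range(1, m - 1) for j in range(1, n - 1)]
        np.testing.assert_allclose(P[:, interior], 0.0, atol=1e-12)

    def test_matches_naive_loops(self, rng):
        img = rng.standard_normal((8, 8))
        np.testing.assert_allclose(extract_patches(img, 3, 3), naive_patches(img, 3, 3), atol=1e-12)


class TestFilters:
    def test_subspace_matches_dense_svd(self, rng):
        P = rng.standard_normal((9, 500))
        P -= P.mean(axis=0, keepdims=True)
        W = fit_pca_filters(P, 4, 3, 3).reshape(4, 9)
        # independent oracle: left singular vectors of the patch matrix
        U = np.linalg.svd(P, full_matrices=False)[0][:, :4]
        angles = np.linalg.svd(W @ U)[1]
        assert np.all(np.abs(angles - 1.0) < 1e-8)

    def test_complete_basis_reconstructs_exactly(self, rng):
        P = rng.standard_normal((9, 400))
        P -= P.mean(axis=0, keepdims=True)
        W = fit_pca_filters(P, 9, 3, 3).reshape(9, 9)
        np.testing.assert_allclose(W.T @ (W @ P), P, atol=1e-8)

    def test_top_l_beats_random_orthonormal_bases(self, rng):
        P = rng.standard_normal((9, 1)) * rng.standard_normal((1, 600))
        P += 0.1 * rng.standard_normal((9, 600))
        P -= P.mean(axis=0, keepdims=True)
        W = fit_pca_filters(P, 3, 3, 3).reshape(3, 9)
        err_pca = np.linalg.norm(P - W.T @ (W @ P))
        for _ in range(100):
            B = np.linalg.qr(rng.standard_normal((9, 3)))[0].T
            assert err_pca <= np.linalg.norm(P - B.T @ (B @ P)) + 1e-9

    def test_l_exceeding_patch_dim_rejected(self, rng):
        with pytest.raises(ValueError, match="patch dimensionality"):
            fit_pca_filters(rng.standard_normal((9, 100)), 10, 3, 3)

    def test_deterministic_sign_convention(self, rng):
        P = rng.standard_normal((9, 300))
        W1 = fit_pca_filters(P, 5, 3, 3)
        W2 = fit_pca_filters(P, 5, 3, 3)
        np.testing.assert_array_equal(W1, W2)
        for f in W1.reshape(5, 9):
            assert f[np.argmax(np.abs(f))] > 0


class TestConvolution:
    def test_delta_filter_is_identity(self, rng):
        img = rng.standard_normal((10, 14))
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        np.testing.assert_allclose(convolve_stage(img, delta[None])[0, 0], img, atol=1e-12)

    def test_output_dimensions(self, rng):
        imgs = rng.standard_normal((4, 32, 96))
        filters = rng.standard_normal((9, 3, 3))
        assert convolve_stage(imgs, filters).shape == (4, 9, 32, 96)

    def test_matches_naive_loops(self, rng):
        img = rng.standard_normal((8, 8))
        filters = rng.standard_normal((3, 3, 3))
        out = convolve_stage(img, filters)[0]
        for l in range(3):
            np.testing.assert_allclose(out[l], naive_conv(img, filters[l]), atol=1e-10)

    def test_filter_larger_than_image_rejected(self, rng):
        with pytest.raises(ValueError):
            convolve_stage(rng.standard_normal((2, 2)), rng.standard_normal((1, 3, 3)))


class TestHashing:
    def test_all_positive_gives_full_code(self):
        maps = np.ones((9, 4, 4))
        np.testing.assert_array_equal(binary_hash(maps), 511)

    def test_nonpositive_gives_zero(self):
        maps = np.zeros((4, 3, 3))  # H(0) = 0: zero is not "greater than 0"
        np.testing.assert_array_equal(binary_hash(maps), 0)

    def test_single_active_map_sets_its_bit(self):
        maps = np.full((4, 2, 2), -1.0)
        maps[2] = 1.0  # map l = 3 (1-based) → bit 2^(3−1) = 4
        np.testing.assert_array_equal(binary_hash(maps), 4)

    def test_matches_naive_loops(self, rng):
        maps = rng.standard_normal((4, 8, 8))
        np.testing.assert_array_equal(binary_hash(maps), naive_hash(maps))


class TestBlockHistograms:
    def test_default_geometry_five_blocks(self):
        assert block_offsets(32, 32, 0.5) == [0]
        assert block_offsets(96, 32, 0.5) == [0, 16, 32, 48, 64]

    def test_flush_final_block(self):
        assert block_offsets(40, 32, 0.5) == [0, 8]
        assert block_offsets(50, 32, 0.5) == [0, 16, 18]

    def test_feature_length_at_defaults(self, rng):
        t_maps = rng.integers(0, 512, (9, 32, 96))
        f = block_histograms(t_maps, 32, 32, 0.5, L2=9)
        assert f.shape == (9 * 512 * 5,) == (23_040,)

    def test_each_block_sums_to_pixel_count(self, rng):
        t_maps = rng.integers(0, 512, (9, 32, 96))
        f = block_histograms(t_maps, 32, 32, 0.5, L2=9).reshape(9 * 5, 512)
        np.testing.assert_array_equal(f.sum(axis=1), 32 * 32)

    def test_zero_overlap_partitions(self, rng):
        t_maps = rng.integers(0, 16, (2, 8, 12))
        f = block_histograms(t_maps, 4, 4, 0.0, L2=4)
        assert f.sum() == 2 * 8 * 12

    def test_matches_naive_loops(self, rng):
        t_map = rng.integers(0, 16, (8, 8))
        out = block_histograms(t_map[None], 4, 4, 0.5, L2=4)
        np.testing.assert_array_equal(out, naive_block_hist(t_map, 4, 4, 0.5, 16))


class TestFitTransform:
    def test_transform_matches_naive_end_to_end(self, rng):
        imgs = rng.standard_normal((5, 8, 8))
        model = pcanet.fit(imgs, k1=3, k2=3, L1=3, L2=4, block_h=4, block_w=4, overlap_ratio=0.5)
        for img in imgs:
            np.testing.assert_array_equal(pcanet.transform(model, img), naive_transform(model, img))

    def test_transform_deterministic(self, rng):
        imgs = rng.standard_normal((4, 16, 16))
        model = pcanet.fit(imgs, L1=4, L2=4, block_h=8, block_w=8)
        img = imgs[0]
        np.testing.assert_array_equal(pcanet.transform(model, img), pcanet.transform(model, img))

    def test_feature_length_formula(self, rng):
        imgs = rng.standard_normal((3, 32, 96))
        model = pcanet.fit(imgs)
        assert model.n_blocks == 5
        assert model.feature_length == 23_040
        assert pcanet.transform(model, imgs[0]).shape == (23_040,)

    def test_degenerate_images_warn_but_complete(self):
        imgs = np.zeros((3, 8, 8))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            model = pcanet.fit(imgs, L1=3, L2=3, block_h=4, block_w=4)
        f = pcanet.transform(model, imgs[0])
        assert f.sum() > 0  # histograms still count every pixel

    def test_shape_mismatch_on_transform(self, rng):
        imgs = rng.standard_normal((3, 8, 8))
        model = pcanet.fit(imgs, L1=3, L2=3, block_h=4, block_w=4)
        with pytest.raises(ValueError, match="shape"):
            pcanet.transform(model, rng.standard_normal((9, 9)))

    def test_model_invariants_enforced(self, rng):
        with pytest.raises(ValueError, match="orthonormal"):
            PCANetModel(
                k1=3, k2=3, L1=2, L2=2,
                W1=np.ones((2, 3, 3)), W2=np.ones((2, 3, 3)),
                block_h=4, block_w=4, overlap_ratio=0.5, input_shape=(8, 8),
            )
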