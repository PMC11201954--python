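"""Two-stage 2D-PCANet feature extraction with hashing and block histograms.

PCANet is a convolutional feature learner with no gradient training: its
filter banks are the leading eigenvectors of the scatter matrix of densely
sampled, mean-centred image patches.  Stage 1 learns L1 filters of size
k1 × k2 from the input images; stage 2 learns L2 filters, of the same
size, from the pooled patches of all stage-1 feature maps.  Every
convolution is a 'same'-size correlation over a zero-padded image, so maps
never shrink.

The output stage binarizes each of the L2 stage-2 maps belonging to one
stage-1 parent (step function at 0), packs the L2 bits into one integer
map with values in [0, 2^L2 − 1] (filter l contributes bit 2^(l−1)), and
pools each integer map into overlapping block histograms.  The final
feature vector has length L1 · 2^L2 · B, where B is the block count — at
the pipeline defaults (32 × 96 input, 32 × 32 blocks, 0.5 overlap) B = 5
and the vector has 9 · 512 · 5 = 23,040 counts.

Filter learning is unsupervised and must be fitted on training data only;
``transform`` uses nothing beyond the fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import get_logger

__all__ = [
    "PCANetModel",
    "extract_patches",
    "fit_pca_filters",
    "convolve_stage",
    "binary_hash",
    "block_histograms",
    "block_offsets",
    "fit",
    "transform",
]

_log = get_logger("pcanet")


@dataclass
class PCANetModel:
    """Fitted stage-1/stage-2 filter banks plus featurization hyperparameters."""

    k1: int
    k2: int
    L1: int
    L2: int
    W1: np.ndarray  # (L1, k1, k2)
    W2: np.ndarray  # (L2, k1, k2)
    block_h: int
    block_w: int
    overlap_ratio: float
    input_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.L1 > self.k1 * self.k2 or self.L2 > self.k1 * self.k2:
            raise ValueError("filter count cannot exceed patch dimensionality k1·k2")
        for name, W, L in (("W1", self.W1, self.L1), ("W2", self.W2, self.L2)):
            W = np.asarray(W, dtype=float)
            if W.shape != (L, self.k1, self.k2):
                raise ValueError(f"{name} must have shape ({L}, {self.k1}, {self.k2})")
            flat = W.reshape(L, -1)
            if not np.allclose(flat @ flat.T, np.eye(L), atol=1e-8):
                raise ValueError(f"{name} filters are not orthonormal")

    @property
    def n_blocks(self) -> int:
        m, n = self.input_shape
        return len(block_offsets(m, self.block_h, self.overlap_ratio)) * len(
            block_offsets(n, self.block_w, self.overlap_ratio)
        )

    @property
    def feature_length(self) -> int:
        return self.L1 * (2 ** self.L2) * self.n_blocks


def extract_patches(image: np.ndarray, k1: int, k2: int) -> np.ndarray:
    """Densely sample mean-centred k1 × k2 patches, one per pixel.

    The image is zero-padded so the patch count is exactly m·n; each column
    of the returned (k1·k2 × m·n) matrix is one vectorized patch with its
    own mean subtracted.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    m, n = image.shape
    pt, pb = (k1 - 1) // 2, k1 // 2
    pl, pr = (k2 - 1) // 2, k2 // 2
    padded = np.pad(image, ((pt, pb), (pl, pr)))
    windows = np.lib.stride_tricks.sliding_window_view(padded, (k1, k2))
    patches = windows.reshape(m * n, k1 * k2).T.copy()
    patches -= patches.mean(axis=0, keepdims=True)
    return patches


def _fix_signs(filters_flat: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|element| entry made positive."""
    out = filters_flat.copy()
    for row in out:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return out


def fit_pca_filters(patches: np.ndarray, L: int, k1: int, k2: int) -> np.ndarray:
    """Top-L eigenvectors of the patch scatter XXᵀ, reshaped to k1 × k2 filters.

    Eigenvectors are ordered by descending eigenvalue with a deterministic
    sign convention.  A (near-)degenerate scatter — e.g. from constant
    training images — still yields a valid orthonormal bank, with a warning.
    """
    d = k1 * k2
    if L > d:
        raise ValueError(f"L={L} exceeds patch dimensionality k1·k2={d}")
    if patches.shape[0] != d:
        raise ValueError(f"patch matrix has {patches.shape[0]} rows, expected {d}")
    if patches.shape[1] <= d:
        raise ValueError("need more patches than the patch dimensionality")
    return _filters_from_scatter(patches @ patches.T, L, k1, k2)


def convolve_stage(images: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """'Same'-size correlation of each image with each filter.

    ``images`` is (n_images, m, n); ``filters`` is (L, k1, k2).  Returns
    (n_images, L, m, n).  Implemented as one im2col matmul per call; a delta
    filter reproduces the image exactly.
    """
    images = np.asarray(images, dtype=float)
    filters = np.asarray(filters, dtype=float)
    if images.ndim == 2:
        images = images[None]
    n_img, m, n = images.shape
    L, k1, k2 = filters.shape
    if k1 > m or k2 > n:
        raise ValueError("filter dimensions exceed image dimensions")
    pt, pb = (k1 - 1) // 2, k1 // 2
    pl, pr = (k2 - 1) // 2, k2 // 2
    padded = np.pad(images, ((0, 0), (pt, pb), (pl, pr)))
    windows = np.lib.stride_tricks.sliding_window_view(padded, (k1, k2), axis=(1, 2))
    cols = windows.reshape(n_img, m * n, k1 * k2)
    maps = cols @ filters.reshape(L, k1 * k2).T  # (n_img, m·n, L)
    return maps.transpose(0, 2, 1).reshape(n_img, L, m, n)


def binary_hash(stage2_group: np.ndarray) -> np.ndarray:
    """Pack one stage-1 parent's L2 binarized maps into an integer map.

    ``stage2_group`` is (L2, m, n); output values lie in [0, 2^L2 − 1] with
    map l contributing bit 2^(l−1) where the map is strictly positive.
    """
    group = np.asarray(stage2_group)
    if group.ndim != 3:
        raise ValueError("expected (L2, m, n) stage-2 maps for one parent")
    L2 = group.shape[0]
    weights = (2 ** np.arange(L2, dtype=np.int64)).reshape(L2, 1, 1)
    return ((group > 0).astype(np.int64) * weights).sum(axis=0)


def block_offsets(size: int, block: int, overlap_ratio: float) -> list[int]:
    """Top-left offsets of sliding blocks: stride block·(1 − overlap), with a
    final flush-to-edge block when the last stride does not align."""
    if block > size:
        raise ValueError(f"block size {block} exceeds map dimension {size}")
    stride = max(1, int(round(block * (1.0 - overlap_ratio))))
    offsets = list(range(0, size - block + 1, stride))
    if offsets[-1] != size - block:
        offsets.append(size - block)
    return offsets


def block_histograms(
    t_maps: np.ndarray, block_h: int, block_w: int, overlap_ratio: float, L2: int
) -> np.ndarray:
    """Concatenated 2^L2-bin block histograms over all L1 integer maps.

    Per map, blocks advance by stride block·(1 − overlap); each block
    contributes a count histogram over the hash alphabet.  Ordering is
    blocks within map, then maps — total length L1 · B · 2^L2.
    """
    t_maps = np.asarray(t_maps)
    if t_maps.ndim == 2:
        t_maps = t_maps[None]
    L1, m, n = t_maps.shape
    n_bins = 2 ** L2
    rows = block_offsets(m, block_h, overlap_ratio)
    cols = block_offsets(n, block_w, overlap_ratio)
    out = np.empty(L1 * len(rows) * len(cols) * n_bins, dtype=np.int64)
    pos = 0
    for l in range(L1):
        for r in rows:
            for c in cols:
                block = t_maps[l, r:r + block_h, c:c + block_w]
                out[pos:pos + n_bins] = np.bincount(block.ravel(), minlength=n_bins)
                pos += n_bins
    return out


def fit(
    images: np.ndarray,
    k1: int = 3,
    k2: int = 3,
    L1: int = 9,
    L2: int = 9,
    block_h: int = 32,
    block_w: int = 32,
    overlap_ratio: float = 0.5,
) -> PCANetModel:
    """Learn the two filter banks from training images (labels unused).

    Stage-1 filters come from the pooled patch scatter of the training
    images; stage-2 filters from the pooled patch scatter of all L1
    stage-1 feature maps of those images.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    if images.ndim != 3 or images.shape[0] < 1:
        raise ValueError("fit requires ≥ 1 training image of identical shape")
    n_img, m, n = images.shape
    d = k1 * k2

    scatter1 = np.zeros((d, d))
    for img in images:
        p = extract_patches(img, k1, k2)
        scatter1 += p @ p.T
    W1 = _filters_from_scatter(scatter1, L1, k1, k2)

    stage1 = convolve_stage(images, W1)  # (n_img, L1, m, n)
    scatter2 = np.zeros((d, d))
    for i in range(n_img):
        for l in range(L1):
            p = extract_patches(stage1[i, l], k1, k2)
            scatter2 += p @ p.T
    W2 = _filters_from_scatter(scatter2, L2, k1, k2)

    return PCANetModel(
        k1=k1, k2=k2, L1=L1, L2=L2, W1=W1, W2=W2,
        block_h=block_h, block_w=block_w, overlap_ratio=overlap_ratio,
        input_shape=(m, n),
    )


def _filters_from_scatter(scatter: np.ndarray, L: int, k1: int, k2: int) -> np.ndarray:
    """Shared eigen-step for pooled scatter matrices (see fit_pca_filters)."""
    d = k1 * k2
    if L > d:
        raise ValueError(f"L={L} exceeds patch dimensionality k1·k2={d}")
    scale = float(np.trace(scatter))
    evals, evecs = np.linalg.eigh(scatter)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # patch mean-centering always nulls the DC direction, so one zero
    # eigenvalue is structural; anything beyond that is a true degeneracy
    n_null = int(np.sum(evals[:L] < 1e-12 * max(scale, 1.0)))
    if scale < 1e-12 or n_null > 1:
        warnings.warn(
            "degenerate patch scatter: trailing PCA filters are an arbitrary "
            "(but deterministic) orthonormal completion",
            RuntimeWarning,
        )
        _log.warning("pcanet: degenerate patch scatter (trace=%.3e)", scale)
    return _fix_signs(evecs[:, :L].T).reshape(L, k1, k2)


def transform(model: PCANetModel, image: np.ndarray) -> np.ndarray:
    """Featurize one image with a fitted model (deterministic).

    Returns the integer count vector of length ``model.feature_length``.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != model.input_shape:
        raise ValueError(f"image shape {image.shape} != model input shape {model.input_shape}")
    stage1 = convolve_stage(image[None], model.W1)[0]          # (L1, m, n)
    stage2 = convolve_stage(stage1, model.W2)                  # (L1, L2, m, n)
    t_maps = np.stack([binary_hash(stage2[l]) for l in range(model.L1)])
    return block_histograms(
        t_maps, model.block_h, model.block_w, model.overlap_ratio, model.L2
    )


def transform_many(model: PCANetModel, images: np.ndarray) -> np.ndarray:
    """Featurize a stack of images; rows are feature vectors."""
    images = np.asarray(images, dtype=float)
    return np.stack([transform(model, img) for img in images])
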