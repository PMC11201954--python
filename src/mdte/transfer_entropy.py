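"""Transfer entropy between channel sequences and connectivity images.

Transfer entropy TE(J→I) is the directed, model-free information flow from
process J to process I: the reduction in conditional entropy of I's next
value when J's past is added to I's own past,

    TE(J→I) = H(i_{t+lag} | i_t^{(k)}) − H(i_{t+lag} | i_t^{(k)}, j_t^{(k)}),

estimated here by plug-in (maximum-likelihood) probabilities over
bin-symbolized sequences.  Binning is equal-frequency (quantile) with 8
symbols by default — scale-invariant, which matters because absolute FrFT
amplitudes differ by orders of magnitude across domains.  Histories default
to k = 1 with a one-step horizon: a 1024-sample epoch cannot support much
larger joint alphabets (8³ cells already ≈ 512).  All entropies are in bits.

For one epoch, pairwise TE over all ordered channel pairs in one FrFT
domain yields a directed channels × channels connectivity matrix with zero
diagonal; the per-domain matrices are cascaded (horizontally concatenated)
into a single channels × (channels · n_domains) image — 32 × 96 at the
pipeline defaults — which is the feature learner's input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frft import DomainRepresentation
from .io_formats import get_logger

__all__ = [
    "TrEnParams",
    "ConnectivityImage",
    "transfer_entropy",
    "tren_matrix",
    "cascade",
    "epoch_image",
]

_log = get_logger("tren")


@dataclass
class TrEnParams:
    """Estimator settings: history length k, horizon lag, symbols per channel."""

    k: int = 1
    lag: int = 1
    bins: int = 8

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("history length k must be ≥ 1")
        if self.lag < 1:
            raise ValueError("lag must be ≥ 1")
        if self.bins < 2:
            raise ValueError("bins must be ≥ 2")

    def min_length(self) -> int:
        return self.k + self.lag + 10 * self.bins


@dataclass
class ConnectivityImage:
    """Cascaded multi-domain transfer-entropy matrix for one epoch.

    ``matrix`` is channels × (channels · n_domains), nonnegative, with a
    zero diagonal inside every square domain block.
    """

    matrix: np.ndarray
    domain_order: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        n = self.matrix.shape[0]
        n_dom = len(self.domain_order) if self.domain_order else self.matrix.shape[1] // n
        if self.matrix.shape[1] != n * n_dom:
            raise ValueError(
                f"width {self.matrix.shape[1]} != channels {n} × domains {n_dom}"
            )
        if (self.matrix < 0).any():
            raise ValueError("connectivity entries must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def domain_block(self, d: int) -> np.ndarray:
        n = self.n_channels
        return self.matrix[:, d * n:(d + 1) * n]


def symbolize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency discretization into ``bins`` symbols.

    Each distinct value maps to the bin containing the midpoint of its
    empirical-CDF mass, so the value → symbol map is deterministic, invariant
    under monotone rescaling, and handles heavily tied (discrete) data
    without merging or splitting value groups.
    """
    x = np.asarray(x, dtype=float)
    uniq, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    cum_before = np.cumsum(counts) - counts
    mid = (cum_before + counts / 2.0) / x.size
    sym_per_value = np.minimum((mid * bins).astype(np.int64), bins - 1)
    return sym_per_value[inv]


def _history_codes(sym: np.ndarray, k: int, bins: int) -> np.ndarray:
    """Code of the k-sample history ending at each index t ≥ k − 1."""
    n = sym.shape[-1]
    code = sym[..., k - 1: n].astype(np.int64).copy()
    for m in range(1, k):
        code = code * bins + sym[..., k - 1 - m: n - m]
    return code


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _te_from_codes(
    fut: np.ndarray, tgt_hist: np.ndarray, src_hist: np.ndarray, bins: int, k: int
) -> float:
    """Plug-in TE in bits from aligned symbol/history code arrays."""
    hk = bins ** k
    joint = (fut * hk + tgt_hist) * hk + src_hist
    counts = np.bincount(joint, minlength=bins * hk * hk).reshape(bins, hk, hk)
    h_f_tp_sp = _entropy_from_counts(counts.ravel())
    h_tp_sp = _entropy_from_counts(counts.sum(axis=0).ravel())
    h_f_tp = _entropy_from_counts(counts.sum(axis=2).ravel())
    h_tp = _entropy_from_counts(counts.sum(axis=(0, 2)))
    te = (h_f_tp - h_tp) - (h_f_tp_sp - h_tp_sp)
    if te < -1e-9:
        _log.warning("plug-in TE estimate %.3e below -1e-9; clamping to 0", te)
    return max(te, 0.0)


def transfer_entropy(
    source: np.ndarray, target: np.ndarray, params: TrEnParams | None = None
) -> float:
    """TE(source → target) in bits over bin-symbolized sequences.

    Nonnegative by construction (tiny negative plug-in artifacts are clamped
    to zero).  Sequences must be equal-length and long enough to populate
    the joint histogram (> k + lag + 10·bins samples).
    """
    params = params or TrEnParams()
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 1:
        raise ValueError("source and target must be equal-length 1-D sequences")
    n = source.shape[0]
    if n <= params.min_length():
        raise ValueError(
            f"sequences of length {n} too short; need > {params.min_length()} samples"
        )
    k, lag, bins = params.k, params.lag, params.bins
    s_sym = symbolize(source, bins)
    t_sym = symbolize(target, bins)
    t_hist = _history_codes(t_sym, k, bins)   # histories ending at t = k−1 … n−1
    s_hist = _history_codes(s_sym, k, bins)
    # future i_{t+lag} aligned with histories ending at t
    fut = t_sym[k - 1 + lag:]
    m = fut.shape[0]
    return _te_from_codes(fut.astype(np.int64), t_hist[:m], s_hist[:m], bins, k)


def tren_matrix(rep: DomainRepresentation | np.ndarray, params: TrEnParams | None = None) -> np.ndarray:
    """Directed channels × channels TE matrix for one domain representation.

    Entry (i, j) is TE(channel_i → channel_j); the diagonal is zero and the
    matrix is generally asymmetric.  Channels are symbolized once and all
    ordered pairs share the symbol arrays.
    """
    params = params or TrEnParams()
    data = rep.coeffs if isinstance(rep, DomainRepresentation) else np.asarray(rep, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a 2-D representation with ≥ 2 channels")
    n_ch, n = data.shape
    if n <= params.min_length():
        raise ValueError(
            f"sequences of length {n} too short; need > {params.min_length()} samples"
        )
    k, lag, bins = params.k, params.lag, params.bins
    syms = np.empty((n_ch, n), dtype=np.int64)
    for c in range(n_ch):
        syms[c] = symbolize(data[c], bins)
    hists = _history_codes(syms, k, bins)
    m = n - (k - 1) - lag
    futs = syms[:, k - 1 + lag:]
    out = np.zeros((n_ch, n_ch))
    for j in range(n_ch):
        fut = futs[j]
        tp = hists[j, :m]
        for i in range(n_ch):
            if i == j:
                continue
            out[i, j] = _te_from_codes(fut, tp, hists[i, :m], bins, k)
    return out


def cascade(matrices: "list[np.ndarray]", domain_order: "list[float] | None" = None) -> ConnectivityImage:
    """Horizontally concatenate per-domain TE matrices into one image.

    Three 32 × 32 matrices yield a 32 × 96 image; a single domain passes
    through unchanged (supporting single-domain ablation runs).
    """
    if not matrices:
        raise ValueError("need at least one domain matrix")
    shapes = {m.shape for m in map(np.asarray, matrices)}
    if len(shapes) != 1:
        raise ValueError(f"domain matrices differ in shape: {sorted(shapes)}")
    (shape,) = shapes
    if shape[0] != shape[1]:
        raise ValueError(f"domain matrices must be square, got {shape}")
    order = list(domain_order) if domain_order is not None else list(range(len(matrices)))
    if len(order) != len(matrices):
        raise ValueError("domain_order length must match the number of matrices")
    return ConnectivityImage(
        matrix=np.concatenate([np.asarray(m, dtype=float) for m in matrices], axis=1),
        domain_order=[float(p) for p in order],
    )


def epoch_image(
    reps: "list[DomainRepresentation]", params: TrEnParams | None = None
) -> ConnectivityImage:
    """Full per-epoch pipeline step: TE matrix per domain, then cascade."""
    mats = [tren_matrix(rep, params) for rep in reps]
    return cascade(mats, domain_order=[rep.order for rep in reps])
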