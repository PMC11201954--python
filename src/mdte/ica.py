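"""Blind source separation and artifact-component removal.

The observed EEG ``X`` (channels × samples) is modelled as a linear mixture
``X = A S`` of statistically independent sources ``S``.  Estimation follows
the classical whitening-then-rotation decomposition: a whitening matrix
``Q`` maps the centred data to ``Z = Q (X − mean)`` with identity
covariance, and an orthogonal rotation ``B`` is then found by a FastICA-style
symmetric fixed-point iteration maximizing non-Gaussianity (tanh contrast),
giving sources ``Y = Bᵀ Z`` and demixing matrix ``W = Bᵀ Q``.

Artifact removal reconstructs the data from the estimated mixing matrix
with selected component rows zeroed; by default, components are flagged as
artifacts when their sample excess kurtosis exceeds a threshold — ocular
transients are sparse, heavy-tailed signals, while genuine background EEG
components stay near-Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import get_logger

__all__ = [
    "ICADecomposition",
    "ICAConvergenceError",
    "whiten",
    "fit_ica",
    "remove_components",
    "auto_select_artifacts",
    "denoise",
]

_log = get_logger("ica")


class ICAConvergenceError(RuntimeError):
    pass


@dataclass
class ICADecomposition:
    """Fitted whitening + rotation with derived demixing/mixing matrices.

    Invariants (verified on construction): ``B`` is orthogonal,
    ``W = Bᵀ Q``, and ``W @ A_hat`` is the identity.
    """

    Q: np.ndarray            # whitening matrix (components × channels)
    B: np.ndarray            # orthogonal rotation (components × components)
    W: np.ndarray            # demixing matrix, = Bᵀ Q
    A_hat: np.ndarray        # estimated mixing, pseudo-inverse of W
    sources: np.ndarray      # Y = W (X − mean), components × samples
    channel_means: np.ndarray
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        m = self.B.shape[0]
        if not np.allclose(self.B.T @ self.B, np.eye(m), atol=1e-8):
            raise ValueError("B is not orthogonal")
        if not np.allclose(self.W, self.B.T @ self.Q, atol=1e-8):
            raise ValueError("W != BᵀQ")
        if not np.allclose(self.W @ self.A_hat, np.eye(m), atol=1e-6):
            raise ValueError("W·A_hat is not the identity")

    @property
    def n_components(self) -> int:
        return self.B.shape[0]


def whiten(
    X: np.ndarray, n_components: int | None = None, rank_tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Whiten a channels × samples matrix.

    Returns ``(Z, Q, channel_means)`` with ``Z = Q (X − mean)`` and
    ``cov(Z) = I``.  Whitening uses the eigendecomposition of the sample
    covariance (PCA).  By default all channel dimensions are kept and a
    rank-deficient covariance is rejected rather than silently reduced;
    passing ``n_components`` keeps only the leading eigendirections, which
    is how re-referenced data (exactly rank channels − 1 after common
    average referencing) is handled.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("whitening requires a 2-D matrix with ≥ 2 channels")
    n_ch, n_samp = X.shape
    if n_samp <= n_ch:
        raise ValueError(f"need more samples ({n_samp}) than channels ({n_ch})")
    keep = n_ch if n_components is None else int(n_components)
    if not (2 <= keep <= n_ch):
        raise ValueError(f"n_components must be in [2, {n_ch}], got {keep}")
    means = X.mean(axis=1)
    Xc = X - means[:, None]
    cov = (Xc @ Xc.T) / (n_samp - 1)
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]  # descending variance
    deficient = int(np.sum(evals[:keep] < rank_tol * evals.max()))
    if deficient:
        raise ValueError(
            f"rank-deficient covariance: {deficient} of the requested {keep} "
            f"dimension(s) carry no variance"
        )
    Q = (evecs[:, :keep] / np.sqrt(evals[:keep])).T  # rows whiten eigen-directions
    Z = Q @ Xc
    return Z, Q, means


def _sym_decorrelate(Wr: np.ndarray) -> np.ndarray:
    """Symmetric decorrelation: W ← (W Wᵀ)^(−1/2) W."""
    evals, evecs = np.linalg.eigh(Wr @ Wr.T)
    return (evecs / np.sqrt(evals)) @ evecs.T @ Wr


def fit_rotation(
    Z: np.ndarray,
    seed: int | np.random.Generator = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> tuple[np.ndarray, bool, int]:
    """Symmetric fixed-point search for the orthogonal rotation B.

    Uses the tanh contrast; all rows are updated in parallel followed by
    symmetric decorrelation, so the result does not depend on component
    extraction order.  Returns ``(B, converged, n_iter)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m, n = Z.shape
    # random orthogonal init
    R = rng.standard_normal((m, m))
    Wr = _sym_decorrelate(R)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        WZ = Wr @ Z
        G = np.tanh(WZ)
        g_prime = 1.0 - G ** 2
        W_new = (G @ Z.T) / n - g_prime.mean(axis=1)[:, None] * Wr
        W_new = _sym_decorrelate(W_new)
        delta = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, Wr)) - 1.0)))
        Wr = W_new
        if delta < tol:
            converged = True
            break
    # rows of Wr are the demixing directions in whitened space: Y = Wr Z = Bᵀ Z
    return Wr.T, converged, n_iter


def fit_ica(
    X: np.ndarray,
    seed: int | np.random.Generator = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
    n_components: int | None = None,
    on_fail: str = "raise",
) -> ICADecomposition:
    """Whiten ``X`` and fit the independent-component rotation.

    Deterministic given ``seed``.  If the iteration fails to converge and
    every recovered component is near-Gaussian (|excess kurtosis| < 0.5) the
    rotation is unidentifiable in principle; a valid decomposition is still
    returned with a warning.  Non-convergence on identifiable data raises
    :class:`ICAConvergenceError` when ``on_fail="raise"`` (the default);
    ``on_fail="warn"`` instead returns the last (always valid) decomposition
    with a warning — appropriate for EEG backgrounds whose many
    near-Gaussian directions keep the symmetric rotation from settling even
    though the heavy-tailed artifact directions are already separated.
    """
    if on_fail not in ("raise", "warn"):
        raise ValueError('on_fail must be "raise" or "warn"')
    Z, Q, means = whiten(X, n_components=n_components)
    B, converged, n_iter = fit_rotation(Z, seed=seed, max_iter=max_iter, tol=tol)
    W = B.T @ Q
    Y = B.T @ Z
    if not converged:
        kurt = stats.kurtosis(Y, axis=1, fisher=True)
        if np.all(np.abs(kurt) < 0.5):
            warnings.warn(
                "ICA rotation did not converge but all components are "
                "near-Gaussian; the rotation is unidentifiable and the "
                "returned decomposition is one valid choice",
                RuntimeWarning,
            )
            _log.warning("ICA: unidentifiable (all-Gaussian) rotation after %d iterations", n_iter)
        elif on_fail == "warn":
            warnings.warn(
                f"ICA rotation did not converge after {n_iter} iterations "
                f"(tol={tol}); returning the last iterate",
                RuntimeWarning,
            )
            _log.warning("ICA: non-converged rotation after %d iterations (tol=%g)", n_iter, tol)
        else:
            raise ICAConvergenceError(
                f"ICA did not converge after {n_iter} iterations (tol={tol})"
            )
    A_hat = np.linalg.pinv(W)
    return ICADecomposition(
        Q=Q, B=B, W=W, A_hat=A_hat, sources=Y, channel_means=means,
        converged=converged, n_iter=n_iter,
    )


def remove_components(
    decomp: ICADecomposition,
    reject_idx: "list[int] | np.ndarray | set[int]",
) -> np.ndarray:
    """Reconstruct the data with the rejected component rows zeroed.

    With an empty rejection list this is the identity reconstruction
    ``A_hat · Y + means`` (exact to numerical tolerance).
    """
    reject = sorted(set(int(i) for i in reject_idx))
    m = decomp.n_components
    if any(i < 0 or i >= m for i in reject):
        raise IndexError(f"component index out of range 0..{m - 1}: {reject}")
    Y = decomp.sources.copy()
    if reject:
        Y[reject, :] = 0.0
    return decomp.A_hat @ Y + decomp.channel_means[:, None]


def auto_select_artifacts(decomp: ICADecomposition, threshold: float = 5.0) -> list[int]:
    """Indices of components whose sample excess kurtosis exceeds ``threshold``.

    Heavy-tailed components correspond to sparse transient artifacts
    (blinks, muscle bursts); near-Gaussian components (excess kurtosis ≈ 0)
    are never selected.  Deterministic.
    """
    kurt = stats.kurtosis(decomp.sources, axis=1, fisher=True)
    return [int(i) for i in np.flatnonzero(kurt > threshold)]


def denoise(
    X: np.ndarray,
    seed: int | np.random.Generator = 0,
    threshold: float = 5.0,
    reject: "list[int] | None" = None,
    n_components: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> tuple[np.ndarray, ICADecomposition, list[int]]:
    """Fit ICA, select artifact components (or use a manual list), reconstruct.

    Returns ``(X_clean, decomposition, rejected_indices)``.  Non-convergence
    of the rotation is tolerated with a warning (see :func:`fit_ica`).
    """
    decomp = fit_ica(
        X, seed=seed, n_components=n_components, max_iter=max_iter, tol=tol,
        on_fail="warn",
    )
    idx = list(reject) if reject is not None else auto_select_artifacts(decomp, threshold)
    if idx:
        _log.info("ICA: rejecting %d component(s): %s", len(idx), idx)
    return remove_components(decomp, idx), decomp, idx
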