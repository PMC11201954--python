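"""Discrete fractional Fourier transform (FrFT) by Hermite eigenbasis.

The order-p FrFT generalizes the Fourier transform by a continuous rotation
angle α = pπ/2 in the time–frequency plane: p = 0 is the identity, p = 1
the ordinary Fourier transform, p = 2 signal reversal, and the family is
periodic in p with period 4; the inverse of order p is order −p.

Discretization follows the commuting-matrix construction: the tridiagonal-
plus-circulant Dickinson–Steiglitz matrix ``S`` commutes with the unitary
DFT, so its eigenvectors form a real orthonormal basis of discrete Hermite
functions that diagonalizes the DFT.  Raising the eigenvalues
``exp(−i·π/2·k)`` to the power p gives an operator that is exactly unitary,
exactly order-additive and exactly period-4 — the defining continuous-domain
properties hold to machine precision, at O(N²) cost per transform.

Each 2 s EEG epoch channel (N = 1024 at 512 Hz) is transformed at orders
p ∈ {0, 0.5, 1} and the absolute coefficient amplitude is kept, giving a
time-domain, a time–frequency-domain and a frequency-domain representation
of the same epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "DomainRepresentation",
    "dfrft_operator",
    "frft",
    "multi_domain",
    "dft_matrix",
    "DEFAULT_ORDERS",
]

DEFAULT_ORDERS: tuple[float, ...] = (0.0, 0.5, 1.0)


@dataclass
class DomainRepresentation:
    """Per-epoch absolute FrFT coefficients at one order.

    ``coeffs`` is a nonnegative channels × window_samples matrix |X_p(u)|;
    its shape always equals the source epoch's shape.
    """

    order: float
    coeffs: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 2:
            raise ValueError("coeffs must be 2-D (channels × samples)")
        if (self.coeffs < 0).any():
            raise ValueError("coeffs must be nonnegative (absolute amplitude)")


def dft_matrix(n: int) -> np.ndarray:
    """Unitary DFT matrix F[m, k] = exp(−2πi·mk/N)/√N (the p = 1 reference)."""
    idx = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(idx, idx) / n) / np.sqrt(n)


@lru_cache(maxsize=8)
def _hermite_basis(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigenbasis of the DFT-commuting matrix, with Hermite index assignment.

    Returns ``(U, k)``: columns of ``U`` are real orthonormal DFT
    eigenvectors ordered by Hermite index; ``k`` are the assigned integer
    indices (0..N−2 plus N for even N, 0..N−1 for odd N), so the DFT
    eigenvalue of column j is exp(−i·π/2·k[j]).
    """
    if n < 2:
        raise ValueError("transform length must be ≥ 2")
    idx = np.arange(n)
    # Dickinson–Steiglitz matrix: tridiagonal + corner terms, commutes with DFT
    S = np.zeros((n, n))
    S[idx, idx] = 2.0 * np.cos(2.0 * np.pi * idx / n)
    off = np.ones(n - 1)
    S[idx[:-1], idx[:-1] + 1] = off
    S[idx[:-1] + 1, idx[:-1]] = off
    S[0, n - 1] = 1.0
    S[n - 1, 0] = 1.0
    # S commutes with the parity operator t → −t (mod N); diagonalizing it
    # separately on the even- and odd-symmetric invariant subspaces keeps
    # near-degenerate S eigenvalues from mixing DFT eigenvalue classes.
    half = n // 2
    n_even = half + 1 if n % 2 == 0 else half + 1   # j = 0..⌊N/2⌋
    E = np.zeros((n, n_even))
    E[0, 0] = 1.0
    for c, j in enumerate(range(1, half + 1), start=1):
        if n % 2 == 0 and j == half:
            E[j, c] = 1.0
        else:
            E[j, c] = E[n - j, c] = 1.0 / np.sqrt(2.0)
    n_odd = n - n_even
    O = np.zeros((n, n_odd))
    for c, j in enumerate(range(1, n_odd + 1)):
        O[j, c] = 1.0 / np.sqrt(2.0)
        O[n - j, c] = -1.0 / np.sqrt(2.0)
    ev_e, vec_e = np.linalg.eigh(E.T @ S @ E)
    ev_o, vec_o = np.linalg.eigh(O.T @ S @ O)
    # descending S eigenvalue ↔ ascending zero-crossing (Hermite) count
    even_vecs = (E @ vec_e)[:, ::-1]
    odd_vecs = (O @ vec_o)[:, ::-1]
    # Hermite indices: even vectors take 0,2,4,…; odd take 1,3,5,…;
    # for even N the even class has one extra vector, assigned index N
    even_idx = list(range(0, 2 * n_even - 2, 2))
    even_idx.append(n if n % 2 == 0 else 2 * n_even - 2)
    odd_idx = list(range(1, 2 * n_odd, 2))
    order = np.argsort(even_idx + odd_idx, kind="stable")
    allvecs = np.concatenate([even_vecs, odd_vecs], axis=1)
    allidx = np.array(even_idx + odd_idx)
    U = allvecs[:, order]
    k = allidx[order]
    return U, k


@lru_cache(maxsize=32)
def _operator_cached(n: int, p4: float) -> np.ndarray:
    U, k = _hermite_basis(n)
    lam = np.exp(-1j * np.pi * 0.5 * p4 * k)
    return (U * lam) @ U.T


def dfrft_operator(N: int, p: float) -> np.ndarray:
    """N × N unitary matrix realizing the order-p discrete FrFT.

    Exactly the identity at p ≡ 0 (mod 4); reduces to the unitary DFT at
    p = 1 and to the parity (signal-reversal) operator at p = 2.
    """
    if N < 2:
        raise ValueError("N must be ≥ 2")
    p4 = float(p) % 4.0
    if p4 == 0.0:
        return np.eye(N, dtype=complex)
    return _operator_cached(int(N), p4)


def frft(x: np.ndarray, p: float) -> np.ndarray:
    """Order-p fractional Fourier transform of a 1-D signal (or stacked rows).

    Energy is preserved (the operator is unitary); ``frft(frft(x, a), b)``
    equals ``frft(x, a + b)`` and order −p inverts order p.
    """
    x = np.asarray(x)
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")
    n = x.shape[-1]
    op = dfrft_operator(n, p)
    return x @ op.T


def multi_domain(
    epoch: np.ndarray,
    fs: float,
    orders: tuple[float, ...] = DEFAULT_ORDERS,
) -> list[DomainRepresentation]:
    """Absolute FrFT amplitude of every channel at each requested order.

    The p = 0 representation equals |epoch| exactly; all outputs share the
    epoch's shape and are nonnegative.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("epoch must be 2-D (channels × samples)")
    reps = []
    for p in orders:
        if float(p) % 4.0 == 0.0:
            coeffs = np.abs(epoch)
        else:
            coeffs = np.abs(frft(epoch, p))
        reps.append(DomainRepresentation(order=float(p), coeffs=coeffs, fs=fs))
    return reps
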