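"""Fractional Gaussian noise via Davies–Harte circulant embedding.

Subdiffusive (and superdiffusive) trajectories are simulated as fractional
Brownian motion with Hurst exponent H = α/2: a zero-mean Gaussian process with
covariance  Cov[B_H(s), B_H(t)] = ½(s^{2H} + t^{2H} − |t−s|^{2H}).  Its unit-step
increments (fractional Gaussian noise, fGn) are stationary with autocovariance

    γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}).

The circulant-embedding sampler is exact when the embedding is nonnegative
definite (true for all H in (0,1) with the even embedding used here); a
Cholesky factorization of the Toeplitz covariance is kept as a fallback for
numerically borderline cases.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy.linalg import cholesky, toeplitz


def fgn_autocovariance(n: int, hurst: float) -> np.ndarray:
    """Autocovariance γ(0..n−1) of unit-variance fGn with Hurst exponent ``hurst``."""
    k = np.arange(n, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


@functools.lru_cache(maxsize=256)
def _circulant_sqrt_eigs(n: int, hurst: float) -> np.ndarray | None:
    """sqrt of the eigenvalues of the 2n-circulant embedding, or None if indefinite."""
    gamma = fgn_autocovariance(n + 1, hurst)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    eigs = np.fft.fft(row).real
    if eigs.min() < -1e-9 * max(1.0, eigs.max()):
        return None
    return np.sqrt(np.clip(eigs, 0.0, None))


@functools.lru_cache(maxsize=64)
def _cholesky_factor(n: int, hurst: float) -> np.ndarray:
    gamma = fgn_autocovariance(n, hurst)
    cov = toeplitz(gamma)
    # jitter for numerically semidefinite H near the ends of (0, 1)
    return cholesky(cov + 1e-12 * np.eye(n), lower=True)


def _fgn_from_normals(normals: np.ndarray, n: int, hurst: float) -> np.ndarray:
    """Deterministic map from iid standard normals to fGn samples.

    ``normals`` has shape (..., draw_dim) with draw_dim = ``fgn_draw_dim(n, hurst)``.
    Exposed separately so the exactness of the sampler's covariance can be
    verified by propagating basis vectors through the (linear) transform.
    """
    if hurst == 0.5:
        return normals[..., :n].copy()
    sq = _circulant_sqrt_eigs(n, hurst)
    if sq is None:
        chol = _cholesky_factor(n, hurst)
        return normals[..., :n] @ chol.T
    m = 2 * n
    z = np.zeros(normals.shape[:-1] + (m,), dtype=complex)
    # real weights at the symmetric points, conjugate pairs elsewhere
    z[..., 0] = sq[0] * normals[..., 0]
    z[..., n] = sq[n] * normals[..., 1]
    a = normals[..., 2 : 2 + (n - 1)]
    b = normals[..., 2 + (n - 1) :]
    z[..., 1:n] = sq[1:n] * (a + 1j * b) / np.sqrt(2.0)
    z[..., n + 1 :] = np.conj(z[..., n - 1 : 0 : -1])
    return (np.fft.fft(z, axis=-1) / np.sqrt(m)).real[..., :n]


def fgn_draw_dim(n: int, hurst: float) -> int:
    """Number of iid standard normals consumed per fGn sample path of length n."""
    if hurst == 0.5 or _circulant_sqrt_eigs(n, hurst) is None:
        return n
    return 2 * n


def sample_fgn(rng: np.random.Generator, n: int, hurst: float, size: int = 1) -> np.ndarray:
    """Draw ``size`` independent unit-variance fGn paths of length ``n``, shape (size, n)."""
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    normals = rng.standard_normal((size, fgn_draw_dim(n, hurst)))
    return _fgn_from_normals(normals, n, hurst)
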