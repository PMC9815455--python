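"""Second-Order Blind Identification.

Whitening followed by joint approximate diagonalization (Jacobi sweeps of
Givens rotations, Cardoso-Souloumiac angles) of symmetrized lagged
covariance matrices. The lag set is free-form: it always contains
{0..150} and is extended by every lag at which the horizontal EOG
autocorrelation is at least 0.3, which captures the line-return
periodicity of reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Decomposition, Recording

__all__ = ["LagSet", "select_lags", "whiten", "joint_diagonalize", "sobi_decompose"]


@dataclass
class LagSet:
    """Ordered set of non-negative covariance lags (samples)."""

    lags: np.ndarray
    base_max: int = 150

    def __post_init__(self):
        lags = np.unique(np.asarray(self.lags, dtype=int))
        if lags.size and lags[0] < 0:
            raise ValueError("lags must be non-negative")
        base = np.arange(self.base_max + 1)
        self.lags = np.unique(np.concatenate([base, lags]))

    def __iter__(self):
        return iter(self.lags)

    def __len__(self):
        return len(self.lags)

    def restrict(self, n_samples: int) -> "LagSet":
        """Drop lags >= n_samples / 3 (too few samples to estimate)."""
        limit = n_samples // 3
        if self.base_max >= limit:
            raise ValueError("recording too short for the base lag range")
        kept = self.lags[self.lags < limit]
        obj = object.__new__(LagSet)
        obj.lags, obj.base_max = kept, self.base_max
        return obj


def _acf_biased(x: np.ndarray, nlags: int) -> np.ndarray:
    """Biased normalized autocorrelation of the demeaned signal (FFT)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    var = np.dot(x, x)
    if var <= 0:
        raise ValueError("degenerate (constant) signal: autocorrelation undefined")
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[: nlags + 1]
    return acov / var


def select_lags(heog: np.ndarray, base_max: int = 150, acf_threshold: float = 0.3,
                search_max: Optional[int] = None, sfreq: float = 600.0) -> LagSet:
    """Lags {0..base_max} plus every lag with EOG autocorrelation >= threshold.

    ``search_max`` defaults to 2 s of samples; it bounds how far beyond the
    base range periodic structure (line-return sweeps) is searched for.
    """
    heog = np.asarray(heog, dtype=float)
    if search_max is None:
        search_max = int(2.0 * sfreq)
    if heog.size <= search_max:
        raise ValueError("heog shorter than the lag search range")
    acf = _acf_biased(heog, search_max)
    extra = np.flatnonzero(acf >= acf_threshold)
    return LagSet(lags=extra, base_max=base_max)


def whiten(data: np.ndarray, n_components: Optional[int] = None,
           rank_tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA whitening: output has identity zero-lag covariance.

    Returns ``(whitened, whitener, dewhitener)`` with
    ``whitened = whitener @ (data - mean)`` and
    ``dewhitener @ whitener`` the projector onto the retained subspace.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least two channels")
    mu = data.mean(axis=1, keepdims=True)
    X = data - mu
    C = (X @ X.T) / X.shape[1]
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > rank_tol * evals[0]
    if n_components is not None:
        keep[n_components:] = False
    if not keep.any():
        raise ValueError("rank-deficient covariance")
    evals, evecs = evals[keep], evecs[:, keep]
    whitener = (evecs / np.sqrt(evals)).T
    dewhitener = evecs * np.sqrt(evals)
    return whitener @ X, whitener, dewhitener


def joint_diagonalize(matrices: Sequence[np.ndarray], tol: float = 1e-8,
                      max_sweeps: int = 100) -> tuple[np.ndarray, dict]:
    """Orthogonal joint diagonalizer of a set of symmetric matrices.

    Jacobi-like sweeps of Givens rotations chosen to minimize the summed
    squared off-diagonal elements; a sweep with every rotation sine below
    ``tol`` stops the iteration. Returns ``(V, info)`` where the columns of
    the orthogonal ``V`` are the joint eigenvectors and ``info`` carries
    convergence data (non-convergence is a warning, not a failure).
    """
    C = np.array([0.5 * (np.asarray(M) + np.asarray(M).T) for M in matrices], dtype=float)
    K, n, _ = C.shape
    V = np.eye(n)

    def offdiag(C):
        off = C.copy()
        idx = np.arange(n)
        off[:, idx, idx] = 0.0
        return float(np.sum(off ** 2))

    off_history = [offdiag(C)]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        rotated = False
        for p in range(n - 1):
            for q in range(p + 1, n):
                ton = C[:, p, p] - C[:, q, q]
                toff = C[:, p, q] + C[:, q, p]
                g11 = np.dot(ton, ton)
                g22 = np.dot(toff, toff)
                g12 = np.dot(ton, toff)
                ton_g = g11 - g22
                toff_g = 2.0 * g12
                theta = 0.5 * np.arctan2(toff_g, ton_g + np.hypot(ton_g, toff_g))
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) > tol:
                    rotated = True
                    # rotate rows/cols p,q of every matrix
                    Cp, Cq = C[:, p, :].copy(), C[:, q, :].copy()
                    C[:, p, :] = c * Cp + s * Cq
                    C[:, q, :] = -s * Cp + c * Cq
                    Cp, Cq = C[:, :, p].copy(), C[:, :, q].copy()
                    C[:, :, p] = c * Cp + s * Cq
                    C[:, :, q] = -s * Cp + c * Cq
                    Vp, Vq = V[:, p].copy(), V[:, q].copy()
                    V[:, p] = c * Vp + s * Vq
                    V[:, q] = -s * Vp + c * Vq
        off_history.append(offdiag(C))
        if not rotated:
            converged = True
            break
    if not converged:
        warnings.warn("joint_diagonalize did not converge within max_sweeps",
                      RuntimeWarning)
    return V, {"converged": converged, "sweeps": sweeps,
               "off_diagonal": off_history}


def _lagged_cov(Z: np.ndarray, lag: int) -> np.ndarray:
    T = Z.shape[1]
    C = (Z[:, : T - lag] @ Z[:, lag:].T) / (T - lag)
    return 0.5 * (C + C.T)


def sobi_decompose(rec: Recording, lagset: Optional[LagSet] = None,
                   n_components: Optional[int] = None,
                   heog: Optional[np.ndarray] = None,
                   tol: float = 1e-8, max_sweeps: int = 100) -> Decomposition:
    """SOBI on the gradiometer channels of a demeaned recording.

    If ``lagset`` is not given it is selected from ``heog`` (or the
    recording's own EOG_H channel) via the autocorrelation rule.
    """
    meg = rec.data[rec.meg_picks]
    if lagset is None:
        if heog is None:
            heog = rec.channel("EOG_H")
        lagset = select_lags(heog, sfreq=rec.sfreq)
    lagset = lagset.restrict(rec.n_samples)

    Z, whitener, dewhitener = whiten(meg, n_components=n_components)
    mats = [_lagged_cov(Z, int(tau)) for tau in lagset if tau > 0]
    V, jd_info = joint_diagonalize(mats, tol=tol, max_sweeps=max_sweeps)

    W = V.T @ whitener
    A = dewhitener @ V
    sources = W @ meg
    # order components by sensor-space variance they explain
    power = (A ** 2).sum(axis=0) * sources.var(axis=1)
    order = np.argsort(power)[::-1]
    W, A, sources = W[order], A[:, order], sources[order]

    meg_names = [rec.ch_names[i] for i in rec.meg_picks]
    return Decomposition(mixing=A, demixing=W, sources=sources, method="sobi",
                         scale=rec.scale, ch_names=meg_names,
                         info={"lags": np.asarray(lagset.lags),
                               "jd": jd_info})
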