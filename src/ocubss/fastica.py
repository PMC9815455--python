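"""Negentropy-based fixed-point ICA with symmetric orthogonalization.

Used in the two-stage pipeline to extract blinks after saccade removal.
Supports estimating the demixing matrix on a blink-enriched subset of
pages and applying it to the full recording afterwards.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import Decomposition, Recording
from .sobi import whiten

__all__ = ["fastica_decompose", "apply_demixing", "GAUSS_LOGCOSH"]

# E[log cosh(X)] for standard normal X; components whose contrast sits near
# this baseline are rotation-unidentifiable and flagged low-confidence
GAUSS_LOGCOSH = 0.3745672966607133


class FastICAError(RuntimeError):
    """Non-convergence after all restarts; carries the partial result."""

    def __init__(self, msg: str, partial: Optional[Decomposition] = None):
        super().__init__(msg)
        self.partial = partial


def _sym_decorrelation(W: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(W @ W.T)
    evals = np.maximum(evals, 1e-300)
    return (evecs / np.sqrt(evals)) @ evecs.T @ W


def _fixed_point(Z: np.ndarray, n_comp: int, tol: float, max_iter: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, bool, int]:
    T = Z.shape[1]
    W = _sym_decorrelation(rng.standard_normal((n_comp, Z.shape[0])))
    for it in range(max_iter):
        Y = W @ Z
        G = np.tanh(Y)
        g_prime = 1.0 - G ** 2
        W_new = (G @ Z.T) / T - (g_prime.mean(axis=1)[:, None]) * W
        W_new = _sym_decorrelation(W_new)
        conv = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0)))
        W = W_new
        if conv < tol:
            return W, True, it + 1
    return W, False, max_iter


def fastica_decompose(rec: Recording, n_components: Optional[int] = None,
                      tol: float = 1e-6, max_iter: int = 1000,
                      seed: int = 0, restarts: int = 5,
                      max_samples: Optional[int] = None) -> Decomposition:
    """Fixed-point ICA (log-cosh contrast, symmetric orthogonalization).

    The update is ``w <- E[z g(w'z)] - E[g'(w'z)] w`` with ``g = tanh``,
    followed by symmetric decorrelation; convergence when every direction
    satisfies ``|1 - |<w_new, w_old>|| < tol``. Up to ``restarts`` random
    restarts (seeds derived from ``seed``) before raising
    :class:`FastICAError` with the partial result attached.

    ``max_samples`` estimates the rotation on a seeded random column subset
    (the returned demixing matrix and sources still cover all samples).
    """
    meg = rec.data[rec.meg_picks]
    Z, whitener, dewhitener = whiten(meg, n_components=n_components)
    n_comp = Z.shape[0]
    Zest = Z
    if max_samples is not None and Z.shape[1] > max_samples:
        cols = np.sort(np.random.default_rng(seed).choice(
            Z.shape[1], size=max_samples, replace=False))
        Zest = np.ascontiguousarray(Z[:, cols])

    W = None
    for attempt in range(restarts):
        rng = np.random.default_rng(seed + 1000 * attempt)
        W, ok, n_iter = _fixed_point(Zest, n_comp, tol, max_iter, rng)
        if ok:
            break
    meg_names = [rec.ch_names[i] for i in rec.meg_picks]
    demix = W @ whitener
    mixing = dewhitener @ W.T
    sources = demix @ meg
    contrast = np.log(np.cosh(W @ Z)).mean(axis=1)
    dec = Decomposition(
        mixing=mixing, demixing=demix, sources=sources, method="fastica",
        scale=rec.scale, ch_names=meg_names,
        info={"converged": ok, "n_iter": n_iter, "contrast": contrast,
              "low_confidence": np.abs(contrast - GAUSS_LOGCOSH) < 0.01},
    )
    if not ok:
        raise FastICAError("FastICA did not converge after restarts", partial=dec)
    return dec


def apply_demixing(dec: Decomposition, rec_full: Recording) -> Decomposition:
    """Apply an estimated demixing matrix to a (possibly larger) recording.

    The recording is brought to the decomposition's scale first; the mixing
    matrix is unchanged.
    """
    meg = rec_full.data[rec_full.meg_picks]
    names = [rec_full.ch_names[i] for i in rec_full.meg_picks]
    if names != dec.ch_names:
        raise ValueError("channel sets do not match")
    if rec_full.scale != dec.scale:
        meg = meg * (dec.scale / rec_full.scale)
    sources = dec.demixing @ meg
    return Decomposition(mixing=dec.mixing, demixing=dec.demixing,
                         sources=sources, method=dec.method, scale=dec.scale,
                         ch_names=list(dec.ch_names), info=dict(dec.info))
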