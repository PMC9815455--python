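"""Separation-quality metrics."""

from __future__ import annotations

import numpy as np

__all__ = ["amari_index", "best_match_correlations"]


def amari_index(demixing: np.ndarray, mixing_true: np.ndarray) -> float:
    """Permutation/scale-invariant separation error of ``P = W A_true``.

    0 means perfect separation (P is a signed scaled permutation); values
    below ~0.1 indicate good unmixing. Normalized to [0, 1].
    """
    P = np.abs(np.asarray(demixing) @ np.asarray(mixing_true))
    n = P.shape[0]
    if P.shape[1] != n:
        raise ValueError("W A must be square (match component counts)")
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * n * (n - 1)))


def best_match_correlations(estimated: np.ndarray, true: np.ndarray) -> np.ndarray:
    """|corr| between each true source and its best-matching estimate."""
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(true, dtype=float)
    e = est - est.mean(axis=1, keepdims=True)
    t = tru - tru.mean(axis=1, keepdims=True)
    e /= np.linalg.norm(e, axis=1, keepdims=True) + 1e-300
    t /= np.linalg.norm(t, axis=1, keepdims=True) + 1e-300
    R = np.abs(t @ e.T)
    return R.max(axis=1)
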