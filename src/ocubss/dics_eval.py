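"""Frequency-domain beamformer evaluation of artifact removal.

Band-limited sensor cross-spectral densities (Welch cross-periodogram,
1-s Hann segments, 50 % overlap, reading pages only) feed a DICS
beamformer whose weights are common to all conditions: they are computed
from the CSD averaged over the uncleaned and the two cleaned conditions,
with the pseudoinverse rank-limited to the lowest rank among the cleaned
CSDs. The weights are then applied to each condition's fully ranked CSD,
yielding per-grid-point band power, normalized reduction maps, parcel
aggregates and uncorrected two-sided t-tests across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import get_window

from .core import Recording
from .forward import ForwardGrid

__all__ = [
    "DEFAULT_BANDS",
    "CrossSpectralDensity",
    "compute_csd",
    "common_filter",
    "source_power",
    "reduction_maps",
    "make_parcellation",
    "parcel_and_test",
]

DEFAULT_BANDS = [(1, 4), (5, 8), (8, 13), (15, 25), (31, 47), (60, 90)]


@dataclass
class CrossSpectralDensity:
    """Sensor x sensor complex Hermitian CSD for one frequency band."""

    band: tuple[float, float]
    matrix: np.ndarray
    rank: int
    n_segments: int

    def validate(self, tol: float = 1e-10) -> None:
        M = self.matrix
        if np.max(np.abs(M - M.conj().T)) > tol * max(np.max(np.abs(M)), 1e-300):
            raise ValueError("CSD is not Hermitian")
        evals = np.linalg.eigvalsh(M)
        if evals.min() < -1e-10 * max(evals.max(), 1e-300):
            raise ValueError("CSD has a significantly negative eigenvalue")


def _reading_segments(rec: Recording, n_per: int, n_step: int) -> list[int]:
    starts = []
    for (s, e), lab in zip(rec.page_spans, rec.page_labels):
        if lab != "reading":
            continue
        t = s
        while t + n_per <= e:
            starts.append(t)
            t += n_step
    return starts


def compute_csd(rec: Recording, band: tuple[float, float], seg_len: float = 1.0,
                overlap: float = 0.5, rank_tol: float = 1e-10,
                ) -> CrossSpectralDensity:
    """Welch-averaged cross-spectral density over the band's FFT bins.

    Only segments fully inside reading pages contribute. The rank is the
    number of eigenvalues above ``rank_tol`` times the largest one.
    """
    lo, hi = band
    if hi > rec.sfreq / 2:
        raise ValueError("band exceeds the Nyquist frequency")
    picks = rec.meg_picks
    X = rec.data[picks]
    n_per = int(round(seg_len * rec.sfreq))
    n_step = max(1, int(round(n_per * (1.0 - overlap))))
    starts = _reading_segments(rec, n_per, n_step)
    if not starts:
        raise ValueError("no reading segment fits the requested length")
    win = get_window("hann", n_per)
    norm = rec.sfreq * np.sum(win ** 2)
    freqs = np.fft.rfftfreq(n_per, 1.0 / rec.sfreq)
    bins = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if bins.size == 0:
        bins = np.array([np.argmin(np.abs(freqs - 0.5 * (lo + hi)))])

    m = X.shape[0]
    C = np.zeros((m, m), dtype=complex)
    for s in starts:
        seg = X[:, s:s + n_per] * win
        F = np.fft.rfft(seg, axis=1)[:, bins] / np.sqrt(norm)
        C += F @ F.conj().T
    C /= len(starts) * bins.size
    C = 0.5 * (C + C.conj().T)
    evals = np.linalg.eigvalsh(C)
    rank = int(np.sum(evals > rank_tol * max(evals.max(), 1e-300)))
    return CrossSpectralDensity(band=band, matrix=C, rank=rank,
                                n_segments=len(starts))


def _rank_limited_pinv(C: np.ndarray, k: int) -> np.ndarray:
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:k]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 0
    evals, evecs = evals[pos], evecs[:, pos]
    return (evecs / evals) @ evecs.conj().T


def common_filter(csd_uncleaned: CrossSpectralDensity,
                  csd_p1: CrossSpectralDensity, csd_p2: CrossSpectralDensity,
                  grid: ForwardGrid, rank: Optional[int] = None,
                  ) -> np.ndarray:
    """Common DICS beamformer weights from the condition-averaged CSD.

    The pseudoinverse is truncated to the lowest rank among the two
    cleaned CSDs (or an explicit ``rank``); per grid point, the dipole
    orientation is the dominant eigenvector of the inverted tangential
    power form, and the weights are ``w = (l' C+ l)^-1 l' C+`` for the
    resulting scalar leadfield.

    Returns complex weights, shape ``(n_points, n_channels)``.
    """
    k = rank if rank is not None else min(csd_p1.rank, csd_p2.rank)
    if k <= 0:
        raise ValueError("rank of the cleaned CSDs is zero")
    C_avg = (csd_uncleaned.matrix + csd_p1.matrix + csd_p2.matrix) / 3.0
    Cinv = _rank_limited_pinv(C_avg, k)

    G = grid.leadfield                        # (m, P, 2) real
    CG = np.tensordot(Cinv, G, axes=(1, 0))   # (m, P, 2)
    # 2x2 tangential power form per point: M = L' C+ L
    M = np.real(np.einsum("mpa,mpb->pab", G.conj(), CG))
    # orientation maximizing output power = dominant eigenvector of M^-1,
    # i.e. the eigenvector of M with the smallest eigenvalue
    _, evecs = np.linalg.eigh(M)
    ori = evecs[:, :, 0]                               # (P, 2)

    l = np.einsum("mpa,pa->mp", G, ori)                # (m, P) scalar leadfields
    Cl = Cinv @ l                                      # (m, P)
    denom = np.einsum("mp,mp->p", l.conj(), Cl)
    denom = np.where(np.abs(denom) < 1e-300, 1e-300, denom)
    w = (Cl / denom).T.conj()                          # (P, m): w = l'C+ / (l'C+l)
    return w


def source_power(weights: np.ndarray, csd: CrossSpectralDensity) -> np.ndarray:
    """Per-point band power ``Re(w C w^H)`` with the condition's full CSD."""
    if weights.shape[1] != csd.matrix.shape[0]:
        raise ValueError("weights and CSD channel counts differ")
    return np.real(np.einsum("pm,mn,pn->p", weights, csd.matrix, weights.conj()))


def reduction_maps(power_unclean: np.ndarray, power_p1: np.ndarray,
                   power_p2: np.ndarray, eps_frac: float = 1e-12,
                   ) -> dict:
    """Normalized power-reduction and pipeline-difference maps.

    ``red_p = (P_unclean - P_p) / P_unclean`` per pipeline and
    ``diff = (reduction_power_p1 - reduction_power_p2) / reduction_power_p2``
    where ``reduction_power_p = P_unclean - P_p``. Negative reductions are
    preserved; guarded divisions are flagged.
    """
    Pu, P1, P2 = (np.asarray(p, dtype=float) for p in
                  (power_unclean, power_p1, power_p2))
    eps_u = eps_frac * max(np.max(np.abs(Pu)), 1e-300)
    guard_u = np.abs(Pu) < eps_u
    du = np.where(guard_u, 1.0, Pu)
    red1 = np.where(guard_u, 0.0, (Pu - P1) / du)
    red2 = np.where(guard_u, 0.0, (Pu - P2) / du)
    rp2 = Pu - P2
    eps_d = eps_frac * max(np.max(np.abs(rp2)), 1e-300)
    guard_d = np.abs(rp2) < eps_d
    diff = np.where(guard_d, 0.0, ((Pu - P1) - rp2) / np.where(guard_d, 1.0, rp2))
    return {"reduction_p1": red1, "reduction_p2": red2, "difference": diff,
            "guarded": guard_u | guard_d}


def make_parcellation(grid: ForwardGrid) -> tuple[np.ndarray, list[str]]:
    """Deterministic geometric sectors standing in for an anatomical atlas.

    Hemisphere (x sign) crossed with frontal / temporal / parietal /
    occipital sectors from the anterior and vertical coordinates. Returns
    per-point parcel indices and the parcel names.
    """
    pts = grid.points
    hemi = np.where(pts[:, 0] < 0, 0, 1)
    y, z = pts[:, 1], pts[:, 2]
    sector = np.full(pts.shape[0], 2)                 # parietal default
    sector[y > 0.02] = 0                              # frontal
    sector[(y <= 0.02) & (y >= -0.02) & (z < 0.0)] = 1  # temporal
    sector[y < -0.02] = 3                             # occipital
    names = []
    for h in ("left", "right"):
        for s in ("frontal", "temporal", "parietal", "occipital"):
            names.append(f"{h}_{s}")
    ids = hemi * 4 + sector
    return ids, names


def parcel_and_test(diff_maps_by_band: dict, parcel_ids: np.ndarray,
                    parcel_names: Sequence[str], alpha: float = 0.005,
                    diff_threshold: float = 0.05) -> dict:
    """Group statistics over subjects' pipeline-difference maps.

    ``diff_maps_by_band`` maps band -> (n_subjects, n_points). Per point
    and band, a two-sided one-sample t-test against zero at ``alpha``
    (deliberately uncorrected); parcels containing significant points get
    their group-mean difference tabulated, and parcel-band combinations
    whose absolute group mean exceeds ``diff_threshold`` are listed.
    """
    first = next(iter(diff_maps_by_band.values()))
    if first.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    records, pvals, large = [], {}, []
    for band, maps in diff_maps_by_band.items():
        t, p = stats.ttest_1samp(maps, 0.0, axis=0)
        p = np.where(np.isnan(p), 1.0, p)
        sig = p < alpha
        pvals[band] = p
        group_mean = maps.mean(axis=0)
        for pid, name in enumerate(parcel_names):
            in_parcel = parcel_ids == pid
            if not in_parcel.any():
                continue
            mean_diff = float(group_mean[in_parcel].mean())
            has_sig = bool(sig[in_parcel].any())
            records.append({"parcel": name, "band": f"{band[0]}-{band[1]}",
                            "mean_difference": mean_diff,
                            "n_points": int(in_parcel.sum()),
                            "n_significant": int(sig[in_parcel].sum()),
                            "contains_significant": has_sig})
            if abs(mean_diff) > diff_threshold:
                large.append((name, band, mean_diff))
    table = pd.DataFrame.from_records(records)
    return {"table": table,
            "significant_table": table[table["contains_significant"]],
            "pvalues": pvals,
            "large_differences": large,
            "alpha": alpha}
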