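"""Feature-based labelling of decomposition components.

Combines time-series features (sawtooth score, kurtosis, spike rate, EOG
correlations) with gradiometer-pair RMS topographies and a rough
leadfield-correlation localization: component sensor patterns are
correlated against the leadfields of every grid point, the 500
best-correlated points are kept, and the share of those points falling in
the eye region decides whether the component can plausibly be ocular.
Thresholds are configuration, not dogma; a manual override hook is
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats

from .core import Decomposition, Recording
from .forward import ForwardGrid

__all__ = [
    "IdentifyConfig",
    "ComponentReport",
    "localize_component",
    "eog_correlation",
    "sawtooth_score",
    "spike_onsets",
    "classify_component",
    "identify_components",
]


@dataclass(frozen=True)
class IdentifyConfig:
    """Thresholds of the automated component classifier."""

    top_k: int = 500
    eye_fraction_min: float = 0.5
    eog_corr_min: float = 0.6
    sawtooth_min: float = 0.6
    kurtosis_min: float = 5.0       # Pearson kurtosis (normal = 3)
    spike_z: float = 4.0
    spike_match_tol: float = 0.5    # relative blink-count mismatch allowed
    eye_region_radius: float = 0.03


@dataclass
class ComponentReport:
    """Per-component features, localization summary and label."""

    index: int
    label: str                       # 'saccade' | 'blink' | 'other'
    kurtosis: float
    heog_corr: float
    veog_corr: float
    veog_corr_restricted: Optional[float]  # on blink segments only
    sawtooth: float
    spike_rate: float                # spikes / s
    eye_fraction: float
    topography: np.ndarray           # per-site RMS of the two pair weights
    top_points: np.ndarray = field(default_factory=lambda: np.empty((0,), int))
    top_correlations: np.ndarray = field(default_factory=lambda: np.empty(0))
    primary: bool = False
    flagged: bool = False            # e.g. blink-like series with non-ocular origin
    score: float = 0.0

    def validate(self) -> None:
        if not (0.0 <= self.eye_fraction <= 1.0):
            raise ValueError("eye_fraction out of [0, 1]")
        for r in (self.heog_corr, self.veog_corr):
            if abs(r) > 1.0 + 1e-12:
                raise ValueError("correlation out of [-1, 1]")
        if self.label not in ("saccade", "blink", "other"):
            raise ValueError("invalid label")


def pair_rms_topography(column: np.ndarray, site_ids: np.ndarray) -> np.ndarray:
    """Per-site RMS of the two gradiometer weights of a mixing column."""
    sites = np.unique(site_ids)
    out = np.empty(sites.size)
    for k, s in enumerate(sites):
        w = column[site_ids == s]
        out[k] = np.sqrt(np.mean(w ** 2))
    return out


def localize_component(topography: np.ndarray, grid: ForwardGrid,
                       top_k: int = 500, eye_region_radius: float = 0.03,
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Leadfield-correlation localization of a sensor pattern.

    For every grid point the correlation is maximized over tangential
    dipole orientations (closed form: norm of the projection of the
    centred topography onto the span of the centred leadfield columns), so
    the result is invariant to the sign and scale of the topography.
    Returns ``(ranked point indices, correlations, eye_fraction)``.
    """
    t = np.asarray(topography, dtype=float)
    if np.all(t == t[0]):
        raise ValueError("zero-variance topography cannot be localized")
    tc = t - t.mean()
    tn = np.linalg.norm(tc)
    G = grid.leadfield                       # (m, P, 2)
    a = G[:, :, 0] - G[:, :, 0].mean(axis=0)
    b = G[:, :, 1] - G[:, :, 1].mean(axis=0)
    aa = np.einsum("mp,mp->p", a, a)
    bb = np.einsum("mp,mp->p", b, b)
    ab = np.einsum("mp,mp->p", a, b)
    ta = tc @ a
    tb = tc @ b
    det = aa * bb - ab ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        proj2 = (ta ** 2 * bb - 2.0 * ta * tb * ab + tb ** 2 * aa) / det
        # rank-deficient leadfield span: fall back to the better single column
        fallback = np.maximum(ta ** 2 / np.where(aa > 0, aa, np.inf),
                              tb ** 2 / np.where(bb > 0, bb, np.inf))
        proj2 = np.where(det > 1e-30 * np.maximum(aa * bb, 1e-300), proj2, fallback)
    corr = np.sqrt(np.clip(proj2, 0.0, None)) / tn
    corr = np.clip(corr, 0.0, 1.0)

    k = min(top_k, corr.size)
    order = np.argsort(corr)[::-1][:k]
    eye_mask = grid.eye_region_mask(radius=eye_region_radius)
    eye_fraction = float(eye_mask[order].mean())
    return order, corr[order], eye_fraction


def eog_correlation(component: np.ndarray, heog: np.ndarray, veog: np.ndarray,
                    segments: Optional[np.ndarray] = None) -> tuple[float, float]:
    """Pearson correlations of a component with the two EOG channels.

    ``segments`` (boolean mask) optionally restricts the computation to
    samples known to contain artifacts (from eye-tracker markers), which
    sharpens the estimate for sparse artifacts such as blinks.
    """
    c, h, v = (np.asarray(a, dtype=float) for a in (component, heog, veog))
    if segments is not None:
        mask = np.asarray(segments, dtype=bool)
        c, h, v = c[mask], h[mask], v[mask]
    for a in (c, h, v):
        if a.std() == 0:
            raise ValueError("zero-variance input to eog_correlation")
    r_h = float(np.corrcoef(c, h)[0, 1])
    r_v = float(np.corrcoef(c, v)[0, 1])
    return r_h, r_v


def sawtooth_score(component: np.ndarray, sfreq: float) -> float:
    """Correlation of a component with its own asymmetric-ramp template.

    Sharp descents (or ascents, for the mirrored polarity) are detected in
    the smoothed derivative; a piecewise-linear ramp rising between
    consecutive sweep events is least-squares fitted and correlated with
    the component. Near 1 for reading-saccade staircases, near 0 for
    oscillatory or spiky series.
    """
    x = np.asarray(component, dtype=float)
    x = x - x.mean()
    if x.std() == 0:
        return 0.0
    dx = np.diff(x)
    win = max(3, int(0.03 * sfreq))
    dx_s = np.convolve(dx, np.ones(win) / win, mode="same")
    scale = np.median(np.abs(dx_s)) + 1e-30
    best = 0.0
    for sign_ in (1.0, -1.0):
        d = sign_ * dx_s
        thresh = max(6.0 * scale, 0.3 * np.max(np.abs(d)) if np.max(np.abs(d)) > 0 else 0)
        peaks, _ = signal.find_peaks(-d, height=thresh,
                                     distance=max(1, int(0.25 * sfreq)))
        if peaks.size < 3:
            continue
        template = np.zeros_like(x)
        bounds = np.concatenate([[0], peaks, [x.size - 1]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e > s:
                template[s:e] = np.linspace(0.0, 1.0, e - s, endpoint=False)
        template -= template.mean()
        if template.std() == 0:
            continue
        r = abs(np.corrcoef(sign_ * x, template)[0, 1])
        best = max(best, float(r))
    return best


def spike_onsets(component: np.ndarray, sfreq: float, z: float = 4.0,
                 min_separation: float = 0.25) -> np.ndarray:
    """Onsets of high-amplitude spikes (robust z-score threshold).

    Threshold crossings closer together than ``min_separation`` seconds are
    merged into one event, so a single wide pulse with ripples counts once.
    """
    x = np.asarray(component, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826 + 1e-30
    above = np.abs(x - med) / mad > z
    onsets = np.flatnonzero(np.diff(np.concatenate([[0], above.astype(int)])) == 1)
    if onsets.size < 2:
        return onsets
    keep = np.concatenate([[True], np.diff(onsets) >= min_separation * sfreq])
    return onsets[keep]


def classify_component(features: dict, config: IdentifyConfig = IdentifyConfig(),
                       ) -> tuple[str, bool]:
    """Rule-based label from the computed features.

    saccade: sawtooth structure + horizontal EOG correlation + ocular origin;
    blink: spike train matching the blink markers + vertical EOG correlation
    + ocular origin + heavy tails. Everything else is 'other'; blink-like
    series with a non-ocular origin are flagged for manual review.
    """
    eye_ok = features["eye_fraction"] >= config.eye_fraction_min
    # the vertical line-position staircase correlates with the vertical
    # EOG instead of the horizontal one, so either channel qualifies
    eog_r = max(abs(features["heog_corr"]), abs(features["veog_corr"]))
    saccade_like = (features["sawtooth"] >= config.sawtooth_min
                    and eog_r >= config.eog_corr_min)
    spike_ok = features.get("spike_match", True)
    blink_like = (spike_ok
                  and abs(features["veog_corr"]) >= config.eog_corr_min
                  and features["kurtosis"] >= config.kurtosis_min)
    if saccade_like and eye_ok:
        return "saccade", False
    if blink_like and eye_ok:
        return "blink", False
    if (saccade_like or blink_like) and not eye_ok:
        return "other", True
    return "other", False


def identify_components(dec: Decomposition, rec: Recording, grid: ForwardGrid,
                        config: IdentifyConfig = IdentifyConfig(),
                        blink_onsets: Optional[np.ndarray] = None,
                        overrides: Optional[dict] = None,
                        ) -> list[ComponentReport]:
    """Score, localize and label every component of a decomposition.

    ``overrides`` maps component index -> label and wins over the automatic
    rule (the manual-inspection stand-in). The highest-scoring component of
    each artifact label is tagged primary.
    """
    heog = rec.channel("EOG_H")
    veog = rec.channel("EOG_V")
    blink_mask = None
    if "ET_BLINK" in rec.ch_names:
        flag = rec.channel("ET_BLINK") > 0.5 * np.max(
            np.abs(rec.channel("ET_BLINK")) + 1e-300)
        if flag.any() and not flag.all():
            # dilate by ~100 ms so pulse flanks are included
            k = int(0.1 * rec.sfreq)
            blink_mask = np.convolve(flag.astype(float), np.ones(2 * k + 1),
                                     mode="same") > 0
    sources = dec.sources if dec.sources is not None else dec.compute_sources(
        rec.data[rec.meg_picks])
    site_ids = rec.site_ids[rec.meg_picks]
    n_blinks = len(blink_onsets) if blink_onsets is not None else None
    duration = rec.n_samples / rec.sfreq
    # top_k = 500 is calibrated against the ~7000-point 7-mm grid; on
    # coarser grids keep the same *fraction* of points so eye_fraction
    # retains its meaning
    top_k = min(config.top_k, max(30, int(0.07 * grid.n_points)))

    reports = []
    for i in range(dec.n_components):
        comp = sources[i]
        col = dec.mixing[:, i]
        r_h, r_v = eog_correlation(comp, heog, veog)
        r_v_restr = None
        if blink_mask is not None:
            try:
                _, r_v_restr = eog_correlation(comp, heog, veog,
                                               segments=blink_mask)
            except ValueError:
                pass
        saw = sawtooth_score(comp, rec.sfreq)
        kurt = float(stats.kurtosis(comp, fisher=False))
        spikes = spike_onsets(comp, rec.sfreq, z=config.spike_z)
        spike_rate = spikes.size / duration
        if n_blinks is not None and n_blinks > 0:
            # temporal alignment with the markers, not raw counts: sparse
            # noise crossings should not disqualify a true blink component
            win = int(0.3 * rec.sfreq)
            hits = sum(np.any(np.abs(spikes - b) <= win) for b in blink_onsets)
            spike_match = (hits / n_blinks) >= config.spike_match_tol
        else:
            spike_match = spikes.size > 0
        try:
            top_pts, top_corr, eye_frac = localize_component(
                col, grid, top_k=top_k,
                eye_region_radius=config.eye_region_radius)
        except ValueError:
            top_pts, top_corr, eye_frac = np.empty(0, int), np.empty(0), 0.0

        # the blink rule sees the sharper, segment-restricted correlation
        r_v_eff = r_v if r_v_restr is None else max(abs(r_v), abs(r_v_restr))
        features = {"eye_fraction": eye_frac, "sawtooth": saw,
                    "heog_corr": r_h, "veog_corr": r_v_eff, "kurtosis": kurt,
                    "spike_match": spike_match}
        label, flagged = classify_component(features, config)
        if overrides and i in overrides:
            label, flagged = overrides[i], False
        if label == "saccade":
            score = saw * abs(r_h) * eye_frac
        elif label == "blink":
            score = abs(r_v) * eye_frac * min(kurt / 10.0, 1.0)
        else:
            score = 0.0
        rep = ComponentReport(index=i, label=label, kurtosis=kurt,
                              heog_corr=r_h, veog_corr=r_v,
                              veog_corr_restricted=r_v_restr, sawtooth=saw,
                              spike_rate=spike_rate, eye_fraction=eye_frac,
                              topography=pair_rms_topography(col, site_ids),
                              top_points=top_pts, top_correlations=top_corr,
                              flagged=flagged, score=score)
        rep.validate()
        reports.append(rep)

    for lab in ("saccade", "blink"):
        group = [r for r in reports if r.label == lab]
        if group:
            max(group, key=lambda r: r.score).primary = True
    return reports
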