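"""Artifact-component removal and the two end-to-end cleaning pipelines.

Pipeline ``sobi_fastica``: per-page demeaning -> SOBI with EOG-selected
lags -> saccade-component removal -> FastICA on the saccade-cleaned data
(falling back to blink-page enrichment if no blink component is found) ->
blink-component removal. Pipeline ``amica``: demeaning and 1e8 scaling ->
adaptive-mixture ICA with one model, escalated to three models if no
saccade or blink component passes the identification criteria ->
component removal (cross-model removal when the best saccade and blink
components live in different models).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import preprocess
from .amica_lite import AmicaModel, amica_fit, cross_model_remove
from .core import Decomposition, Recording
from .fastica import FastICAError, fastica_decompose, apply_demixing
from .forward import ForwardGrid
from .identify import IdentifyConfig, identify_components
from .sobi import sobi_decompose

__all__ = ["PipelineConfig", "PipelineError", "remove_components", "run_pipeline"]


class PipelineError(RuntimeError):
    """No removable artifact component found; carries a diagnostic report."""

    def __init__(self, msg: str, reports=None):
        super().__init__(msg)
        self.reports = reports


@dataclass
class PipelineConfig:
    n_components: Optional[int] = 40
    amica_max_iter: int = 200
    amica_max_samples: Optional[int] = 60000
    amica_n_mix: int = 3
    fastica_max_iter: int = 500
    fastica_tol: float = 1e-4
    fastica_max_samples: Optional[int] = 60000
    identify: IdentifyConfig = IdentifyConfig()
    seed: int = 0
    # raise PipelineError when no removable component is found, instead of
    # returning the (demeaned) input unchanged
    error_if_none: bool = False


def remove_components(dec: Decomposition, rec: Recording,
                      indices: Sequence[int]) -> Recording:
    """Subtract ``A[:, indices] s[indices]`` from the gradiometer data.

    Works in the decomposition's scale and returns a recording in the
    recording's own units; empty index set returns the data unchanged.
    Page spans are preserved.
    """
    indices = np.asarray(list(indices), dtype=int)
    out = rec.copy()
    if indices.size == 0:
        return out
    if np.any((indices < 0) | (indices >= dec.n_components)):
        raise IndexError("component index out of range")
    picks = rec.meg_picks
    x = rec.data[picks] * (dec.scale / rec.scale)
    s = dec.demixing[indices] @ x
    x_clean = x - dec.mixing[:, indices] @ s
    out.data[picks] = x_clean * (rec.scale / dec.scale)
    return out


def _labelled(reports, label):
    return [r for r in reports if r.label == label]


def _primary(reports, label):
    cands = [r for r in reports if r.label == label and r.primary]
    return cands[0] if cands else None


def _run_sobi_fastica(rec, grid, cfg, prov):
    blink_onsets = preprocess.blink_onsets_from_eyetrack(rec)
    demeaned = preprocess.demean_pages(rec)

    sobi_in = preprocess.apply_scale(demeaned, "sobi")
    dec_sobi = sobi_decompose(sobi_in, n_components=cfg.n_components)
    rep_sobi = identify_components(dec_sobi, sobi_in, grid, cfg.identify,
                                   blink_onsets=blink_onsets)
    sacc = [r.index for r in _labelled(rep_sobi, "saccade")]
    prov["sobi"] = {"lags": dec_sobi.info["lags"].tolist(),
                    "saccade_components": sacc,
                    "labels": [r.label for r in rep_sobi]}
    stage1 = remove_components(dec_sobi, demeaned, sacc)

    def _fastica_reports(rec_est):
        scaled = preprocess.apply_scale(rec_est, "fastica")
        try:
            dec = fastica_decompose(scaled, n_components=cfg.n_components,
                                    max_iter=cfg.fastica_max_iter,
                                    tol=cfg.fastica_tol, seed=cfg.seed,
                                    max_samples=cfg.fastica_max_samples)
        except FastICAError as exc:
            # near-Gaussian residual directions often stall the symmetric
            # iteration; the partial solution is still usable for blinks
            dec = exc.partial
        full_scaled = preprocess.apply_scale(stage1, "fastica")
        dec_full = apply_demixing(dec, full_scaled)
        reps = identify_components(dec_full, full_scaled, grid, cfg.identify,
                                   blink_onsets=blink_onsets)
        return dec_full, reps

    dec_fast, rep_fast = _fastica_reports(stage1)
    enriched = False
    if not _labelled(rep_fast, "blink") and blink_onsets.size:
        # blink-page enrichment: estimate on blink pages, apply everywhere
        try:
            subset, picked = preprocess.select_blink_pages(stage1, blink_onsets)
            dec_fast, rep_fast = _fastica_reports(subset)
            enriched = True
            prov["fastica_enriched_pages"] = picked
        except ValueError:
            pass
    blink = [r.index for r in _labelled(rep_fast, "blink")]
    prov["fastica"] = {"blink_components": blink, "enriched": enriched,
                       "labels": [r.label for r in rep_fast]}
    if not sacc and not blink:
        prov["no_artifacts_found"] = True
        if cfg.error_if_none:
            raise PipelineError("no artifact component found by SOBI-FastICA",
                                reports=(rep_sobi, rep_fast))
    cleaned = remove_components(dec_fast, stage1, blink)
    return cleaned, (rep_sobi, rep_fast), (dec_sobi, dec_fast)


def _amica_reports(models, rec_scaled, grid, cfg, blink_onsets):
    all_reports = []
    for h, mdl in enumerate(models):
        dec = mdl.to_decomposition(rec_scaled)
        reps = identify_components(dec, rec_scaled, grid, cfg.identify,
                                   blink_onsets=blink_onsets)
        all_reports.append((h, dec, reps))
    return all_reports


def _best(all_reports, label):
    best = None
    for h, dec, reps in all_reports:
        for r in reps:
            if r.label == label and (best is None or r.score > best[2].score):
                best = (h, dec, r)
    return best


def _run_amica(rec, grid, cfg, prov):
    blink_onsets = preprocess.blink_onsets_from_eyetrack(rec)
    demeaned = preprocess.demean_pages(rec)
    scaled = preprocess.apply_scale(demeaned, "amica")

    def _fit(n_models):
        return amica_fit(scaled, n_models=n_models, n_mix=cfg.amica_n_mix,
                         max_iter=cfg.amica_max_iter, seed=cfg.seed,
                         n_components=cfg.n_components,
                         max_samples=cfg.amica_max_samples)

    n_models = 1
    models = _fit(1)
    reports = _amica_reports(models, scaled, grid, cfg, blink_onsets)
    best_s, best_b = _best(reports, "saccade"), _best(reports, "blink")
    if best_s is None or best_b is None:
        # model-count policy: escalate only when necessary
        n_models = 3
        models = _fit(3)
        reports = _amica_reports(models, scaled, grid, cfg, blink_onsets)
        best_s, best_b = _best(reports, "saccade"), _best(reports, "blink")
    prov["amica"] = {"n_models": n_models,
                     "labels": [[r.label for r in reps] for _, _, reps in reports]}
    if best_s is None and best_b is None:
        prov["no_artifacts_found"] = True
        if cfg.error_if_none:
            raise PipelineError("no artifact component found by AMICA",
                                reports=[reps for _, _, reps in reports])
        return demeaned, reports, models

    found = [b for b in (best_s, best_b) if b is not None]
    model_idx = {b[0] for b in found}
    if len(model_idx) <= 1:
        h = found[0][0]
        _, dec, reps = reports[h]
        idx = [r.index for r in reps if r.label in ("saccade", "blink")]
        prov["amica"]["removed"] = {"model": h, "components": idx}
        cleaned = remove_components(dec, demeaned, idx)
    else:
        h_a, h_b = best_s[0], best_b[0]
        comps_a = [r.index for r in reports[h_a][2] if r.label == "saccade"]
        comps_b = [r.index for r in reports[h_b][2] if r.label == "blink"]
        prov["amica"]["removed"] = {"cross_model": True,
                                    "model_a": h_a, "components_a": comps_a,
                                    "model_b": h_b, "components_b": comps_b}
        cleaned = cross_model_remove((models[h_a], models[h_b]), scaled,
                                     comps_a, comps_b)
    return cleaned, reports, models


def run_pipeline(rec: Recording, pipeline: str, grid: ForwardGrid,
                 config: Optional[PipelineConfig] = None,
                 ) -> tuple[Recording, dict]:
    """Run one of the two artifact-removal pipelines end to end.

    Returns the cleaned recording (original units, page spans preserved)
    and a provenance log with lags, seeds, component labels and the removed
    index sets. When nothing removable is found (even after model
    escalation) the demeaned input is returned unchanged and the provenance
    carries ``no_artifacts_found``; set ``config.error_if_none`` to get a
    :class:`PipelineError` with the diagnostic reports instead.
    """
    if pipeline not in ("sobi_fastica", "amica"):
        raise ValueError("pipeline must be 'sobi_fastica' or 'amica'")
    cfg = config or PipelineConfig()
    prov: dict = {"pipeline": pipeline, "seed": cfg.seed}
    if pipeline == "sobi_fastica":
        cleaned, reports, decs = _run_sobi_fastica(rec, grid, cfg, prov)
    else:
        cleaned, reports, decs = _run_amica(rec, grid, cfg, prov)
    prov["reports"] = reports
    prov["decompositions"] = decs
    return cleaned, prov
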