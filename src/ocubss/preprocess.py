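"""Data handling before decomposition.

Per-page demeaning (before concatenation), page concatenation,
method-specific scaling (1e10 for FastICA, 1e8 for AMICA, none for SOBI),
restriction to reading pages, and blink-page enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import Recording

__all__ = [
    "MethodScale",
    "SCALE_FACTORS",
    "demean_pages",
    "concatenate_pages",
    "split_pages",
    "restrict_to_label",
    "select_blink_pages",
    "apply_scale",
    "remove_scale",
    "meg_only",
    "blink_onsets_from_eyetrack",
]

SCALE_FACTORS = {"fastica": 1e10, "amica": 1e8, "sobi": 1.0}


@dataclass(frozen=True)
class MethodScale:
    """Method-specific data multiplier; round-trips exactly."""

    method: str

    @property
    def factor(self) -> float:
        try:
            return SCALE_FACTORS[self.method]
        except KeyError:
            raise ValueError(f"unknown method {self.method!r}") from None


def demean_pages(rec: Recording) -> Recording:
    """Zero the mean of every channel within every page span."""
    out = rec.copy()
    for start, stop in out.page_spans:
        if stop <= start:
            raise ValueError("empty page span")
        out.data[:, start:stop] -= out.data[:, start:stop].mean(axis=1, keepdims=True)
    return out


def _check_compatible(recs: Sequence[Recording]) -> None:
    first = recs[0]
    for r in recs[1:]:
        if r.ch_names != first.ch_names or r.sfreq != first.sfreq:
            raise ValueError("recordings have mismatching channels or sfreq")
        if r.scale != first.scale:
            raise ValueError("recordings have mismatching scale")


def concatenate_pages(recs: Sequence[Recording]) -> Recording:
    """Append recordings sample-wise, rebuilding page spans."""
    if not recs:
        raise ValueError("nothing to concatenate")
    _check_compatible(recs)
    out = recs[0].copy()
    out.data = np.concatenate([r.data for r in recs], axis=1)
    spans, labels = [], []
    offset = 0
    for r in recs:
        for (s, e), lab in zip(r.page_spans, r.page_labels):
            spans.append((offset + s, offset + e))
            labels.append(lab)
        offset += r.n_samples
    out.page_spans, out.page_labels = spans, labels
    out.validate()
    return out


def split_pages(rec: Recording) -> list[Recording]:
    """One single-page recording per page span."""
    out = []
    for (s, e), lab in zip(rec.page_spans, rec.page_labels):
        page = rec.copy()
        page.data = rec.data[:, s:e].copy()
        page.page_spans = [(0, e - s)]
        page.page_labels = [lab]
        out.append(page)
    return out


def restrict_to_label(rec: Recording, label: str = "reading") -> Recording:
    """Keep only pages with the given task label (e.g. drop scanning data)."""
    pages = [p for p in split_pages(rec) if p.page_labels[0] == label]
    if not pages:
        raise ValueError(f"no pages labelled {label!r}")
    return concatenate_pages(pages)


def blink_onsets_from_eyetrack(rec: Recording) -> np.ndarray:
    """Blink onset samples from the ET_BLINK eye-tracker flag channel."""
    flag = rec.channel("ET_BLINK") > 0.5
    return np.flatnonzero(np.diff(np.concatenate([[0], flag.astype(int)])) == 1)


def select_blink_pages(rec: Recording, blink_onsets: Iterable[int],
                       ) -> tuple[Recording, list[int]]:
    """Concatenation of the pages that contain at least one blink onset.

    Returns the enriched recording and the selected page indices, so a
    demixing matrix estimated on the enriched data can afterwards be
    applied to all pages.
    """
    onsets = np.asarray(list(blink_onsets), dtype=int)
    pages = split_pages(rec)
    picked = [i for i, (s, e) in enumerate(rec.page_spans)
              if np.any((onsets >= s) & (onsets < e))]
    if not picked:
        raise ValueError("no page contains a blink; enrichment impossible")
    return concatenate_pages([pages[i] for i in picked]), picked


def apply_scale(rec: Recording, method: str) -> Recording:
    """Multiply the data by the method-specific factor (tracked in ``scale``)."""
    factor = MethodScale(method).factor
    out = rec.copy()
    out.data = out.data * factor
    out.scale = rec.scale * factor
    return out


def remove_scale(rec: Recording) -> Recording:
    """Return the data to original units (exact round trip)."""
    out = rec.copy()
    out.data = out.data / out.scale
    out.scale = 1.0
    return out


def meg_only(rec: Recording) -> Recording:
    """Gradiometer channels only; EOG/eye-tracker stay in the source object."""
    return rec.select_channels(rec.meg_picks)
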