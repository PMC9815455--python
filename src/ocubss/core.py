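"""Core data containers for the linear mixing model ``x(t) = A s(t) + n(t)``.

A :class:`Recording` holds multichannel sensor data with page structure,
a :class:`Decomposition` holds the estimated mixing/demixing matrices and
component time courses ``s(t) = W x(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SensorArray",
    "Recording",
    "Decomposition",
    "GRAD",
    "EOG_H",
    "EOG_V",
    "EYETRACK",
]

# channel type tags
GRAD = "grad"
EOG_H = "eog_h"
EOG_V = "eog_v"
EYETRACK = "eyetrack"


@dataclass
class SensorArray:
    """Planar-gradiometer array geometry on a spherical cap.

    Each *site* carries two orthogonal planar gradiometers whose responses
    are modelled as the finite difference of the radial field component at
    the two coil centres, divided by the baseline.

    Attributes
    ----------
    positions : ndarray, shape (n_sites, 3)
        Site centres in head coordinates (m). Origin at sphere centre,
        x = right, y = anterior, z = superior.
    normals : ndarray, shape (n_sites, 3)
        Outward (radial) unit normals.
    tangent1, tangent2 : ndarray, shape (n_sites, 3)
        Unit baseline directions of the two gradiometers of each pair.
    baseline : float
        Coil-centre separation in metres.
    """

    positions: np.ndarray
    normals: np.ndarray
    tangent1: np.ndarray
    tangent2: np.ndarray
    baseline: float = 0.0168

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def n_channels(self) -> int:
        return 2 * self.n_sites

    def channel_names(self) -> list[str]:
        names = []
        for i in range(self.n_sites):
            names.append(f"MEG{i:03d}a")
            names.append(f"MEG{i:03d}b")
        return names

    def coil_centres(self) -> np.ndarray:
        """Coil-centre positions, shape (n_channels, 2, 3).

        Channel ``2*i`` is the tangent1 gradiometer of site ``i`` and
        channel ``2*i + 1`` its orthogonal tangent2 partner.
        """
        half = 0.5 * self.baseline
        out = np.empty((self.n_channels, 2, 3))
        out[0::2, 0] = self.positions + half * self.tangent1
        out[0::2, 1] = self.positions - half * self.tangent1
        out[1::2, 0] = self.positions + half * self.tangent2
        out[1::2, 1] = self.positions - half * self.tangent2
        return out


@dataclass
class Recording:
    """Channels x samples recording with page structure.

    ``data`` is in original physical units times ``scale`` (``scale`` is 1
    unless a method-specific multiplier has been applied; see
    :mod:`ocubss.preprocess`).
    """

    data: np.ndarray  # (n_channels, n_samples)
    ch_names: list[str]
    ch_types: list[str]
    sfreq: float
    page_spans: list[tuple[int, int]]
    site_ids: np.ndarray  # per-channel site id, -1 for non-MEG channels
    pair_ids: np.ndarray  # 0/1 within a site, -1 for non-MEG channels
    page_labels: list[str] = field(default_factory=list)  # 'reading'|'scanning'
    scale: float = 1.0
    sensors: Optional[SensorArray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length does not match data")
        if not self.page_labels:
            self.page_labels = ["reading"] * len(self.page_spans)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def picks(self, ch_type: str) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.ch_types) if t == ch_type], dtype=int)

    @property
    def meg_picks(self) -> np.ndarray:
        return self.picks(GRAD)

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            ch_names=list(self.ch_names),
            ch_types=list(self.ch_types),
            page_spans=list(self.page_spans),
            site_ids=self.site_ids.copy(),
            pair_ids=self.pair_ids.copy(),
            page_labels=list(self.page_labels),
        )

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        """Check page-span and gradiometer-pair invariants."""
        spans = self.page_spans
        if not spans:
            raise ValueError("page_spans must be nonempty")
        prev = 0
        for start, stop in spans:
            if start != prev or stop <= start:
                raise ValueError("page_spans must be disjoint, ordered and contiguous")
            prev = stop
        if prev != self.n_samples:
            raise ValueError("page_spans must cover all samples")
        if len(self.page_labels) != len(spans):
            raise ValueError("page_labels must match page_spans")
        meg = self.meg_picks
        if meg.size:
            sites, counts = np.unique(self.site_ids[meg], return_counts=True)
            if not np.all(counts == 2):
                raise ValueError("every MEG site must carry exactly two gradiometers")

    def select_channels(self, picks: Sequence[int]) -> "Recording":
        picks = np.asarray(picks, dtype=int)
        return replace(
            self,
            data=self.data[picks].copy(),
            ch_names=[self.ch_names[i] for i in picks],
            ch_types=[self.ch_types[i] for i in picks],
            site_ids=self.site_ids[picks].copy(),
            pair_ids=self.pair_ids[picks].copy(),
            page_spans=list(self.page_spans),
            page_labels=list(self.page_labels),
        )


@dataclass
class Decomposition:
    """Result of a blind source separation: ``s(t) = W x(t)``, ``x ~ A s``.

    ``mixing`` (A) is (m, n) and maps components to sensors in the scaled
    data units; ``demixing`` (W) is (n, m). ``scale`` records the
    method-specific multiplier that was applied to the data the
    decomposition was estimated on, so sensor-space reconstructions can be
    returned to original units.
    """

    mixing: np.ndarray
    demixing: np.ndarray
    sources: Optional[np.ndarray]
    method: str
    scale: float = 1.0
    ch_names: list[str] = field(default_factory=list)
    info: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.demixing.shape[0]

    @property
    def n_channels(self) -> int:
        return self.demixing.shape[1]

    def compute_sources(self, data: np.ndarray) -> np.ndarray:
        return self.demixing @ data

    def validate(self, data: Optional[np.ndarray] = None, rtol: float = 1e-8) -> None:
        m, n = self.mixing.shape
        if self.demixing.shape != (n, m):
            raise ValueError("mixing/demixing shapes inconsistent")
        if n > m:
            raise ValueError("more components than channels")
        if data is not None and self.sources is not None:
            err = np.linalg.norm(self.demixing @ data - self.sources)
            ref = np.linalg.norm(self.sources) + 1e-30
            if err > rtol * ref:
                raise ValueError("sources do not equal demixing @ data")
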