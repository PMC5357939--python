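"""Nuclei segmentation from the hematoxylin channel.

Hematoxylin marks nuclei, so candidate nuclei are MSER blobs of the
hematoxylin density image (oriented so nuclei are *bright*: density, not
intensity).  Candidates are kept when their area is plausible for a
nucleus and when they overlap a "high hematoxylin rate" mask — a
tophat / maximum-filter / Gaussian / intensity-adjustment pipeline
thresholded with Otsu's method — which rejects stable blobs that are not
actually strongly stained.  The surviving regions yield centroids and a
binary nuclei location map consumed by the arrangement features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter
from skimage.morphology import disk, white_tophat

from .mser import CandidateRegion, MserConfig, detect_mser_regions
from .preprocess import DegenerateHistogramError, otsu_threshold

__all__ = [
    "NucleiConfig",
    "Nucleus",
    "NucleusSet",
    "NucleiLocationMap",
    "detect_mser",
    "hematoxylin_rate_mask",
    "select_nuclei",
    "location_map",
]


@dataclass
class NucleiConfig:
    """Nucleus selection parameters at the 0.5 um/px working scale.

    Size bounds [50, 800] px cover nucleus radii of roughly 4-16 px;
    ``min_rate_overlap`` is the fraction of region pixels that must fall
    inside the high-hematoxylin-rate mask.  Filter sizes: white tophat
    disk radius ``tophat_radius``, maximum filter window ``max_filter_size``
    and Gaussian ``rate_sigma``.
    """

    min_area: int = 50
    max_area: int = 800
    min_rate_overlap: float = 0.5
    tophat_radius: int = 10
    max_filter_size: int = 5
    rate_sigma: float = 2.0
    mser: MserConfig = field(default_factory=MserConfig)


@dataclass
class Nucleus:
    nucleus_id: int
    centroid: tuple[float, float]  # (row, col)
    area: int
    pixels: np.ndarray | None = None  # flat indices, absent after CSV round trip


@dataclass
class NucleusSet:
    """Segmented nuclei of one ROI."""

    nuclei: list[Nucleus]
    image_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.nuclei)

    @property
    def centroids(self) -> np.ndarray:
        if not self.nuclei:
            return np.empty((0, 2))
        return np.asarray([n.centroid for n in self.nuclei], dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return np.asarray([n.area for n in self.nuclei], dtype=float)

    def to_dataframe(self, sample_id: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                sample_id=sample_id,
                nucleus_id=[n.nucleus_id for n in self.nuclei],
                row=[n.centroid[0] for n in self.nuclei],
                col=[n.centroid[1] for n in self.nuclei],
                area_px=[n.area for n in self.nuclei],
            )
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, image_shape: tuple[int, int]
    ) -> "NucleusSet":
        nuclei = [
            Nucleus(int(r.nucleus_id), (float(r.row), float(r.col)), int(r.area_px))
            for r in df.itertuples()
        ]
        return cls(nuclei=nuclei, image_shape=image_shape)

    def label_image(self) -> np.ndarray:
        """Label image of nucleus regions (0 = background)."""
        lab = np.zeros(self.image_shape, dtype=np.int32)
        flat = lab.ravel()
        for n in self.nuclei:
            if n.pixels is not None:
                flat[n.pixels] = n.nucleus_id + 1
        return lab


@dataclass
class NucleiLocationMap:
    """One marked pixel per nucleus centroid; collisions keep multiplicity."""

    counts: np.ndarray  # uint16 multiplicity image

    @property
    def binary(self) -> np.ndarray:
        return self.counts > 0

    @property
    def n_nuclei(self) -> int:
        return int(self.counts.sum())

    @property
    def points(self) -> np.ndarray:
        """(n_marked, 2) marked coordinates (unique pixels)."""
        return np.argwhere(self.counts > 0)


def detect_mser(hema: np.ndarray, config: MserConfig | None = None) -> list[CandidateRegion]:
    """MSER blob candidates from the hematoxylin density image."""
    return detect_mser_regions(hema, config)


def hematoxylin_rate_mask(
    hema: np.ndarray, config: NucleiConfig | None = None
) -> np.ndarray:
    """Binary mask of high hematoxylin density.

    Pipeline: white tophat (emphasizes nucleus-scale bright structure over
    the cytoplasm background) -> maximum filter -> Gaussian blur -> linear
    adjustment to full range -> Otsu threshold.
    """
    cfg = config or NucleiConfig()
    img = np.asarray(hema, dtype=float)
    top = white_tophat(img, disk(cfg.tophat_radius))
    top = maximum_filter(top, size=cfg.max_filter_size)
    top = gaussian_filter(top, cfg.rate_sigma)
    lo, hi = top.min(), top.max()
    if hi <= lo:
        warnings.warn("degenerate hematoxylin image; empty rate mask")
        return np.zeros(img.shape, dtype=bool)
    adj = (top - lo) / (hi - lo) * 255.0
    try:
        t = otsu_threshold(adj.astype(np.uint8))
    except DegenerateHistogramError:
        warnings.warn("degenerate adjusted image; empty rate mask")
        return np.zeros(img.shape, dtype=bool)
    return adj > t


def select_nuclei(
    candidates: list[CandidateRegion],
    rate_mask: np.ndarray,
    config: NucleiConfig | None = None,
) -> NucleusSet:
    """Filter MSER candidates down to nuclei.

    Keeps candidates whose area lies in the configured bounds and whose
    pixel overlap with the high-hematoxylin-rate mask reaches
    ``min_rate_overlap``.  Overlapping survivors (possible only with
    externally supplied candidates) are resolved by keeping the more
    stable region.
    """
    cfg = config or NucleiConfig()
    rate_flat = np.asarray(rate_mask, dtype=bool).ravel()
    shape = rate_mask.shape

    kept: list[CandidateRegion] = []
    occupied = np.zeros(rate_flat.size, dtype=bool)
    for reg in sorted(candidates, key=lambda r: r.stability):
        if not (cfg.min_area <= reg.area <= cfg.max_area):
            continue
        overlap = rate_flat[reg.pixels].mean() if reg.pixels.size else 0.0
        if overlap < cfg.min_rate_overlap:
            continue
        if occupied[reg.pixels].any():
            continue  # merged into the more stable, already-kept region
        occupied[reg.pixels] = True
        kept.append(reg)

    kept.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    nuclei = [
        Nucleus(i, reg.centroid, reg.area, pixels=reg.pixels)
        for i, reg in enumerate(kept)
    ]
    return NucleusSet(nuclei=nuclei, image_shape=shape)


def location_map(nuclei: NucleusSet) -> NucleiLocationMap:
    """Mark each nucleus centroid (rounded to the nearest pixel)."""
    counts = np.zeros(nuclei.image_shape, dtype=np.uint16)
    h, w = nuclei.image_shape
    for n in nuclei.nuclei:
        r = int(np.clip(np.rint(n.centroid[0]), 0, h - 1))
        c = int(np.clip(np.rint(n.centroid[1]), 0, w - 1))
        counts[r, c] += 1
    return NucleiLocationMap(counts=counts)
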