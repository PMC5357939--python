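"""Assemble the 241-entry feature vector for one preprocessed ROI.

Texture extractors run per neighborhood instance (each nucleus bounding
box, each 35x35 nucleus window, each 50x50 tile, the whole ROI box) and
per stain channel, and the instance values are averaged into one number
per catalogue entry.  Channel routing: ``-H`` features read the
hematoxylin density, ``-E`` the eosin density, both quantized to 8 bit
with a fixed density scale.  LBP and SIFT are computed once per channel
over the full image and aggregated per window, which avoids window-border
artifacts; GLCM is computed per window directly.

Missing data policy: a catalogue entry with no valid neighborhood
instance (e.g. nucleus-anchored features of an ROI with zero nuclei) is
NaN with its missing flag set; downstream consumers drop such entries
pairwise (KS tests) or impute training-set medians (classification).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..mser import CandidateRegion, quantize_density
from ..nuclei import NucleusSet, location_map
from ..stains import StainChannels
from .catalogue import CatalogueEntry, FEATURE_NAMES, N_FEATURES, feature_catalogue
from .distribution import (
    density_features,
    nuclei_angle_features,
    nuclei_distance_features,
)
from .texture import (
    dense_sift,
    glcm_stats,
    lbp_code_image,
    lbp_histogram_of_codes,
    mser_region_stats,
)

__all__ = ["FeatureConfig", "FeatureVector", "extract_features"]


@dataclass
class FeatureConfig:
    glcm_levels: int = 16
    lbp_P: int = 8
    lbp_R: float = 1.0
    block_size: int = 50
    nhood_size: int = 35
    block_min_cover: float = 0.5  # tile fraction required inside the mask
    density_sigma: float = 8.0
    density_lbp_R: float = 2.0
    od_scale: float = 2.0


@dataclass
class FeatureVector:
    """Ordered 241-value descriptor of one ROI."""

    sample_id: str
    values: np.ndarray
    missing: np.ndarray
    names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        assert len(self.values) == N_FEATURES
        assert len(self.missing) == N_FEATURES

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.sample_id)


def _windows_for_nuclei(
    nuclei: NucleusSet, size: int, shape: tuple[int, int]
) -> list[tuple[int, int, int, int]]:
    """size x size windows centered on centroids, clipped at borders."""
    half = size // 2
    h, w = shape
    wins = []
    for n in nuclei.nuclei:
        r = int(np.rint(n.centroid[0]))
        c = int(np.rint(n.centroid[1]))
        wins.append(
            (max(0, r - half), min(h, r + half + 1), max(0, c - half), min(w, c + half + 1))
        )
    return wins


def _bbox_windows(nuclei: NucleusSet, shape: tuple[int, int]) -> list[tuple[int, int, int, int]]:
    h, w = shape
    wins = []
    for n in nuclei.nuclei:
        if n.pixels is not None and n.pixels.size:
            rows, cols = np.divmod(n.pixels, w)
            wins.append((int(rows.min()), int(rows.max()) + 1, int(cols.min()), int(cols.max()) + 1))
        else:  # centroid-only nuclei (e.g. after CSV round trip)
            half = max(2, int(np.sqrt(n.area / np.pi)))
            r, c = (int(np.rint(x)) for x in n.centroid)
            wins.append((max(0, r - half), min(h, r + half + 1), max(0, c - half), min(w, c + half + 1)))
    return wins


def _tiles(
    shape: tuple[int, int], size: int, mask: np.ndarray, min_cover: float
) -> list[tuple[int, int, int, int]]:
    """Complete, non-overlapping size x size tiles covered by the mask."""
    h, w = shape
    out = []
    for r0 in range(0, h - size + 1, size):
        for c0 in range(0, w - size + 1, size):
            if mask[r0 : r0 + size, c0 : c0 + size].mean() >= min_cover:
                out.append((r0, r0 + size, c0, c0 + size))
    return out


def extract_features(
    stains: StainChannels,
    roi_mask: np.ndarray,
    tissue_mask: np.ndarray,
    nuclei: NucleusSet,
    candidates: list[CandidateRegion] | None = None,
    sample_id: str = "",
    config: FeatureConfig | None = None,
) -> FeatureVector:
    """Compute the full ordered feature vector for one ROI."""
    cfg = config or FeatureConfig()
    shape = stains.shape
    channels = {
        "H": quantize_density(stains.hematoxylin, cfg.od_scale),
        "E": quantize_density(stains.eosin, cfg.od_scale),
    }

    # neighborhood instances
    windows: dict[str, list[tuple[int, int, int, int]]] = {
        "nucleus_bbox": _bbox_windows(nuclei, shape),
        "nucleus_35": _windows_for_nuclei(nuclei, cfg.nhood_size, shape),
        "block_50_masked": _tiles(shape, cfg.block_size, tissue_mask, cfg.block_min_cover),
        "block_50_unmasked": _tiles(shape, cfg.block_size, roi_mask, cfg.block_min_cover),
        "roi_bbox": [(0, shape[0], 0, shape[1])],
    }

    results: dict[tuple[str, str, str, str], tuple[float, bool]] = {}

    def put(extractor: str, nbhd: str, ch: str, stat: str, val: float, miss: bool) -> None:
        results[(extractor, nbhd, ch, stat)] = (val, miss)

    # ---- GLCM ----------------------------------------------------------
    from .catalogue import GLCM_STATS

    for ch, img in channels.items():
        for nbhd, wins in windows.items():
            acc: dict[str, list[float]] = {s: [] for s in GLCM_STATS}
            for r0, r1, c0, c1 in wins:
                st = glcm_stats(img[r0:r1, c0:c1], cfg.glcm_levels)
                if st is not None:
                    for s in GLCM_STATS:
                        acc[s].append(st[s])
            for s in GLCM_STATS:
                if acc[s]:
                    put("glcm", nbhd, ch, s, float(np.mean(acc[s])), False)
                else:
                    put("glcm", nbhd, ch, s, np.nan, True)

    # ---- LBP (global code image, windowed histograms) ------------------
    n_bins = cfg.lbp_P + 2
    for ch, img in channels.items():
        codes = lbp_code_image(img, cfg.lbp_P, cfg.lbp_R, mask_border=True)
        for nbhd, wins in windows.items():
            hists = [
                lbp_histogram_of_codes(codes[r0:r1, c0:c1], cfg.lbp_P)
                for r0, r1, c0, c1 in wins
                if (r1 - r0) > 0 and (c1 - c0) > 0
            ]
            if hists:
                mean_hist = np.mean(hists, axis=0)
                for k in range(n_bins):
                    put("lbp", nbhd, ch, f"bin{k + 1}", float(mean_hist[k]), False)
            else:
                for k in range(n_bins):
                    put("lbp", nbhd, ch, f"bin{k + 1}", np.nan, True)

    # ---- SIFT (dense grid, windowed summaries) -------------------------
    for ch, img in channels.items():
        ds = dense_sift(img)
        # per-nucleus 35x35 windows
        stats_per_win = []
        for r0, r1, c0, c1 in windows["nucleus_35"]:
            sel = (
                (ds.centers[:, 0] >= r0) & (ds.centers[:, 0] < r1)
                & (ds.centers[:, 1] >= c0) & (ds.centers[:, 1] < c1)
            )
            s = ds.summarize(sel)
            if s is not None:
                stats_per_win.append(s)
        if stats_per_win:
            for key in stats_per_win[0]:
                put(
                    "sift", "nucleus_35", ch, key,
                    float(np.mean([s[key] for s in stats_per_win])), False,
                )
        else:
            for b in range(1, 9):
                put("sift", "nucleus_35", ch, f"band{b}_mean", np.nan, True)
                put("sift", "nucleus_35", ch, f"band{b}_std", np.nan, True)
        roi_stats = ds.summarize()
        if roi_stats is not None:
            for key, v in roi_stats.items():
                put("sift", "roi_bbox", ch, key, float(v), False)
        else:
            for b in range(1, 9):
                put("sift", "roi_bbox", ch, f"band{b}_mean", np.nan, True)

    # ---- MSER region summaries -----------------------------------------
    regs = candidates if candidates is not None else []
    mser_vals = mser_region_stats(regs, shape, tissue_px=int(np.sum(tissue_mask)))
    for k, v in mser_vals.items():
        put("mser", "roi_bbox", "H", k, v, len(regs) == 0 and k != "MSERCount")

    # ---- nuclei arrangement --------------------------------------------
    dist_vals, dist_miss = nuclei_distance_features(nuclei)
    for k, v in dist_vals.items():
        put("distance", "nucleus_100", "-", k, v, dist_miss[k])
    ang_vals, ang_miss = nuclei_angle_features(nuclei)
    for k, v in ang_vals.items():
        put("angle", "nucleus_100", "-", k, v, ang_miss[k])
    dens_vals, dens_miss = density_features(
        location_map(nuclei), tissue_mask, cfg.density_sigma, cfg.density_lbp_R
    )
    for k, v in dens_vals.items():
        stat = k if not k.startswith("DensityLBP") else f"bin{k[len('DensityLBP'):]}"
        put("density", "roi_bbox", "-", stat, v, dens_miss[k])

    # ---- assemble in catalogue order -----------------------------------
    values = np.full(N_FEATURES, np.nan)
    missing = np.ones(N_FEATURES, dtype=bool)
    for i, entry in enumerate(feature_catalogue()):
        key = (entry.extractor_id, entry.neighborhood_id, entry.channel_id, entry.stat)
        if entry.extractor_id in ("distance", "angle", "density"):
            key = (entry.extractor_id, entry.neighborhood_id, "-", entry.stat)
        if key not in results:
            raise KeyError(f"extractor produced no value for {entry}")
        values[i], missing[i] = results[key]
    return FeatureVector(sample_id=sample_id, values=values, missing=missing)
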