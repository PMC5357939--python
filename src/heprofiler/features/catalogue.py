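"""The fixed, ordered 241-feature catalogue.

Texture statistics (GLCM, LBP, SIFT) are measured at several neighborhood
scales — per-nucleus bounding box, a 35x35 window around each nucleus,
non-overlapping 50x50 blocks with unwanted regions excluded ("mROI-Block")
or included ("ROI-Block"), and the whole ROI bounding box — and on both the
hematoxylin (-H) and eosin (-E) density channels; the scale is encoded as a
name prefix (e.g. Contrast-H, NhoodContrast-H, mROI-BlockContrast-H,
ROI-BlockContrast-H, ROIContrast-H).  Nuclei-arrangement features (inter-
nucleus distances, neighbor-orientation circular statistics, Gaussian
density-map statistics) are computed from the nuclei location map, plus
MSER region summaries.  The catalogue is the single source of truth for
feature order; every extracted vector aligns to it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

__all__ = ["CatalogueEntry", "feature_catalogue", "catalogue_dataframe", "N_FEATURES"]

N_FEATURES = 241

#: neighborhood id -> feature-name prefix
TEXTURE_NEIGHBORHOODS: list[tuple[str, str]] = [
    ("nucleus_bbox", ""),
    ("nucleus_35", "Nhood"),
    ("block_50_masked", "mROI-Block"),
    ("block_50_unmasked", "ROI-Block"),
    ("roi_bbox", "ROI"),
]

GLCM_STATS = ["MeanInt", "Contrast", "Correlation", "Energy", "Homogeneity"]
N_LBP_BINS = 10  # rotation-invariant uniform codes for P=8: bins 0..9
N_SIFT_BANDS = 8

DISTANCE_STATS = [
    "NhoodMeanDist",
    "NhoodMaxDist",
    "NhoodStdDist",
    "NhoodSkewness",
    "meanNucDistInNucNB",
    "numberOfNucInNucNB",
    "meanNucSize",
]

ANGLE_STATS = [
    "NhoodNucAngleR",
    "NhoodNucAngleVar",
    "NhoodNucAngleStd",
    "NhoodNucAngleStd0",
    "NhoodNucAngleSkew",
    "NhoodNucAngleKurt",
    "NhoodNucAngleVarABS",
    "NhoodNucAngleStd0ABS",
    "NhoodNucAngleSkewABS",
    "NhoodNucAngleKurtABS",
]

MSER_STATS = [
    "MSERCount",
    "MSERDensity",
    "MSERMeanArea",
    "MSERStdArea",
    "MSERMeanStability",
    "MSERMeanEcc",
]

DENSITY_STATS = [
    "DensityMean",
    "DensityMax",
    "DensityStd",
    "DensitySkew",
    "DensityKurt",
    "DensityP10",
    "DensityP25",
    "DensityP50",
    "DensityP75",
    "DensityP90",
]


@dataclass(frozen=True)
class CatalogueEntry:
    name: str
    extractor_id: str  # glcm | lbp | sift | mser | distance | angle | density
    neighborhood_id: str
    channel_id: str  # H | E | - (channel-free features)
    stat: str  # statistic key within the extractor output


def _build() -> list[CatalogueEntry]:
    entries: list[CatalogueEntry] = []
    # GLCM statistics: 5 stats x 5 neighborhoods x 2 channels = 50
    for nbhd, prefix in TEXTURE_NEIGHBORHOODS:
        for ch in ("H", "E"):
            for stat in GLCM_STATS:
                entries.append(
                    CatalogueEntry(f"{prefix}{stat}-{ch}", "glcm", nbhd, ch, stat)
                )
    # LBP histogram bins: 10 bins x 5 neighborhoods x 2 channels = 100
    for nbhd, prefix in TEXTURE_NEIGHBORHOODS:
        for ch in ("H", "E"):
            for k in range(1, N_LBP_BINS + 1):
                entries.append(
                    CatalogueEntry(f"{prefix}LBP{k}{ch}", "lbp", nbhd, ch, f"bin{k}")
                )
    # SIFT orientation-band energies: (mean+sd) x 8 bands x 2 ch at the
    # 35x35 scale = 32, band means x 2 ch over the whole ROI = 16
    for ch in ("H", "E"):
        for b in range(1, N_SIFT_BANDS + 1):
            entries.append(
                CatalogueEntry(
                    f"NhoodSIFT{b}Mean-{ch}", "sift", "nucleus_35", ch, f"band{b}_mean"
                )
            )
            entries.append(
                CatalogueEntry(
                    f"NhoodSIFT{b}Std-{ch}", "sift", "nucleus_35", ch, f"band{b}_std"
                )
            )
    for ch in ("H", "E"):
        for b in range(1, N_SIFT_BANDS + 1):
            entries.append(
                CatalogueEntry(f"ROISIFT{b}-{ch}", "sift", "roi_bbox", ch, f"band{b}_mean")
            )
    # MSER region summaries = 6
    for stat in MSER_STATS:
        entries.append(CatalogueEntry(stat, "mser", "roi_bbox", "H", stat))
    # nuclei distances = 7, neighbor-orientation circular stats = 10
    for stat in DISTANCE_STATS:
        entries.append(CatalogueEntry(stat, "distance", "nucleus_100", "-", stat))
    for stat in ANGLE_STATS:
        entries.append(CatalogueEntry(stat, "angle", "nucleus_100", "-", stat))
    # Gaussian density-map statistics = 10 + DensityLBP bins = 10
    for stat in DENSITY_STATS:
        entries.append(CatalogueEntry(stat, "density", "roi_bbox", "-", stat))
    for k in range(1, N_LBP_BINS + 1):
        entries.append(CatalogueEntry(f"DensityLBP{k}", "density", "roi_bbox", "-", f"bin{k}"))
    assert len(entries) == N_FEATURES, len(entries)
    assert len({e.name for e in entries}) == N_FEATURES
    return entries


_CATALOGUE = _build()


def feature_catalogue() -> list[CatalogueEntry]:
    """The ordered 241-entry feature catalogue (immutable records)."""
    return list(_CATALOGUE)


def catalogue_dataframe() -> pd.DataFrame:
    """Machine-readable catalogue export."""
    return pd.DataFrame([asdict(e) for e in _CATALOGUE])


FEATURE_NAMES: list[str] = [e.name for e in _CATALOGUE]
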