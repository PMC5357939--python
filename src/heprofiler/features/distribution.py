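"""Nuclei-arrangement features from the location map.

Distances, neighbor counts and neighbor-orientation statistics are
computed per nucleus over an axis-aligned square window centered on its
centroid (side 100 px for the "Nhood" statistics, 35 px for the "NucNB"
ones), then averaged over nuclei to give one ROI-level value.

Orientation of a neighbor is an *axial* quantity: an ordered "beads in a
row" epithelium presents neighbors along both directions of the local row
axis, so angles are doubled (the standard axial-data transform) before the
trigonometric moments; ABS variants fold the angle to [0, pi] first.
Density features come from a Gaussian-filtered location map.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import kurtosis, skew

from .. import circstats
from ..nuclei import NucleiLocationMap, NucleusSet
from .texture import lbp_histogram_of_codes, lbp_code_image

__all__ = [
    "nuclei_distance_features",
    "nuclei_angle_features",
    "density_features",
]

NHOOD_HALF = 50.0  # half-side of the 100x100 window
NUCNB_HALF = 17.5  # half-side of the 35x35 window


def _neighbor_offsets(centroids: np.ndarray, i: int, half: float) -> np.ndarray:
    """Offsets (dr, dc) to neighbors of nucleus i inside its square window."""
    d = centroids - centroids[i]
    inside = (np.abs(d[:, 0]) <= half) & (np.abs(d[:, 1]) <= half)
    inside[i] = False
    return d[inside]


def nuclei_distance_features(
    nuclei: NucleusSet,
) -> tuple[dict[str, float], dict[str, bool]]:
    """Inter-nucleus distance and count statistics.

    Per nucleus: Euclidean distances to neighbors in the 100 px window
    (mean/max/sd; skewness where >= 3 neighbors give it meaning), the
    count and mean distance within the 35 px window, and the mean nucleus
    area.  ROI values average over nuclei for which the statistic is
    defined; a statistic defined for no nucleus is flagged missing
    (counts default to 0).
    """
    names = [
        "NhoodMeanDist", "NhoodMaxDist", "NhoodStdDist", "NhoodSkewness",
        "meanNucDistInNucNB", "numberOfNucInNucNB", "meanNucSize",
    ]
    values = {k: np.nan for k in names}
    missing = {k: True for k in names}
    n = len(nuclei)
    if n == 0:
        return values, missing

    cents = nuclei.centroids
    means, maxs, stds, skews, nb_means, nb_counts = [], [], [], [], [], []
    for i in range(n):
        off = _neighbor_offsets(cents, i, NHOOD_HALF)
        if len(off) >= 1:
            dist = np.hypot(off[:, 0], off[:, 1])
            means.append(dist.mean())
            maxs.append(dist.max())
            stds.append(dist.std())
            if len(dist) >= 3 and dist.std() > 0:
                skews.append(skew(dist, bias=True))
        off_nb = _neighbor_offsets(cents, i, NUCNB_HALF)
        nb_counts.append(len(off_nb))
        if len(off_nb) >= 1:
            nb_means.append(np.hypot(off_nb[:, 0], off_nb[:, 1]).mean())

    for key, acc in [
        ("NhoodMeanDist", means), ("NhoodMaxDist", maxs),
        ("NhoodStdDist", stds), ("NhoodSkewness", skews),
        ("meanNucDistInNucNB", nb_means),
    ]:
        if acc:
            values[key] = float(np.mean(acc))
            missing[key] = False
    values["numberOfNucInNucNB"] = float(np.mean(nb_counts))
    missing["numberOfNucInNucNB"] = False
    values["meanNucSize"] = float(nuclei.areas.mean())
    missing["meanNucSize"] = False
    return values, missing


def _angle_stats(doubled: np.ndarray, suffix: str) -> dict[str, float]:
    return {
        f"NhoodNucAngleR{suffix}": circstats.resultant_length(doubled),
        f"NhoodNucAngleVar{suffix}": circstats.circ_var(doubled),
        f"NhoodNucAngleStd{suffix}": circstats.circ_std(doubled),
        f"NhoodNucAngleStd0{suffix}": circstats.angular_deviation(doubled),
        f"NhoodNucAngleSkew{suffix}": circstats.circ_skewness(doubled),
        f"NhoodNucAngleKurt{suffix}": circstats.circ_kurtosis(doubled),
    }


ANGLE_KEYS = [
    "NhoodNucAngleR", "NhoodNucAngleVar", "NhoodNucAngleStd", "NhoodNucAngleStd0",
    "NhoodNucAngleSkew", "NhoodNucAngleKurt",
    "NhoodNucAngleVarABS", "NhoodNucAngleStd0ABS",
    "NhoodNucAngleSkewABS", "NhoodNucAngleKurtABS",
]


def nuclei_angle_features(
    nuclei: NucleusSet,
) -> tuple[dict[str, float], dict[str, bool]]:
    """Circular statistics of neighbor orientations, averaged over nuclei.

    For each nucleus the angles theta = atan2(dr, dc) to its neighbors in
    the 100 px window are doubled (axial data) and summarized by resultant
    length, circular variance/std, angular deviation, and second-moment
    skewness/kurtosis; ABS variants use |theta| in [0, pi].  Nuclei
    without neighbors do not contribute; with no contributing nucleus all
    angle features are flagged missing.
    """
    values = {k: np.nan for k in ANGLE_KEYS}
    missing = {k: True for k in ANGLE_KEYS}
    cents = nuclei.centroids
    per_nucleus: list[dict[str, float]] = []
    for i in range(len(nuclei)):
        off = _neighbor_offsets(cents, i, NHOOD_HALF)
        if len(off) == 0:
            continue
        theta = np.arctan2(off[:, 0], off[:, 1])
        stats = _angle_stats(2.0 * theta, "")
        stats.update(_angle_stats(2.0 * np.abs(theta), "ABS"))
        per_nucleus.append(stats)
    if not per_nucleus:
        return values, missing
    for key in ANGLE_KEYS:
        src = key if key in per_nucleus[0] else key  # all present
        values[key] = float(np.mean([s[src] for s in per_nucleus]))
        missing[key] = False
    return values, missing


DENSITY_KEYS = [
    "DensityMean", "DensityMax", "DensityStd", "DensitySkew", "DensityKurt",
    "DensityP10", "DensityP25", "DensityP50", "DensityP75", "DensityP90",
] + [f"DensityLBP{k}" for k in range(1, 11)]


def density_features(
    loc_map: NucleiLocationMap,
    tissue_mask: np.ndarray | None = None,
    sigma: float = 8.0,
    lbp_radius: float = 2.0,
) -> tuple[dict[str, float], dict[str, bool]]:
    """Statistics of the Gaussian-filtered nuclei location map.

    The kernel is normalized, so the unmasked density integrates to the
    nucleus count (up to border spill-out).  Scalar statistics are taken
    within the tissue mask; the DensityLBP histogram applies riu2 LBP
    (P=8, R=2) to the density image rescaled to 8 bit.
    """
    values = {k: 0.0 for k in DENSITY_KEYS}
    missing = {k: loc_map.n_nuclei == 0 for k in DENSITY_KEYS}
    density = gaussian_filter(loc_map.counts.astype(float), sigma, mode="constant")
    if loc_map.n_nuclei == 0:
        return values, missing

    mask = (
        np.ones(density.shape, dtype=bool)
        if tissue_mask is None or not np.any(tissue_mask)
        else np.asarray(tissue_mask, dtype=bool)
    )
    vals = density[mask]
    values.update(
        DensityMean=float(vals.mean()),
        DensityMax=float(vals.max()),
        DensityStd=float(vals.std()),
        DensitySkew=float(skew(vals, bias=True)) if vals.std() > 0 else 0.0,
        DensityKurt=float(kurtosis(vals, bias=True)) if vals.std() > 0 else 0.0,
    )
    for p in (10, 25, 50, 75, 90):
        values[f"DensityP{p}"] = float(np.percentile(vals, p))

    dmax = density.max()
    q = np.clip(density / dmax * 255.0, 0, 255).astype(np.uint8)
    codes = lbp_code_image(q, P=8, R=lbp_radius, mask_border=True)
    hist = lbp_histogram_of_codes(codes[mask], P=8)
    for k in range(10):
        values[f"DensityLBP{k + 1}"] = float(hist[k])
    return values, missing
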