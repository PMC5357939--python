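"""Maximally stable extremal regions on top of skimage's max-tree.

MSER finds connected components of upper level sets {I >= t} whose area is
stable over a threshold range.  The component tree itself comes from
``skimage.morphology.max_tree``; this module adds the stability measure and
region selection.  For a canonical component R at gray level v, the
variation is ``(|R_{v-delta}| - |R_v|) / |R_v|`` where ``R_{v-delta}`` is
the enclosing component at level v - delta (the usual one-sided
approximation).  Candidates below ``max_variation`` and inside the area
bounds are accepted greedily in order of increasing variation, suppressing
nested duplicates so the surviving regions are pairwise disjoint.

The tree passes are O(n pixels) loops, jitted with numba.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from skimage.morphology import max_tree

__all__ = ["MserConfig", "CandidateRegion", "detect_mser_regions"]


@dataclass
class MserConfig:
    """MSER parameters on the 8-bit quantized density image.

    ``delta`` is the gray-level step of the stability test; areas are in
    pixels and bound the detector loosely (nucleus-level size selection
    happens later); ``od_scale`` maps optical density to the 8-bit range;
    ``smooth_sigma`` is a light Gaussian denoise before the tree build.
    """

    delta: int = 5
    min_area: int = 30
    max_area: int = 2000
    max_variation: float = 0.5
    od_scale: float = 2.0
    smooth_sigma: float = 1.0


@dataclass
class CandidateRegion:
    """One stable extremal region (connected pixel set)."""

    pixels: np.ndarray  # flat indices into the source image
    area: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) inclusive
    centroid: tuple[float, float]
    mean_intensity: float
    stability: float  # variation; lower = more stable
    level: int  # gray level of the component


@njit(cache=True)
def _accumulate_areas(parent, order):
    n = parent.size
    area = np.ones(n, np.int64)
    for i in range(n - 1, -1, -1):
        p = order[i]
        q = parent[p]
        if q != p:
            area[q] += area[p]
    return area


@njit(cache=True)
def _node_variation(value, parent, area, canonical, delta):
    n = value.size
    var = np.full(n, -1.0)
    for p in range(n):
        if not canonical[p]:
            continue
        v = value[p]
        a = p
        # climb canonical ancestors until level drops by >= delta
        while value[a] > v - delta:
            nxt = parent[a]
            if nxt == a:
                break
            a = nxt
        var[p] = (area[a] - area[p]) / area[p]
    return var


@njit(cache=True)
def _greedy_select(order_by_var, parent, canonical, eligible):
    """Accept candidates by increasing variation, suppressing nesting."""
    n = parent.size
    accepted = np.zeros(n, np.bool_)
    blocked_below = np.zeros(n, np.bool_)  # an accepted node exists in subtree
    for k in range(order_by_var.size):
        p = order_by_var[k]
        if not eligible[p]:
            continue
        if blocked_below[p]:
            continue
        # check accepted ancestors
        a = p
        conflict = False
        while True:
            nxt = parent[a]
            if nxt == a:
                break
            a = nxt
            if canonical[a] and accepted[a]:
                conflict = True
                break
        if conflict:
            continue
        accepted[p] = True
        a = p
        while True:
            blocked_below[a] = True
            nxt = parent[a]
            if nxt == a:
                break
            a = nxt
    return accepted


@njit(cache=True)
def _assign_labels(order, parent, accepted):
    n = parent.size
    label = np.full(n, -1, np.int64)
    for i in range(n):
        p = order[i]
        if accepted[p]:
            label[p] = p
        elif parent[p] != p:
            label[p] = label[parent[p]]
    return label


def quantize_density(density: np.ndarray, od_scale: float = 2.0) -> np.ndarray:
    """Map an optical-density image onto uint8 with a fixed scale."""
    if density.dtype == np.uint8:
        return density
    scaled = np.clip(np.asarray(density, float) / od_scale, 0.0, 1.0) * 255.0
    return scaled.astype(np.uint8)


def detect_mser_regions(
    density: np.ndarray, config: MserConfig | None = None
) -> list[CandidateRegion]:
    """Detect stable bright blobs in a (hematoxylin) density image.

    The input is quantized to 8 bit with a fixed density scale so results
    are comparable across images; a light Gaussian smooth suppresses
    single-pixel noise components.  Returns pairwise-disjoint regions.
    """
    cfg = config or MserConfig()
    img = np.asarray(density, dtype=float)
    if cfg.smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, cfg.smooth_sigma)
    q = quantize_density(img, cfg.od_scale)
    if q.max() == q.min():
        return []

    parent_img, order = max_tree(q, connectivity=2)
    parent = parent_img.ravel()
    value = q.ravel().astype(np.int64)
    area = _accumulate_areas(parent, order)
    canonical = (parent == np.arange(parent.size)) | (value[parent] != value)
    var = _node_variation(value, parent, area, canonical, cfg.delta)

    eligible = (
        canonical
        & (area >= cfg.min_area)
        & (area <= cfg.max_area)
        & (var >= 0)
        & (var <= cfg.max_variation)
    )
    root = order[0]
    eligible[root] = False
    if not eligible.any():
        return []

    cand = np.flatnonzero(eligible)
    # deterministic order: variation asc, then larger area, then index
    sort_idx = np.lexsort((cand, -area[cand], var[cand]))
    accepted = _greedy_select(cand[sort_idx], parent, canonical, eligible)
    label = _assign_labels(order, parent, accepted)

    h, w = q.shape
    regions: list[CandidateRegion] = []
    labeled = np.flatnonzero(label >= 0)
    if labeled.size == 0:
        return []
    groups = label[labeled]
    sorter = np.argsort(groups, kind="stable")
    labeled = labeled[sorter]
    groups = groups[sorter]
    bounds = np.flatnonzero(np.diff(groups)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [groups.size]])
    dens_flat = np.asarray(density, dtype=float).ravel()
    for s, e in zip(starts, ends):
        pix = labeled[s:e]
        node = groups[s]
        rows, cols = np.divmod(pix, w)
        regions.append(
            CandidateRegion(
                pixels=pix,
                area=int(area[node]),
                bbox=(int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())),
                centroid=(float(rows.mean()), float(cols.mean())),
                mean_intensity=float(dens_flat[pix].mean()),
                stability=float(var[node]),
                level=int(value[node]),
            )
        )
    regions.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    return regions
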