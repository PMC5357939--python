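"""Texture descriptors: GLCM statistics, LBP histograms, dense SIFT bands,
MSER region summaries.

All block-level operations take 8-bit intensity images (stain densities
quantized to [0, 255]).  GLCM statistics use the Haralick formulation on a
symmetric, normalized co-occurrence matrix averaged over the four unit
offsets (0,1), (1,1), (1,0), (1,-1) at 16 gray levels.  LBP uses the
rotation-invariant uniform coding (P=8), giving a 10-bin histogram.  The
SIFT-style descriptors are gradient-orientation histograms over 4x4
spatial cells of 16x16 patches on a dense grid (step 8), L2-normalized
with the usual 0.2 clipping; features summarize the per-orientation-band
energy across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern

from ..mser import CandidateRegion

__all__ = [
    "glcm_stats",
    "lbp_histogram",
    "lbp_code_image",
    "sift_block_features",
    "DenseSift",
    "mser_region_stats",
]

GLCM_OFFSET_ANGLES = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]


def quantize_levels(block: np.ndarray, levels: int = 16) -> np.ndarray:
    """Uniformly requantize an 8-bit image to ``levels`` gray levels."""
    return (np.asarray(block).astype(np.uint16) * levels // 256).astype(np.uint8)


def glcm_stats(
    block: np.ndarray, levels: int = 16, angles: list[float] | None = None
) -> dict[str, float] | None:
    """Haralick statistics of the offset-averaged co-occurrence matrix.

    Returns mean intensity (on the 8-bit scale), contrast, correlation,
    energy and homogeneity, or None when the block is too small to form
    pixel pairs.  A constant block has contrast 0, energy 1 and, by the
    usual convention, correlation 1.  ``angles`` overrides the default
    four unit offsets.
    """
    block = np.asarray(block)
    if block.ndim != 2 or min(block.shape) < 2:
        return None
    q = quantize_levels(block, levels)
    glcm = graycomatrix(
        q, distances=[1], angles=angles or GLCM_OFFSET_ANGLES, levels=levels,
        symmetric=True, normed=True,
    )
    return {
        "MeanInt": float(np.mean(block)),
        "Contrast": float(np.mean(graycoprops(glcm, "contrast"))),
        "Correlation": float(np.mean(graycoprops(glcm, "correlation"))),
        "Energy": float(np.mean(graycoprops(glcm, "ASM"))),
        "Homogeneity": float(np.mean(graycoprops(glcm, "homogeneity"))),
    }


def lbp_code_image(
    image: np.ndarray, P: int = 8, R: float = 1.0, mask_border: bool = False
) -> np.ndarray:
    """Rotation-invariant uniform LBP code per pixel (codes 0..P+1).

    With ``mask_border`` the image-border ring (width ceil(R)), whose
    circular neighborhoods leave the image, is set to -1 so downstream
    histograms can exclude those artifact codes.
    """
    img = np.asarray(image)
    if not np.issubdtype(img.dtype, np.integer):
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    codes = local_binary_pattern(img, P, R, method="uniform").astype(int)
    if mask_border:
        b = int(np.ceil(R))
        codes[:b, :] = codes[-b:, :] = -1
        codes[:, :b] = codes[:, -b:] = -1
    return codes


def lbp_histogram(block: np.ndarray, P: int = 8, R: float = 1.0) -> np.ndarray | None:
    """Normalized histogram of riu2 LBP codes over the block interior.

    None when the block cannot contain the circular neighborhood.  The
    histogram has P+2 bins and sums to 1; a constant block concentrates
    all mass in the all-ones uniform pattern bin (code P).
    """
    block = np.asarray(block)
    if block.ndim != 2 or min(block.shape) <= 2 * (np.ceil(R) + 1):
        return None
    codes = lbp_code_image(block, P, R, mask_border=True)
    return lbp_histogram_of_codes(codes, P)


def lbp_histogram_of_codes(codes: np.ndarray, P: int = 8) -> np.ndarray:
    """Normalized histogram of precomputed codes; negatives are excluded."""
    flat = np.asarray(codes, int).ravel()
    flat = flat[flat >= 0]
    hist = np.bincount(flat, minlength=P + 2).astype(float)
    s = hist.sum()
    return hist / s if s > 0 else hist


# ---------------------------------------------------------------------------
# Dense SIFT-style descriptors
# ---------------------------------------------------------------------------

N_ORI = 8
PATCH = 16
CELL = 4
STEP = 8
_CLIP = 0.2


@dataclass
class DenseSift:
    """Dense descriptor grid for one image.

    ``centers``: (n, 2) patch-center coordinates; ``band_energy``: (n, 8)
    per-descriptor orientation-band energies (sum of the normalized
    descriptor over spatial cells, per band).
    """

    centers: np.ndarray
    band_energy: np.ndarray

    def summarize(self, select: np.ndarray | None = None) -> dict[str, float] | None:
        """Mean and sd of each band's energy over (selected) grid points."""
        e = self.band_energy if select is None else self.band_energy[select]
        if e.shape[0] == 0:
            return None
        out: dict[str, float] = {}
        for b in range(N_ORI):
            out[f"band{b + 1}_mean"] = float(e[:, b].mean())
            out[f"band{b + 1}_std"] = float(e[:, b].std())
        return out


def _orientation_energy(image: np.ndarray) -> np.ndarray:
    """(H, W, 8) gradient-magnitude maps split by orientation bin."""
    img = np.asarray(image, dtype=float)
    gr, gc = np.gradient(img)
    mag = np.hypot(gr, gc)
    ang = np.arctan2(gr, gc)  # (-pi, pi]
    bins = np.floor((ang + np.pi) / (2 * np.pi) * N_ORI).astype(int) % N_ORI
    energy = np.zeros(img.shape + (N_ORI,))
    rows, cols = np.indices(img.shape)
    energy[rows, cols, bins] = mag
    return energy


def _box_sums(arr: np.ndarray, size: int) -> np.ndarray:
    """Sliding-window box sums along the two leading axes."""
    c = np.cumsum(np.cumsum(arr, axis=0), axis=1)
    c = np.pad(c, [(1, 0), (1, 0)] + [(0, 0)] * (arr.ndim - 2))
    return (
        c[size:, size:] - c[:-size, size:] - c[size:, :-size] + c[:-size, :-size]
    )


def dense_sift(image: np.ndarray, step: int = STEP, patch: int = PATCH) -> DenseSift:
    """Compute descriptors on a dense grid over the whole image."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if h < patch or w < patch:
        return DenseSift(centers=np.empty((0, 2)), band_energy=np.empty((0, N_ORI)))
    energy = _orientation_energy(img)
    cells = _box_sums(energy, CELL)  # cell sum with top-left at (r, c)
    r0 = np.arange(0, h - patch + 1, step)
    c0 = np.arange(0, w - patch + 1, step)
    n_cells = patch // CELL
    offs = np.arange(n_cells) * CELL
    # gather (nr, nc, 4, 4, 8) descriptors
    rr = (r0[:, None] + offs[None, :])  # (nr, 4)
    cc = (c0[:, None] + offs[None, :])  # (nc, 4)
    d = cells[rr[:, None, :, None], cc[None, :, None, :], :]
    d = d.reshape(len(r0), len(c0), n_cells * n_cells, N_ORI)
    flat = d.reshape(-1, n_cells * n_cells, N_ORI)
    norms = np.linalg.norm(flat.reshape(flat.shape[0], -1), axis=1, keepdims=True)
    norms = np.where(norms == 0, 1.0, norms)
    desc = flat / norms[:, :, None]
    desc = np.minimum(desc, _CLIP)
    norms2 = np.linalg.norm(desc.reshape(desc.shape[0], -1), axis=1, keepdims=True)
    norms2 = np.where(norms2 == 0, 1.0, norms2)
    desc = desc / norms2[:, :, None]
    band = desc.sum(axis=1)  # (n, 8)
    centers = np.stack(
        np.meshgrid(r0 + patch / 2 - 0.5, c0 + patch / 2 - 0.5, indexing="ij"), axis=-1
    ).reshape(-1, 2)
    return DenseSift(centers=centers, band_energy=band)


def sift_block_features(block: np.ndarray) -> dict[str, float] | None:
    """Aggregated dense-descriptor band statistics for one block.

    None (missing) when the block is smaller than one descriptor patch.
    A constant block has zero gradient everywhere, hence all band
    energies 0.
    """
    ds = dense_sift(np.asarray(block))
    return ds.summarize()


# ---------------------------------------------------------------------------
# MSER region summaries
# ---------------------------------------------------------------------------

def _region_eccentricity(reg: CandidateRegion, width: int) -> float:
    rows, cols = np.divmod(reg.pixels, width)
    if rows.size < 2:
        return 0.0
    cov = np.cov(np.stack([rows, cols]).astype(float))
    ev = np.sort(np.linalg.eigvalsh(cov))
    if ev[1] <= 0:
        return 0.0
    return float(np.sqrt(max(0.0, 1.0 - ev[0] / ev[1])))


def mser_region_stats(
    regions: list[CandidateRegion],
    image_shape: tuple[int, int],
    tissue_px: int | None = None,
) -> dict[str, float]:
    """Summary statistics of an ROI's stable extremal regions.

    ``MSERDensity`` is regions per 10^4 px of effective tissue (or of the
    whole image when no tissue mask is given).  An empty region list
    yields zeros (flagged missing downstream except for the count).
    """
    n = len(regions)
    ref_px = tissue_px if tissue_px else image_shape[0] * image_shape[1]
    if n == 0:
        return {k: 0.0 for k in (
            "MSERCount", "MSERDensity", "MSERMeanArea", "MSERStdArea",
            "MSERMeanStability", "MSERMeanEcc",
        )}
    areas = np.asarray([r.area for r in regions], dtype=float)
    stab = np.asarray([r.stability for r in regions], dtype=float)
    ecc = np.asarray([_region_eccentricity(r, image_shape[1]) for r in regions])
    return {
        "MSERCount": float(n),
        "MSERDensity": float(n / ref_px * 1e4),
        "MSERMeanArea": float(areas.mean()),
        "MSERStdArea": float(areas.std()),
        "MSERMeanStability": float(stab.mean()),
        "MSERMeanEcc": float(ecc.mean()),
    }
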