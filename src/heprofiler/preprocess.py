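"""ROI preprocessing: stain normalization, tissue masking, stain separation.

The steps mirror standard H&E pipeline practice: per-channel histogram
matching against a cohort reference removes section-to-section staining
variation; a channel-difference image with contrast-limited mapping and
Otsu thresholding isolates the effective tissue area (excluding lumen,
secretion and empty glass); Beer-Lambert color deconvolution separates the
hematoxylin and eosin contributions (see :mod:`heprofiler.stains`).

Conventions: coordinates are (row, col), 0-based, origin top-left;
histograms use 256 bins and are computed within the ROI mask only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import closing, disk, opening, remove_small_holes

from .stains import StainChannels, color_deconvolve  # noqa: F401  (re-export)

__all__ = [
    "ReferenceHistogram",
    "PreprocessConfig",
    "compute_reference_histogram",
    "match_histogram",
    "otsu_threshold",
    "segment_effective_tissue",
    "color_deconvolve",
    "StainChannels",
]


class DegenerateHistogramError(ValueError):
    """Raised when a constant image leaves Otsu's criterion undefined."""


@dataclass
class PreprocessConfig:
    """Tunables of the tissue-masking pipeline.

    The channel difference defaults to blue - green: both hematoxylin and
    eosin absorb green strongly and blue only weakly, so the difference
    tracks total stain presence and is near zero on lumen/secretion and
    empty glass.  The contrast-limited mapping linearly rescales after
    saturating ``clip_fraction`` of the in-mask intensity tails.
    """

    diff_channels: tuple[int, int] = (2, 1)  # blue - green
    clip_fraction: float = 0.01
    morph_radius: int = 3
    max_hole_px: int = 500


@dataclass
class ReferenceHistogram:
    """Mean per-channel intensity histogram of a representative cohort."""

    histograms: np.ndarray  # (3, 256) densities, each summing to 1
    n_source_images: int = 0

    @property
    def cdfs(self) -> np.ndarray:
        cdf = np.cumsum(self.histograms, axis=1)
        return cdf / cdf[:, -1:]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "histograms": self.histograms.tolist(),
                    "n_source_images": self.n_source_images,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceHistogram":
        obj = json.loads(Path(path).read_text())
        return cls(
            histograms=np.asarray(obj["histograms"], dtype=float),
            n_source_images=int(obj["n_source_images"]),
        )


def _channel_histogram(channel: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    vals = channel[mask] if mask is not None else channel.ravel()
    hist = np.bincount(vals.astype(np.uint8).ravel(), minlength=256).astype(float)
    total = hist.sum()
    return hist / total if total > 0 else hist


def compute_reference_histogram(
    images: list[np.ndarray],
    masks: list[np.ndarray] | None = None,
) -> ReferenceHistogram:
    """Mean of per-image normalized RGB histograms over a cohort.

    Each image contributes equally (its histogram is normalized to unit
    mass before averaging), so large ROIs do not dominate the reference.
    """
    if len(images) == 0:
        raise ValueError("no reference images given")
    if masks is None:
        masks = [None] * len(images)
    acc = np.zeros((3, 256))
    for img, mask in zip(images, masks):
        for c in range(3):
            acc[c] += _channel_histogram(img[..., c], mask)
    return ReferenceHistogram(histograms=acc / len(images), n_source_images=len(images))


def match_histogram(
    image: np.ndarray,
    ref: ReferenceHistogram,
    roi_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Map each RGB channel's CDF onto the reference CDF (monotone LUT).

    Only pixels inside ``roi_mask`` are transformed (and only they define
    the image's histogram); pixels outside are passed through untouched.
    CDF inversion ties resolve to the lowest intensity.
    """
    image = np.asarray(image)
    out = image.copy()
    ref_cdfs = ref.cdfs
    for c in range(3):
        hist = _channel_histogram(image[..., c], roi_mask)
        cdf = np.cumsum(hist)
        if cdf[-1] == 0:
            continue
        cdf = cdf / cdf[-1]
        # smallest reference intensity whose CDF reaches the image CDF
        lut = np.searchsorted(ref_cdfs[c], cdf - 1e-12, side="left")
        lut = np.clip(lut, 0, 255).astype(np.uint8)
        mapped = lut[image[..., c]]
        if roi_mask is not None:
            out[..., c][roi_mask] = mapped[roi_mask]
        else:
            out[..., c] = mapped
    return out


def otsu_threshold(gray: np.ndarray, mask: np.ndarray | None = None) -> int:
    """Otsu's threshold over a 256-bin histogram of the (masked) image.

    Returns the lowest integer t maximizing the between-class variance of
    the split {v <= t} vs {v > t}.  Input is scaled to [0, 255] if not
    already 8-bit.  Raises :class:`DegenerateHistogramError` on constant
    input.
    """
    vals = gray[mask] if mask is not None else np.asarray(gray).ravel()
    vals = np.asarray(vals, dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise DegenerateHistogramError("constant image: Otsu threshold undefined")
    if gray.dtype != np.uint8 or lo < 0 or hi > 255:
        vals = (vals - lo) / (hi - lo) * 255.0
    hist = np.bincount(np.clip(vals, 0, 255).astype(np.uint8), minlength=256).astype(
        float
    )
    p = hist / hist.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(p)
    m0 = np.cumsum(p * levels)
    mT = m0[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = np.where(
            (w0 > 0) & (w1 > 0), (mT * w0 - m0) ** 2 / (w0 * w1), -np.inf
        )
    return int(np.argmax(between))


def segment_effective_tissue(
    rgb: np.ndarray,
    roi_mask: np.ndarray,
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    """Binary effective-tissue mask within the ROI.

    Pipeline: channel difference -> contrast-limited linear mapping
    (saturating the configured tail fraction) -> Otsu threshold ->
    morphological opening, closing and hole filling -> intersect with the
    ROI mask.  A degenerate (constant) difference image returns the full
    ROI mask with a warning.
    """
    cfg = config or PreprocessConfig()
    roi_mask = np.asarray(roi_mask, dtype=bool)
    a, b = cfg.diff_channels
    diff = np.asarray(rgb[..., a], dtype=float) - np.asarray(rgb[..., b], dtype=float)

    vals = diff[roi_mask]
    if vals.size == 0 or vals.max() == vals.min():
        warnings.warn("degenerate channel-difference image; returning full ROI mask")
        return roi_mask.copy()
    lo, hi = np.percentile(vals, [100 * cfg.clip_fraction, 100 * (1 - cfg.clip_fraction)])
    if hi == lo:
        lo, hi = vals.min(), vals.max()
    mapped = np.clip((diff - lo) / (hi - lo), 0.0, 1.0) * 255.0

    try:
        t = otsu_threshold(mapped.astype(np.uint8), roi_mask)
    except DegenerateHistogramError:
        warnings.warn("degenerate mapped image; returning full ROI mask")
        return roi_mask.copy()
    tissue = (mapped > t) & roi_mask

    selem = disk(cfg.morph_radius)
    tissue = opening(tissue, selem)
    tissue = closing(tissue, selem)
    tissue = remove_small_holes(tissue, max_size=cfg.max_hole_px)
    return tissue & roi_mask
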