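"""End-to-end convenience layer: ROI in, feature vector out.

Chains the stages in the canonical order — histogram matching against a
cohort reference, effective-tissue segmentation, color deconvolution,
MSER nuclei segmentation, feature extraction — and exposes a cohort-level
driver that returns the feature matrix used by selection, classification
and reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureConfig, FeatureVector, extract_features
from .mser import CandidateRegion
from .nuclei import (
    NucleiConfig,
    NucleusSet,
    detect_mser,
    hematoxylin_rate_mask,
    select_nuclei,
)
from .preprocess import (
    PreprocessConfig,
    ReferenceHistogram,
    compute_reference_histogram,
    color_deconvolve,
    match_histogram,
    segment_effective_tissue,
)
from .stains import StainChannels
from .synth import RoiSample

__all__ = ["PipelineConfig", "SampleProducts", "process_sample", "cohort_features"]


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    nuclei: NucleiConfig = field(default_factory=NucleiConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)


@dataclass
class SampleProducts:
    """All intermediate products of one ROI run (QC and testing)."""

    sample_id: str
    matched_rgb: np.ndarray
    tissue_mask: np.ndarray
    stains: StainChannels
    candidates: list[CandidateRegion]
    nuclei: NucleusSet
    features: FeatureVector


def process_sample(
    rgb: np.ndarray,
    roi_mask: np.ndarray,
    reference: ReferenceHistogram | None = None,
    config: PipelineConfig | None = None,
    sample_id: str = "",
) -> SampleProducts:
    """Run the full single-ROI pipeline."""
    cfg = config or PipelineConfig()
    roi_mask = np.asarray(roi_mask, dtype=bool)
    matched = match_histogram(rgb, reference, roi_mask) if reference else rgb
    tissue = segment_effective_tissue(matched, roi_mask, cfg.preprocess)
    stains = color_deconvolve(matched)
    candidates = detect_mser(stains.hematoxylin, cfg.nuclei.mser)
    rate = hematoxylin_rate_mask(stains.hematoxylin, cfg.nuclei)
    nuclei = select_nuclei(candidates, rate, cfg.nuclei)
    fv = extract_features(
        stains, roi_mask, tissue, nuclei, candidates, sample_id, cfg.features
    )
    return SampleProducts(
        sample_id=sample_id,
        matched_rgb=matched,
        tissue_mask=tissue,
        stains=stains,
        candidates=candidates,
        nuclei=nuclei,
        features=fv,
    )


def cohort_features(
    samples: list[RoiSample],
    config: PipelineConfig | None = None,
    reference: ReferenceHistogram | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix and labels for a cohort of ROI samples.

    When no reference histogram is given it is computed from the cohort
    itself (the representative-set convention).
    """
    if reference is None:
        reference = compute_reference_histogram(
            [s.rgb for s in samples], [s.roi_mask for s in samples]
        )
    rows, labels, ids = [], [], []
    for s in samples:
        prod = process_sample(s.rgb, s.roi_mask, reference, config, s.sample_id)
        rows.append(prod.features.to_series())
        labels.append(s.label)
        ids.append(s.sample_id)
    X = pd.DataFrame(rows)
    X.index = ids
    return X, pd.Series(labels, index=ids, name="label")
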