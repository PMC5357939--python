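import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from heprofiler import synth
from heprofiler.pipeline import process_sample


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_cohort():
    """12 ROI samples (6 ordered epithelial, 6 scattered neoplastic)."""
    return synth.generate_cohort_samples(6, ["epithelial", "neoplastic"], seed=11)


@pytest.fixture(scope="session")
def epithelial_sample():
    params = synth.class_params("epithelial", seed=3)
    return synth.render_he(synth.generate_layout(params), params)


@pytest.fixture(scope="session")
def processed_epithelial(epithelial_sample):
    return process_sample(
        epithelial_sample.rgb, epithelial_sample.roi_mask, sample_id="epi3"
    )
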