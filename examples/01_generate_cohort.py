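"""Generate a labelled synthetic H&E ROI cohort with ground truth.

Renders ordered epithelial acini ("beads in a row" nuclei on rings) and
dense scattered neoplastic lesions, with per-image staining variation,
and writes images, masks and label/centroid tables.
"""

import tempfile
from pathlib import Path

import numpy as np

from heprofiler.synth import generate_cohort

out = Path(tempfile.mkdtemp(prefix="heprofiler_cohort_"))
labels = generate_cohort(5, ["epithelial", "neoplastic"], seed=7, out_dir=out)

print(f"cohort written to {out}")
print(labels.groupby("class").size().rename("n").to_string())
print(f"files: {len(list(out.glob('*.png')))} PNGs + labels.csv + centroids.csv")

# per-image stain gain variation is what histogram matching later removes
from imageio.v3 import imread

means = [imread(out / p).mean() for p in labels["path"]]
print(f"mean RGB intensity across images: {np.min(means):.1f}-{np.max(means):.1f} "
      "(staining variation between sections)")
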