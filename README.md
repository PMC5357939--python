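# heprofiler

Quantitative profiling of H&E-stained tissue regions of interest (ROIs),
built for separating early neoplastic lesions from normal epithelium in
prostate histology and for exploring spatial heterogeneity within normal
tissue.  It is aimed at computational-pathology and cancer-model
researchers who want interpretable, engineered features rather than
black-box embeddings.

The pipeline:

1. **Stain normalization** — per-channel histogram matching against a
   cohort-mean reference removes section-to-section staining variation.
2. **Effective-tissue masking** — a channel-difference image with
   contrast-limited mapping and Otsu thresholding excludes lumen,
   secretion and empty glass.
3. **Stain separation** — Beer–Lambert color deconvolution
   (`OD_c = −ln((I_c+1)/(I0+1))`, unmixed through a unit-norm H/E/residual
   stain matrix) yields hematoxylin and eosin density images.
4. **Nuclei segmentation** — maximally stable extremal regions (MSER) of
   the hematoxylin density, filtered by nucleus-plausible size and by
   overlap with a high-hematoxylin-rate mask.
5. **Feature extraction** — a fixed, ordered catalogue of **241
   features**: GLCM statistics (contrast, correlation, energy,
   homogeneity, mean intensity), rotation-invariant uniform LBP
   histograms and dense SIFT orientation-band energies at five
   neighborhood scales × two stain channels, MSER region summaries, and
   nuclei-arrangement features — inter-nucleus distances, axial circular
   statistics of neighbor orientations (variance 1−R, circular sd
   √(−2 ln R), skewness, kurtosis, with R the mean resultant length of
   doubled angles), and Gaussian density-map statistics.
6. **Feature stability selection** — per-feature two-sample
   Kolmogorov–Smirnov screen (α = 0.05) retaining features whose
   distributions agree between two control cohorts.
7. **Classification** — a 50-tree bagged random forest evaluated by
   leave-one-out cross-validation (one model per sample), with held-out
   class probabilities, Mann–Whitney AUC, confusion matrices and
   LOOCV-averaged feature importances.
8. **Reporting** — t-SNE embeddings, hierarchically clustered feature
   heatmaps, polar angle histograms; every figure's numbers are also
   written as CSV.

Because datasets of this kind are rarely published with per-nucleus
ground truth, the package includes a first-class **synthetic H&E ROI
generator**: acinar epithelium with nuclei ordered "beads in a row"
versus dense scattered lesions, rendered through the same stain model
the pipeline inverts, with per-image stain variation, ground-truth
centroids and tissue masks.  See `docs/methods.md` for the model and
all parameter choices.

## Worked example

```python
from heprofiler import synth
from heprofiler.pipeline import cohort_features
from heprofiler.classify import ForestConfig, loocv, roc_auc

samples = synth.generate_cohort_samples(12, ["epithelial", "neoplastic"], seed=31)
X, y = cohort_features(samples)          # 24 x 241 feature matrix
res = loocv(X, y.to_numpy(), ForestConfig(n_trees=50, seed=0))
roc = roc_auc(res.probabilities[:, 1], res.true_labels == res.classes[1])
print(res.n_models, roc.auc)
```

prints

```
LOOCV: 24 models trained (one per sample), held-out AUC = 1.000
```

— 24 forests (one per left-out sample) whose held-out probabilities
separate the ordered from the scattered arrangement perfectly at the
default class contrast.  The arrangement features carry the signal; from
the same cohort:

```
NhoodNucAngleVar       epithelial    0.590   neoplastic    0.821
numberOfNucInNucNB     epithelial    0.257   neoplastic    0.832
```

i.e. neighbor orientations around each nucleus are concentrated along
the local row axis in normal epithelium (low axial circular variance)
and dispersed in the lesion class, which also packs more nuclei into
each 35×35 px neighborhood.  The scripts in `examples/` walk through
each stage (generation, preprocessing, segmentation, features +
selection, classification + reporting) and print what the numbers mean;
`heprofiler --help` exposes the same stages as a command line.

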