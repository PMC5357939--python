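"""Synthetic H&E ROI generator with per-image ground truth.

Real prostate ROIs of this kind are acinar cross sections: a ring of
epithelium around a lumen, with nuclei sitting basally in an ordered
"beads in a row" arrangement.  Early neoplastic lesions instead fill the
epithelial band with dense, scattered nuclei.  The generator emulates
exactly that statistical contrast:

* ``epithelial`` scenes place nuclei at even arclength spacing on one or
  more concentric circles (smooth closed curves) inside the tissue band,
  with configurable positional jitter and an optional ``disorder``
  fraction of nuclei relocated by a hard-core scatter;
* ``neoplastic`` scenes place all nuclei by a hard-core (minimum
  inter-center distance) uniform process filling the band;
* ``himyc`` is a denser, larger-nuclei variant of the scattered class so
  the three-group classification path can be exercised.

Colors are synthesized through the same Beer-Lambert stain basis the
deconvolution step assumes (see :mod:`heprofiler.stains`), so stain
unmixing is exactly invertible up to 8-bit quantization.  The emulated
pixel scale is 0.5 um/px (a 20x objective), hence nucleus radii default
to ~9-11 px.  Everything is a pure function of the parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .stains import StainBasis, DEFAULT_BASIS, remix

__all__ = [
    "SceneParams",
    "RoiSample",
    "Layout",
    "LayoutInfeasibleError",
    "generate_layout",
    "render_he",
    "generate_cohort",
    "generate_cohort_samples",
    "class_params",
    "separation_specs",
    "CLASS_DEFAULTS",
]

#: Emulated pixel scale, micrometres per pixel (20x objective).
MICRONS_PER_PX = 0.5


class LayoutInfeasibleError(RuntimeError):
    """Requested nucleus count cannot be placed at the minimum spacing."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic ROI scene.

    ``lumen_fraction`` is the fraction of the circular ROI occupied by the
    central lumen/secretion region; the remainder is the epithelial tissue
    band.  ``stain_gain`` multiplies all stain densities, emulating
    section-to-section staining variation.  ``disorder`` (epithelial only)
    relocates that fraction of nuclei from the rings into a hard-core
    scatter, providing a continuous dial between the ordered and the
    scattered arrangement.
    """

    image_size: int = 256
    arrangement_class: str = "epithelial"  # epithelial | neoplastic | himyc
    n_nuclei: int = 50
    nucleus_radius_px: float = 9.0
    nucleus_radius_sd_px: float = 1.0
    ring_jitter_px: float = 1.5
    stain_gain: float = 1.0
    lumen_fraction: float = 0.30
    noise_sd: float = 3.0
    hard_core_factor: float = 1.5
    disorder: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 128:
            raise ValueError("image_size must be >= 128")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if not (0.0 <= self.lumen_fraction < 1.0):
            raise ValueError("lumen_fraction must be in [0, 1)")
        if self.stain_gain <= 0:
            raise ValueError("stain_gain must be > 0")
        if self.arrangement_class not in ("epithelial", "neoplastic", "himyc"):
            raise ValueError(f"unknown arrangement_class {self.arrangement_class!r}")
        if not (0.0 <= self.disorder <= 1.0):
            raise ValueError("disorder must be in [0, 1]")

    # Scene geometry (derived) -------------------------------------------
    @property
    def roi_radius(self) -> float:
        return 0.45 * self.image_size

    @property
    def lumen_radius(self) -> float:
        return float(np.sqrt(self.lumen_fraction) * self.roi_radius)


@dataclass
class Layout:
    """Nucleus centers (row, col) and per-nucleus radii for one scene."""

    centers: np.ndarray  # (n, 2) float
    radii: np.ndarray  # (n,) float

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class RoiSample:
    """One ROI: RGB render, ROI mask, label and (synthetic) ground truth."""

    rgb: np.ndarray
    roi_mask: np.ndarray
    label: str
    lobe: str = "LP"
    sample_id: str = ""
    truth_centroids: np.ndarray | None = None
    truth_tissue_mask: np.ndarray | None = None
    params: SceneParams | None = None


# ---------------------------------------------------------------------------
# Layout generation
# ---------------------------------------------------------------------------

def _hard_core_scatter(
    rng: np.random.Generator,
    n: int,
    center: float,
    r_inner: float,
    r_outer: float,
    min_dist: float,
    existing: np.ndarray | None = None,
    max_attempts_per_point: int = 400,
) -> np.ndarray:
    """Dart-throwing placement in an annulus with a minimum spacing."""
    placed: list[np.ndarray] = [] if existing is None else [p for p in existing]
    n_existing = len(placed)
    attempts = 0
    budget = max_attempts_per_point * max(n, 1)
    while len(placed) - n_existing < n:
        if attempts > budget:
            raise LayoutInfeasibleError(
                f"could not place {n} nuclei at spacing {min_dist:.1f}px "
                f"in annulus [{r_inner:.0f}, {r_outer:.0f}]"
            )
        attempts += 1
        # uniform in annulus area
        rad = np.sqrt(rng.uniform(r_inner**2, r_outer**2))
        ang = rng.uniform(0.0, 2.0 * np.pi)
        p = np.array([center + rad * np.sin(ang), center + rad * np.cos(ang)])
        if placed:
            d2 = np.min(np.sum((np.asarray(placed) - p) ** 2, axis=1))
            if d2 < min_dist**2:
                continue
        placed.append(p)
    out = np.asarray(placed[n_existing:], dtype=float)
    return out.reshape(-1, 2)


def generate_layout(params: SceneParams) -> Layout:
    """Place nucleus centers for one scene; deterministic given the seed.

    Raises :class:`LayoutInfeasibleError` when ``n_nuclei`` cannot fit the
    tissue band at the minimum spacing.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_nuclei
    r_nuc = params.nucleus_radius_px
    radii = np.clip(
        rng.normal(r_nuc, params.nucleus_radius_sd_px, size=n), 0.65 * r_nuc, 1.3 * r_nuc
    )
    if n == 0:
        return Layout(centers=np.empty((0, 2)), radii=radii)

    c = params.image_size / 2.0
    band_in = params.lumen_radius + 1.2 * r_nuc
    band_out = params.roi_radius - 1.2 * r_nuc
    if band_out <= band_in:
        raise LayoutInfeasibleError("tissue band too narrow for nucleus radius")

    if params.arrangement_class == "epithelial":
        n_scatter = int(round(params.disorder * n))
        n_ring = n - n_scatter
        # concentric rings through the band, even arclength spacing
        ring_step = 2.6 * r_nuc
        ring_radii = np.arange(band_in + 0.2 * r_nuc, band_out, ring_step)
        if len(ring_radii) == 0:
            ring_radii = np.array([(band_in + band_out) / 2.0])
        spacing = 2.4 * r_nuc
        caps = np.floor(2.0 * np.pi * ring_radii / spacing).astype(int)
        if caps.sum() < n_ring:
            raise LayoutInfeasibleError(
                f"ring capacity {caps.sum()} < requested {n_ring} nuclei"
            )
        # fill rings proportionally to capacity
        counts = np.floor(caps * n_ring / caps.sum()).astype(int)
        while counts.sum() < n_ring:
            counts[np.argmax(caps - counts)] += 1
        pts = []
        for r_ring, k in zip(ring_radii, counts):
            if k == 0:
                continue
            phase = rng.uniform(0.0, 2.0 * np.pi)
            ang = phase + 2.0 * np.pi * np.arange(k) / k
            rr = np.full(k, r_ring)
            if params.ring_jitter_px > 0:
                rr = rr + rng.normal(0.0, params.ring_jitter_px, size=k)
                ang = ang + rng.normal(0.0, params.ring_jitter_px / r_ring, size=k)
            pts.append(
                np.stack([c + rr * np.sin(ang), c + rr * np.cos(ang)], axis=1)
            )
        centers = np.concatenate(pts) if pts else np.empty((0, 2))
        if n_scatter > 0:
            scattered = _hard_core_scatter(
                rng,
                n_scatter,
                c,
                band_in,
                band_out,
                min_dist=params.hard_core_factor * r_nuc,
                existing=centers,
            )
            centers = np.concatenate([centers, scattered])
    else:  # neoplastic / himyc: hard-core uniform scatter filling the band
        centers = _hard_core_scatter(
            rng, n, c, band_in, band_out, min_dist=params.hard_core_factor * r_nuc
        )
    return Layout(centers=centers, radii=radii)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

# Stain densities of the tissue compartments at stain_gain = 1.
NUCLEUS_H = 0.90
NUCLEUS_E = 0.15
CYTOPLASM_H = 0.12
CYTOPLASM_E = 0.35


def _disk_mask(size: int, radius: float) -> np.ndarray:
    c = size / 2.0
    rr, cc = np.ogrid[:size, :size]
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


def render_he(
    layout: Layout,
    params: SceneParams,
    basis: StainBasis = DEFAULT_BASIS,
) -> RoiSample:
    """Render a layout into an 8-bit H&E-like RGB ROI with ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 9001)))
    size = params.image_size
    gain = params.stain_gain

    roi_mask = _disk_mask(size, params.roi_radius)
    lumen = _disk_mask(size, params.lumen_radius)
    tissue = roi_mask & ~lumen

    h_dens = np.zeros((size, size))
    e_dens = np.zeros((size, size))
    h_dens[tissue] = CYTOPLASM_H * gain
    e_dens[tissue] = CYTOPLASM_E * gain

    nuc_mask = np.zeros((size, size), dtype=bool)
    for (r, c), rad in zip(layout.centers, layout.radii):
        elong = rng.uniform(0.8, 1.0)
        theta = rng.uniform(0.0, np.pi)
        rr, cc = draw_ellipse(r, c, rad, rad * elong, shape=(size, size), rotation=theta)
        level = max(0.2, rng.normal(NUCLEUS_H, 0.06)) * gain
        h_dens[rr, cc] = level
        e_dens[rr, cc] = NUCLEUS_E * gain
        nuc_mask[rr, cc] = True

    rgb = remix(h_dens, e_dens, basis=basis).astype(float)
    if params.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, params.noise_sd, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    return RoiSample(
        rgb=rgb,
        roi_mask=roi_mask,
        label=params.arrangement_class,
        truth_centroids=layout.centers.copy(),
        truth_tissue_mask=tissue,
        params=params,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Per-class study conditions: the ordered epithelial ring arrangement, the
#: dense scattered lesion, and a denser / larger-nuclei scattered variant.
CLASS_DEFAULTS: dict[str, dict] = {
    "epithelial": dict(
        arrangement_class="epithelial",
        n_nuclei=45,
        nucleus_radius_px=9.0,
        nucleus_radius_sd_px=1.0,
        ring_jitter_px=1.5,
        lumen_fraction=0.30,
        hard_core_factor=2.0,
    ),
    "neoplastic": dict(
        arrangement_class="neoplastic",
        n_nuclei=70,
        nucleus_radius_px=8.0,
        nucleus_radius_sd_px=1.0,
        lumen_fraction=0.05,
        hard_core_factor=2.2,
    ),
    "himyc": dict(
        arrangement_class="himyc",
        n_nuclei=42,
        nucleus_radius_px=10.5,
        nucleus_radius_sd_px=1.0,
        lumen_fraction=0.02,
        hard_core_factor=2.2,
    ),
}

#: Section-to-section stain variation: stain_gain ~ LogNormal(0, 0.2).
STAIN_GAIN_SIGMA = 0.2


def class_params(class_name: str, *, seed: int = 0, **overrides) -> SceneParams:
    """Default :class:`SceneParams` for a named arrangement class."""
    spec = dict(CLASS_DEFAULTS[class_name])
    spec.update(overrides)
    return SceneParams(seed=seed, **spec)


def separation_specs(separation: float) -> dict[str, dict]:
    """Two-class parameter sets with a tunable separation dial in [0, 1].

    At ``separation=1`` the classes are the study defaults; as it shrinks
    the epithelial class gains jitter and a scattered (disordered)
    fraction, and the lesion density shrinks toward the epithelial count,
    so the arrangements converge.
    """
    s = float(separation)
    if not (0.0 <= s <= 1.0):
        raise ValueError("separation must be in [0, 1]")
    epi = dict(CLASS_DEFAULTS["epithelial"])
    neo = dict(CLASS_DEFAULTS["neoplastic"])
    # epithelium loses order: jitter grows, a fraction scatters off the rings
    epi["ring_jitter_px"] = 1.5 + 9.0 * (1.0 - s)
    epi["disorder"] = 1.0 - s  # at s=0 the classes are indistinguishable
    epi["lumen_fraction"] = 0.30 - 0.10 * (1.0 - s)
    epi["hard_core_factor"] = 1.7
    # the lesion relaxes toward the epithelial geometry (count quadratic in
    # s keeps the packing away from the jamming density mid-dial)
    neo["n_nuclei"] = int(round(45 + 25.0 * s * s))
    neo["nucleus_radius_px"] = 8.0 + 1.0 * (1.0 - s)
    neo["lumen_fraction"] = 0.05 + 0.15 * (1.0 - s)
    neo["hard_core_factor"] = 2.2 - 0.5 * (1.0 - s)
    return {"epithelial": epi, "neoplastic": neo}


def _child_seed(root_seed: int, index: int) -> np.random.SeedSequence:
    """Counter-scheme child seed: SeedSequence keyed by (root, index)."""
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(index,))


def generate_cohort_samples(
    n_per_class: int,
    class_specs: dict[str, dict] | list[str] | None = None,
    seed: int = 0,
    image_size: int = 256,
) -> list[RoiSample]:
    """Generate an in-memory labelled cohort, reproducible from ``seed``.

    Per-image stain gains are drawn LogNormal(0, 0.2) so the cohort shows
    the staining variation that histogram matching is meant to remove.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if class_specs is None:
        class_specs = ["epithelial", "neoplastic"]
    if isinstance(class_specs, (list, tuple)):
        class_specs = {name: dict(CLASS_DEFAULTS[name]) for name in class_specs}

    samples: list[RoiSample] = []
    index = 0
    for cls_name, spec in class_specs.items():
        for i in range(n_per_class):
            ss = _child_seed(seed, index)
            img_seed, gain_seed = (int(x) for x in ss.generate_state(2))
            gain = float(
                np.exp(np.random.default_rng(gain_seed).normal(0.0, STAIN_GAIN_SIGMA))
            )
            params = SceneParams(
                image_size=image_size,
                stain_gain=gain,
                seed=img_seed % (2**31),
                **spec,
            )
            layout = generate_layout(params)
            sample = render_he(layout, params)
            sample.label = cls_name
            sample.sample_id = f"{cls_name}_{i:03d}"
            samples.append(sample)
            index += 1
    return samples


def generate_cohort(
    n_per_class: int,
    class_specs: dict[str, dict] | list[str] | None = None,
    seed: int = 0,
    out_dir: str | Path = "cohort",
    image_size: int = 256,
) -> pd.DataFrame:
    """Generate a cohort and write images, masks and label tables to disk.

    Writes ``<id>.png`` (RGB), ``<id>_mask.png`` (255 = ROI), a
    ``labels.csv`` (sample_id, path, mask_path, class, lobe, seed) and a
    ``centroids.csv`` (sample_id, row, col) of the ground-truth nuclei.
    """
    from imageio.v3 import imwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = generate_cohort_samples(n_per_class, class_specs, seed, image_size)

    rows, cent_rows = [], []
    for s in samples:
        img_path = out / f"{s.sample_id}.png"
        mask_path = out / f"{s.sample_id}_mask.png"
        imwrite(img_path, s.rgb)
        imwrite(mask_path, (s.roi_mask.astype(np.uint8) * 255))
        rows.append(
            dict(
                sample_id=s.sample_id,
                path=img_path.name,
                mask_path=mask_path.name,
                **{"class": s.label},
                lobe=s.lobe,
                seed=s.params.seed if s.params else -1,
            )
        )
        for r, c in s.truth_centroids:
            cent_rows.append(dict(sample_id=s.sample_id, row=r, col=c))
    labels = pd.DataFrame(rows)
    labels.to_csv(out / "labels.csv", index=False)
    pd.DataFrame(cent_rows).to_csv(out / "centroids.csv", index=False)
    return labels
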