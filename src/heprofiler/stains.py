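"""Beer-Lambert stain model for H&E imagery.

Transmitted light through a stained section follows Beer-Lambert: for color
channel c, the recorded intensity is ``I_c = I0 * exp(-OD_c)`` where the
optical density ``OD_c`` is a linear mix of per-stain densities through a
3x3 matrix of unit-norm stain absorption vectors.  Color deconvolution
inverts that mix to recover hematoxylin, eosin and a residual channel.

The default basis is the canonical H&E pair (hematoxylin absorbing red and
green, eosin absorbing mostly green) with the residual completed as the
unit cross product, so the matrix is always invertible.  The synthetic
renderer uses the same forward model, which makes the
render -> deconvolve round trip exact up to 8-bit quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StainChannels", "StainBasis", "DEFAULT_BASIS", "color_deconvolve", "remix"]

#: White level of the 8-bit transmitted-light model. OD = -ln((I + 1) / (I0 + 1))
#: so a saturated pixel (255) has exactly zero optical density.
I0 = 255.0

_HEMATOXYLIN = (0.650, 0.704, 0.286)
_EOSIN = (0.072, 0.990, 0.105)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class StainBasis:
    """Unit-norm absorption vectors (rows) for H, E and the residual."""

    hematoxylin: tuple[float, float, float] = _HEMATOXYLIN
    eosin: tuple[float, float, float] = _EOSIN

    @property
    def matrix(self) -> np.ndarray:
        """3x3 row-stochastic-direction stain matrix [H; E; residual]."""
        h = _unit(np.asarray(self.hematoxylin, dtype=float))
        e = _unit(np.asarray(self.eosin, dtype=float))
        r = _unit(np.cross(h, e))
        return np.stack([h, e, r])

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


DEFAULT_BASIS = StainBasis()


@dataclass
class StainChannels:
    """Per-stain optical-density images from color deconvolution.

    The three named planes are clipped to be nonnegative (physical
    densities) and share the input image shape.  ``raw`` keeps the signed
    unmixed densities, (H, W, 3); pixels outside the stain simplex have
    negative raw entries, and only ``raw`` remixes back to the exact
    input.
    """

    hematoxylin: np.ndarray
    eosin: np.ndarray
    residual: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    raw: np.ndarray | None = field(repr=False, default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.hematoxylin.shape


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Optical density per channel: OD = -ln((I + 1) / (I0 + 1))."""
    arr = np.asarray(rgb, dtype=float)
    return -np.log((arr + 1.0) / (I0 + 1.0))


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_od` and quantize to 8 bit."""
    inten = (I0 + 1.0) * np.exp(-np.asarray(od, dtype=float)) - 1.0
    return np.clip(np.rint(inten), 0, 255).astype(np.uint8)


def color_deconvolve(rgb: np.ndarray, basis: StainBasis = DEFAULT_BASIS) -> StainChannels:
    """Unmix an 8-bit RGB image into H, E and residual optical densities.

    Negative unmixed densities (noise outside the stain simplex) are
    clipped to zero.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    od = rgb_to_od(rgb)
    raw = (od.reshape(-1, 3) @ basis.inverse).reshape(rgb.shape)
    dens = np.clip(raw, 0.0, None)
    return StainChannels(
        hematoxylin=dens[..., 0], eosin=dens[..., 1], residual=dens[..., 2], raw=raw
    )


def remix(
    h_density: np.ndarray,
    e_density: np.ndarray,
    residual: np.ndarray | None = None,
    basis: StainBasis = DEFAULT_BASIS,
) -> np.ndarray:
    """Forward Beer-Lambert model: stain densities -> 8-bit RGB image."""
    h = np.asarray(h_density, dtype=float)
    e = np.asarray(e_density, dtype=float)
    r = np.zeros_like(h) if residual is None else np.asarray(residual, dtype=float)
    dens = np.stack([h, e, r], axis=-1)
    od = dens.reshape(-1, 3) @ basis.matrix
    return od_to_rgb(od.reshape(dens.shape))
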