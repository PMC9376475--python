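"""Colour handling for brightfield H-DAB tiles.

Brightfield IHC obeys Beer-Lambert absorption: per colour channel the
transmitted intensity is I = I0 * 10**(-OD), and optical densities of the
individual chromogens (hematoxylin, DAB) mix additively.  Everything here
works in that OD space: estimate the incident white point I0 from background
glass, convert intensities to OD, and unmix the OD vectors into per-stain
concentration maps with a fixed stain basis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, SingularBasisError

logger = logging.getLogger(__name__)

#: Ceiling applied to optical densities; 8-bit data cannot resolve OD > ~2.4
#: (1/255 of full scale), so values are clamped here.
DEFAULT_OD_MAX = 3.0


@dataclasses.dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB tile plus its physical pixel size in microns."""

    pixels: np.ndarray  # H x W x 3, values in [0, 255]
    microns_per_pixel: float = 0.5

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidInputError("RGBImage requires an H x W x 3 array")
        if px.min() < 0 or px.max() > 255:
            raise InvalidInputError("RGB values must lie in [0, 255]")
        if not self.microns_per_pixel > 0:
            raise InvalidInputError("microns_per_pixel must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclasses.dataclass(frozen=True)
class WhitePoint:
    """Per-channel incident (background) intensity I0.

    ``from_background`` records whether the estimate came from qualifying
    background pixels or from the documented fallback path.
    """

    i0: np.ndarray  # shape (3,), each in (0, 255]
    from_background: bool = True

    def __post_init__(self) -> None:
        i0 = np.asarray(self.i0, dtype=float)
        if i0.shape != (3,):
            raise InvalidInputError("white point must have three components")
        if np.any(i0 <= 0):
            raise InvalidInputError("white point components must be positive")
        object.__setattr__(self, "i0", i0)


@dataclasses.dataclass(frozen=True)
class StainBasis:
    """Unit stain vectors spanning OD space.

    ``hema_vec`` and ``dab_vec`` are the absorption directions of the two
    chromogens; ``residual_vec`` completes the basis (default: their cross
    product) and soaks up everything neither stain explains.
    """

    hema_vec: np.ndarray
    dab_vec: np.ndarray
    residual_vec: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "dab", "residual")

    def __post_init__(self) -> None:
        vecs = []
        for v in (self.hema_vec, self.dab_vec, self.residual_vec):
            v = np.asarray(v, dtype=float)
            n = np.linalg.norm(v)
            if v.shape != (3,) or n == 0:
                raise InvalidInputError("stain vectors must be nonzero 3-vectors")
            vecs.append(v / n)
        object.__setattr__(self, "hema_vec", vecs[0])
        object.__setattr__(self, "dab_vec", vecs[1])
        object.__setattr__(self, "residual_vec", vecs[2])
        if abs(np.linalg.det(self.matrix)) < 1e-8:
            raise SingularBasisError("stain vectors are linearly dependent")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix whose columns are the stain vectors (OD = M @ conc)."""
        return np.stack([self.hema_vec, self.dab_vec, self.residual_vec], axis=1)

    @classmethod
    def hdab(cls) -> "StainBasis":
        """Published H-DAB stain vectors (Ruifrok-Johnston coefficients)."""
        hema = np.array([0.650, 0.704, 0.286])
        dab = np.array([0.268, 0.570, 0.776])
        residual = np.cross(hema, dab)
        return cls(hema, dab, residual)

    @classmethod
    def from_json(cls, path) -> "StainBasis":
        with open(path) as fh:
            d = json.load(fh)
        residual = d.get("residual")
        if residual is None:
            residual = np.cross(d["hematoxylin"], d["dab"])
        return cls(np.asarray(d["hematoxylin"]), np.asarray(d["dab"]), np.asarray(residual))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "hematoxylin": self.hema_vec.tolist(),
                    "dab": self.dab_vec.tolist(),
                    "residual": self.residual_vec.tolist(),
                },
                fh,
                indent=2,
            )


@dataclasses.dataclass(frozen=True)
class ODImage:
    """Per-pixel optical density of an RGB tile."""

    od: np.ndarray  # H x W x 3, in [0, od_max]
    od_max: float = DEFAULT_OD_MAX


@dataclasses.dataclass(frozen=True)
class StainChannels:
    """Per-stain concentration maps from deconvolution.

    ``hema`` and ``dab`` are clamped at zero from below; the residual keeps
    its sign so off-basis colour remains visible to diagnostics.
    """

    hema: np.ndarray
    dab: np.ndarray
    residual: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.hema.shape


def estimate_white_balance(
    img: RGBImage,
    background_quantile: float = 0.99,
    saturation_max: float = 0.1,
    brightness_min: float = 0.5,
) -> WhitePoint:
    """Estimate the incident intensity I0 from background glass pixels.

    Background is defined as near-achromatic (saturation below
    ``saturation_max``), bright (above ``brightness_min`` of full scale)
    pixels; I0 is the per-channel ``background_quantile`` over them.  If no
    pixel qualifies the quantile is taken over the whole tile and the result
    flagged, with components floored at 1 so the subsequent log transform is
    defined.
    """
    if not 0 < background_quantile < 1:
        raise InvalidInputError("background_quantile must be in (0, 1)")
    px = np.asarray(img.pixels, dtype=float).reshape(-1, 3)
    if px.size == 0:
        raise InvalidInputError("empty image")
    mx = px.max(axis=1)
    mn = px.min(axis=1)
    sat = (mx - mn) / np.maximum(mx, 1e-9)
    mask = (sat < saturation_max) & (mx / 255.0 > brightness_min)
    from_background = bool(mask.any())
    if not from_background:
        logger.warning(
            "no background pixels qualify for white balance; "
            "falling back to global quantile"
        )
    sel = px[mask] if from_background else px
    i0 = np.quantile(sel, background_quantile, axis=0)
    if np.any(i0 < 1.0):
        logger.warning("white point floored at 1 intensity unit")
        i0 = np.maximum(i0, 1.0)
    return WhitePoint(i0=i0, from_background=from_background)


def rgb_to_od(img: RGBImage, wp: WhitePoint, od_max: float = DEFAULT_OD_MAX) -> ODImage:
    """Beer-Lambert transform: OD_c = -log10(max(I_c, 1) / I0_c), clamped to [0, od_max].

    Intensities are floored at 1 before the log so fully absorbed (zero)
    pixels map to a finite density.
    """
    px = np.asarray(img.pixels, dtype=float)
    od = -np.log10(np.maximum(px, 1.0) / wp.i0)
    od = np.clip(od, 0.0, od_max)
    return ODImage(od=od, od_max=od_max)


def deconvolve(od: ODImage, basis: StainBasis) -> StainChannels:
    """Unmix OD vectors into stain concentrations by solving OD = M @ c per pixel.

    With a full 3-vector basis this is the exact linear solve (equivalently
    the least-squares projection); hematoxylin and DAB concentrations are
    clamped at zero from below.
    """
    m = basis.matrix
    if abs(np.linalg.det(m)) < 1e-8:
        raise SingularBasisError("stain basis is singular")
    flat = np.asarray(od.od, dtype=float).reshape(-1, 3)
    conc = flat @ np.linalg.inv(m).T
    h, w = od.od.shape[:2]
    conc = conc.reshape(h, w, 3)
    return StainChannels(
        hema=np.maximum(conc[..., 0], 0.0),
        dab=np.maximum(conc[..., 1], 0.0),
        residual=conc[..., 2],
    )


def reconstruct(
    channels: StainChannels,
    basis: StainBasis,
    wp: WhitePoint,
    od_max: float = DEFAULT_OD_MAX,
    microns_per_pixel: float = 0.5,
) -> RGBImage:
    """Invert deconvolution and the OD transform (validation round-trip).

    Composes the concentration maps back through the stain matrix, applies
    the inverse Beer-Lambert transform against ``wp`` and quantizes to 8-bit.
    """
    conc = np.stack([channels.hema, channels.dab, channels.residual], axis=-1)
    od = np.clip(conc @ basis.matrix.T, 0.0, od_max)
    intensity = wp.i0 * np.power(10.0, -od)
    px = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    return RGBImage(pixels=px, microns_per_pixel=microns_per_pixel)


def compose_od(
    hema: np.ndarray,
    dab: np.ndarray,
    basis: StainBasis,
    residual: np.ndarray | None = None,
) -> np.ndarray:
    """Forward-mix concentration maps into an H x W x 3 OD image."""
    od = hema[..., None] * basis.hema_vec + dab[..., None] * basis.dab_vec
    if residual is not None:
        od = od + residual[..., None] * basis.residual_vec
    return od
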