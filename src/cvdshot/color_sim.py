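"""Dichromat (color-vision-deficiency) simulation of sRGB images.

Simulates how a protanope, deuteranope or tritanope perceives an image by
projecting each pixel, in LMS cone space, onto the 2-D surface a dichromat
can distinguish.  The default model is the Brettel–Viénot–Mollon
construction: a single projection plane for protanopia/deuteranopia and two
half-planes (hinged on the neutral axis) for tritanopia.  The precomputed
Machado et al. severity-1.0 matrices are available as an alternate model.

Pipeline for every condition other than ``none``::

    sRGB --decode--> linear RGB --M--> LMS --project--> LMS
         --M^-1--> linear RGB --clip--> --encode--> sRGB

All matrices live in an LMS space normalized so that linear-RGB white
(1, 1, 1) maps to LMS (1, 1, 1); the projection planes contain that neutral
axis, so achromatic pixels are exact fixed points of the simulation.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

__all__ = [
    "CVDCondition",
    "ColorImage",
    "DichromatModel",
    "ValidationError",
    "srgb_to_linear",
    "linear_to_srgb",
    "build_dichromat_model",
    "machado_matrix",
    "simulate_cvd",
    "batch_simulate",
    "RGB_TO_LMS",
    "LMS_TO_RGB",
]


class ValidationError(ValueError):
    """Raised when an image or argument violates a documented precondition."""


class CVDCondition(str, enum.Enum):
    """Which dichromacy is simulated; ``none`` means normal color vision."""

    NONE = "none"
    PROTANOPIA = "protanopia"
    DEUTERANOPIA = "deuteranopia"
    TRITANOPIA = "tritanopia"

    @classmethod
    def parse(cls, value: "str | CVDCondition") -> "CVDCondition":
        """Accept canonical names plus the common short forms (protan, prot...)."""
        if isinstance(value, cls):
            return value
        aliases = {
            "none": cls.NONE,
            "normal": cls.NONE,
            "protanopia": cls.PROTANOPIA,
            "protan": cls.PROTANOPIA,
            "prot": cls.PROTANOPIA,
            "deuteranopia": cls.DEUTERANOPIA,
            "deutan": cls.DEUTERANOPIA,
            "deuter": cls.DEUTERANOPIA,
            "deut": cls.DEUTERANOPIA,
            "tritanopia": cls.TRITANOPIA,
            "tritan": cls.TRITANOPIA,
            "trit": cls.TRITANOPIA,
        }
        key = str(value).strip().lower()
        if key not in aliases:
            raise ValidationError(
                f"unknown CVD condition {value!r}; expected one of "
                f"{[c.value for c in cls]}"
            )
        return aliases[key]


# ---------------------------------------------------------------------------
# Color-space constants
# ---------------------------------------------------------------------------

# IEC 61966-2-1 sRGB primaries, D65 white.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

# Hunt–Pointer–Estevez cone responses (equal-energy normalized form).
_XYZ_TO_LMS_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.0, 0.0, 1.0],
    ]
)

_RGB_TO_LMS_RAW = _XYZ_TO_LMS_HPE @ _SRGB_TO_XYZ
_WHITE_RAW = _RGB_TO_LMS_RAW @ np.ones(3)

#: Linear RGB -> LMS, row-normalized so white (1,1,1) maps to LMS (1,1,1).
RGB_TO_LMS = _RGB_TO_LMS_RAW / _WHITE_RAW[:, None]
#: LMS -> linear RGB (exact inverse of :data:`RGB_TO_LMS`).
LMS_TO_RGB = np.linalg.inv(RGB_TO_LMS)

#: LMS of the neutral (achromatic) axis in this normalization.
WHITE_LMS = np.ones(3)

# CIE 1931 2-degree color-matching function values at the anchor wavelengths
# of the dichromat construction: 475/575 nm (protan, deutan) and 485/660 nm
# (tritan half-planes).
_ANCHOR_XYZ = {
    475: np.array([0.1421, 0.1126, 1.0419]),
    485: np.array([0.05795, 0.1693, 0.6162]),
    575: np.array([0.8425, 0.9154, 0.0018]),
    660: np.array([0.1649, 0.0610, 0.0000]),
}


def _anchor_lms(wavelength_nm: int) -> np.ndarray:
    """LMS direction of a monochromatic anchor, in the normalized space."""
    return (_XYZ_TO_LMS_HPE @ _ANCHOR_XYZ[wavelength_nm]) / _WHITE_RAW


def _axis_projection(missing_axis: int, plane_second: np.ndarray) -> np.ndarray:
    """Projection along cone axis ``missing_axis`` onto the plane through the
    origin spanned by the neutral axis and ``plane_second``.

    ``P = I - e n^T / (n . e)`` with ``n`` the plane normal is idempotent and
    rank 2 by construction, and fixes every vector in the plane exactly.
    """
    n = np.cross(WHITE_LMS, plane_second)
    if abs(n[missing_axis]) < 1e-12:
        raise ValueError("projection plane is parallel to the missing cone axis")
    e = np.zeros(3)
    e[missing_axis] = 1.0
    return np.eye(3) - np.outer(e, n) / n[missing_axis]


@dataclass(frozen=True)
class DichromatModel:
    """Linear-algebraic realization of one dichromacy.

    For protanopia/deuteranopia ``projection`` is the single LMS plane
    projection; for tritanopia ``projection``/``projection_alt`` are the two
    half-plane projections and ``separating_normal`` is the LMS normal of the
    plane (through the neutral axis and the S cone axis) that decides which
    half-plane a pixel belongs to.  Pixels with a non-negative dot product
    against the normal — the reddish side — use ``projection``.
    """

    condition: CVDCondition
    rgb_to_lms: np.ndarray
    lms_to_rgb: np.ndarray
    projection: np.ndarray
    projection_alt: Optional[np.ndarray] = None
    separating_normal: Optional[np.ndarray] = None

    def project_lms(self, lms: np.ndarray) -> np.ndarray:
        """Apply the (half-)plane projection to an (..., 3) LMS array."""
        if self.projection_alt is None:
            return lms @ self.projection.T
        side = lms @ self.separating_normal
        out = np.where(
            (side >= 0.0)[..., None],
            lms @ self.projection.T,
            lms @ self.projection_alt.T,
        )
        return out


def build_dichromat_model(condition: "str | CVDCondition") -> DichromatModel:
    """Build the Brettel/Viénot projection model for one dichromacy.

    Raises a usage error for ``none`` — there is no model for normal vision.
    """
    condition = CVDCondition.parse(condition)
    if condition is CVDCondition.NONE:
        raise ValidationError("no dichromat model for normal vision (condition 'none')")
    if condition is CVDCondition.PROTANOPIA:
        proj = _axis_projection(0, _anchor_lms(575))
        return DichromatModel(condition, RGB_TO_LMS, LMS_TO_RGB, proj)
    if condition is CVDCondition.DEUTERANOPIA:
        proj = _axis_projection(1, _anchor_lms(575))
        return DichromatModel(condition, RGB_TO_LMS, LMS_TO_RGB, proj)
    # Tritanopia: two half-planes hinged on the neutral axis, anchored at
    # 660 nm (reddish side) and 485 nm (bluish-greenish side).  The deciding
    # plane contains the neutral axis and the S axis: normal = W x e_S.
    proj_red = _axis_projection(2, _anchor_lms(660))
    proj_blue = _axis_projection(2, _anchor_lms(485))
    separating = np.cross(WHITE_LMS, np.array([0.0, 0.0, 1.0]))
    return DichromatModel(
        CVDCondition.TRITANOPIA,
        RGB_TO_LMS,
        LMS_TO_RGB,
        projection=proj_red,
        projection_alt=proj_blue,
        separating_normal=separating,
    )


# Machado, Oliveira & Fernandes (2009) physiologically-based simulation,
# severity 1.0, applied directly in linear RGB.  Rows sum to 1, so the gray
# axis is preserved, but these are not idempotent projections.
_MACHADO = {
    CVDCondition.PROTANOPIA: np.array(
        [
            [0.152286, 1.052583, -0.204868],
            [0.114503, 0.786281, 0.099216],
            [-0.003882, -0.048116, 1.051998],
        ]
    ),
    CVDCondition.DEUTERANOPIA: np.array(
        [
            [0.367322, 0.860646, -0.227968],
            [0.280085, 0.672501, 0.047413],
            [-0.011820, 0.042940, 0.968881],
        ]
    ),
    CVDCondition.TRITANOPIA: np.array(
        [
            [1.255528, -0.076749, -0.178779],
            [-0.078411, 0.930809, 0.147602],
            [0.004733, 0.691367, 0.303900],
        ]
    ),
}


def machado_matrix(condition: "str | CVDCondition") -> np.ndarray:
    """Machado et al. severity-1.0 linear-RGB matrix for one dichromacy."""
    condition = CVDCondition.parse(condition)
    if condition is CVDCondition.NONE:
        raise ValidationError("no dichromat model for normal vision (condition 'none')")
    return _MACHADO[condition].copy()


# ---------------------------------------------------------------------------
# Images and transfer functions
# ---------------------------------------------------------------------------

_SPACES = ("srgb", "linear_rgb", "lms")


@dataclass
class ColorImage:
    """An H x W x 3 float raster with a color-space tag.

    Channel values are in [0, 1] when the tag is ``srgb`` (8-bit files decode
    as value/255); ``linear_rgb`` values may transiently leave the gamut
    after a projection and are clipped on re-encoding.
    """

    pixels: np.ndarray
    space: str = "srgb"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError(
                f"expected an HxWx3 raster, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError("image must be at least 1x1")
        if self.space not in _SPACES:
            raise ValidationError(f"unknown color space tag {self.space!r}")
        bad = ~np.isfinite(self.pixels)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValidationError(f"non-finite channel value at pixel index {idx}")
        if self.space == "srgb":
            out = (self.pixels < 0.0) | (self.pixels > 1.0)
            if out.any():
                idx = tuple(int(i) for i in np.argwhere(out)[0])
                raise ValidationError(
                    f"sRGB channel value out of [0, 1] at pixel index {idx}: "
                    f"{self.pixels[idx]!r}"
                )

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def copy(self) -> "ColorImage":
        return ColorImage(self.pixels.copy(), self.space)

    @classmethod
    def open(cls, path: "str | Path") -> "ColorImage":
        """Read a PNG/JPEG file; alpha channels are dropped with a warning."""
        with Image.open(path) as im:
            if im.mode in ("RGBA", "LA", "PA"):
                logger.warning("dropping alpha channel of %s", path)
            rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.float64) / 255.0
        return cls(arr, "srgb")

    def save(self, path: "str | Path") -> None:
        """Write as 8-bit RGB; values re-encode as round(value*255)."""
        if self.space != "srgb":
            raise ValidationError("only sRGB images can be written to file")
        data = np.rint(self.pixels * 255.0).astype(np.uint8)
        Image.fromarray(data, mode="RGB").save(path)


def _srgb_decode(values: np.ndarray) -> np.ndarray:
    # IEC 61966-2-1 piecewise electro-optical transfer function.
    v = np.asarray(values, dtype=np.float64)
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _srgb_encode(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=np.float64)
    v = np.clip(v, 0.0, None)
    return np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1.0 / 2.4) - 0.055)


def srgb_to_linear(image: ColorImage) -> ColorImage:
    """Decode gamma-encoded sRGB to linear light (both in [0, 1])."""
    if image.space != "srgb":
        raise ValidationError(f"expected an sRGB image, got {image.space!r}")
    return ColorImage(_srgb_decode(image.pixels), "linear_rgb")


def linear_to_srgb(image: ColorImage) -> ColorImage:
    """Encode linear light back to sRGB, hard-clipping to [0, 1]."""
    if image.space != "linear_rgb":
        raise ValidationError(f"expected a linear RGB image, got {image.space!r}")
    clipped = np.clip(image.pixels, 0.0, 1.0)
    return ColorImage(np.clip(_srgb_encode(clipped), 0.0, 1.0), "srgb")


def simulate_cvd(
    image: ColorImage,
    condition: "str | CVDCondition",
    model: str = "brettel",
) -> ColorImage:
    """Simulate how a dichromat perceives an sRGB image.

    Parameters
    ----------
    image:
        Valid sRGB :class:`ColorImage`.
    condition:
        Dichromacy to simulate; ``none`` returns an identical copy.
    model:
        ``"brettel"`` (default, the Brettel/Viénot LMS projection) or
        ``"machado"`` (precomputed severity-1.0 linear-RGB matrix).
    """
    condition = CVDCondition.parse(condition)
    if image.space != "srgb":
        raise ValidationError("simulate_cvd expects an sRGB image")
    if condition is CVDCondition.NONE:
        return image.copy()
    linear = srgb_to_linear(image).pixels
    if model == "machado":
        projected = linear @ machado_matrix(condition).T
    elif model == "brettel":
        dichromat = build_dichromat_model(condition)
        lms = linear @ dichromat.rgb_to_lms.T
        lms = dichromat.project_lms(lms)
        projected = lms @ dichromat.lms_to_rgb.T
    else:
        raise ValidationError(f"unknown simulation model {model!r}")
    return linear_to_srgb(ColorImage(projected, "linear_rgb"))


_RASTER_SUFFIXES = (".png", ".jpg", ".jpeg")


def batch_simulate(
    input_dir: "str | Path",
    output_dir: "str | Path",
    condition: "str | CVDCondition",
    model: str = "brettel",
) -> int:
    """Simulate every PNG/JPEG in ``input_dir`` into ``output_dir``.

    Outputs keep the input basename but are always written as PNG (lossless,
    so repeated simulation is bit-stable).  Unreadable files are logged and
    skipped; the count of images written is returned.
    """
    condition = CVDCondition.parse(condition)
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    files = sorted(
        p for p in input_dir.iterdir()
        if p.is_file() and p.suffix.lower() in _RASTER_SUFFIXES
    )
    if not files:
        logger.warning("no raster files found in %s", input_dir)
        return 0
    written = 0
    for path in files:
        try:
            image = ColorImage.open(path)
        except (OSError, UnidentifiedImageError, ValidationError) as exc:
            logger.error("skipping unreadable image %s: %s", path, exc)
            continue
        simulate_cvd(image, condition, model=model).save(
            output_dir / (path.stem + ".png")
        )
        written += 1
    return written
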