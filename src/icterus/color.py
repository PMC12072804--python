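"""White-reference color correction and YCbCr conversion.

The correction model is the diagonal von Kries chromatic adaptation: each
channel of the image is scaled by the ratio of a target white to the observed
mean of a known-white reference patch photographed in the same frame.  With a
truly white reference this cancels any diagonal illuminant cast exactly, so
images taken under different lighting become comparable.

The diagonal is applied directly to the camera's R, G, B channels (treating
them as the long/medium/short-wavelength analogue) without gamma
linearization or a cone-space transform; both refinements are available as
keyword switches but default off, since the correction is defined relative to
pixel values of the reference paper as captured.

YCbCr uses the full-range ITU-R BT.601 matrix (the JPEG convention), which is
what consumer phone cameras encode.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigurationError, ContractViolationWarning, DegenerateReferenceError

#: (row_start, col_start, row_stop, col_stop), 0-based, half-open.
PixelBox = tuple[int, int, int, int]


class ColorTag(str, enum.Enum):
    SRGB_RAW = "sRGB-raw"
    WHITE_BALANCED = "white-balanced"


@dataclass
class RGBImage:
    """An 8-bit RGB image held as real values in [0, 255].

    Keeping float pixels avoids accumulating quantization error across the
    correction and colorspace stages; rounding happens only on PNG export.
    """

    pixels: np.ndarray  # (H, W, 3) float64 in [0, 255]
    tag: ColorTag = ColorTag.SRGB_RAW

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ConfigurationError(
                f"RGBImage needs an (H, W, 3) array, got shape {self.pixels.shape}"
            )
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ConfigurationError("RGB intensities must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class YCbCrImage:
    """Full-range YCbCr image; all three channels clipped to [0, 255]."""

    pixels: np.ndarray  # (H, W, 3) float64

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ConfigurationError(
                f"YCbCrImage needs an (H, W, 3) array, got shape {self.pixels.shape}"
            )


@dataclass
class ReferencePatch:
    """A rectangular known-white region and its observed channel means."""

    region: PixelBox
    mean_rgb: np.ndarray  # (3,) float64

    def __post_init__(self) -> None:
        self.mean_rgb = np.asarray(self.mean_rgb, dtype=np.float64)


@dataclass
class WhiteBalanceTransform:
    """Diagonal von Kries gains: gains[c] = target_white[c] / reference_mean[c].

    ``domain`` records whether the gains act on raw pixel values (default) or
    on gamma-linearized intensities.
    """

    gains: np.ndarray  # (3,) float64, > 0
    target_white: np.ndarray = field(
        default_factory=lambda: np.array([255.0, 255.0, 255.0])
    )
    domain: str = "rgb"  # "rgb" | "linear-rgb"

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=np.float64)
        self.target_white = np.asarray(self.target_white, dtype=np.float64)
        if not np.all(np.isfinite(self.gains)) or np.any(self.gains <= 0):
            raise ConfigurationError("white-balance gains must be finite and > 0")
        if self.domain not in ("rgb", "linear-rgb"):
            raise ConfigurationError(f"unknown gain domain {self.domain!r}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "gains": self.gains.tolist(),
                "target_white": self.target_white.tolist(),
                "domain": self.domain,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "WhiteBalanceTransform":
        d = json.loads(text)
        return cls(np.array(d["gains"]), np.array(d["target_white"]), d.get("domain", "rgb"))


_GAMMA = 2.2


def _linearize(v: np.ndarray) -> np.ndarray:
    return 255.0 * (np.asarray(v, dtype=np.float64) / 255.0) ** _GAMMA


def _delinearize(v: np.ndarray) -> np.ndarray:
    return 255.0 * (np.asarray(v, dtype=np.float64) / 255.0) ** (1.0 / _GAMMA)


def _check_box(box: PixelBox, shape: tuple[int, int]) -> None:
    r0, c0, r1, c1 = box
    h, w = shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ConfigurationError(
            f"region {box} is empty or outside an image of shape {shape}"
        )


def measure_reference(image: RGBImage, region: PixelBox) -> ReferencePatch:
    """Arithmetic per-channel means over a rectangular reference region."""
    _check_box(region, image.shape)
    r0, c0, r1, c1 = region
    mean = image.pixels[r0:r1, c0:c1].reshape(-1, 3).mean(axis=0)
    return ReferencePatch(region=region, mean_rgb=mean)


def fit_von_kries(
    patch: ReferencePatch,
    target_white: tuple[float, float, float] = (255.0, 255.0, 255.0),
    linearize: bool = False,
) -> WhiteBalanceTransform:
    """Gains mapping the observed reference means onto the target white.

    With ``linearize`` the ratio is formed between gamma-decoded (2.2)
    intensities instead of raw pixel values, for workflows that treat the
    stored image as gamma-encoded light.
    """
    mean = patch.mean_rgb
    if np.any(mean <= 0):
        raise DegenerateReferenceError(
            f"reference patch mean {mean} has a non-positive channel; "
            "cannot form von Kries gains"
        )
    target = np.asarray(target_white, dtype=np.float64)
    if linearize:
        return WhiteBalanceTransform(
            gains=_linearize(target) / _linearize(mean),
            target_white=target,
            domain="linear-rgb",
        )
    return WhiteBalanceTransform(gains=target / mean, target_white=target)


def apply_von_kries(image: RGBImage, wb: WhiteBalanceTransform) -> RGBImage:
    """Scale each channel by its gain, clipping to [0, 255].

    Warns (without refusing) if the image is already tagged white-balanced,
    since re-applying a diagonal correction silently compounds the gains.
    """
    if image.tag is ColorTag.WHITE_BALANCED:
        warnings.warn(
            "apply_von_kries called on an already white-balanced image",
            ContractViolationWarning,
            stacklevel=2,
        )
    if wb.domain == "linear-rgb":
        out = _delinearize(np.clip(_linearize(image.pixels) * wb.gains, 0.0, 255.0))
    else:
        out = np.clip(image.pixels * wb.gains, 0.0, 255.0)
    return RGBImage(pixels=out, tag=ColorTag.WHITE_BALANCED)


def clipped_fraction(image: RGBImage, wb: WhiteBalanceTransform) -> float:
    """Fraction of channel values that the correction would clip at 255."""
    return float(np.mean(image.pixels * wb.gains > 255.0))


# Full-range BT.601 RGB -> YCbCr matrix and offset.
_RGB2YCBCR = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_YCBCR_OFFSET = np.array([0.0, 128.0, 128.0])


def rgb_to_ycbcr(image: RGBImage) -> YCbCrImage:
    """Full-range BT.601 conversion, clipped to [0, 255]."""
    ycbcr = image.pixels @ _RGB2YCBCR.T + _YCBCR_OFFSET
    return YCbCrImage(pixels=np.clip(ycbcr, 0.0, 255.0))


def ycbcr_to_rgb(image: YCbCrImage) -> RGBImage:
    """Inverse full-range BT.601 conversion (for round-trip checks)."""
    rgb = (image.pixels - _YCBCR_OFFSET) @ np.linalg.inv(_RGB2YCBCR).T
    return RGBImage(pixels=np.clip(rgb, 0.0, 255.0), tag=ColorTag.SRGB_RAW)


def read_image(path: str | Path) -> RGBImage:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    return RGBImage(pixels=arr, tag=ColorTag.SRGB_RAW)


def write_image(image: RGBImage, path: str | Path) -> None:
    arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)
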