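"""RoI pixel sets and the 1567-dimensional color-feature vector.

Two representations of the masked region feed the downstream models:

* the raw **pixel set** — every YCbCr triplet inside the mask, order-free,
  consumed by the permutation-invariant set regressor;
* a fixed-length **feature vector** — consumed by the tabular tree models.

The feature layout is explicit and versioned.  Per channel (Y, Cb, Cr): a
512-bin normalized histogram over [0, 256) (3 x 512 = 1536), then ten order
and moment statistics per channel (3 x 10 = 30), then log(N), the log pixel
count — 1567 entries in total.  Histograms use half-intensity bins so the
vector remains informative after sub-unit color shifts; the count term lets a
model exploit RoI size if it carries signal.

Moments use population (divide-by-n) formulas, and the skewness/kurtosis of a
zero-variance channel are defined as 0 so the vector is always finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .color import RGBImage, YCbCrImage, PixelBox, rgb_to_ycbcr
from .errors import ConfigurationError, EmptyRoIError

FEATURE_LENGTH = 1567
N_HIST_BINS = 512
LAYOUT_VERSION = "hist512+moments10+logN/1"

_CHANNELS = ("y", "cb", "cr")
_MOMENT_NAMES = (
    "mean",
    "sd",
    "min",
    "max",
    "median",
    "iqr",
    "skewness",
    "kurtosis",
    "p10",
    "p90",
)


@dataclass
class RoIMask:
    """Boolean region-of-interest mask over an image."""

    mask: np.ndarray  # (H, W) bool
    kind: str = "sclera"  # "sclera" | "urine"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ConfigurationError("RoI mask must be a 2-D boolean array")

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class PixelSet:
    """The multiset of YCbCr triplets inside one subject's RoI."""

    triplets: np.ndarray  # (N, 3) float64
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.triplets = np.asarray(self.triplets, dtype=np.float64)
        if self.triplets.ndim != 2 or self.triplets.shape[1] != 3:
            raise ConfigurationError("pixel set must be an (N, 3) array")
        if self.triplets.shape[0] < 1:
            raise EmptyRoIError("pixel set must contain at least one pixel")


@dataclass
class FeatureVector:
    """Fixed-length color-feature summary of one pixel set."""

    values: np.ndarray  # (1567,)
    layout_version: str = LAYOUT_VERSION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (FEATURE_LENGTH,):
            raise ConfigurationError(
                f"feature vector must have length {FEATURE_LENGTH}, "
                f"got {self.values.shape}"
            )


def extract_pixel_set(image: YCbCrImage, mask: RoIMask, subject_id: str = "") -> PixelSet:
    """All YCbCr triplets under the mask; N equals the mask's popcount."""
    if image.pixels.shape[:2] != mask.mask.shape:
        raise ConfigurationError(
            f"mask shape {mask.mask.shape} does not match image {image.pixels.shape[:2]}"
        )
    if mask.count == 0:
        raise EmptyRoIError("mask selects no pixels")
    return PixelSet(triplets=image.pixels[mask.mask], subject_id=subject_id)


def _channel_moments(x: np.ndarray) -> list[float]:
    sd = float(np.std(x))  # population formula
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    q10, q25, q50, q75, q90 = np.percentile(x, [10, 25, 50, 75, 90])
    return [
        float(np.mean(x)),
        sd,
        float(np.min(x)),
        float(np.max(x)),
        float(q50),
        float(q75 - q25),
        skew,
        kurt,
        float(q10),
        float(q90),
    ]


def extract_features(pixels: PixelSet) -> FeatureVector:
    """Histogram + moment summary of a pixel set; permutation invariant."""
    # per-channel sort makes every downstream statistic exactly permutation
    # invariant (summation order is fixed), not just up to rounding
    x = np.sort(pixels.triplets, axis=0)
    n = x.shape[0]
    blocks: list[np.ndarray] = []
    for c in range(3):
        hist, _ = np.histogram(x[:, c], bins=N_HIST_BINS, range=(0.0, 256.0))
        blocks.append(hist.astype(np.float64) / n)
    moments = [m for c in range(3) for m in _channel_moments(x[:, c])]
    blocks.append(np.asarray(moments))
    blocks.append(np.asarray([math.log(n)]))
    return FeatureVector(values=np.concatenate(blocks))


def feature_names() -> list[str]:
    """Column names matching the vector layout, f0000 ... f1566 style labels."""
    names = []
    for ch in _CHANNELS:
        names += [f"hist_{ch}_{b:03d}" for b in range(N_HIST_BINS)]
    for ch in _CHANNELS:
        names += [f"{ch}_{m}" for m in _MOMENT_NAMES]
    names.append("log_n_pixels")
    return names


def segment_fallback(
    image: RGBImage, box: PixelBox, brightness_min: float = 140.0, chroma_max: float = 40.0
) -> RoIMask:
    """Heuristic bright/low-chroma segmentation inside a user box.

    A convenience for user-supplied photographs without masks: selects pixels
    within ``box`` that are bright (luma above ``brightness_min``) and nearly
    achromatic (|Cb-128| and |Cr-128| below ``chroma_max``), which is what an
    exposed sclera looks like.  This is an explicitly approximate stand-in for
    a real annotation, not part of the validated protocol.
    """
    r0, c0, r1, c1 = box
    ycbcr = rgb_to_ycbcr(image).pixels
    sel = (
        (ycbcr[..., 0] >= brightness_min)
        & (np.abs(ycbcr[..., 1] - 128.0) <= chroma_max)
        & (np.abs(ycbcr[..., 2] - 128.0) <= chroma_max)
    )
    window = np.zeros(sel.shape, dtype=bool)
    window[r0:r1, c0:c1] = True
    return RoIMask(mask=sel & window, kind="sclera")
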