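"""Synthetic scleral and urine photographs with a known white reference.

Each rendered frame contains (a) a reference patch whose *true* surface color
is pure white and (b) a region of interest whose true color encodes the
subject's total bilirubin B through a saturating yellowing law on the blue
channel:

    blue = base_blue * (1 - g * B / (B + K))

with yellowing gain ``g`` and half-saturation constant ``K`` (mg/dL).  The
Michaelis-type form mirrors the clinical observation that scleral yellowing
saturates at high bilirubin while staying invertible at low B.  The whole
frame is then multiplied channel-wise by one random illuminant gain triplet
(the per-photo lighting cast the white-balance stage must undo), degraded by
i.i.d. Gaussian pixel noise, and clipped to [0, 255].

The urine renderer applies the same law but multiplies the attenuation by a
per-subject log-normal confounder — urine color responds to hydration, diet
and pigments other than bilirubin — so the urine pathway carries a noisier
version of the same signal.  Its white reference is the background itself.

Rendering is a pure function of (record, scene config): the per-subject
random stream is derived from the scene seed and a stable hash of the
subject id.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .cohort import SubjectRecord
from .color import ColorTag, PixelBox, ReferencePatch, RGBImage, measure_reference
from .errors import ConfigurationError
from .features import RoIMask


@dataclass
class SceneConfig:
    """Geometry, optics and noise of the synthetic photographs."""

    image_size: tuple[int, int] = (64, 96)  # (H, W) pixels
    sclera_base_rgb: tuple[float, float, float] = (232.0, 226.0, 216.0)
    urine_base_rgb: tuple[float, float, float] = (248.0, 244.0, 224.0)
    background_rgb: tuple[float, float, float] = (178.0, 144.0, 120.0)  # skin tone
    yellowing_gain: float = 0.65  # fraction of blue removed at full saturation
    yellowing_halfsat: float = 5.0  # K, mg/dL
    illuminant_low: float = 0.7  # per-channel uniform gain range; defaults
    illuminant_high: float = 1.2  # avoid systematic clipping at the patch
    pixel_noise_sd: float = 4.0  # 8-bit intensity units
    urine_confound_sd: float = 0.5  # log-scale sd of the urine confounder
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ConfigurationError("image must be at least 8x8 to fit patch and RoI")
        if self.illuminant_low <= 0 or self.illuminant_high < self.illuminant_low:
            raise ConfigurationError("illuminant gains must be positive, low <= high")
        if self.pixel_noise_sd < 0 or self.urine_confound_sd < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        for rgb in (self.sclera_base_rgb, self.urine_base_rgb, self.background_rgb):
            if min(rgb) < 0 or max(rgb) > 255:
                raise ConfigurationError("base colors must lie in [0, 255]")
        if not (0 <= self.yellowing_gain <= 1) or self.yellowing_halfsat <= 0:
            raise ConfigurationError("yellowing gain in [0,1], half-saturation > 0")


def _subject_rng(scene: SceneConfig, record: SubjectRecord, stage: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{stage}:{record.subject_id}".encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence((scene.seed, sub)))


def patch_box(scene: SceneConfig) -> PixelBox:
    """White reference patch: the left half of the frame."""
    h, w = scene.image_size
    return (0, 0, h, w // 2)


def _ellipse_mask(scene: SceneConfig) -> np.ndarray:
    h, w = scene.image_size
    cy, cx = h / 2.0, 3.0 * w / 4.0
    ry, rx = h * 0.30, w * 0.18
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def blue_attenuation(total_bilirubin: float, scene: SceneConfig) -> float:
    """Fraction of the blue channel removed at bilirubin B (saturating law)."""
    b = total_bilirubin
    return scene.yellowing_gain * b / (b + scene.yellowing_halfsat)


def _finish(
    true_image: np.ndarray,
    rng: np.random.Generator,
    scene: SceneConfig,
) -> np.ndarray:
    gains = rng.uniform(scene.illuminant_low, scene.illuminant_high, size=3)
    out = true_image * gains
    if scene.pixel_noise_sd > 0:
        out = out + rng.normal(0.0, scene.pixel_noise_sd, size=out.shape)
    return np.clip(out, 0.0, 255.0)


def render_sclera_image(
    record: SubjectRecord, scene: SceneConfig
) -> tuple[RGBImage, RoIMask, ReferencePatch]:
    """One subject's eye-region photograph with the A4-style white patch."""
    scene.validate()
    h, w = scene.image_size
    box = patch_box(scene)
    roi = _ellipse_mask(scene)
    if roi[:, : w // 2].any():
        raise ConfigurationError("sclera RoI overlaps the reference patch")

    true = np.empty((h, w, 3), dtype=np.float64)
    true[:] = scene.background_rgb
    r0, c0, r1, c1 = box
    true[r0:r1, c0:c1] = 255.0
    color = np.array(scene.sclera_base_rgb, dtype=np.float64)
    color[2] *= 1.0 - blue_attenuation(record.total_bilirubin, scene)
    true[roi] = color

    rng = _subject_rng(scene, record, "sclera")
    image = RGBImage(pixels=_finish(true, rng, scene), tag=ColorTag.SRGB_RAW)
    patch = measure_reference(image, box)
    return image, RoIMask(mask=roi, kind="sclera"), patch


def render_urine_image(
    record: SubjectRecord, scene: SceneConfig
) -> tuple[RGBImage, RoIMask, ReferencePatch]:
    """One subject's urine container against a white reference background."""
    scene.validate()
    h, w = scene.image_size
    box = patch_box(scene)  # left half of the white background
    roi = _ellipse_mask(scene)

    rng = _subject_rng(scene, record, "urine")
    confound = (
        float(np.exp(rng.normal(0.0, scene.urine_confound_sd)))
        if scene.urine_confound_sd > 0
        else 1.0
    )
    attn = min(1.0, blue_attenuation(record.total_bilirubin, scene) * confound)

    true = np.full((h, w, 3), 255.0, dtype=np.float64)  # white background
    color = np.array(scene.urine_base_rgb, dtype=np.float64)
    color[2] *= 1.0 - attn
    true[roi] = color

    image = RGBImage(pixels=_finish(true, rng, scene), tag=ColorTag.SRGB_RAW)
    patch = measure_reference(image, box)
    return image, RoIMask(mask=roi, kind="urine"), patch


def write_mask(mask: RoIMask, path: str | Path) -> None:
    Image.fromarray(np.where(mask.mask, 255, 0).astype(np.uint8), mode="L").save(path)


def read_mask(path: str | Path, kind: str = "sclera") -> RoIMask:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return RoIMask(mask=arr > 127, kind=kind)


def write_geometry(box: PixelBox, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"reference_box": list(box)}))


def read_geometry(path: str | Path) -> PixelBox:
    box = json.loads(Path(path).read_text())["reference_box"]
    return (int(box[0]), int(box[1]), int(box[2]), int(box[3]))
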