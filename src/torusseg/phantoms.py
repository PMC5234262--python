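"""Synthetic wound phantoms with exact ground truth.

A phantom emulates a stage-IV pressure-ulcer photograph at the level of
detail the segmentation method responds to: a dark reddish elliptical
lesion on a lighter skin-tone background with a mild horizontal
illumination gradient, an optionally Gaussian-blurred lesion boundary
(blurred edges indicate growing tissue in real wounds), additive Gaussian
channel noise, and optional distractor disks standing in for dressing
material or markers.  The ground-truth mask is the *unblurred* ellipse
raster, fixed before any degradation, so every stage of the pipeline can be
scored exactly.  All randomness is driven by the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .errors import InvalidSpecError

DEFAULT_LESION_COLOR = (120, 30, 25)   # dark reddish ulcer tissue
DEFAULT_SKIN_COLOR = (210, 170, 150)   # light skin tone


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; every field is reproducible state."""

    height: int = 256
    width: int = 256
    lesion_center: tuple[float, float] = (128.0, 128.0)  # (row, col)
    lesion_axes: tuple[float, float] = (40.0, 25.0)      # semi-axes (a, b), px
    lesion_angle: float = 0.0                            # radians
    lesion_color: tuple[int, int, int] = DEFAULT_LESION_COLOR
    skin_color: tuple[int, int, int] = DEFAULT_SKIN_COLOR
    edge_blur_sigma: float = 0.0                         # px; 0 = sharp edge
    noise_sigma: float = 0.0                             # gray levels
    distractors: tuple = ()   # ((row, col), radius, (r, g, b)) entries
    seed: int = 0


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray   # (N, M, 3) uint8
    truth: np.ndarray   # (N, M) bool, the unblurred ellipse raster
    spec: PhantomSpec


def _ellipse_mask(spec: PhantomSpec) -> np.ndarray:
    rows, cols = np.mgrid[0:spec.height, 0:spec.width].astype(np.float64)
    r0, c0 = spec.lesion_center
    a, b = spec.lesion_axes
    ca, sa = math.cos(spec.lesion_angle), math.sin(spec.lesion_angle)
    # rotate into the ellipse frame (x along semi-axis a)
    x = (cols - c0) * ca + (rows - r0) * sa
    y = -(cols - c0) * sa + (rows - r0) * ca
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def _check_inside_frame(spec: PhantomSpec) -> None:
    a, b = spec.lesion_axes
    if a <= 0 or b <= 0:
        raise InvalidSpecError(f"lesion semi-axes must be positive, got {a}, {b}")
    ca, sa = math.cos(spec.lesion_angle), math.sin(spec.lesion_angle)
    half_w = math.sqrt((a * ca) ** 2 + (b * sa) ** 2)   # horizontal extent
    half_h = math.sqrt((a * sa) ** 2 + (b * ca) ** 2)   # vertical extent
    r0, c0 = spec.lesion_center
    if (r0 - half_h < 0 or r0 + half_h > spec.height - 1
            or c0 - half_w < 0 or c0 + half_w > spec.width - 1):
        raise InvalidSpecError(
            f"lesion ellipse extends outside the {spec.height}x{spec.width} frame"
        )


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom image and its exact ground-truth mask.

    Construction order: skin background with ±10% horizontal illumination
    gradient → distractor disks → lesion alpha-composited on top (alpha is
    the ellipse indicator, Gaussian-blurred by ``edge_blur_sigma``) →
    i.i.d. Gaussian channel noise, clipped to [0, 255].  The truth mask is
    the sharp ellipse, independent of blur and noise.
    """
    for color in (spec.lesion_color, spec.skin_color):
        if not all(0 <= c <= 255 for c in color):
            raise InvalidSpecError(f"color {color} outside [0, 255]")
    _check_inside_frame(spec)
    truth = _ellipse_mask(spec)

    gradient = np.linspace(0.9, 1.1, spec.width)[np.newaxis, :, np.newaxis]
    img = np.asarray(spec.skin_color, dtype=np.float64) * np.ones(
        (spec.height, spec.width, 1)
    ) * gradient

    for (r0, c0), radius, color in spec.distractors:
        rows, cols = np.mgrid[0:spec.height, 0:spec.width].astype(np.float64)
        disk = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius ** 2
        img[disk] = np.asarray(color, dtype=np.float64)

    alpha = truth.astype(np.float64)
    if spec.edge_blur_sigma > 0:
        alpha = ndi.gaussian_filter(alpha, spec.edge_blur_sigma)
    lesion = np.asarray(spec.lesion_color, dtype=np.float64)
    img = img * (1.0 - alpha[..., np.newaxis]) + lesion * alpha[..., np.newaxis]

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return PhantomSample(image=image, truth=truth, spec=spec)


#: distractor palette: gauze white and a marker blue, both lighter than the
#: lesion so the darkest-component rule stays decidable.
_DISTRACTOR_COLORS = ((235, 228, 215), (90, 130, 190))

#: blur radii cycled through the suite (px); spans sharp to heavily blurred.
_SUITE_BLURS = (0.0, 2.0, 4.0, 8.0)


def phantom_suite(n: int, seed: int = 0) -> list[PhantomSample]:
    """A deterministic suite of ``n`` phantoms spanning the documented ranges.

    Semi-axes 15-60 px, arbitrary orientation, blur cycling 0-8 px, noise
    uniform in 0-10 gray levels, 0-2 bright distractor disks placed clear of
    the lesion; everything derived from ``seed``.
    """
    if n < 1:
        raise InvalidSpecError(f"suite size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    samples = []
    for k in range(n):
        h = w = 256
        a = rng.uniform(25, 60)
        b = rng.uniform(15, a)
        angle = rng.uniform(0, math.pi)
        margin = math.hypot(a, b) + 4
        r0 = rng.uniform(margin, h - 1 - margin)
        c0 = rng.uniform(margin, w - 1 - margin)
        blur = _SUITE_BLURS[k % len(_SUITE_BLURS)]
        noise = rng.uniform(0, 10)
        n_distract = int(rng.integers(0, 3))
        distractors = []
        for _ in range(n_distract):
            radius = rng.uniform(8, 20)
            for _attempt in range(50):
                dr = rng.uniform(radius, h - 1 - radius)
                dc = rng.uniform(radius, w - 1 - radius)
                if math.hypot(dr - r0, dc - c0) > margin + radius + 10:
                    color = _DISTRACTOR_COLORS[
                        int(rng.integers(0, len(_DISTRACTOR_COLORS)))
                    ]
                    distractors.append(((dr, dc), radius, color))
                    break
        spec = PhantomSpec(
            height=h, width=w,
            lesion_center=(r0, c0), lesion_axes=(a, b), lesion_angle=angle,
            edge_blur_sigma=blur, noise_sigma=noise,
            distractors=tuple(distractors),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        samples.append(generate_phantom(spec))
    return samples
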