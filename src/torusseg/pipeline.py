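"""End-to-end segmentation pipeline.

The full method: grayscale conversion → optional downscaling → sweep of the
frequency parameter r over [r_min, r_max] → per level, toroidal operators,
Otsu binarization and inner-boundary contour extraction → accumulation of
all per-level contours into an edge map → morphological refinement (closing,
hole filling, small-component removal) → selection of the final wound
component as the darkest surviving region.

Everything up to contour fusion is elementwise per pixel, so per-level
results are independent of processing order; the pipeline is a pure
function of the image bytes and the configuration.
"""

from __future__ import annotations

import json
import logging
import pathlib
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import scipy.ndimage as ndi
import yaml
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk

from .errors import (
    AllLevelsDegenerateError,
    DegenerateLevelError,
    InvalidImageError,
    InvalidParameterError,
    SaturationWarning,
)
from .frequency import frequency_sweep
from .io_color import downscale_max_side, rgb_to_gray
from .thresholding import LevelBinarization, binarize_level  # noqa: F401
from .toroidal import TorusConfig, make_grids, toroidal_operators

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Segmentation parameters.

    Defaults reproduce the standard protocol: 30 contrast levels with the
    frequency parameter swept over [0.013, 0.015] and torus major radius
    R = 100 px.  ``min_component_area=None`` means 0.5% of the image area.
    ``component_selection`` is ``"darkest"`` (the wound is the darkest
    region) or ``"largest"``.

    Robustness controls: ``level_consensus_ratio`` drops levels whose low
    class Ω₁ has an area outside [median/ratio, median·ratio] of the sweep
    (Otsu occasionally lands outside the lesion/background gap on noisy
    images; such levels flood the edge map — None fuses every level);
    ``min_edge_support_frac`` is the fraction of fused levels whose contour
    must pass through a pixel for it to count as edge support (0 keeps any
    single-level contour); ``min_contour_component`` discards smaller
    connected support fragments (noise speckle rings) before closing.
    """

    r_min: float = 0.013
    r_max: float = 0.015
    levels: int = 30
    R: float = 100.0
    amplitude_offset: float = 1.0
    threshold_target: str = "ta"
    bins: int = 256
    level_consensus_ratio: float | None = 3.0
    min_edge_support_frac: float = 0.1
    min_contour_component: int = 32
    morph_radius: int = 5
    min_component_area: float | None = None
    component_selection: str = "darkest"
    max_side: int = 1024
    saturation_std_floor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.r_min <= self.r_max):
            raise InvalidParameterError(
                f"need 0 < r_min <= r_max, got {self.r_min}, {self.r_max}"
            )
        if self.levels < 1:
            raise InvalidParameterError(f"levels must be >= 1, got {self.levels}")
        if self.morph_radius < 1:
            raise InvalidParameterError(
                f"morph_radius must be >= 1, got {self.morph_radius}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class EdgeMap:
    """Per-pixel count of contrast levels whose partition boundary passes
    through the pixel, plus the number of non-degenerate levels fused."""

    counts: np.ndarray
    levels_used: int


@dataclass(frozen=True)
class LevelSummary:
    r: float
    t: int
    t_value: float
    omega1_area: int
    fused: bool = True


@dataclass(frozen=True)
class SegmentationResult:
    """Final mask with per-level diagnostics and the provenance config."""

    mask: np.ndarray
    edge_map: EdgeMap
    per_level: list[LevelSummary]
    provenance: PipelineConfig
    empty: bool
    skipped_levels: list[tuple[float, str]] = field(default_factory=list)

    def diagnostics_record(self) -> dict:
        """JSON-serializable run record: r grid, thresholds, skips."""
        return {
            "levels_used": self.edge_map.levels_used,
            "empty": self.empty,
            "per_level": [
                {"r": s.r, "t": s.t, "t_value": s.t_value,
                 "omega1_area": s.omega1_area, "fused": s.fused}
                for s in self.per_level
            ],
            "skipped": [{"r": r, "reason": why} for r, why in self.skipped_levels],
            "config": asdict(self.provenance),
        }


def extract_contours(binarization: LevelBinarization) -> np.ndarray:
    """Inner boundary of Ω₁: its pixels with at least one 4-neighbour in Ω₂.

    Pixels outside the frame count as Ω₂, so an Ω₁ region touching the
    border contributes its border pixels to the contour.
    """
    return inner_boundary(binarization.omega1)


def inner_boundary(mask: np.ndarray) -> np.ndarray:
    """Pixels of ``mask`` 4-adjacent to background (outside treated as background)."""
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, constant_values=False)
    has_bg_neighbour = (
        ~padded[:-2, 1:-1] | ~padded[2:, 1:-1]
        | ~padded[1:-1, :-2] | ~padded[1:-1, 2:]
    )
    return m & has_bg_neighbour


def fuse_levels(contours: list[np.ndarray]) -> EdgeMap:
    """Sum per-level contour indicators into an edge-support count map."""
    if not contours:
        raise InvalidImageError("cannot fuse an empty contour list")
    shapes = {c.shape for c in contours}
    if len(shapes) > 1:
        raise InvalidImageError(f"contour shape mismatch: {sorted(shapes)}")
    counts = np.zeros(contours[0].shape, dtype=np.int64)
    for c in contours:
        counts += c.astype(np.int64)
    return EdgeMap(counts=counts, levels_used=len(contours))


def morphological_refine(
    edges: EdgeMap, gray: np.ndarray, cfg: PipelineConfig
) -> np.ndarray:
    """Turn the fused edge map into the final wound mask.

    Edge support keeps pixels crossed by at least ``min_edge_support_frac``
    of the fused levels' contours, then tiny support fragments (noise
    speckle rings) are discarded.  Closing with a disk bridges the
    remaining contour fragments into a closed curve, hole filling recovers
    its interior, components below the area floor are discarded, and the
    surviving component with the lowest mean amplitude (the wound is the
    darkest region) is returned.  An empty mask is a legal outcome.
    """
    floor = max(1, int(np.ceil(cfg.min_edge_support_frac * edges.levels_used)))
    support = edges.counts >= floor
    support = _drop_small_components(support, cfg.min_contour_component)
    shape = support.shape
    if not support.any():
        return np.zeros(shape, dtype=bool)
    closed = closing(support, footprint=disk(cfg.morph_radius))
    filled = ndi.binary_fill_holes(closed)
    min_area = cfg.min_component_area
    if min_area is None:
        min_area = 0.005 * filled.size
    labels = label(filled, connectivity=2)
    best_label, best_score = 0, None
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        if cfg.component_selection == "largest":
            score = -region.area
        else:  # darkest: lowest mean grayscale amplitude
            score = float(gray[labels == region.label].mean())
        if best_score is None or score < best_score:
            best_label, best_score = region.label, score
    if best_label == 0:
        return np.zeros(shape, dtype=bool)
    return labels == best_label


def _drop_small_components(mask: np.ndarray, min_size: int) -> np.ndarray:
    if min_size <= 1 or not mask.any():
        return mask
    lbl = label(mask, connectivity=2)
    sizes = np.bincount(lbl.ravel())
    sizes[0] = 0
    return sizes[lbl] >= min_size


def segment(
    img: np.ndarray,
    cfg: PipelineConfig | None = None,
    diagnostics_dir=None,
) -> SegmentationResult:
    """Segment a wound photograph.

    Deterministic composition of every pipeline stage; degenerate contrast
    levels are skipped with a log record.  When ``diagnostics_dir`` is set,
    per-level T̄_a / T̄_p / contour PNGs and a JSON run record are written
    there.

    Raises
    ------
    AllLevelsDegenerateError
        If the image has no amplitude contrast at all, or every level of the
        sweep was degenerate.
    """
    cfg = cfg or PipelineConfig()
    diag = pathlib.Path(diagnostics_dir) if diagnostics_dir is not None else None
    if diag is not None:
        diag.mkdir(parents=True, exist_ok=True)
    gray = rgb_to_gray(img)
    gray = downscale_max_side(gray, cfg.max_side)
    if np.ptp(gray) == 0:
        # A constant amplitude image yields a constant frequency field: the
        # decomposition would respond to the coordinate grids only, never to
        # the image, so every level is degenerate by definition.
        raise AllLevelsDegenerateError(
            f"image has zero amplitude contrast; no level can segment it "
            f"(config: {cfg})"
        )
    if gray.std() < cfg.saturation_std_floor:
        warnings.warn(
            "grayscale image is nearly constant (possible channel saturation); "
            "thresholds will be unreliable",
            SaturationWarning,
            stacklevel=2,
        )
    grids = make_grids(*gray.shape)
    torus = TorusConfig(R=cfg.R)
    fields = frequency_sweep(
        gray, cfg.r_min, cfg.r_max, cfg.levels, amplitude_offset=cfg.amplitude_offset
    )
    binarizations: list[LevelBinarization] = []
    skipped: list[tuple[float, str]] = []
    for fld in fields:
        try:
            level = toroidal_operators(
                gray, grids, fld, torus, amplitude_offset=cfg.amplitude_offset
            )
            binz = binarize_level(
                level, bins=cfg.bins, threshold_target=cfg.threshold_target
            )
        except DegenerateLevelError as exc:
            log.warning("skipping degenerate level r=%g: %s", fld.r, exc)
            skipped.append((fld.r, str(exc)))
            continue
        binarizations.append(binz)
        if diag is not None:
            _write_level_pngs(diag, len(binarizations) - 1, level,
                              extract_contours(binz))
        log.info(
            "level r=%g: t=%d, |omega1|=%d", fld.r, binz.threshold.t,
            int(binz.omega1.sum()),
        )
    if not binarizations:
        raise AllLevelsDegenerateError(
            f"all {cfg.levels} levels were degenerate (config: {cfg})"
        )
    fused_flags = _consensus_flags(binarizations, cfg.level_consensus_ratio)
    per_level = [
        LevelSummary(
            r=b.r,
            t=b.threshold.t,
            t_value=b.threshold.t_value,
            omega1_area=int(b.omega1.sum()),
            fused=bool(flag),
        )
        for b, flag in zip(binarizations, fused_flags)
    ]
    for s in per_level:
        if not s.fused:
            log.info("level r=%g excluded from fusion by area consensus", s.r)
    contours = [
        extract_contours(b)
        for b, flag in zip(binarizations, fused_flags)
        if flag
    ]
    edge_map = fuse_levels(contours)
    mask = morphological_refine(edge_map, gray, cfg)
    result = SegmentationResult(
        mask=mask,
        edge_map=edge_map,
        per_level=per_level,
        provenance=cfg,
        empty=not bool(mask.any()),
        skipped_levels=skipped,
    )
    if diag is not None:
        write_diagnostics(result, diag)
    return result


def _consensus_flags(
    binarizations: list[LevelBinarization], ratio: float | None
) -> list[bool]:
    """Flag the levels kept for fusion by area consensus across the sweep.

    A level whose Ω₁ area lies outside [median/ratio, median·ratio] of the
    sweep's median area is an Otsu failure (its threshold missed the
    lesion/background gap) and is excluded.  If the rule would exclude
    everything, every level is kept.
    """
    if ratio is None or len(binarizations) < 3:
        return [True] * len(binarizations)
    areas = np.array([b.omega1.sum() for b in binarizations], dtype=np.float64)
    med = float(np.median(areas))
    if med == 0:
        return [True] * len(binarizations)
    flags = [bool(med / ratio <= max(a, 1.0) <= med * ratio) for a in areas]
    if not any(flags):
        return [True] * len(binarizations)
    return flags


def _write_level_pngs(directory, index: int, level, contour: np.ndarray) -> None:
    import imageio.v3 as iio

    for name, arr in (
        ("ta", level.t_a_norm),
        ("tp", level.t_p_norm),
        ("contour", contour.astype(np.float64)),
    ):
        png = np.rint(np.clip(arr, 0, 1) * 255).astype(np.uint8)
        iio.imwrite(directory / f"level_{index:02d}_{name}.png", png,
                    extension=".png")


def write_diagnostics(result: SegmentationResult, directory) -> None:
    """Write the JSON run record to ``directory/run_record.json``."""
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "run_record.json", "w") as fh:
        json.dump(result.diagnostics_record(), fh, indent=2)
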