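"""Segmentation accuracy by digital image correlation.

The accuracy measure is the Pearson product-moment correlation over all
pixels of two equal-shape images,

    ρ(A, B) = Σ (A - Ā)(B - B̄) / sqrt(Σ (A - Ā)² · Σ (B - B̄)²),

computed here between the predicted binary mask and the ground-truth mask.
ρ is undefined for a constant input (zero variance); batch summaries count
such failures separately and exclude them from the moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .errors import InvalidImageError, UndefinedCorrelationError
from .pipeline import SegmentationResult


def image_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation over all pixels of two equal-shape images.

    Raises
    ------
    InvalidImageError
        On shape mismatch.
    UndefinedCorrelationError
        If either input is constant.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidImageError(f"shape mismatch: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    ssa = float((da * da).sum())
    ssb = float((db * db).sum())
    if ssa == 0 or ssb == 0:
        raise UndefinedCorrelationError(
            "correlation is undefined for a constant image"
        )
    return float((da * db).sum() / np.sqrt(ssa * ssb))


@dataclass(frozen=True)
class BatchSummary:
    """Sample statistics of per-image correlations.

    ``ddof`` records the standard-deviation convention used (1 = sample,
    0 = population).  Undefined correlations are counted in ``n_failed``
    and excluded from the moments.
    """

    mean: float
    std: float
    min: float
    max: float
    n: int
    n_failed: int
    per_image: list[float] = field(default_factory=list)
    ddof: int = 1


def evaluate_batch(results, ddof: int = 1) -> BatchSummary:
    """Score a batch of (prediction, ground truth) pairs.

    ``results`` is an iterable of ``(pred, truth)`` where ``pred`` is a
    binary mask or a :class:`SegmentationResult` and ``truth`` a binary
    mask.  Ground truth at a different resolution is resized with
    nearest-neighbour interpolation to the prediction's shape.
    """
    rhos: list[float] = []
    n_failed = 0
    pairs = list(results)
    if not pairs:
        raise InvalidImageError("cannot evaluate an empty batch")
    for pred, truth in pairs:
        if isinstance(pred, SegmentationResult):
            pred = pred.mask
        pred = np.asarray(pred)
        truth = np.asarray(truth)
        if truth.shape != pred.shape:
            truth = resize(
                truth.astype(np.float64), pred.shape, order=0,
                preserve_range=True, anti_aliasing=False,
            ) > 0.5
        try:
            rhos.append(image_correlation(pred.astype(np.float64),
                                          truth.astype(np.float64)))
        except UndefinedCorrelationError:
            n_failed += 1
    if not rhos:
        raise UndefinedCorrelationError(
            "every pair in the batch had an undefined correlation"
        )
    arr = np.asarray(rhos)
    std = float(arr.std(ddof=ddof)) if arr.size > ddof else 0.0
    return BatchSummary(
        mean=float(arr.mean()),
        std=std,
        min=float(arr.min()),
        max=float(arr.max()),
        n=len(rhos),
        n_failed=n_failed,
        per_image=rhos,
        ddof=ddof,
    )
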