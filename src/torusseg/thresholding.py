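"""Otsu threshold optimizer and per-level binarization.

Each contrast level is reduced to a binary partition Ω₁/Ω₂ by Otsu's
method: the histogram of the normalized product operator T̄_p is split at
the threshold t maximizing the between-class variance

    J(t) = ω₀ (μ₀ - μ_T)² + ω₁ (μ₁ - μ_T)²,

where ω₀, ω₁ are the class probabilities of bins {0..t-1} and {t..L-1},
μ₀, μ₁ their mean bin levels and μ_T the global mean.  The identities
ω₀ + ω₁ = 1 and ω₀μ₀ + ω₁μ₁ = μ_T hold for every returned result.

The optimized threshold is then applied to the additive operator T̄_a
(configurable to T̄_p): Ω₁ collects the pixels in bins below t, i.e. the
low-valued class, which for wound photographs is the dark lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateHistogramError,
    DegenerateLevelError,
    InvalidImageError,
    InvalidParameterError,
)
from .toroidal import DecompositionLevel

DEFAULT_BINS = 256


@dataclass(frozen=True)
class GrayHistogram:
    """Bin probabilities of a [0, 1]-valued field on L equal-width bins."""

    probs: np.ndarray
    L: int


@dataclass(frozen=True)
class ThresholdResult:
    """Otsu optimum and the class statistics behind it.

    ``t`` is the threshold bin index in [1, L-1]; bins {0..t-1} form class 0
    and {t..L-1} class 1.  ``t_value = t / L`` is the corresponding boundary
    on the [0, 1] value scale.  Means and the objective are on the bin-index
    scale.
    """

    t: int
    t_value: float
    J: float
    class_means: tuple[float, float]
    class_weights: tuple[float, float]
    global_mean: float


@dataclass(frozen=True)
class LevelBinarization:
    """Binary partition of one contrast level: ``omega1`` is the low class
    (values in bins below the threshold), ``omega2`` its complement."""

    omega1: np.ndarray
    omega2: np.ndarray
    threshold: ThresholdResult
    r: float


def histogram(values: np.ndarray, bins: int = DEFAULT_BINS) -> GrayHistogram:
    """Probability histogram of a [0, 1]-valued array on equal-width bins.

    The last bin is right-closed so the value 1.0 is counted.
    """
    values = np.asarray(values, dtype=np.float64)
    if bins < 2:
        raise InvalidParameterError(f"need at least 2 bins, got {bins}")
    if values.size == 0:
        raise InvalidImageError("cannot histogram an empty array")
    if values.min() < 0 or values.max() > 1:
        raise InvalidImageError("histogram input must lie within [0, 1]")
    counts, _ = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return GrayHistogram(probs=counts / values.size, L=bins)


def bin_index(values: np.ndarray, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Map [0, 1] values to their histogram bin index (value 1.0 → last bin)."""
    idx = np.floor(np.asarray(values, dtype=np.float64) * bins).astype(np.int64)
    return np.clip(idx, 0, bins - 1)


def otsu(hist: GrayHistogram) -> ThresholdResult:
    """Threshold maximizing the between-class variance J(t).

    Candidates are t ∈ {1, …, L-1} with both classes nonempty; ties are
    broken at the smallest maximizing t.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two bins are occupied (constant field).
    """
    p = np.asarray(hist.probs, dtype=np.float64)
    L = hist.L
    if np.count_nonzero(p > 0) < 2:
        raise DegenerateHistogramError(
            "histogram has a single occupied bin; no threshold separates classes"
        )
    i = np.arange(L, dtype=np.float64)
    mu_t = float(np.sum(p * i))
    # w0[k] and first-moment m0[k] accumulate bins {0..k}; threshold t = k+1.
    w0 = np.cumsum(p)[:-1]
    m0 = np.cumsum(p * i)[:-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(valid, m0 / w0, 0.0)
        mu1 = np.where(valid, (mu_t - m0) / w1, 0.0)
    J = w0 * (mu0 - mu_t) ** 2 + w1 * (mu1 - mu_t) ** 2
    J[~valid] = -np.inf
    k = int(np.argmax(J))  # first maximum → smallest t
    t = k + 1
    return ThresholdResult(
        t=t,
        t_value=t / L,
        J=float(J[k]),
        class_means=(float(mu0[k]), float(mu1[k])),
        class_weights=(float(w0[k]), float(w1[k])),
        global_mean=mu_t,
    )


def binarize_level(
    level: DecompositionLevel,
    bins: int = DEFAULT_BINS,
    threshold_target: str = "ta",
) -> LevelBinarization:
    """Otsu-binarize one contrast level.

    The threshold is always optimized on the histogram of the product
    operator T̄_p; ``threshold_target`` selects which operator it is applied
    to — ``"ta"`` (default) thresholds the additive operator T̄_a, ``"tp"``
    thresholds T̄_p itself.

    Raises
    ------
    DegenerateLevelError
        If the T̄_p histogram is degenerate (constant operator).
    """
    if threshold_target not in ("ta", "tp"):
        raise InvalidParameterError(
            f"threshold_target must be 'ta' or 'tp', got {threshold_target!r}"
        )
    try:
        thr = otsu(histogram(level.t_p_norm, bins))
    except DegenerateHistogramError as exc:
        raise DegenerateLevelError(
            f"degenerate T_p histogram at r={level.r}: {exc}"
        ) from exc
    target = level.t_a_norm if threshold_target == "ta" else level.t_p_norm
    omega1 = bin_index(target, bins) < thr.t
    return LevelBinarization(
        omega1=omega1, omega2=~omega1, threshold=thr, r=level.r
    )
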