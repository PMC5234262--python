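"""Toroidal contrast decomposition.

A torus of major radius R, parametrized by two angles, has planar
components that are independent periodic functions of its two parameters.
Re-reading those components as per-pixel image transforms, with the angle
arguments driven by each pixel's synthetic frequency ``f`` and its
normalized grid coordinate, gives the horizontal and vertical
decompositions

    THD(u; f) = [R + cos(2π f u)] · cos(2π · arctan f)
    TVD(v; f) = [R + cos(2π f v)] · sin(2π · arctan f)

where ``u`` (resp. ``v``) is a symmetric linear ramp in [-1, 1] along the
horizontal (resp. vertical) axis, constant along the other.  The two
decompositions combine with the shifted amplitude image Ã through
elementwise (Hadamard) products into an additive and a product operator

    T_a = Ã ∘ (TVD + THD),      T_p = Ã² ∘ (TVD ∘ THD),

each stored after normalization T̄ = |T| / max|T| so values lie in [0, 1]
with maximum exactly 1.  All operations are purely local: no pixel's output
depends on its neighbourhood.

The carrier factors cos/sin(2π·arctan f) are the mechanism of contrast
amplification: over the working frequency band the cosine carrier crosses
zero, so small amplitude differences map to large relative differences in
the operators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateLevelError, InvalidImageError, InvalidParameterError
from .frequency import DEFAULT_AMPLITUDE_OFFSET, FrequencyField


@dataclass(frozen=True)
class TorusConfig:
    """Torus geometry: major radius R in pixels (the minor radius does not
    enter the planar decomposition; its cosine coefficient is unity)."""

    R: float = 100.0

    def __post_init__(self):
        if not self.R > 0:
            raise InvalidParameterError(f"torus major radius must be > 0, got {self.R}")


@dataclass(frozen=True)
class CoordinateGrids:
    """Normalized pixel-coordinate grids.

    ``u`` varies along columns (horizontal axis), constant down each column;
    ``v`` is the transpose pattern.  Both are symmetric about 0 within
    [-1, 1].
    """

    u: np.ndarray
    v: np.ndarray


@dataclass(frozen=True)
class DecompositionLevel:
    """One contrast level of the toroidal decomposition.

    ``thd``/``tvd`` are the raw decompositions; ``t_a_norm``/``t_p_norm``
    the normalized additive and product operators in [0, 1]; ``r`` the
    generating frequency parameter.
    """

    thd: np.ndarray
    tvd: np.ndarray
    t_a_norm: np.ndarray
    t_p_norm: np.ndarray
    r: float


def make_grids(height: int, width: int) -> CoordinateGrids:
    """Build the symmetric coordinate ramps for an image of the given size.

    Each row of ``u`` is the ``width``-point ramp spanning
    ``[-(width-1)/width, +(width-1)/width]``; each column of ``v`` the
    analogous ``height``-point ramp.  A single-pixel axis degenerates to {0}.
    """
    if height < 1 or width < 1:
        raise InvalidParameterError(
            f"image dimensions must be >= 1, got {height}x{width}"
        )
    u_row = _symmetric_ramp(width)
    v_col = _symmetric_ramp(height)
    u = np.broadcast_to(u_row[np.newaxis, :], (height, width)).copy()
    v = np.broadcast_to(v_col[:, np.newaxis], (height, width)).copy()
    return CoordinateGrids(u=u, v=v)


def _symmetric_ramp(n: int) -> np.ndarray:
    if n == 1:
        return np.zeros(1)
    end = (n - 1) / n
    return np.linspace(-end, end, n)


def thd(grids: CoordinateGrids, freq: FrequencyField, cfg: TorusConfig) -> np.ndarray:
    """Toroidal horizontal decomposition, elementwise over the image."""
    _check_shapes(grids.u, freq.values)
    f = freq.values
    return (cfg.R + np.cos(2 * np.pi * f * grids.u)) * np.cos(2 * np.pi * np.arctan(f))


def tvd(grids: CoordinateGrids, freq: FrequencyField, cfg: TorusConfig) -> np.ndarray:
    """Toroidal vertical decomposition, elementwise over the image."""
    _check_shapes(grids.v, freq.values)
    f = freq.values
    return (cfg.R + np.cos(2 * np.pi * f * grids.v)) * np.sin(2 * np.pi * np.arctan(f))


def _check_shapes(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise InvalidImageError(f"shape mismatch between fields: {sorted(shapes)}")


def toroidal_operators(
    gray: np.ndarray,
    grids: CoordinateGrids,
    freq: FrequencyField,
    cfg: TorusConfig,
    amplitude_offset: float = DEFAULT_AMPLITUDE_OFFSET,
) -> DecompositionLevel:
    """Additive and product toroidal operators for one contrast level.

    Uses the same shifted amplitude Ã = A + amplitude_offset that generated
    the frequency field, so the two stages are mutually consistent.

    Raises
    ------
    DegenerateLevelError
        If either operator is identically zero (no contrast to normalize);
        the sweep skips such levels.
    """
    gray = np.asarray(gray, dtype=np.float64)
    _check_shapes(gray, grids.u, grids.v, freq.values)
    a = gray + amplitude_offset
    h = thd(grids, freq, cfg)
    v = tvd(grids, freq, cfg)
    t_a = a * (v + h)
    t_p = (a ** 2) * (v * h)
    return DecompositionLevel(
        thd=h,
        tvd=v,
        t_a_norm=_normalize(t_a, "T_a", freq.r),
        t_p_norm=_normalize(t_p, "T_p", freq.r),
        r=freq.r,
    )


def _normalize(t: np.ndarray, name: str, r: float) -> np.ndarray:
    mag = np.abs(t)
    peak = mag.max()
    if peak == 0:
        raise DegenerateLevelError(
            f"{name} is identically zero at r={r}; level carries no contrast"
        )
    return mag / peak
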