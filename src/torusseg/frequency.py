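"""Per-pixel synthetic frequency field.

Each pixel of the amplitude image is assigned a dimensionless "synthetic
frequency"

    f(m, n; r) = 1 / Ã(m, n)^r,

where ``Ã = A + amplitude_offset`` maps stored 8-bit amplitudes [0, 255]
onto the working range [1, 256] (the unit offset removes the singularity at
zero amplitude), and ``r > 0`` is the *frequency parameter*.  Frequencies
are inversely related to amplitude: dark pixels oscillate fast, bright
pixels slowly.  Sweeping ``r`` over a narrow interval produces a stack of
distinct contrast levels; for amplitudes ≥ 1 all frequencies lie in (0, 1],
pinned at f = 1 for Ã = 1 regardless of r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

DEFAULT_AMPLITUDE_OFFSET = 1.0


@dataclass(frozen=True)
class FrequencyField:
    """Per-pixel synthetic frequencies for one value of the frequency parameter.

    Attributes
    ----------
    values : ndarray
        ``(N, M)`` array of frequencies, all finite and in (0, 1] when the
        shifted amplitudes are ≥ 1.
    r : float
        The generating frequency parameter.
    """

    values: np.ndarray
    r: float


def synthetic_frequency(
    gray: np.ndarray,
    r: float,
    amplitude_offset: float = DEFAULT_AMPLITUDE_OFFSET,
) -> FrequencyField:
    """Compute ``f = 1 / (A + amplitude_offset)**r`` for every pixel.

    Raises
    ------
    InvalidParameterError
        If ``r <= 0``.
    """
    if not r > 0:
        raise InvalidParameterError(f"frequency parameter r must be > 0, got {r}")
    shifted = np.asarray(gray, dtype=np.float64) + amplitude_offset
    values = shifted ** (-float(r))
    return FrequencyField(values=values, r=float(r))


def r_grid(r_min: float, r_max: float, levels: int) -> np.ndarray:
    """Evenly spaced frequency-parameter grid on [r_min, r_max], inclusive.

    ``levels == 1`` degenerates to the single value ``r_min``.
    """
    if not (0 < r_min <= r_max):
        raise InvalidParameterError(
            f"need 0 < r_min <= r_max, got r_min={r_min}, r_max={r_max}"
        )
    if levels < 1:
        raise InvalidParameterError(f"levels must be >= 1, got {levels}")
    if levels == 1:
        return np.array([r_min], dtype=np.float64)
    return np.linspace(r_min, r_max, levels)


def frequency_sweep(
    gray: np.ndarray,
    r_min: float = 0.013,
    r_max: float = 0.015,
    levels: int = 30,
    amplitude_offset: float = DEFAULT_AMPLITUDE_OFFSET,
    r_values=None,
) -> list[FrequencyField]:
    """Frequency fields for a sweep of the frequency parameter.

    The default sweep (30 levels over [0.013, 0.015]) defines the contrast
    stack used by the segmentation pipeline.  ``r_values`` overrides the
    linear grid with an explicit list.
    """
    grid = np.asarray(r_values, dtype=np.float64) if r_values is not None \
        else r_grid(r_min, r_max, levels)
    if grid.size < 1 or not (grid > 0).all():
        raise InvalidParameterError("explicit r grid must be nonempty and positive")
    return [synthetic_frequency(gray, r, amplitude_offset) for r in grid]
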