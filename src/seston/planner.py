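"""Minimum training-set size for a direct continuous-output model.

A classification-then-regression pipeline can be compared to a
hypothetical network that regresses turbidity directly only through a
common currency. The planner quantizes a target turbidimeter's accuracy
profile into "pseudo-classes": contiguous FNU ranges within which the
instrument cannot distinguish values. Below a split point the instrument
quotes an absolute half-width (e.g. +/-0.05 FNU), so the low range
divides into ``span / (2 * halfwidth)`` bands. Above the split it quotes
a relative half-width r, so band edges grow geometrically by
``(1 + 2r)`` and the count is the smallest integer c with
``low_boundary * (1 + 2r)**c > high_boundary``. Multiplying the total
pseudo-class count by a recommended images-per-class figure gives a
floor on the dataset size such a direct-regression model would need.

For the reference instrument profile (+/-0.05 FNU on 0-2.5,
+/-2% on 2.5-55, 150 images per class) the chain is
25 low ranges + 79 high ranges = 104 pseudo-classes -> 15,600 images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class AccuracyProfile:
    """Accuracy profile of a target instrument.

    Attributes
    ----------
    abs_halfwidth_low : float
        Absolute accuracy half-width in FNU on the low range.
    low_range : (float, float)
        FNU interval where absolute accuracy applies.
    rel_halfwidth_high : float
        Relative accuracy half-width (fraction) on the high range.
    high_range : (float, float)
        FNU interval where relative accuracy applies; must start where
        the low range ends.
    images_per_class : int
        Recommended minimum training images per (pseudo-)class.
    """

    abs_halfwidth_low: float = 0.05
    low_range: tuple[float, float] = (0.0, 2.5)
    rel_halfwidth_high: float = 0.02
    high_range: tuple[float, float] = (2.5, 55.0)
    images_per_class: int = 150

    def __post_init__(self):
        if self.abs_halfwidth_low <= 0:
            raise ValueError("abs_halfwidth_low must be positive")
        if self.rel_halfwidth_high <= 0:
            raise ValueError("rel_halfwidth_high must be positive")
        if not (self.low_range[0] < self.low_range[1]):
            raise ValueError("low_range must be increasing")
        if not (0 < self.high_range[0] < self.high_range[1]):
            raise ValueError("high_range must be positive and increasing")
        if self.low_range[1] != self.high_range[0]:
            raise ValueError("ranges must be contiguous")
        if self.images_per_class < 1:
            raise ValueError("images_per_class must be >= 1")


def count_low_ranges(profile: AccuracyProfile) -> int:
    """Number of distinct-accuracy bands on the absolute-accuracy range.

    The low span divides into bands of width twice the half-width;
    the count is rounded to the nearest integer.
    """
    span = profile.low_range[1] - profile.low_range[0]
    return round(span / (2.0 * profile.abs_halfwidth_low))


def count_high_ranges(profile: AccuracyProfile) -> int:
    """Number of distinct-accuracy bands on the relative-accuracy range.

    Smallest integer c with ``lo * (1 + 2r)**c > hi`` — band widths grow
    geometrically because the half-width scales with the value.
    """
    lo, hi = profile.high_range
    growth = 1.0 + 2.0 * profile.rel_halfwidth_high
    # epsilon guard: when hi/lo is an exact power of the growth factor,
    # that last band is taken to reach the boundary (one step covers it).
    return max(1, math.ceil(math.log(hi / lo) / math.log(growth) - 1e-9))


def minimum_images(profile: AccuracyProfile) -> dict[str, int]:
    """Pseudo-class counts and the implied minimum training-set size.

    Returns a dict with ``n_low``, ``n_high``, ``pseudo_classes`` and
    ``min_images``.
    """
    n_low = count_low_ranges(profile)
    n_high = count_high_ranges(profile)
    pseudo = n_low + n_high
    return {
        "n_low": n_low,
        "n_high": n_high,
        "pseudo_classes": pseudo,
        "min_images": pseudo * profile.images_per_class,
    }
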