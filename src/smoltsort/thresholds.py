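"""Decision thresholds from mixture fits: weighted-density mode intersections.

A "threshold value" is the point where two adjacent weighted component
densities are equal, w_lo * phi(x; mu_lo, sd_lo) = w_hi * phi(x; mu_hi,
sd_hi), taken inside the open interval between the two component means.
Equating the log densities gives a quadratic in x (linear when the two
variances are equal), so the intersection has a closed form.  A bimodal
best fit yields one threshold; a trimodal fit yields two (lower/middle and
middle/upper); a unimodal best fit yields none and the metric is unusable
for classification.

Thresholds are computed on the fitting scale (log10 for the maturation
markers, raw millimetres for fork length) and reported on the original
measurement scale, back-transforming log10 fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mixture import Component, ModelSelection

__all__ = [
    "ThresholdSet",
    "component_intersection",
    "intersection_with_flag",
    "thresholds_from_selection",
]

#: grid points used by the no-root fallback search
_FALLBACK_GRID = 200_001


@dataclass(frozen=True)
class ThresholdSet:
    """Per-metric threshold value(s), reported on the measurement scale.

    ``orientation`` is "standard" (values above threshold1 gate as
    maturing) except for *amh*, whose expression falls as maturation
    starts, hence "inverted" (values below threshold1 gate).  ``usable``
    is false iff the best fit was unimodal, in which case the metric
    contributes nothing to classification.
    """

    metric: str
    treatment: str
    scale: str  # fitting scale: "raw" or "log10"
    threshold1: Optional[float]
    threshold2: Optional[float] = None
    orientation: str = "standard"
    fallback1: bool = False
    fallback2: bool = False

    def __post_init__(self):
        if self.scale not in ("raw", "log10"):
            raise ValueError(f"invalid scale {self.scale!r}")
        if self.orientation not in ("standard", "inverted"):
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.orientation == "inverted" and self.metric not in ("", "amh"):
            raise ValueError("inverted orientation is reserved for amh")
        if self.threshold2 is not None:
            if self.threshold1 is None:
                raise ValueError("threshold2 requires threshold1")
            if not self.threshold1 < self.threshold2:
                raise ValueError("threshold1 must be < threshold2")

    @property
    def usable(self) -> bool:
        return self.threshold1 is not None


def _check_pair(c_low: Component, c_high: Component) -> None:
    for c in (c_low, c_high):
        if not (math.isfinite(c.mean) and math.isfinite(c.sd)
                and math.isfinite(c.weight)):
            raise ValueError("non-finite component parameters")
        if c.sd <= 0 or c.weight <= 0:
            raise ValueError("component sd and weight must be positive")
    if not c_low.mean < c_high.mean:
        raise ValueError(
            f"c_low.mean ({c_low.mean}) must be < c_high.mean ({c_high.mean})")


def _log_density_gap(x: np.ndarray, c_low: Component, c_high: Component):
    """log(w_lo phi_lo) - log(w_hi phi_hi) evaluated at x."""
    zl = (x - c_low.mean) / c_low.sd
    zh = (x - c_high.mean) / c_high.sd
    return (math.log(c_low.weight / c_high.weight)
            + math.log(c_high.sd / c_low.sd)
            + 0.5 * (zh * zh - zl * zl))


def intersection_with_flag(c_low: Component,
                           c_high: Component) -> tuple[float, bool]:
    """Weighted-density intersection with a fallback indicator.

    Solves the quadratic from equating log weighted normal densities and
    returns the root in the open interval (mu_low, mu_high).  When two
    roots fall inside, the crossing where dominance passes from the lower
    to the upper component (gap decreasing) is taken.  When no real root
    lies inside — possible under extreme weight imbalance — the in-interval
    argmin of |posterior(low) - posterior(high)| on a dense grid is
    returned and flagged as a fallback.
    """
    _check_pair(c_low, c_high)
    wl, ml, sl = c_low.weight, c_low.mean, c_low.sd
    wh, mh, sh = c_high.weight, c_high.mean, c_high.sd

    al, ah = 1.0 / (2.0 * sl * sl), 1.0 / (2.0 * sh * sh)
    a = ah - al
    b = 2.0 * (al * ml - ah * mh)
    c = ah * mh * mh - al * ml * ml + math.log((wl * sh) / (wh * sl))

    roots: list[float] = []
    if abs(a) < 1e-14 * max(al, ah):
        if b != 0.0:
            roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc >= 0.0:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]

    inside = sorted(r for r in roots if ml < r < mh)
    if len(inside) == 1:
        return inside[0], False
    if len(inside) == 2:
        # prefer the crossing where the lower component loses dominance
        for r in inside:
            slope = (_log_density_gap(np.array([r + 1e-9 * (mh - ml)]),
                                      c_low, c_high)
                     - _log_density_gap(np.array([r - 1e-9 * (mh - ml)]),
                                        c_low, c_high))
            if slope[0] < 0:
                return r, False
        return inside[0], False

    # fallback: dense grid argmin of the posterior difference
    xs = np.linspace(ml, mh, _FALLBACK_GRID)[1:-1]
    gap = _log_density_gap(xs, c_low, c_high)
    # |posterior_low - posterior_high| = |tanh(gap / 2)|, monotone in |gap|
    return float(xs[np.argmin(np.abs(gap))]), True


def component_intersection(c_low: Component, c_high: Component) -> float:
    """The threshold between two adjacent components (fitting scale)."""
    return intersection_with_flag(c_low, c_high)[0]


def thresholds_from_selection(sel: ModelSelection,
                              orientation: str = "standard",
                              scale: str = "raw") -> ThresholdSet:
    """Convert a BIC-selected mixture into a :class:`ThresholdSet`.

    A unimodal best fit produces an unusable set with no thresholds; a
    bimodal fit produces threshold1; a trimodal fit produces threshold1
    (components 1/2) and threshold2 (components 2/3).  ``scale`` names the
    scale the mixture was fitted on; thresholds from log10 fits are
    back-transformed (10**t) for reporting on the measurement scale.
    """
    best = sel.best
    t1 = t2 = None
    f1 = f2 = False
    if best.k >= 2:
        t1, f1 = intersection_with_flag(best.components[0], best.components[1])
    if best.k == 3:
        t2, f2 = intersection_with_flag(best.components[1], best.components[2])
    if scale == "log10":
        t1 = None if t1 is None else 10.0 ** t1
        t2 = None if t2 is None else 10.0 ** t2
    return ThresholdSet(metric=sel.metric, treatment=sel.treatment,
                        scale=scale, threshold1=t1, threshold2=t2,
                        orientation=orientation, fallback1=f1, fallback2=f2)
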