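"""Conversion of grouped or sparsely supported age data to single-year curves.

Epidemiological inputs arrive as values at scattered support ages and are
interpolated with natural cubic splines; claims cost aggregates arrive in
five-year age groups and are linearly interpolated between group midpoints.
Both produce an "age curve": a dense vector over integer ages 0..100.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .grids import AGES

__all__ = ["spline_ages", "linear_by_age_group"]


def _clip(curve: np.ndarray, lower: float | None, upper: float | None) -> np.ndarray:
    if lower is not None or upper is not None:
        curve = np.clip(curve, lower, upper)
    return curve


def spline_ages(
    grouped: Iterable[tuple[float, float]],
    *,
    lower: float | None = 0.0,
    upper: float | None = None,
) -> np.ndarray:
    """Natural cubic spline through ``(age, value)`` support points.

    Evaluated at integer ages 0..100 with constant extrapolation beyond the
    outermost support points.  Exact at the support points.  With fewer than
    three points a linear interpolant is used instead (with a warning).

    Parameters
    ----------
    grouped
        ``(age, value)`` pairs with strictly increasing, distinct ages.
    lower, upper
        Valid domain of the payload; the curve is clipped to it after
        interpolation (proportions use ``(0, 1)``, rates and costs
        ``(0, None)``).  Pass ``None`` to disable a bound.
    """
    pts = sorted(grouped)
    if not pts:
        raise ValueError("no support points")
    ages = np.asarray([p[0] for p in pts], dtype=float)
    vals = np.asarray([p[1] for p in pts], dtype=float)
    if np.unique(ages).size != ages.size:
        raise ValueError("duplicate support ages")
    if not (np.isfinite(ages).all() and np.isfinite(vals).all()):
        raise ValueError("non-finite support points")

    if ages.size < 3:
        warnings.warn(
            f"only {ages.size} support point(s); falling back to linear interpolation",
            UserWarning,
            stacklevel=2,
        )
        curve = np.interp(AGES.astype(float), ages, vals)
        return _clip(curve, lower, upper)

    spline = CubicSpline(ages, vals, bc_type="natural")
    x = np.clip(AGES.astype(float), ages[0], ages[-1])  # constant extrapolation
    curve = spline(x)
    # guarantee exactness at integer support ages despite float evaluation
    on_grid = ages[(ages == np.round(ages)) & (ages >= 0) & (ages <= 100)]
    curve[on_grid.astype(int)] = vals[np.isin(ages, on_grid)]
    return _clip(curve, lower, upper)


def linear_by_age_group(
    grouped: Sequence[tuple[float, float, float]],
    *,
    lower: float | None = 0.0,
    upper: float | None = None,
) -> np.ndarray:
    """Piecewise-linear age curve from ``(group_lo, group_hi, value)`` rows.

    Each group value is anchored at the group midpoint ``(lo + hi) / 2``;
    the curve is linear between adjacent midpoints and constant before the
    first and after the last midpoint.  Groups must be ordered, contiguous
    (``hi + 1 == next lo``) and cover ages 0..100.
    """
    rows = list(grouped)
    if not rows:
        raise ValueError("no age groups")
    lo = np.asarray([r[0] for r in rows], dtype=float)
    hi = np.asarray([r[1] for r in rows], dtype=float)
    vals = np.asarray([r[2] for r in rows], dtype=float)
    if np.any(hi < lo):
        raise ValueError("group with hi < lo")
    if lo[0] > 0 or hi[-1] < 100:
        raise ValueError("groups must cover ages 0..100")
    if np.any(lo[1:] != hi[:-1] + 1):
        raise ValueError("groups must be ordered and contiguous (no gaps/overlaps)")
    if not np.isfinite(vals).all():
        raise ValueError("non-finite group values")

    mid = (lo + hi) / 2.0
    curve = np.interp(AGES.astype(float), mid, vals)
    return _clip(curve, lower, upper)
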