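"""Cubic regression spline bases on quantile knots.

The smoothers used for longitude and latitude are unpenalized natural cubic
regression splines: cardinal basis functions on a fixed set of knots placed
at covariate quantiles. Natural splines are linear beyond the boundary
knots, so spatial predictions extrapolate linearly away from the hydrophone
network rather than exploding cubically.

A basis with ``q`` knots spans a ``q``-dimensional space whose elements sum
to the constant function; the first cardinal column is dropped so the
remaining ``q - 1`` columns are full rank alongside an intercept. A smoother
requested with ``df`` degrees of freedom therefore uses ``df + 1`` knots.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["quantile_knots", "cr_basis", "cr_design"]


def quantile_knots(x: np.ndarray, df: int) -> np.ndarray:
    """Place ``df + 1`` knots at equally spaced quantiles of ``x``.

    Raises
    ------
    ValueError
        If ``x`` has fewer than ``df + 1`` distinct values, in which case
        the knots would coincide and the basis would be singular.
    """
    x = np.asarray(x, dtype=float)
    n_knots = df + 1
    uniq = np.unique(x)
    if uniq.size < n_knots:
        raise ValueError(
            f"covariate has {uniq.size} distinct values; "
            f"need at least {n_knots} for a {df}-df spline"
        )
    probs = np.linspace(0.0, 1.0, n_knots)
    knots = np.quantile(x, probs)
    # Quantiles of heavily tied data can still coincide; fall back to
    # equally spaced quantiles of the distinct values.
    if np.unique(knots).size < n_knots:
        knots = np.quantile(uniq, probs)
    return np.unique(knots)


def cr_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the full cardinal natural-cubic-spline basis.

    Column ``j`` is the natural cubic spline interpolating the ``j``-th
    standard basis vector at the knots, extended linearly (with the boundary
    slope) outside the knot range. Returns an ``(n, q)`` matrix for ``q``
    knots; the columns sum to one everywhere, including the extrapolation
    region.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    q = knots.size
    lo, hi = knots[0], knots[-1]
    inside = np.clip(x, lo, hi)
    basis = np.empty((x.size, q))
    eye = np.eye(q)
    for j in range(q):
        cs = CubicSpline(knots, eye[:, j], bc_type="natural")
        col = cs(inside)
        # linear continuation beyond the boundary knots
        below = x < lo
        above = x > hi
        if below.any():
            col[below] = cs(lo) + cs(lo, 1) * (x[below] - lo)
        if above.any():
            col[above] = cs(hi) + cs(hi, 1) * (x[above] - hi)
        basis[:, j] = col
    return basis


def cr_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Identifiable spline design: the cardinal basis minus its first column.

    With an intercept present this spans exactly the natural-spline space on
    the given knots and contributes ``q - 1`` model degrees of freedom.
    """
    return cr_basis(x, knots)[:, 1:]
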