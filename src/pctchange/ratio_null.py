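"""Closed-form approximate correlations for ratio variables.

Two variables that share a component — ``x/z`` and ``y/z``, or baseline
``x`` and percentage change ``(x - y)/x`` — are *mathematically coupled*:
their correlation is non-zero even when the underlying variables are
unrelated.  Karl Pearson's 1897 first-order approximation gives the
expected correlation between two ratio variables ``x/z`` and ``y/w`` in
terms of coefficients of variation ``V`` and pairwise correlations ``r``:

    r(x/z, y/w) = (r_xy V_x V_y - r_xw V_x V_w - r_yz V_y V_z + r_zw V_z V_w)
                  / [ sqrt(V_x^2 + V_z^2 - 2 r_xz V_x V_z)
                      * sqrt(V_y^2 + V_w^2 - 2 r_yw V_y V_w) ]

Every special case in this module delegates to that single formula.  The
one that matters for pre/post designs is the correlation between ``x`` and
``y/x``; writing the CV ratio ``k = V_x / V_y`` it reduces to

    r(x, y/x) = (r_xy - k) / sqrt(1 + k^2 - 2 k r_xy)

and the appropriate null for testing percentage change against baseline is
this value at ``k = 1`` with the sign flipped (percentage change is
``1 - y/x``):

    rho_0 = sqrt((1 - r_xy) / 2).

The approximation requires means away from zero and denominator CVs small
(|V| < 1 for the underlying series to converge).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "RatioMoments",
    "NullBasis",
    "NullSpec",
    "UndefinedCorrelationError",
    "ApproximationWarning",
    "approx_corr_index_ratios",
    "corr_x_vs_negyx",
    "corr_surface_k",
    "chayes_null",
    "appropriate_null",
]

_R_ONE_TOL = 1e-12  # |1 - r| below this counts as the r = 1 singularity


class UndefinedCorrelationError(ValueError):
    """The approximate correlation is undefined at this parameter point."""


class ApproximationWarning(UserWarning):
    """The first-order approximation is applied outside its comfort zone."""


class NullBasis(str, Enum):
    """Provenance of a null correlation value."""

    APPROPRIATE_K1 = "appropriate_k1"   # k = 1 null given observed r_xy
    CHAYES_ZERO_R = "chayes_zero_r"     # r_xy forced to 0 (Chayes)
    CONVENTIONAL_ZERO = "conventional_zero"  # the usual rho = 0 null


@dataclass(frozen=True)
class NullSpec:
    """A null correlation with its provenance."""

    rho0: float
    r_xy_used: Optional[float]
    basis: NullBasis

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho0 <= 1.0:
            raise ValueError(f"rho0 = {self.rho0} outside [-1, 1]")


@dataclass(frozen=True)
class RatioMoments:
    """CVs and pairwise correlations feeding the general formula.

    For ``corr(x/z, y/w)``: CVs of all four variables and the six pairwise
    correlations.  Constant variables get ``cv = 0`` and their correlations
    are immaterial (set them to 0).
    """

    cv_x: float
    cv_y: float
    cv_z: float
    cv_w: float
    r_xy: float = 0.0
    r_xz: float = 0.0
    r_xw: float = 0.0
    r_yz: float = 0.0
    r_yw: float = 0.0
    r_zw: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_xy", "r_xz", "r_xw", "r_yz", "r_yw", "r_zw"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} = {r} outside [-1, 1]")
        for name in ("cv_z", "cv_w"):
            v = abs(getattr(self, name))
            if v >= 1.0:
                raise ValueError(
                    f"|{name}| = {v} >= 1: the series behind the "
                    "approximation does not converge"
                )


def _warn_large_cv(*cvs: float) -> None:
    big = [v for v in cvs if 0.5 <= abs(v) < 1.0]
    if big:
        warnings.warn(
            f"CV(s) {big} in [0.5, 1): the first-order approximation "
            "may be poor",
            ApproximationWarning,
            stacklevel=3,
        )


def approx_corr_index_ratios(moments: RatioMoments) -> float:
    """Pearson's approximate correlation between ``x/z`` and ``y/w``.

    Single source of truth for every special case in this module.  Raises
    :class:`UndefinedCorrelationError` when a denominator factor vanishes
    (e.g. ``x/z`` has zero approximate variance).  A result outside
    [-1, 1] — possible because this is a first-order approximation — is
    returned as-is with an :class:`ApproximationWarning`, never silently
    clamped.
    """
    m = moments
    _warn_large_cv(m.cv_x, m.cv_y, m.cv_z, m.cv_w)
    num = (
        m.r_xy * m.cv_x * m.cv_y
        - m.r_xw * m.cv_x * m.cv_w
        - m.r_yz * m.cv_y * m.cv_z
        + m.r_zw * m.cv_z * m.cv_w
    )
    var_left = m.cv_x**2 + m.cv_z**2 - 2.0 * m.r_xz * m.cv_x * m.cv_z
    var_right = m.cv_y**2 + m.cv_w**2 - 2.0 * m.r_yw * m.cv_y * m.cv_w
    if var_left <= 0.0 or var_right <= 0.0:
        raise UndefinedCorrelationError(
            "approximation undefined: a ratio variable has zero "
            "approximate variance"
        )
    r = num / math.sqrt(var_left * var_right)
    if 1.0 < abs(r) <= 1.0 + 1e-9:
        return math.copysign(1.0, r)  # floating-point overshoot only
    if not -1.0 <= r <= 1.0:
        warnings.warn(
            f"approximate correlation {r:.4f} outside [-1, 1]; the "
            "first-order formula is breaking down here",
            ApproximationWarning,
            stacklevel=2,
        )
    return r


def corr_x_vs_negyx(V_x: float, V_y: float, r_xy: float) -> float:
    """Expected correlation between ``x`` and ``-y/x``.

    Equals the expected correlation between baseline and percentage change
    ``(x - y)/x``:

        (V_x - r_xy V_y) / sqrt(V_x^2 + V_y^2 - 2 r_xy V_x V_y)

    Undefined when ``V_x = V_y`` and ``r_xy = 1`` (the percentage change is
    then exactly constant).
    """
    if V_x <= 0.0 or V_y <= 0.0:
        raise ValueError("CVs must be positive")
    # corr(x, y/x) via the general formula: numerator x / constant z,
    # denominator-shared w = x (so r_xw = 1, cv_w = cv_x, r_yw = r_xy).
    try:
        r = approx_corr_index_ratios(
            RatioMoments(
                cv_x=V_x, cv_y=V_y, cv_z=0.0, cv_w=V_x,
                r_xy=r_xy, r_xw=1.0, r_yw=r_xy,
            )
        )
    except UndefinedCorrelationError:
        raise UndefinedCorrelationError(
            "correlation between x and -y/x undefined: V_x = V_y with "
            "r_xy = 1 makes y/x constant"
        ) from None
    return -r


def corr_surface_k(k: float, r_xy: float) -> float:
    """Expected ``corr(x, y/x)`` as a function of ``k = V_x/V_y`` and ``r_xy``.

        (r_xy - k) / sqrt(1 + k^2 - 2 k r_xy)

    The surface has an exact singularity structure at ``r_xy = 1``:
    undefined for ``k = 1``; ``+1`` for ``k < 1``; ``-1`` for ``k > 1``.
    At ``r_xy = -1`` the value is ``-1`` for every ``k``.
    """
    if k <= 0.0:
        raise ValueError(f"k must be positive, got {k}")
    if not -1.0 <= r_xy <= 1.0:
        raise ValueError(f"r_xy = {r_xy} outside [-1, 1]")
    if 1.0 - r_xy < _R_ONE_TOL:
        if abs(k - 1.0) < _R_ONE_TOL:
            raise UndefinedCorrelationError(
                "corr(x, y/x) undefined at r_xy = 1, k = 1"
            )
        return 1.0 if k < 1.0 else -1.0
    # The surface depends on the CVs only through k, so evaluate at a CV
    # scale safely inside the convergence region regardless of k.
    scale = 0.01 / max(1.0, k)
    return -corr_x_vs_negyx(k * scale, scale, r_xy)


def chayes_null(V_x: float, V_y: float) -> float:
    """Chayes' null correlation between ``y/x`` and ``x``: r_xy forced to 0.

        -V_x / sqrt(V_x^2 + V_y^2)

    Setting ``r_xy = 0`` is rarely realistic for repeated measurements —
    pre- and post-treatment values are almost always positively
    correlated — so this null is kept for reference, not recommended;
    results carry the ``chayes_zero_r`` basis tag.
    """
    if V_x < 0.0 or V_y < 0.0:
        raise ValueError("CVs must be non-negative")
    if V_x == 0.0 and V_y == 0.0:
        raise UndefinedCorrelationError("both CVs zero: null undefined")
    if V_y == 0.0:
        return -1.0
    return corr_surface_k(V_x / V_y, 0.0)


def appropriate_null(r_xy: float) -> NullSpec:
    """Appropriate null correlation between baseline and percentage change.

    Under the null of *no relation* between percentage change and baseline,
    the CV of the measurement is unchanged by treatment (``k = 1``), and the
    expected ``corr(x, (x - y)/x)`` given the observed pre/post correlation
    ``r_xy`` is

        rho_0 = sqrt((1 - r_xy) / 2),

    i.e. ``-corr_surface_k(1, r_xy)``.  This — not zero — is the value the
    observed coupled correlation must be tested against.

    Raises at ``r_xy = 1`` (singular); at ``r_xy = -1`` returns 1 with a
    warning (degenerate boundary).
    """
    if not -1.0 <= r_xy <= 1.0:
        raise ValueError(f"r_xy = {r_xy} outside [-1, 1]")
    if 1.0 - r_xy < _R_ONE_TOL:
        raise UndefinedCorrelationError(
            "appropriate null undefined at r_xy = 1 (k = 1 singularity)"
        )
    if 1.0 + r_xy < _R_ONE_TOL:
        warnings.warn(
            "r_xy = -1 is a degenerate boundary; returning rho0 = 1",
            ApproximationWarning,
            stacklevel=2,
        )
        return NullSpec(rho0=1.0, r_xy_used=r_xy, basis=NullBasis.APPROPRIATE_K1)
    rho0 = math.sqrt((1.0 - r_xy) / 2.0)
    return NullSpec(rho0=rho0, r_xy_used=r_xy, basis=NullBasis.APPROPRIATE_K1)
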