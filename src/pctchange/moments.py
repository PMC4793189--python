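"""Sufficient statistics for the percentage-change test.

The test of whether percentage change ``(x - y) / x`` is related to the
baseline value ``x`` runs entirely off a handful of moments: the means and
standard deviations of baseline and follow-up, their coefficients of
variation ``V = s / m``, the CV ratio ``k = V_x / V_y``, and the plain
Pearson correlation ``r_xy``.  This module computes them from paired data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class DegenerateSampleError(ValueError):
    """A variable has zero variance, so correlations are undefined."""


class CVUndefinedError(ValueError):
    """A coefficient of variation is requested but its mean is (near) zero."""


# Refuse a CV when |mean| is this many times smaller than the SD: the
# approximation behind the test requires means away from zero.
_MEAN_ZERO_REL_TOL = 1e-12


@dataclass(frozen=True)
class PairedSample:
    """Per-subject baseline (``x``) and follow-up (``y``) measurements.

    Parameters
    ----------
    baseline, followup
        Equal-length numeric vectors, at least 4 subjects (the Fisher
        standard error ``1/sqrt(n-3)`` needs ``n > 3``).
    label
        Optional free-text description.
    """

    baseline: np.ndarray
    followup: np.ndarray
    label: Optional[str] = None

    def __post_init__(self) -> None:
        x = np.asarray(self.baseline, dtype=float)
        y = np.asarray(self.followup, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise ValueError("baseline and followup must be 1-D vectors")
        if x.shape != y.shape:
            raise ValueError(
                f"baseline (n={x.size}) and followup (n={y.size}) differ in length"
            )
        if x.size < 4:
            raise ValueError(
                f"need at least 4 paired observations, got {x.size}"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("all measurements must be finite")
        object.__setattr__(self, "baseline", x)
        object.__setattr__(self, "followup", y)

    @property
    def n(self) -> int:
        return int(self.baseline.size)


@dataclass(frozen=True)
class MomentSummary:
    """Means, SDs, CVs, CV ratio k and Pearson correlation of a paired sample.

    ``cv_x``/``cv_y`` are ``None`` when the corresponding mean is zero (the
    CV is undefined there, and the downstream approximation inapplicable);
    ``k`` is ``None`` whenever either CV is.
    """

    n: int
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    r_xy: float
    cv_x: Optional[float] = field(default=None)
    cv_y: Optional[float] = field(default=None)
    k: Optional[float] = field(default=None)


def _cv(mean: float, sd: float) -> Optional[float]:
    if abs(mean) < _MEAN_ZERO_REL_TOL * sd:
        return None
    return sd / mean


def summarize(sample: PairedSample) -> MomentSummary:
    """Compute the moment summary of a paired sample.

    Standard deviations use the ``n - 1`` (sample) denominator.  A zero
    mean makes the corresponding CV unavailable (``None``) rather than
    silently NaN; zero variance in either variable is an error because the
    Pearson correlation is then undefined.
    """
    x, y = sample.baseline, sample.followup
    mean_x, mean_y = float(np.mean(x)), float(np.mean(y))
    sd_x, sd_y = float(np.std(x, ddof=1)), float(np.std(y, ddof=1))
    if sd_x == 0.0:
        raise DegenerateSampleError("baseline has zero variance")
    if sd_y == 0.0:
        raise DegenerateSampleError("followup has zero variance")
    cv_x = _cv(mean_x, sd_x)
    cv_y = _cv(mean_y, sd_y)
    k = None
    if cv_x is not None and cv_y is not None and cv_y != 0.0:
        k = cv_x / cv_y
    return MomentSummary(
        n=sample.n,
        mean_x=mean_x,
        sd_x=sd_x,
        mean_y=mean_y,
        sd_y=sd_y,
        r_xy=sample_correlation(x, y),
        cv_x=cv_x,
        cv_y=cv_y,
        k=k,
    )


def percentage_change(sample: PairedSample) -> np.ndarray:
    """Element-wise percentage change ``(x - y) / x`` as a fraction.

    Positive values mean reduction from baseline.  Kept on the fractional
    scale internally: correlations are invariant to the ``x100`` rescaling
    used in reports.
    """
    x, y = sample.baseline, sample.followup
    zeros = np.flatnonzero(x == 0.0)
    if zeros.size:
        raise ValueError(
            "percentage change undefined: zero baseline at indices "
            f"{zeros.tolist()}"
        )
    return (x - y) / x


def cv_ratio_k(summary: MomentSummary) -> float:
    """CV ratio ``k = V_x / V_y``.

    ``k`` close to 1 suggests no relation between percentage change and
    baseline; ``k > 1`` a positive relation, ``k < 1`` an inverse one.  The
    raw value is always returned — the formal decision belongs to the
    z-test, not to an equality band on ``k``.
    """
    if summary.cv_x is None or summary.cv_y is None:
        raise CVUndefinedError(
            "CV undefined (a mean is zero); the CV ratio k is unavailable"
        )
    if summary.cv_y == 0.0:
        raise CVUndefinedError("follow-up CV is zero; k is unavailable")
    return summary.cv_x / summary.cv_y


def direction_tag(k: float) -> str:
    """Qualitative reading of the CV ratio (diagnostic only)."""
    if k > 1.0:
        return "positive"
    if k < 1.0:
        return "inverse"
    return "no relation"


def sample_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if np.ptp(a) == 0.0:
        raise DegenerateSampleError("first vector is constant")
    if np.ptp(b) == 0.0:
        raise DegenerateSampleError("second vector is constant")
    return float(np.corrcoef(a, b)[0, 1])
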