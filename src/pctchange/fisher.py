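"""Fisher z machinery and the percentage-change-versus-baseline test.

The observed correlation between baseline ``x`` and percentage change
``(x - y)/x`` is compared with the appropriate null correlation
``rho_0 = sqrt((1 - r_xy)/2)`` via Fisher's z transformation:

    z = (arctanh(r_obs) - arctanh(rho_0)) * sqrt(n - 3)

which is referred to the standard normal (two-sided by default).  The
conventional test — the same machinery with ``rho_0 = 0`` — is provided
for comparison; it is the practice the appropriate null corrects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .moments import (
    DegenerateSampleError,
    MomentSummary,
    PairedSample,
    percentage_change,
    sample_correlation,
    summarize,
)
from .ratio_null import NullBasis, NullSpec, appropriate_null

__all__ = [
    "TestResult",
    "fisher_z",
    "fisher_z_test",
    "test_percentage_change",
    "conventional_test",
    "test_from_summary",
]

_CLAMP_TOL = 1e-12  # |r| within this of 1 signals degeneracy, not arctanh(inf)


@dataclass(frozen=True)
class TestResult:
    """Outcome of testing the coupled correlation against a null value.

    ``direction`` reads the sign of ``r_obs - rho0``: positive means
    greater percentage change at higher baseline, negative means less.
    ``proportional`` flags the short-circuit case where follow-up is
    exactly proportional to baseline (percentage change constant, no test
    needed: there is no relation by construction).
    """

    n: int
    r_obs: Optional[float]
    r_xy: float
    k: Optional[float]
    null: Optional[NullSpec]
    z_stat: Optional[float]
    p_two_sided: Optional[float]
    alpha: float
    reject: bool
    direction: str
    method: str
    proportional: bool = False
    summary: Optional[MomentSummary] = None


def fisher_z(r: float) -> float:
    """Fisher z transformation ``arctanh(r) = 0.5 ln((1+r)/(1-r))``."""
    if not -1.0 < r < 1.0:
        raise ValueError(f"Fisher z requires |r| < 1, got r = {r}")
    return math.atanh(r)


def fisher_z_test(r_obs: float, rho0: float, n: int) -> tuple[float, float]:
    """z statistic and two-sided p for ``H0: rho = rho0``.

    ``z = (arctanh(r_obs) - arctanh(rho0)) * sqrt(n - 3)``; the transform
    is approximately normal with standard error ``1/sqrt(n - 3)``.
    """
    if n < 4:
        raise ValueError(
            f"insufficient sample for Fisher SE: need n >= 4, got {n}"
        )
    z = (fisher_z(r_obs) - fisher_z(rho0)) * math.sqrt(n - 3)
    p = 2.0 * stats.norm.sf(abs(z))
    return z, float(p)


def _direction(diff: float) -> str:
    if diff > 0:
        return "greater percentage change at higher baseline"
    if diff < 0:
        return "less percentage change at higher baseline"
    return "no departure from the null"


def _run(
    r_obs: float,
    r_xy: float,
    n: int,
    alpha: float,
    null: NullSpec,
    method: str,
    k: Optional[float] = None,
    summary: Optional[MomentSummary] = None,
) -> TestResult:
    if abs(r_obs) >= 1.0 - _CLAMP_TOL:
        raise DegenerateSampleError(
            f"observed coupled correlation r = {r_obs} is at the boundary; "
            "the Fisher transform is undefined"
        )
    z, p = fisher_z_test(r_obs, null.rho0, n)
    return TestResult(
        n=n,
        r_obs=r_obs,
        r_xy=r_xy,
        k=k,
        null=null,
        z_stat=z,
        p_two_sided=p,
        alpha=alpha,
        reject=p < alpha,
        direction=_direction(r_obs - null.rho0),
        method=method,
        proportional=False,
        summary=summary,
    )


def _proportional_result(
    r_xy: float, n: int, alpha: float, null: Optional[NullSpec], method: str,
    k: Optional[float], summary: Optional[MomentSummary],
) -> TestResult:
    return TestResult(
        n=n, r_obs=None, r_xy=r_xy, k=k, null=null, z_stat=None,
        p_two_sided=None, alpha=alpha, reject=False,
        direction="exact proportionality: percentage change constant, "
                  "no relation with baseline (test not needed)",
        method=method, proportional=True, summary=summary,
    )


def test_percentage_change(
    sample: PairedSample,
    alpha: float = 0.05,
    rho0_override: Optional[float] = None,
) -> TestResult:
    """Test corr(x, (x-y)/x) against the appropriate (k = 1) null.

    ``rho0`` is derived from the *sample* pre/post correlation ``r_xy``
    unless ``rho0_override`` supplies a population value for sensitivity
    analysis.  Exact proportionality (``y = c x``) short-circuits: the
    percentage change is constant, so there is no relation by construction
    and nothing to test.
    """
    smry = summarize(sample)
    pct = percentage_change(sample)
    if float(pct.std()) == 0.0:
        # y exactly proportional to x: percentage change is constant, the
        # coupled correlation (and the k = 1 null at r_xy = 1) undefined.
        return _proportional_result(
            smry.r_xy, sample.n, alpha, None, "appropriate", smry.k, smry)
    if rho0_override is None:
        null = appropriate_null(smry.r_xy)
    else:
        null = NullSpec(rho0=rho0_override, r_xy_used=smry.r_xy,
                        basis=NullBasis.APPROPRIATE_K1)
    r_obs = sample_correlation(sample.baseline, pct)
    return _run(r_obs, smry.r_xy, sample.n, alpha, null, "appropriate",
                k=smry.k, summary=smry)


def conventional_test(sample: PairedSample, alpha: float = 0.05) -> TestResult:
    """The usual test: corr(x, (x-y)/x) against zero.

    Implemented with the same Fisher z machinery so the two methods sit on
    one scale; shown to be misleading whenever ``rho_0`` is far from 0.
    """
    smry = summarize(sample)
    pct = percentage_change(sample)
    null = NullSpec(rho0=0.0, r_xy_used=None, basis=NullBasis.CONVENTIONAL_ZERO)
    if float(pct.std()) == 0.0:
        return _proportional_result(
            smry.r_xy, sample.n, alpha, null, "conventional", smry.k, smry)
    r_obs = sample_correlation(sample.baseline, pct)
    return _run(r_obs, smry.r_xy, sample.n, alpha, null, "conventional",
                k=smry.k, summary=smry)


def test_from_summary(
    r_obs: float,
    r_xy: float,
    n: int,
    alpha: float = 0.05,
    method: str = "appropriate",
) -> TestResult:
    """Run either test from printed summary statistics alone.

    Useful when only ``n``, ``r_xy`` and the observed coupled correlation
    are reported, as in published pre/post analyses.
    """
    if method == "appropriate":
        null = appropriate_null(r_xy)
    elif method == "conventional":
        null = NullSpec(rho0=0.0, r_xy_used=None,
                        basis=NullBasis.CONVENTIONAL_ZERO)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _run(r_obs, r_xy, n, alpha, null, method)
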