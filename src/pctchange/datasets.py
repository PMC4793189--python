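"""Built-in fixture datasets and the parametric paired-sample generator.

Two 10-patient systolic blood-pressure toy vectors illustrate the method's
logic: one where follow-up is exactly proportional to baseline (constant
20% reduction, hence no relation between percentage change and baseline,
and unchanged CV), and one where higher baselines get larger percentage
reductions (the CV shrinks: V_y < V_x, k > 1).  Two published pre/post
analyses are included as summary statistics: a periodontal probing-depth
study (n = 47) and a CD4-count study under antiretroviral therapy
(n = 100).  Patient-level data for those studies were never deposited, so
the generator provides bivariate-normal stand-ins with a chosen CV ratio
and pre/post correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .moments import PairedSample

__all__ = [
    "SummaryFixture",
    "GeneratorSpec",
    "bp_proportional",
    "bp_heterogeneous",
    "example1_summary",
    "example2_summary",
    "generate_paired_sample",
]

_BP_BASELINE = (130.0, 135.0, 140.0, 145.0, 150.0,
                155.0, 160.0, 165.0, 170.0, 175.0)
_BP_HET_FOLLOWUP = (104.0, 108.0, 112.0, 108.75, 112.5,
                    116.25, 120.0, 115.5, 119.0, 122.5)


class SummaryFixture(NamedTuple):
    """Printed summary statistics of a published pre/post analysis."""

    n: int
    r_xy: float      # correlation between baseline and follow-up
    r_obs: float     # observed corr(baseline, percentage change)
    label: str


#: Periodontal probing pocket depth, 47 infrabony lesions treated with
#: guided tissue regeneration (reduction expected).
example1_summary = SummaryFixture(
    n=47, r_xy=0.207, r_obs=0.354,
    label="probing pocket depth, guided tissue regeneration (n=47)")

#: CD4 counts of 100 HIV-infected subjects after 4 months of
#: antiretroviral therapy (increase expected).
example2_summary = SummaryFixture(
    n=100, r_xy=0.484, r_obs=0.711,
    label="CD4 count, antiretroviral therapy (n=100)")


def bp_proportional() -> PairedSample:
    """Blood-pressure toy with y = 0.8 x: constant 20% reduction."""
    x = np.array(_BP_BASELINE)
    return PairedSample(baseline=x, followup=0.8 * x,
                        label="blood pressure toy, y = 0.8x")


def bp_heterogeneous() -> PairedSample:
    """Blood-pressure toy with reduction growing from 20% to 30%.

    First three follow-ups are 0.8x, the middle four 0.75x, the last
    three 0.7x: greater percentage reduction at higher baseline, so the
    follow-up CV is smaller than the baseline CV (k > 1).
    """
    return PairedSample(
        baseline=np.array(_BP_BASELINE),
        followup=np.array(_BP_HET_FOLLOWUP),
        label="blood pressure toy, heterogeneous percentage reduction")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the bivariate-normal paired-sample generator.

    The population CV ratio equals ``target_k`` and the population pre/post
    correlation ``target_r_xy``; the follow-up mean is ``0.8 mean_x``
    (a 20% average reduction, matching the toy examples; immaterial to
    correlations).
    """

    n: int
    target_r_xy: float
    target_k: float = 1.0
    mean_x: float = 100.0
    sd_x: float = 10.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be at least 4")
        if not -1.0 < self.target_r_xy < 1.0:
            raise ValueError("|target_r_xy| must be < 1")
        if self.target_k <= 0.0:
            raise ValueError("target_k must be positive")
        if self.sd_x <= 0.0:
            raise ValueError("sd_x must be positive")
        if self.mean_x == 0.0:
            raise ValueError("mean_x must be non-zero (CV undefined)")


def generate_paired_sample(spec: GeneratorSpec) -> PairedSample:
    """Draw a seeded bivariate-normal paired sample matching the spec."""
    rng = np.random.default_rng(spec.seed)
    mean_y = 0.8 * spec.mean_x
    cv_x = spec.sd_x / spec.mean_x
    sd_y = (cv_x / spec.target_k) * mean_y
    z1 = rng.standard_normal(spec.n)
    z2 = rng.standard_normal(spec.n)
    r = spec.target_r_xy
    x = spec.mean_x + spec.sd_x * z1
    y = mean_y + sd_y * (r * z1 + np.sqrt(1.0 - r**2) * z2)
    return PairedSample(
        baseline=x, followup=y,
        label=f"synthetic bivariate normal (k={spec.target_k}, "
              f"r_xy={spec.target_r_xy}, seed={spec.seed})")
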