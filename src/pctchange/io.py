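"""Delimited-text input and human-readable reporting.

Column convention when names are not supplied: the FIRST column is the
baseline and the SECOND the follow-up.  This matters — percentage change
``(x - y)/x`` is direction-sensitive, so swapping the columns changes the
sign of everything downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .empirical_null import NullSimConfig, monte_carlo_p, simulate_null_distribution
from .fisher import TestResult, conventional_test, test_percentage_change
from .moments import PairedSample, summarize

__all__ = ["LoadReport", "Report", "read_paired_csv", "run_report"]


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping from reading a delimited file."""

    path: str
    baseline_col: str
    followup_col: str
    n_rows: int
    n_dropped: int


def read_paired_csv(
    path,
    baseline_col: Optional[str] = None,
    followup_col: Optional[str] = None,
    delimiter: Optional[str] = None,
) -> tuple[PairedSample, LoadReport]:
    """Read paired baseline/follow-up data from a CSV or TSV file.

    Rows with missing values in either column are dropped (complete-case)
    and counted in the returned :class:`LoadReport`.  Column names default
    to the first (baseline) and second (follow-up) columns of the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sep = delimiter
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(
            f"{path}: need at least two columns, found {list(df.columns)}")
    if baseline_col is None:
        baseline_col = str(df.columns[0])
    if followup_col is None:
        followup_col = str(df.columns[1])
    for col in (baseline_col, followup_col):
        if col not in df.columns:
            raise KeyError(
                f"column {col!r} not found; available columns: "
                f"{list(df.columns)}")
    sub = df[[baseline_col, followup_col]].copy()
    for col in (baseline_col, followup_col):
        coerced = pd.to_numeric(sub[col], errors="coerce")
        bad = coerced.isna() & sub[col].notna()
        if bad.any():
            rows = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
            raise ValueError(
                f"column {col!r}: non-numeric values at file line(s) {rows}")
        sub[col] = coerced
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if len(complete) < 4:
        raise ValueError(
            f"{path}: only {len(complete)} complete rows; need at least 4")
    sample = PairedSample(
        baseline=complete[baseline_col].to_numpy(float),
        followup=complete[followup_col].to_numpy(float),
        label=str(path),
    )
    return sample, LoadReport(
        path=str(path),
        baseline_col=baseline_col,
        followup_col=followup_col,
        n_rows=len(complete),
        n_dropped=n_dropped,
    )


@dataclass(frozen=True)
class Report:
    """Plain-text report plus its machine-readable twin."""

    text: str
    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True)


def _fmt(v, nd=3):
    return "NA" if v is None else f"{v:.{nd}f}"


def _result_block(res: TestResult, title: str) -> list[str]:
    lines = [f"{title}:"]
    if res.null is not None:
        lines.append(f"  null correlation rho0 = {_fmt(res.null.rho0)} "
                     f"(basis: {res.null.basis.value})")
    if res.proportional:
        lines.append(f"  {res.direction}")
    else:
        lines.append(f"  z = {_fmt(res.z_stat)}   two-sided P = "
                     f"{_fmt(res.p_two_sided)}   "
                     f"{'reject' if res.reject else 'do not reject'} "
                     f"at alpha = {res.alpha:g}")
        lines.append(f"  direction: {res.direction}")
    return lines


def _result_dict(res: TestResult) -> dict:
    return {
        "rho0": res.null.rho0 if res.null is not None else None,
        "basis": res.null.basis.value if res.null is not None else None,
        "r_obs": res.r_obs,
        "z": res.z_stat,
        "p_two_sided": res.p_two_sided,
        "alpha": res.alpha,
        "reject": res.reject,
        "proportional": res.proportional,
        "direction": res.direction,
    }


def run_report(
    sample: PairedSample,
    alpha: float = 0.05,
    reps: int = 100_000,
    seed: Optional[int] = None,
) -> Report:
    """Full analysis report for a paired sample.

    Moment summary, the appropriate-null and conventional tests, and the
    empirical-null centile comparison from ``reps`` simulated replicates.
    Deterministic for a fixed seed.
    """
    smry = summarize(sample)
    appr = test_percentage_change(sample, alpha=alpha)
    conv = conventional_test(sample, alpha=alpha)

    lines = []
    if sample.label:
        lines.append(f"Sample: {sample.label}")
    lines.append(f"n = {sample.n}")
    lines.append(
        f"baseline:  mean = {smry.mean_x:.3f}  sd = {smry.sd_x:.3f}  "
        f"V_x = {_fmt(smry.cv_x)}")
    lines.append(
        f"follow-up: mean = {smry.mean_y:.3f}  sd = {smry.sd_y:.3f}  "
        f"V_y = {_fmt(smry.cv_y)}")
    lines.append(f"CV ratio k = V_x/V_y = {_fmt(smry.k)}")
    lines.append(f"corr(baseline, follow-up) r_xy = {smry.r_xy:.3f}")
    if appr.r_obs is not None:
        lines.append(
            f"corr(baseline, percentage change) r_obs = {appr.r_obs:.3f}")
    lines.extend(_result_block(appr, "Appropriate-null test (k = 1)"))
    lines.extend(_result_block(conv, "Conventional test (rho0 = 0)"))

    mc_data = None
    if not appr.proportional:
        dist = simulate_null_distribution(NullSimConfig(
            n=sample.n, r_xy=smry.r_xy, reps=reps, seed=seed))
        mc = monte_carlo_p(appr.r_obs, dist)
        lines.append("Empirical null (simulated under k = 1):")
        lines.append(
            f"  median = {dist.median:.3f}   95% band = "
            f"({dist.centile_2_5:.3f}, {dist.centile_97_5:.3f})   "
            f"reps = {dist.reps}   seed = {seed}")
        lines.append(f"  {mc.statement}")
        lines.append(f"  Monte-Carlo two-sided P = {mc.p:.4f}")
        mc_data = {
            "median": dist.median,
            "centile_2_5": dist.centile_2_5,
            "centile_97_5": dist.centile_97_5,
            "reps": dist.reps,
            "seed": seed,
            "p_two_sided": mc.p,
            "statement": mc.statement,
        }

    data = {
        "label": sample.label,
        "n": sample.n,
        "moments": {
            "mean_x": smry.mean_x, "sd_x": smry.sd_x, "cv_x": smry.cv_x,
            "mean_y": smry.mean_y, "sd_y": smry.sd_y, "cv_y": smry.cv_y,
            "k": smry.k, "r_xy": smry.r_xy,
        },
        "appropriate": _result_dict(appr),
        "conventional": _result_dict(conv),
        "empirical_null": mc_data,
    }
    return Report(text="\n".join(lines), data=data)
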