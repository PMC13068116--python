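"""Cohort-level statistics over per-patient TEE estimates.

The battery: Shapiro-Wilk normality of the TEE distribution, a one-sample
t-test of the cohort mean against a clinical reference (1500 kcal/m^2/day is
the standard pediatric benchmark), and Pearson / Spearman correlations of TEE
with age.  All tests are two-sided; alpha is reported alongside, never used to
gate output.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSummary",
    "one_sample_t",
    "shapiro_wilk",
    "correlations",
    "cohort_run",
]


class DegenerateSampleError(ValueError):
    """The sample has no variance (or too few points) for the requested test."""


@dataclasses.dataclass
class CohortSummary:
    n: int
    mean_tee: float
    sd_tee: float
    shapiro_w: float
    shapiro_p: float
    t_stat: float
    t_p: float
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    mu0: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.sd_tee < 0:
            raise ValueError("sd_tee must be >= 0")
        for p in (self.shapiro_p, self.t_p, self.pearson_p, self.spearman_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value {p} outside [0, 1]")
        for r in (self.pearson_r, self.spearman_r):
            if abs(r) > 1.0 + 1e-12:
                raise ValueError(f"correlation {r} outside [-1, 1]")

    def report_text(self) -> str:
        """Plain-text block in the reporting style of a results section."""
        return (
            f"N = {self.n}; TEE = {self.mean_tee:.0f} +/- {self.sd_tee:.0f} kcal/m^2/day\n"
            f"Shapiro-Wilk: W = {self.shapiro_w:.4f}, p = {self.shapiro_p:.4f}\n"
            f"One-sample t-test vs {self.mu0:.0f} kcal/m^2/day: "
            f"t = {self.t_stat:.3f}, p = {self.t_p:.4f}\n"
            f"Pearson r = {self.pearson_r:.3f} (p = {self.pearson_p:.4f}); "
            f"Spearman r = {self.spearman_r:.3f} (p = {self.spearman_p:.4f})"
        )


def one_sample_t(values, mu0: float) -> tuple[float, float]:
    """Two-sided one-sample t-test: t = (mean - mu0) / (sd / sqrt(n)).

    Sample sd uses the n-1 denominator; p comes from Student's t with n-1
    degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise DegenerateSampleError("need at least 2 values")
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise DegenerateSampleError("zero variance sample")
    t = (float(values.mean()) - mu0) / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return t, p


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p (delegates to the standard routine)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {values.size}")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def correlations(age, tee) -> tuple[float, float, float, float]:
    """Pearson and Spearman correlation of age vs TEE.

    Returns ``(pearson_r, pearson_p, spearman_r, spearman_p)``; ranks use
    average tie handling and p-values the t-approximation with n-2 df.
    """
    age = np.asarray(age, dtype=float)
    tee = np.asarray(tee, dtype=float)
    if age.size != tee.size or age.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if age.std() == 0 or tee.std() == 0:
        raise DegenerateSampleError("zero variance in age or TEE: correlation undefined")
    pr = stats.pearsonr(age, tee)
    sr = stats.spearmanr(age, tee)
    return float(pr.statistic), float(pr.pvalue), float(sr.statistic), float(sr.pvalue)


def cohort_run(
    reports: pd.DataFrame, mu0: float = 1500.0, alpha: float = 0.05
) -> CohortSummary:
    """Assemble the full statistical battery from a report table.

    ``reports`` needs ``tee_area`` and ``age_years`` columns (the report
    writer's schema).
    """
    for col in ("tee_area", "age_years"):
        if col not in reports.columns:
            raise ValueError(f"reports table lacks required column {col!r}")
    tee = reports["tee_area"].to_numpy(dtype=float)
    age = reports["age_years"].to_numpy(dtype=float)
    t, t_p = one_sample_t(tee, mu0)
    w, w_p = shapiro_wilk(tee)
    pr, pr_p, sr, sr_p = correlations(age, tee)
    return CohortSummary(
        n=int(tee.size),
        mean_tee=float(tee.mean()),
        sd_tee=float(tee.std(ddof=1)),
        shapiro_w=w,
        shapiro_p=w_p,
        t_stat=t,
        t_p=t_p,
        pearson_r=pr,
        pearson_p=pr_p,
        spearman_r=sr,
        spearman_p=sr_p,
        mu0=mu0,
        alpha=alpha,
    )
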