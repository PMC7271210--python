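"""Cohort association statistics: additive genotype-trait regression and
covariate-adjusted Spearman partial correlations.

The additive model regresses the log-transformed trait on allele dosage
(0/1/2) with a-priori covariates (typically age, sex and percent total fat
mass) and, optionally, the dosage of a secondary conditioning variant; the
reported coefficient is the per-allele effect on the log trait. Partial
Spearman correlations rank-transform both variables (mid-ranks for ties),
residualise the ranks on the covariates by least squares, and correlate the
residuals; the p-value uses the t transform with n - 2 - k degrees of
freedom for k covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)


class SingularFitError(ValueError):
    """Design matrix is rank-deficient (collinear columns)."""


@dataclass
class AssocResult:
    beta: float  # per-allele effect on log trait
    se: float
    p_value: float
    n: int


@dataclass
class PartialCorResult:
    rho: float
    p_value: float
    n: int
    k: int  # number of covariates


def _complete_cases(df: pd.DataFrame, cols: Sequence[str], what: str) -> pd.DataFrame:
    sub = df.loc[:, list(cols)]
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        logger.info("%s: dropped %d incomplete row(s)", what, dropped)
    return complete


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify the first column that adds no rank
        culprits = []
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : j + 1]) == np.linalg.matrix_rank(x[:, :j]):
                culprits.append(design.columns[j])
        raise SingularFitError(f"collinear design columns: {culprits}")


def additive_assoc(
    cohort: pd.DataFrame,
    trait: str,
    snv: str,
    covariates: Sequence[str] = (),
    condition_on: str | None = None,
    log_transform: bool = True,
    bonferroni: int = 1,
    stratify: str | None = None,
) -> AssocResult | dict:
    """Per-allele additive association of a (log-transformed) trait with dosage.

    Missing data are handled by complete-case analysis (dropped rows are
    logged). ``condition_on`` adds a secondary variant's dosage to the model.
    ``bonferroni`` multiplies the p-value by the stated number of tests
    (capped at 1). With ``stratify``, one result per stratum is returned as a
    dict keyed by stratum level.
    """
    if stratify is not None:
        out = {}
        for level, sub in cohort.groupby(stratify, sort=True):
            out[level] = additive_assoc(
                sub, trait, snv, covariates, condition_on, log_transform, bonferroni
            )
        return out

    cols = [trait, snv, *covariates] + ([condition_on] if condition_on else [])
    data = _complete_cases(cohort, cols, "additive_assoc")
    if len(data) < 10:
        raise ValueError(f"need at least 10 complete rows, have {len(data)}")
    y = data[trait].to_numpy(dtype=float)
    if log_transform:
        if np.any(y <= 0):
            raise ValueError("trait must be positive for log transform")
        y = np.log(y)
    design = data[[snv, *covariates] + ([condition_on] if condition_on else [])].astype(float)
    design.insert(0, "const", 1.0)
    _check_rank(design)
    fit = sm.OLS(y, design).fit()
    return AssocResult(
        beta=float(fit.params[snv]),
        se=float(fit.bse[snv]),
        p_value=min(float(fit.pvalues[snv]) * max(bonferroni, 1), 1.0),
        n=len(data),
    )


def partial_spearman(
    cohort: pd.DataFrame,
    x: str,
    y: str,
    covariates: Sequence[str] = (),
) -> PartialCorResult:
    """Spearman partial correlation of x and y given covariates.

    Reduces to the ordinary Spearman correlation when no covariates are
    supplied, and is invariant to strictly monotone transforms of x or y.
    """
    cols = [x, y, *covariates]
    data = _complete_cases(cohort, cols, "partial_spearman")
    n, k = len(data), len(covariates)
    if n < k + 4:
        raise ValueError(f"need at least {k + 4} complete rows for {k} covariates, have {n}")
    rx = sps.rankdata(data[x].to_numpy(dtype=float))
    ry = sps.rankdata(data[y].to_numpy(dtype=float))
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant variable after ranking")
    z = np.column_stack([np.ones(n)] + [data[c].to_numpy(dtype=float) for c in covariates])
    res_x = rx - z @ np.linalg.lstsq(z, rx, rcond=None)[0]
    res_y = ry - z @ np.linalg.lstsq(z, ry, rcond=None)[0]
    denom = np.sqrt((res_x**2).sum() * (res_y**2).sum())
    if denom == 0:
        raise ValueError("a variable is fully explained by the covariates")
    rho = float(np.clip((res_x * res_y).sum() / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df=df))
    return PartialCorResult(rho=rho, p_value=p, n=n, k=k)
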