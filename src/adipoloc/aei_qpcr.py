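"""Relative qPCR quantification and allelic-expression-imbalance testing.

Two related procedures live here. The delta-Ct transform converts cycle
thresholds to relative expression, ``efficiency ** (calibrator_Ct -
sample_Ct)``, normalised to the geometric mean of one or more reference
genes. The AEI workflow calibrates allelic-discrimination readouts against a
standard curve built from homozygous genomic DNA mixed at known ratios
(30:70 through 70:30 percent effect allele), inverts the fitted line to
estimate the true percent effect allele of experimental samples, and tests
for allelic imbalance with a paired two-tailed t-test of cDNA against gDNA:
in a heterozygote, genomic DNA carries the two alleles 50:50, so a cDNA
ratio deviating from the paired gDNA ratio indicates unequal allelic
expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_MIX_LEVELS = (30.0, 40.0, 50.0, 60.0, 70.0)
DEFAULT_EFFICIENCY = 2.0


class CalibrationError(ValueError):
    """Raised when a standard curve cannot support inversion."""


@dataclass
class CtRecord:
    """One sample's cycle thresholds for a target and its reference genes."""

    sample_id: str
    target_ct: float
    reference_cts: Mapping[str, float]
    calibrator_ct: float
    efficiency: float = DEFAULT_EFFICIENCY

    def __post_init__(self) -> None:
        if self.efficiency <= 1:
            raise ValueError(f"amplification efficiency must exceed 1, got {self.efficiency}")
        cts = [self.target_ct, self.calibrator_ct, *self.reference_cts.values()]
        if not np.all(np.isfinite(cts)):
            raise ValueError(f"non-finite Ct value for sample {self.sample_id}")


def delta_ct(record: CtRecord) -> float:
    """Reference-normalised relative expression from cycle thresholds.

    Raw expression of each gene is ``efficiency ** (calibrator_Ct - Ct)``;
    the target's raw value is divided by the geometric mean of the reference
    genes' raw values. With a single reference amplifying identically to the
    calibrator this returns 1.
    """
    if not record.reference_cts:
        raise ValueError(f"sample {record.sample_id} has no reference genes")
    raw_target = record.efficiency ** (record.calibrator_ct - record.target_ct)
    raw_refs = [
        record.efficiency ** (record.calibrator_ct - ct) for ct in record.reference_cts.values()
    ]
    return raw_target / float(np.exp(np.mean(np.log(raw_refs))))


@dataclass
class StandardCurveData:
    """Replicate observed %EA at each known gDNA mix level."""

    true_pct: np.ndarray
    observed_pct: np.ndarray
    note: str = ""

    def __post_init__(self) -> None:
        self.true_pct = np.asarray(self.true_pct, dtype=float)
        self.observed_pct = np.asarray(self.observed_pct, dtype=float)
        if self.true_pct.shape != self.observed_pct.shape:
            raise ValueError("true and observed arrays must align")
        if len(np.unique(self.true_pct)) < 2:
            raise ValueError("standard curve needs at least two distinct mix levels")
        if np.any((self.observed_pct < 0) | (self.observed_pct > 100)):
            raise ValueError("observed %EA outside [0,100]")

    def level_means(self) -> pd.DataFrame:
        df = pd.DataFrame({"true_pct": self.true_pct, "observed_pct": self.observed_pct})
        return df.groupby("true_pct", as_index=False)["observed_pct"].mean()


@dataclass
class CalibrationCurve:
    """Least-squares line of mean observed %EA on true %EA."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n_levels: int


def fit_standard_curve(data: StandardCurveData, min_slope: float = 0.05) -> CalibrationCurve:
    """Fit the calibration line through the per-level mean observed %EA.

    A non-positive (or near-zero, below ``min_slope``) slope means the assay
    does not respond monotonically to the allele ratio; inversion would be
    meaningless, so a :class:`CalibrationError` is raised.
    """
    means = data.level_means()
    x = means["true_pct"].to_numpy()
    y = means["observed_pct"].to_numpy()
    fit = sps.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    dof = max(len(x) - 2, 1)
    curve = CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
        n_levels=len(x),
    )
    if curve.slope <= min_slope:
        raise CalibrationError(
            f"standard-curve slope {curve.slope:.4g} is non-positive or near zero; "
            "refusing to invert"
        )
    return curve


def estimate_ea(curve: CalibrationCurve, observed_pct):
    """Invert the calibration line: estimated %EA = (observed - intercept)/slope.

    Estimates are clipped to [0, 100]; clipping triggers a warning because it
    signals observations outside the calibrated range.
    """
    if curve.slope <= 0:
        raise CalibrationError("cannot invert a non-increasing standard curve")
    observed = np.asarray(observed_pct, dtype=float)
    est = (observed - curve.intercept) / curve.slope
    clipped = (est < 0) | (est > 100)
    if np.any(clipped):
        warnings.warn(
            f"{int(np.sum(clipped))} estimate(s) outside [0,100] clipped", stacklevel=2
        )
        est = np.clip(est, 0.0, 100.0)
    return float(est) if est.ndim == 0 else est


def estimate_ea_interp(data: StandardCurveData, observed_pct):
    """Monotone piecewise-linear alternative to the straight-line inversion.

    Interpolates true %EA against the per-level mean observed %EA; the level
    means must be strictly increasing or a :class:`CalibrationError` is
    raised. Observations outside the calibrated range are linearly
    extrapolated from the end segments, then clipped to [0, 100].
    """
    means = data.level_means()
    x = means["observed_pct"].to_numpy()
    y = means["true_pct"].to_numpy()
    if np.any(np.diff(x) <= 0):
        raise CalibrationError("per-level mean observed %EA is not strictly increasing")
    observed = np.asarray(observed_pct, dtype=float)
    est = np.interp(observed, x, y)
    # np.interp holds ends flat; extrapolate with the terminal slopes instead
    lo, hi = observed < x[0], observed > x[-1]
    est = np.where(lo, y[0] + (observed - x[0]) * (y[1] - y[0]) / (x[1] - x[0]), est)
    est = np.where(
        hi, y[-1] + (observed - x[-1]) * (y[-1] - y[-2]) / (x[-1] - x[-2]), est
    )
    clipped = (est < 0) | (est > 100)
    if np.any(clipped):
        warnings.warn(
            f"{int(np.sum(clipped))} estimate(s) outside [0,100] clipped", stacklevel=2
        )
        est = np.clip(est, 0.0, 100.0)
    return float(est) if est.ndim == 0 else est


@dataclass
class AEIMeasurement:
    """One calibrated allelic-discrimination measurement."""

    subject_id: str
    group: str  # tissue / cell fraction label
    material: str  # "gDNA" or "cDNA"
    observed_pct: float
    estimated_pct: float | None = None


@dataclass
class AEITestResult:
    group: str
    n_pairs: int
    mean_difference: float  # cDNA - gDNA, percentage points
    t_statistic: float
    p_value: float


def _paired_t(diff: np.ndarray) -> tuple[float, float]:
    # scipy's ttest_rel returns nan for zero-variance differences; the
    # degenerate cases have well-defined limits that we return instead.
    sd = diff.std(ddof=1)
    if sd == 0:
        if diff.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t = diff.mean() / (sd / np.sqrt(len(diff)))
    p = 2.0 * sps.t.sf(abs(t), df=len(diff) - 1)
    return float(t), float(p)


def test_aei(
    measurements: list[AEIMeasurement] | pd.DataFrame,
    use_calibrated: bool = True,
) -> pd.DataFrame:
    """Paired two-tailed t-test of %EA, cDNA versus gDNA, per group.

    Accepts a list of :class:`AEIMeasurement` or an equivalent tidy frame with
    columns ``subject_id, group, material, observed_pct[, estimated_pct]``.
    Subjects lacking either material within a group are excluded with a
    warning. By default the calibrated estimates are compared; pass
    ``use_calibrated=False`` to test the raw observed percentages.
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = pd.DataFrame([vars(m) for m in measurements])
    value_col = "estimated_pct" if use_calibrated else "observed_pct"
    if use_calibrated and (
        "estimated_pct" not in measurements or measurements["estimated_pct"].isna().any()
    ):
        raise ValueError("calibrated estimates missing; run estimate_ea first")
    results = []
    for group, sub in measurements.groupby("group", sort=True):
        wide = sub.pivot_table(
            index="subject_id", columns="material", values=value_col, aggfunc="mean"
        )
        if "gDNA" not in wide.columns or "cDNA" not in wide.columns:
            raise ValueError(f"group {group!r} lacks one of the gDNA/cDNA materials")
        complete = wide.dropna(subset=["gDNA", "cDNA"])
        n_dropped = len(wide) - len(complete)
        if n_dropped:
            warnings.warn(
                f"group {group!r}: excluded {n_dropped} unpaired subject(s)", stacklevel=2
            )
        if len(complete) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 complete pairs")
        diff = (complete["cDNA"] - complete["gDNA"]).to_numpy()
        t, p = _paired_t(diff)
        results.append(
            AEITestResult(
                group=str(group),
                n_pairs=len(complete),
                mean_difference=float(diff.mean()),
                t_statistic=t,
                p_value=p,
            )
        )
    return pd.DataFrame([vars(r) for r in results])
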