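"""Adipocyte morphometry, paired nonparametric comparison, zebrafish regional
adiposity and cell-growth kinetics.

Adipocytes are modelled as spheres. From a histological cross-sectional area
``A`` (um^2), assumed circular, the histological diameter is
``d_hist = 2*sqrt(A/pi)``; the real cell diameter corrects for tissue
shrinkage as ``d = 1.1 * d_hist``; the volume is ``V = pi*d**3/6`` (um^3);
and the cell weight is ``w = 0.915 * V`` in units of 1e-12 g, using the
density of fat-cell triglycerides, 0.915 g/ml (1 um^3 of triglyceride weighs
0.915e-12 g). Biopsy-level summaries convert the *median* cell area, not the
mean of per-cell weights.

Doubling time from two counts follows
``T_d = (t2 - t1) * log(2) / log(q2 / q1)``; a multi-timepoint least-squares
variant regresses log2(count) on time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

TRIGLYCERIDE_DENSITY = 0.915  # g/ml == 1e-12 g per um^3
SHRINKAGE_CORRECTION = 1.1  # real diameter / histological diameter
MIN_CELLS_PER_BIOPSY = 250


@dataclass
class AdipocyteSummary:
    """Morphometric summary derived from one cross-sectional area (um^2)."""

    area_um2: float
    d_hist_um: float
    d_um: float
    volume_um3: float
    weight_pg: float  # 1e-12 g
    n_cells: int = 1
    weight_pg_percell_median: float | None = None


def area_to_weight(area_um2: float) -> AdipocyteSummary:
    """Sphere-model conversion of one cross-sectional area to volume and weight."""
    if not area_um2 > 0:
        raise ValueError(f"cell area must be positive, got {area_um2}")
    d_hist = 2.0 * np.sqrt(area_um2 / np.pi)
    d = SHRINKAGE_CORRECTION * d_hist
    volume = np.pi * d**3 / 6.0
    weight = TRIGLYCERIDE_DENSITY * volume
    return AdipocyteSummary(
        area_um2=float(area_um2),
        d_hist_um=float(d_hist),
        d_um=float(d),
        volume_um3=float(volume),
        weight_pg=float(weight),
    )


def summarise_biopsy(areas_um2, biopsy_id: str | None = None) -> AdipocyteSummary:
    """Summarise one biopsy: median area first, then the sphere-model conversion.

    The default weight is ``area_to_weight(median area)``; the median of
    per-cell weights is reported alongside (the two coincide because the
    conversion is monotone, up to even-count median interpolation).
    Panels below 250 cells trigger a warning rather than an error.
    """
    areas = np.asarray(areas_um2, dtype=float)
    if areas.size == 0:
        raise ValueError(f"empty cell panel for biopsy {biopsy_id or '?'}")
    if np.any(areas <= 0):
        raise ValueError("cell areas must be positive")
    if areas.size < MIN_CELLS_PER_BIOPSY:
        warnings.warn(
            f"biopsy {biopsy_id or '?'} has {areas.size} cells (< {MIN_CELLS_PER_BIOPSY})",
            stacklevel=2,
        )
    summary = area_to_weight(float(np.median(areas)))
    summary.n_cells = int(areas.size)
    summary.weight_pg_percell_median = float(
        np.median([area_to_weight(a).weight_pg for a in areas])
    )
    return summary


def cumulative_area_distribution(areas_um2, bin_edges) -> pd.DataFrame:
    """Cumulative frequency of cell areas at each bin edge (ECDF evaluated at edges)."""
    areas = np.sort(np.asarray(areas_um2, dtype=float))
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    cum = np.searchsorted(areas, edges, side="right") / areas.size
    return pd.DataFrame({"area_um2": edges, "cumulative_frequency": cum})


@dataclass
class PairedTestResult:
    n_pairs: int
    median_difference: float
    p_value: float
    statistic: float


def compare_matched_pairs(values_a, values_b, exact_max_n: int = 25) -> PairedTestResult:
    """Two-tailed Wilcoxon signed-rank test on matched observations.

    Zero differences are dropped before ranking (classic Wilcoxon
    convention); if every difference is zero the test is vacuous and p = 1 by
    convention. The exact null distribution is used for up to ``exact_max_n``
    non-zero pairs, the normal approximation with continuity correction above.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matched samples must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} incomplete pair(s)", stacklevel=2)
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("no complete pairs")
    if a.size < 5:
        warnings.warn("fewer than 5 pairs; the signed-rank p-value is uninformative",
                      stacklevel=2)
    diff = a - b
    nz = diff[diff != 0]
    if nz.size == 0:
        return PairedTestResult(
            n_pairs=int(a.size), median_difference=0.0, p_value=1.0, statistic=0.0
        )
    method = "exact" if nz.size <= exact_max_n else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method, correction=True)
    return PairedTestResult(
        n_pairs=int(a.size),
        median_difference=float(np.median(diff)),
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
    )


# --- zebrafish regional adiposity ------------------------------------------

#: Wild-type regression of body mass on body area (mg; area in the units of
#: the source regression, R^2 = 0.95, n = 41). Valid for wild-type fish; body
#: composition changes in mutants may distort the area-mass relationship.
MASS_PROXY_INTERCEPT_MG = 4327.4627
MASS_PROXY_SLOPE_MG_PER_UNIT = 0.0004094


@dataclass
class FishQuant:
    """Per-fish body and adipose-depot areas from stained images."""

    fish_id: str
    genotype: str
    sex: str
    body_area: float
    total_adipose_area: float
    abdominal_area: float | None = None
    peripheral_area: float | None = None

    def __post_init__(self) -> None:
        if self.body_area <= 0:
            raise ValueError(f"fish {self.fish_id}: body area must be positive")
        for name in ("total_adipose_area", "abdominal_area", "peripheral_area"):
            v = getattr(self, name)
            if v is not None and v > self.body_area:
                raise ValueError(f"fish {self.fish_id}: {name} exceeds body area")


@dataclass
class AdiposityMetrics:
    fish_id: str
    adiposity_pct: float
    abdominal_peripheral_ratio: float | None


def adiposity_metrics(fish: FishQuant) -> AdiposityMetrics:
    """Generalised adiposity (% of body area) and abdominal/peripheral ratio."""
    pct = 100.0 * fish.total_adipose_area / fish.body_area
    ratio = None
    if fish.abdominal_area is not None and fish.peripheral_area is not None:
        if fish.peripheral_area <= 0:
            raise ValueError(f"fish {fish.fish_id}: peripheral area must be positive for ratio")
        ratio = fish.abdominal_area / fish.peripheral_area
    return AdiposityMetrics(
        fish_id=fish.fish_id, adiposity_pct=float(pct), abdominal_peripheral_ratio=ratio
    )


def body_area_mass_proxy(body_area: float) -> float:
    """Body mass (mg) predicted from body area via the wild-type regression.

    A proxy calibrated on wild-type fish only; at body_area = 0 it returns the
    intercept, an extrapolation far outside the calibration range.
    """
    return MASS_PROXY_INTERCEPT_MG + MASS_PROXY_SLOPE_MG_PER_UNIT * float(body_area)


# --- growth kinetics --------------------------------------------------------


@dataclass
class GrowthSeries:
    """Cell counts (or fluorescence) over time, in days."""

    timepoints: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.timepoints.shape != self.counts.shape:
            raise ValueError("timepoints and counts must align")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.counts <= 0):
            raise ValueError("counts must be positive")


def doubling_time(t1: float, q1: float, t2: float, q2: float) -> float:
    """Population doubling time ``(t2-t1)*log(2)/log(q2/q1)`` in days.

    Negative values (a shrinking culture) are returned with a warning; equal
    counts make the formula undefined and raise.
    """
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if q1 <= 0 or q2 <= 0:
        raise ValueError("counts must be positive")
    if q2 == q1:
        raise ValueError("equal counts: doubling time undefined (log(1) division)")
    td = (t2 - t1) * np.log(2.0) / np.log(q2 / q1)
    if td < 0:
        warnings.warn(f"negative doubling time {td:.3g} days (shrinking culture)", stacklevel=2)
    return float(td)


def fit_doubling_time(series: GrowthSeries) -> float:
    """Least-squares doubling time from all timepoints: 1/slope of log2(q) on t."""
    if series.timepoints.size < 2:
        raise ValueError("need at least two timepoints")
    slope = np.polyfit(series.timepoints, np.log2(series.counts), 1)[0]
    if slope == 0:
        raise ValueError("flat growth curve: doubling time undefined")
    return float(1.0 / slope)
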