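"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the study's inputs rather
than any particular dataset:

* **Genotypes** — two haplotypes per individual; within a haplotype, alleles
  arise by thresholding a latent first-order autoregressive Gaussian at each
  variant's allele frequency, so linkage disequilibrium decays geometrically
  with marker distance at a controllable rate ``ld_rho``. This is an
  emulation of LD, not an estimate of any real region's LD.
* **Quantitative traits** — additive allelic effects at designated causal
  variants plus Gaussian noise.
* **Colocalisation pairs** — two traits on one shared genotype panel,
  realising each of the five hypotheses (H0 neither associated, H1/H2 one
  trait only, H3 two distinct causal variants, H4 one shared causal variant).
* **Allelic qPCR readout** — observed %EA is an affine function of the true
  mix fraction plus Gaussian noise, truncated to [0, 100] (truncations are
  counted and warned about).
* **Adipocyte areas** — log-normal per depot/genotype group.
* **Cell growth** — exponential growth with multiplicative log-normal count
  noise (counts stay positive; noise is mean-one so expected counts follow
  the noiseless curve).

Determinism: every generator takes its seed from the config; one top-level
seed plus a fixed per-generator stream offset makes stages independently
re-runnable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .phenotype_metrics import GrowthSeries

# fixed stream offsets: one top-level seed, independent per-generator streams
_STREAM_GENOTYPES = 101
_STREAM_TRAIT = 211
_STREAM_TRAIT_B = 223
_STREAM_AEI = 307
_STREAM_AREAS = 401
_STREAM_GROWTH = 503
_STREAM_COHORT = 601


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# --- genotype and trait simulation -----------------------------------------


@dataclass
class RegionSimConfig:
    """One genomic region: panel size, LD decay, and the causal model."""

    n_variants: int
    n_individuals: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.9
    causal_indices: tuple[int, ...] = ()
    effect_sizes: tuple[float, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must be ordered within (0, 0.5], got {self.maf_range}")
        if not (0 <= self.ld_rho < 1):
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if len(self.causal_indices) != len(self.effect_sizes):
            raise ValueError("causal_indices and effect_sizes must have equal length")
        for idx in self.causal_indices:
            if not (0 <= idx < self.n_variants):
                raise ValueError(f"causal index {idx} outside [0, {self.n_variants})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x variants, values 0/1/2) with variant metadata."""

    dosages: np.ndarray
    positions: np.ndarray
    variant_ids: list[str]
    effect_alleles: list[str]
    other_alleles: list[str]
    allele_freqs: np.ndarray  # ground-truth per-variant effect-allele frequency

    def __post_init__(self) -> None:
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def ld_matrix(self) -> np.ndarray:
        """Empirical dosage correlation matrix (monomorphic columns give nan)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.corrcoef(self.dosages, rowvar=False)


def _simulate_haplotypes(rng, n_hap: int, thresholds: np.ndarray, rho: float) -> np.ndarray:
    m = thresholds.size
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1)) * np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    # marginal of each z_j is N(0,1); thresholding at Phi^-1(f_j) gives freq f_j
    return (z < thresholds).astype(np.int8)


def simulate_genotypes(config: RegionSimConfig) -> GenotypePanel:
    """Simulate dosages from two latent-AR(1)-thresholded haplotypes per person."""
    rng = _rng(config.seed, _STREAM_GENOTYPES)
    m, n = config.n_variants, config.n_individuals
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = norm.ppf(freqs)
    hap1 = _simulate_haplotypes(rng, n, thresholds, config.ld_rho)
    hap2 = _simulate_haplotypes(rng, n, thresholds, config.ld_rho)
    positions = np.int64(1_000_000) + np.cumsum(rng.integers(200, 5_000, size=m))
    return GenotypePanel(
        dosages=(hap1 + hap2).astype(np.int8),
        positions=positions,
        variant_ids=[f"var{j:04d}" for j in range(m)],
        effect_alleles=["A"] * m,
        other_alleles=["G"] * m,
        allele_freqs=freqs,
    )


@dataclass
class SimulatedTrait:
    """Per-individual trait values plus the generating ground truth."""

    values: np.ndarray
    causal_indices: tuple[int, ...]
    effect_sizes: tuple[float, ...]
    noise_sd: float


def simulate_trait(
    panel: GenotypePanel, config: RegionSimConfig, stream: int = _STREAM_TRAIT
) -> SimulatedTrait:
    """Additive-model trait: sum of causal dosage effects plus Gaussian noise."""
    rng = _rng(config.seed, stream)
    y = rng.normal(0.0, config.noise_sd, size=panel.n_individuals)
    for idx, eff in zip(config.causal_indices, config.effect_sizes):
        y = y + eff * panel.dosages[:, idx]
    return SimulatedTrait(
        values=y,
        causal_indices=tuple(config.causal_indices),
        effect_sizes=tuple(config.effect_sizes),
        noise_sd=config.noise_sd,
    )


def marginal_summary_stats(
    panel: GenotypePanel, trait: np.ndarray | SimulatedTrait, chrom: str = "6"
) -> pd.DataFrame:
    """Per-variant simple linear regression of the trait on dosage.

    Returns the standard summary-statistics table (variant_id, chr, pos,
    alleles, eaf, beta, se, n). Monomorphic variants carry no association
    information and are excluded with a warning; an all-monomorphic panel is
    an error.
    """
    y = trait.values if isinstance(trait, SimulatedTrait) else np.asarray(trait, dtype=float)
    g = panel.dosages.astype(float)
    n = g.shape[0]
    if y.shape[0] != n:
        raise ValueError("trait length does not match panel")
    gc = g - g.mean(axis=0)
    sxx = (gc**2).sum(axis=0)
    poly = sxx > 0
    if not poly.any():
        raise ValueError("all variants are monomorphic; no summary statistics")
    if not poly.all():
        excluded = [panel.variant_ids[j] for j in np.flatnonzero(~poly)]
        warnings.warn(
            f"excluding {len(excluded)} monomorphic variant(s): {excluded[:5]}", stacklevel=2
        )
    yc = y - y.mean()
    sxy = gc[:, poly].T @ yc
    beta = sxy / sxx[poly]
    syy = float(yc @ yc)
    rss = np.maximum(syy - beta * sxy, 0.0)
    with np.errstate(divide="ignore"):
        se = np.sqrt(rss / max(n - 2, 1) / sxx[poly])
    keep = np.flatnonzero(poly)
    return pd.DataFrame(
        {
            "variant_id": [panel.variant_ids[j] for j in keep],
            "chr": chrom,
            "pos": panel.positions[keep],
            "effect_allele": [panel.effect_alleles[j] for j in keep],
            "other_allele": [panel.other_alleles[j] for j in keep],
            "eaf": g[:, keep].mean(axis=0) / 2.0,
            "beta": beta,
            "se": se,
            "n": n,
        }
    )


COLOC_SCENARIOS = ("H0", "H1", "H2", "H3", "H4")


@dataclass
class ColocPairSim:
    """Two aligned summary-statistic tables over one panel, with truth label."""

    stats_a: pd.DataFrame
    stats_b: pd.DataFrame
    scenario: str
    causal_a: tuple[int, ...]
    causal_b: tuple[int, ...]
    panel: GenotypePanel


def simulate_coloc_pair(scenario: str, config: RegionSimConfig) -> ColocPairSim:
    """Simulate a trait pair realising one colocalisation hypothesis.

    ``config.causal_indices``/``effect_sizes`` list the causal-capable
    variants: H4 gives both traits the first; H3 gives trait A the first and
    trait B the second (distinct, hence >= 2 required); H1/H2 give only one
    trait the first; H0 gives neither any.
    """
    if scenario not in COLOC_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {COLOC_SCENARIOS}")
    k = len(config.causal_indices)
    if scenario != "H0" and k < 1:
        raise ValueError(f"scenario {scenario} needs at least one causal variant in config")
    if scenario == "H3":
        if k < 2 or config.causal_indices[0] == config.causal_indices[1]:
            raise ValueError("H3 needs two distinct causal-capable variants")
    panel = simulate_genotypes(config)

    def one(indices: tuple[int, ...], stream: int) -> pd.DataFrame:
        effs = tuple(config.effect_sizes[config.causal_indices.index(i)] for i in indices)
        sub = RegionSimConfig(
            n_variants=config.n_variants,
            n_individuals=config.n_individuals,
            maf_range=config.maf_range,
            ld_rho=config.ld_rho,
            causal_indices=indices,
            effect_sizes=effs,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        return marginal_summary_stats(panel, simulate_trait(panel, sub, stream=stream))

    first = (config.causal_indices[0],) if k else ()
    second = (config.causal_indices[1],) if k > 1 else ()
    causal_a, causal_b = {
        "H0": ((), ()),
        "H1": (first, ()),
        "H2": ((), first),
        "H3": (first, second),
        "H4": (first, first),
    }[scenario]
    stats_a = one(causal_a, _STREAM_TRAIT)
    stats_b = one(causal_b, _STREAM_TRAIT_B)
    return ColocPairSim(
        stats_a=stats_a,
        stats_b=stats_b,
        scenario=scenario,
        causal_a=causal_a,
        causal_b=causal_b,
        panel=panel,
    )


# --- allelic-discrimination (AEI) readout ----------------------------------


@dataclass
class AEISimConfig:
    """Forward model for the allelic qPCR readout.

    ``true_ea_percent`` maps (subject_id, group, material) to the true percent
    effect allele of that sample; a heterozygous gDNA sample is 50 by
    definition. ``calibration_slope``/``intercept`` are the assay's affine
    bias; ``noise_sd`` is in percentage points.
    """

    true_ea_percent: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    calibration_slope: float = 1.0
    calibration_intercept: float = 0.0
    noise_sd: float = 0.0
    n_replicate_pairs: int = 3
    mix_levels: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0, 70.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicate_pairs < 1:
            raise ValueError("need at least one replicate pair")
        for lev in self.mix_levels:
            if not (0 < lev < 100):
                raise ValueError(f"mix level {lev} outside (0, 100)")
        for key, pct in self.true_ea_percent.items():
            if not (0 <= pct <= 100):
                raise ValueError(f"true %EA {pct} for {key} outside [0, 100]")


@dataclass
class AEIExperimentSim:
    """Simulated standard curve and sample readouts, with truth retained."""

    standard_curve: pd.DataFrame  # true_pct, replicate, observed_pct
    samples: pd.DataFrame  # subject_id, group, material, true_pct, observed_pct
    config: AEISimConfig
    n_truncated: int = 0


def simulate_aei(config: AEISimConfig) -> AEIExperimentSim:
    """Apply the affine-plus-noise readout model to mixes and samples."""
    rng = _rng(config.seed, _STREAM_AEI)
    truncated = 0

    def observe(true_pct: float, size: int) -> np.ndarray:
        nonlocal truncated
        mean = config.calibration_slope * float(true_pct) + config.calibration_intercept
        obs = np.full(size, mean)
        if config.noise_sd > 0:
            obs += rng.normal(0.0, config.noise_sd, size=size)
        out = np.clip(obs, 0.0, 100.0)
        truncated += int(np.sum(out != obs))
        return out

    curve_rows = []
    for level in config.mix_levels:
        obs = observe(level, size=config.n_replicate_pairs)
        for r in range(config.n_replicate_pairs):
            curve_rows.append(
                {"true_pct": level, "replicate": r + 1, "observed_pct": float(obs[r])}
            )
    sample_rows = []
    for (subject, group, material), pct in config.true_ea_percent.items():
        obs = float(observe(pct, size=1)[0])
        sample_rows.append(
            {
                "subject_id": subject,
                "group": group,
                "material": material,
                "true_pct": pct,
                "observed_pct": obs,
            }
        )
    if truncated:
        warnings.warn(f"{truncated} observation(s) truncated to [0, 100]", stacklevel=2)
    return AEIExperimentSim(
        standard_curve=pd.DataFrame(curve_rows),
        samples=pd.DataFrame(
            sample_rows,
            columns=["subject_id", "group", "material", "true_pct", "observed_pct"],
        ),
        config=config,
        n_truncated=truncated,
    )


# --- adipocyte areas and growth --------------------------------------------


@dataclass
class AdipocyteSimConfig:
    """Log-normal area model per group (depot/genotype)."""

    groups: Mapping[str, tuple[float, float]]  # group -> (log_mean, log_sd)
    n_cells: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        for group, (_, log_sd) in self.groups.items():
            if log_sd <= 0:
                raise ValueError(f"group {group!r}: log_sd must be positive")


def simulate_adipocyte_areas(config: AdipocyteSimConfig) -> pd.DataFrame:
    """Draw per-cell areas (um^2): tidy frame with biopsy_id and area_um2."""
    rng = _rng(config.seed, _STREAM_AREAS)
    frames = []
    for group, (log_mean, log_sd) in config.groups.items():
        areas = np.exp(rng.normal(log_mean, log_sd, size=config.n_cells))
        frames.append(pd.DataFrame({"biopsy_id": group, "area_um2": areas}))
    return pd.concat(frames, ignore_index=True)


@dataclass
class GrowthSimConfig:
    """Exponential growth with multiplicative log-normal count noise."""

    true_doubling_time: float  # days
    timepoints: tuple[float, ...]
    count_noise_cv: float = 0.0
    initial_count: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_doubling_time <= 0:
            raise ValueError("doubling time must be positive")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.initial_count <= 0:
            raise ValueError("initial_count must be positive")
        if self.count_noise_cv < 0:
            raise ValueError("count_noise_cv must be non-negative")


def simulate_growth(config: GrowthSimConfig) -> GrowthSeries:
    """Counts ``q0 * 2**(t/T_d)`` times mean-one log-normal noise."""
    rng = _rng(config.seed, _STREAM_GROWTH)
    t = np.asarray(config.timepoints, dtype=float)
    q = config.initial_count * 2.0 ** (t / config.true_doubling_time)
    if config.count_noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.count_noise_cv**2))
        q = q * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=t.size))
    return GrowthSeries(timepoints=t, counts=q)


# --- synthetic cohorts for association statistics --------------------------


@dataclass
class CohortSimConfig:
    """Cohort with one test SNV, log-scale trait effects and covariates.

    The trait is generated multiplicatively: ``log(trait)`` is linear in
    dosage, age (years), sex (1 = female), percent total fat mass and
    menopause status, plus Gaussian noise. Menopause follows the cohort
    convention: females aged >= 51 years are coded post-menopausal.
    """

    n: int = 1000
    maf: float = 0.3
    beta: float = 0.0  # per-allele effect on log trait
    age_range: tuple[float, float] = (30.0, 65.0)
    age_effect: float = 0.0
    sex_effect: float = 0.0
    fat_effect: float = 0.0
    menopause_effect: float = 0.0
    noise_sd: float = 0.3
    baseline_log: float = 7.0
    condition_r: float = 0.0  # LD (haplotype correlation) with a conditioning SNV
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        if self.n < 10:
            raise ValueError("cohort too small")
        if not (-1 < self.condition_r < 1):
            raise ValueError("condition_r must be in (-1, 1)")


@dataclass
class CohortSim:
    table: pd.DataFrame
    config: CohortSimConfig


MENOPAUSE_AGE_CUTOFF = 51.0


def simulate_cohort(config: CohortSimConfig) -> CohortSim:
    """Synthetic cohort table: dosage, covariates and a positive trait."""
    rng = _rng(config.seed, _STREAM_COHORT)
    n = config.n
    dosage = rng.binomial(2, config.maf, size=n).astype(float)
    age = rng.uniform(*config.age_range, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)  # 1 = female
    pct_fat = np.clip(rng.normal(30.0, 8.0, size=n), 5.0, 60.0)
    menopause = ((sex == 1) & (age >= MENOPAUSE_AGE_CUTOFF)).astype(float)
    log_trait = (
        config.baseline_log
        + config.beta * dosage
        + config.age_effect * age
        + config.sex_effect * sex
        + config.fat_effect * pct_fat
        + config.menopause_effect * menopause
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "dosage": dosage,
            "age": age,
            "sex": sex,
            "pct_fat": pct_fat,
            "menopause": menopause,
            "trait": np.exp(log_trait),
        }
    )
    if config.condition_r != 0.0:
        # conditioning SNV sharing haplotype correlation condition_r with the test SNV
        h_test = rng.random(size=(n, 2)) < config.maf
        keep = rng.random(size=(n, 2)) < abs(config.condition_r)
        h_cond = np.where(keep, h_test, rng.random(size=(n, 2)) < config.maf)
        table["dosage"] = h_test.sum(axis=1).astype(float)
        table["dosage_cond"] = h_cond.sum(axis=1).astype(float)
        log_trait = (
            config.baseline_log
            + config.beta * table["dosage"].to_numpy()
            + config.age_effect * age
            + config.sex_effect * sex
            + config.fat_effect * pct_fat
            + config.menopause_effect * menopause
            + rng.normal(0.0, config.noise_sd, size=n)
        )
        table["trait"] = np.exp(log_trait)
    return CohortSim(table=table, config=config)
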