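"""Approximate-Bayes-factor fine-mapping and credible sets.

Given per-variant effect estimates ``beta_j`` with variances ``V_j = se_j**2``
from one conditioned association signal, each variant's evidence for
association is the Wakefield approximate Bayes factor

    Lambda_j = sqrt(V_j / (V_j + omega)) * exp(omega * beta_j**2
                                               / (2 * V_j * (V_j + omega)))

against a zero-centred Gaussian prior on allelic effects with variance
``omega`` (default 0.04). Under the single-causal-variant assumption the
posterior probability that variant ``j`` drives the signal is
``pi_j = Lambda_j / sum_k Lambda_k``, and the 99% credible set is the
smallest prefix of variants, ordered by descending ``pi``, whose cumulative
posterior reaches the level.

All Bayes-factor arithmetic is carried out in log space, so z-scores up to
|beta|/se = 100 and beyond cause no overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

DEFAULT_OMEGA = 0.04
DEFAULT_LEVEL = 0.99


def log_abf(beta, variance, omega: float = DEFAULT_OMEGA):
    """Natural log of the approximate Bayes factor in favour of association.

    Parameters
    ----------
    beta : float or array
        Estimated allelic effect (log-OR for binary traits, trait units per
        effect allele for quantitative traits).
    variance : float or array
        Squared standard error of ``beta``. Must be positive.
    omega : float
        Prior variance of allelic effects. Must be positive.

    Returns
    -------
    float or ndarray
        ``log Lambda = 0.5*log(V/(V+omega)) + omega*beta**2/(2*V*(V+omega))``.
    """
    beta = np.asarray(beta, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if omega <= 0:
        raise ValueError(f"prior variance omega must be positive, got {omega}")
    if np.any(variance <= 0) or np.any(~np.isfinite(variance)):
        bad = np.atleast_1d(np.flatnonzero(~(np.atleast_1d(variance) > 0)))
        raise ValueError(f"non-positive effect variance at index/indices {bad.tolist()}")
    out = 0.5 * np.log(variance / (variance + omega)) + omega * beta**2 / (
        2.0 * variance * (variance + omega)
    )
    return out if out.ndim else float(out)


@dataclass
class ABFSet:
    """Per-variant log Bayes factors and posterior probabilities of causality."""

    variant_id: np.ndarray
    log_abf: np.ndarray
    pip: np.ndarray
    omega: float = DEFAULT_OMEGA

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id)
        self.log_abf = np.asarray(self.log_abf, dtype=float)
        self.pip = np.asarray(self.pip, dtype=float)
        if not (len(self.variant_id) == len(self.log_abf) == len(self.pip)):
            raise ValueError("ABFSet arrays must have equal length")
        if abs(self.pip.sum() - 1.0) > 1e-9:
            raise ValueError(f"posterior probabilities sum to {self.pip.sum()}, not 1")


def posterior_probs(log_abfs, variant_ids=None, omega: float = DEFAULT_OMEGA) -> ABFSet:
    """Normalise log Bayes factors into per-variant posterior probabilities.

    ``pi_j = exp(log Lambda_j - logsumexp(log Lambda))`` — invariant to adding
    any constant to every log Bayes factor.
    """
    la = np.asarray(log_abfs, dtype=float)
    if la.size == 0:
        raise ValueError("no Bayes factors supplied")
    if not np.any(np.isfinite(la)):
        raise ValueError("at least one finite log Bayes factor is required")
    pip = np.exp(la - logsumexp(la))
    pip /= pip.sum()  # remove residual rounding so the simplex is exact
    if variant_ids is None:
        variant_ids = np.arange(la.size)
    return ABFSet(variant_id=np.asarray(variant_ids), log_abf=la, pip=pip, omega=omega)


@dataclass
class CredibleSet:
    """The smallest descending-posterior prefix reaching the credible level."""

    variant_ids: list = field(default_factory=list)
    cumulative_posterior: float = 0.0
    n_variants: int = 0
    span_bp: int = 0
    level: float = DEFAULT_LEVEL


def credible_set(abfset: ABFSet, positions, level: float = DEFAULT_LEVEL) -> CredibleSet:
    """Construct the credible set at ``level`` (default 0.99).

    Variants are ordered by descending posterior probability; exact ties are
    broken by ascending genomic position, then by variant id, so the output is
    deterministic. The span is ``max(pos) - min(pos)`` over members (0 for a
    singleton).
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"credible level must be in (0,1), got {level}")
    positions = np.asarray(positions)
    if len(positions) != len(abfset.pip):
        raise ValueError("positions length does not match ABF set")
    ids_str = abfset.variant_id.astype(str)
    # lexsort: last key is primary
    order = np.lexsort((ids_str, positions, -abfset.pip))
    cum = np.cumsum(abfset.pip[order])
    # smallest prefix with cumulative posterior >= level (tolerate rounding at 1)
    k = int(np.searchsorted(cum, min(level, cum[-1]) - 1e-12) + 1)
    members = order[:k]
    span = int(positions[members].max() - positions[members].min()) if k else 0
    return CredibleSet(
        variant_ids=list(abfset.variant_id[members]),
        cumulative_posterior=float(cum[k - 1]),
        n_variants=k,
        span_bp=span,
        level=level,
    )


@dataclass
class FinemapReport:
    """Per-variant table plus the credible-set summary from one signal."""

    table: pd.DataFrame
    abfset: ABFSet
    credible_set: CredibleSet
    omega: float
    level: float


def run_finemap(
    stats: pd.DataFrame,
    omega: float = DEFAULT_OMEGA,
    level: float = DEFAULT_LEVEL,
) -> FinemapReport:
    """Fine-map one conditioned signal from a summary-statistics table.

    ``stats`` needs columns ``variant_id``, ``pos``, ``beta``, ``se``. Rows
    with missing beta or se are dropped with a warning; a non-positive se is
    an error naming the variant. The result is insensitive to input row order.
    """
    df = stats.copy()
    bad = df["beta"].isna() | df["se"].isna()
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} variant(s) with missing beta/se: "
            f"{df.loc[bad, 'variant_id'].tolist()[:5]}",
            stacklevel=2,
        )
        df = df.loc[~bad]
    if df.empty:
        raise ValueError("no variants with complete beta and se")
    nonpos = df["se"] <= 0
    if nonpos.any():
        raise ValueError(
            f"non-positive se for variant(s) {df.loc[nonpos, 'variant_id'].tolist()}"
        )
    la = log_abf(df["beta"].to_numpy(), df["se"].to_numpy() ** 2, omega=omega)
    abfset = posterior_probs(la, variant_ids=df["variant_id"].to_numpy(), omega=omega)
    cs = credible_set(abfset, df["pos"].to_numpy(), level=level)
    members = set(cs.variant_ids)
    table = pd.DataFrame(
        {
            "variant_id": df["variant_id"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "log_abf": abfset.log_abf,
            "pip": abfset.pip,
            "in_credible_set": [v in members for v in df["variant_id"]],
        }
    ).sort_values("pip", ascending=False, kind="stable", ignore_index=True)
    return FinemapReport(table=table, abfset=abfset, credible_set=cs, omega=omega, level=level)
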