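"""Bayesian colocalisation of two association signals over one region.

Enumerates the five standard hypotheses for a region of m variants —
H0 (no association), H1/H2 (one trait associated), H3 (both, distinct causal
variants), H4 (both, one shared causal variant) — assuming at most one causal
variant per trait. With per-variant log Bayes factors ``la_j`` and ``lb_j``
(Wakefield ABFs with trait-specific prior effect variances) and per-variant
prior probabilities ``p1``, ``p2``, ``p12``, the unnormalised hypothesis
weights are

    H0 = 1
    H1 = p1 * S1,            S1  = sum_j exp(la_j)
    H2 = p2 * S2,            S2  = sum_j exp(lb_j)
    H3 = p1 * p2 * (S1*S2 - S12)
    H4 = p12 * S12,          S12 = sum_j exp(la_j + lb_j)

(S1*S2 - S12 is the sum over ordered pairs j != k of exp(la_j + lb_k).)
Posteriors PP0..PP4 are these weights normalised. Everything is computed with
log-sum-exp; if floating-point cancellation drives the H3 term negative it is
clamped to zero with a warning.

The decision rule declares colocalisation when PP3 + PP4 >= 0.99 and
PP4/PP3 >= 5 (PP3 = 0 counts as the ratio being satisfied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .finemap import log_abf

#: Conventional per-variant prior probabilities of association.
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
#: Prior effect-variance for a quantitative trait (sd 0.15 per allele).
DEFAULT_W = 0.0225

DECISION_SUM_THRESHOLD = 0.99
DECISION_RATIO_THRESHOLD = 5.0


@dataclass
class ColocPriors:
    """Per-variant hypothesis priors and per-trait effect-variance priors."""

    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    p12: float = DEFAULT_P12
    w1: float = DEFAULT_W
    w2: float = DEFAULT_W

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12", "w1", "w2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior {name} must be positive")

    def check_region_size(self, m: int) -> None:
        """Warn if the implied prior mass over non-null configurations is >= 1."""
        total = m * (self.p1 + self.p2 + self.p12) + m * (m - 1) * self.p1 * self.p2
        if total >= 1:
            warnings.warn(
                f"priors imply non-null prior mass {total:.3g} >= 1 for m={m} variants",
                stacklevel=3,
            )


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_variants: int
    decision: str = "ambiguous"

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    def best_hypothesis(self) -> int:
        return int(np.argmax(self.pp))


def _align(stats_a: pd.DataFrame, stats_b: pd.DataFrame) -> None:
    ids_a = stats_a["variant_id"].to_numpy()
    ids_b = stats_b["variant_id"].to_numpy()
    if len(ids_a) != len(ids_b) or not (ids_a == ids_b).all():
        only_a = sorted(set(ids_a) - set(ids_b))
        only_b = sorted(set(ids_b) - set(ids_a))
        raise ValueError(
            "variant lists differ between the two traits "
            f"(only in A: {only_a[:5]}; only in B: {only_b[:5]}; "
            "inputs must cover the identical ordered variant list)"
        )


def coloc_abf(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    priors: ColocPriors | None = None,
    sum_threshold: float = DECISION_SUM_THRESHOLD,
    ratio_threshold: float = DECISION_RATIO_THRESHOLD,
) -> ColocResult:
    """Posterior probabilities PP0..PP4 for two aligned summary-stat tables.

    Both tables must cover the identical ordered variant list (strict
    ``variant_id`` equality; no allele flipping is attempted) and have
    positive standard errors throughout.
    """
    priors = priors or ColocPriors()
    _align(stats_a, stats_b)
    m = len(stats_a)
    if m == 0:
        raise ValueError("empty region")
    priors.check_region_size(m)
    for label, df in (("A", stats_a), ("B", stats_b)):
        if (df["se"] <= 0).any():
            bad = df.loc[df["se"] <= 0, "variant_id"].tolist()
            raise ValueError(f"non-positive se in trait {label} for {bad}")

    la = log_abf(stats_a["beta"].to_numpy(), stats_a["se"].to_numpy() ** 2, omega=priors.w1)
    lb = log_abf(stats_b["beta"].to_numpy(), stats_b["se"].to_numpy() ** 2, omega=priors.w2)

    l_s1 = logsumexp(la)
    l_s2 = logsumexp(lb)
    l_s12 = logsumexp(la + lb)

    log_h = np.empty(5)
    log_h[0] = 0.0
    log_h[1] = np.log(priors.p1) + l_s1
    log_h[2] = np.log(priors.p2) + l_s2
    log_h[4] = np.log(priors.p12) + l_s12
    # H3 ∝ S1*S2 - S12, evaluated as exp-of-log with compensated subtraction
    l_prod = l_s1 + l_s2
    if m == 1 or l_s12 >= l_prod:
        if m > 1 and l_s12 > l_prod + 1e-9:
            warnings.warn(
                "S12 exceeded S1*S2 by more than rounding; H3 clamped to zero",
                stacklevel=2,
            )
        log_h[3] = -np.inf
    else:
        # log(S1*S2 - S12) = l_prod + log1p(-exp(l_s12 - l_prod))
        diff = -np.expm1(l_s12 - l_prod)
        if diff <= 0.0:
            warnings.warn("catastrophic cancellation in H3; clamped to zero", stacklevel=2)
            log_h[3] = -np.inf
        else:
            log_h[3] = np.log(priors.p1) + np.log(priors.p2) + l_prod + np.log(diff)

    pp = np.exp(log_h - logsumexp(log_h))
    pp /= pp.sum()
    result = ColocResult(*pp, n_variants=m)
    result.decision = coloc_decision(result, sum_threshold, ratio_threshold)
    return result


def coloc_decision(
    result: ColocResult,
    sum_threshold: float = DECISION_SUM_THRESHOLD,
    ratio_threshold: float = DECISION_RATIO_THRESHOLD,
) -> str:
    """Categorical call from the posterior vector.

    ``colocalised`` iff PP3+PP4 >= sum_threshold and PP4/PP3 >= ratio_threshold
    (a zero PP3 counts as the ratio being satisfied); ``distinct`` when the sum
    passes but the ratio fails; ``ambiguous`` otherwise.
    """
    both = result.pp3 + result.pp4
    ratio_ok = result.pp3 == 0 or result.pp4 / result.pp3 >= ratio_threshold
    if both >= sum_threshold:
        return "colocalised" if ratio_ok else "distinct"
    return "ambiguous"


def coloc_table(result: ColocResult) -> pd.DataFrame:
    """Single-row summary table (pp0..pp4, nsnps, decision)."""
    return pd.DataFrame(
        [
            {
                "pp0": result.pp0,
                "pp1": result.pp1,
                "pp2": result.pp2,
                "pp3": result.pp3,
                "pp4": result.pp4,
                "nsnps": result.n_variants,
                "decision": result.decision,
            }
        ]
    )


def coloc_abf_table(
    stats_a: pd.DataFrame, stats_b: pd.DataFrame, priors: ColocPriors | None = None
) -> pd.DataFrame:
    """Per-variant log Bayes factors for both traits (diagnostic output)."""
    priors = priors or ColocPriors()
    _align(stats_a, stats_b)
    return pd.DataFrame(
        {
            "variant_id": stats_a["variant_id"].to_numpy(),
            "pos": stats_a["pos"].to_numpy(),
            "log_abf_a": log_abf(
                stats_a["beta"].to_numpy(), stats_a["se"].to_numpy() ** 2, omega=priors.w1
            ),
            "log_abf_b": log_abf(
                stats_b["beta"].to_numpy(), stats_b["se"].to_numpy() ** 2, omega=priors.w2
            ),
        }
    )
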