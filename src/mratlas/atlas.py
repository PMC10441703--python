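"""Cohort meta-analysis, binary-outcome power, Bonferroni tiers, and
assembly of the exposure-by-outcome atlas table.

Power follows the standard normal-approximation for the IVW estimate of a
binary outcome: with n participants, case fraction phi, and instrument
variance explained R^2, the IVW z-statistic has non-centrality
sqrt(n R^2 phi (1 - phi)) * |ln OR|, so two-sided power at level alpha is
Phi(lambda - z_{1-alpha/2}) + Phi(-lambda - z_{1-alpha/2}). At OR = 1 this
returns exactly alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, MrAtlasError


# ---------------------------------------------------------------------------
# fixed-effect inverse-variance meta-analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    pvalue: float
    cohort_weights: tuple[float, ...]  # inverse-variance shares, sum to 1


def meta_fixed(per_cohort: Sequence[tuple[float, float]]) -> MetaResult:
    """Fixed-effect inverse-variance pooling of per-cohort (beta, se).

    The METAL-style standard-error scheme: weights 1/se^2, pooled
    se = 1/sqrt(sum of weights). A single cohort passes through unchanged.
    """
    if not per_cohort:
        raise MrAtlasError("meta_fixed requires at least one cohort")
    betas = np.array([b for b, _ in per_cohort], float)
    ses = np.array([s for _, s in per_cohort], float)
    if np.any(ses <= 0):
        raise MrAtlasError("all cohort standard errors must be > 0")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MetaResult(beta, se, p, tuple(w / np.sum(w)))


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


def power_binary(
    n_total: float, case_fraction: float, r2: float, or_alt: float, alpha: float = 0.05
) -> float:
    """Two-sided power to detect ``or_alt`` with the IVW estimator."""
    if not 0 < case_fraction < 1:
        raise ConfigurationError(f"case_fraction must be in (0, 1), got {case_fraction}")
    if not 0 < r2 < 1:
        raise ConfigurationError(f"r2 must be in (0, 1), got {r2}")
    if or_alt <= 0:
        raise ConfigurationError(f"or_alt must be > 0, got {or_alt}")
    if n_total <= 0:
        raise ConfigurationError(f"n_total must be > 0, got {n_total}")
    lam = math.sqrt(n_total * r2 * case_fraction * (1.0 - case_fraction)) * abs(math.log(or_alt))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.sf(z - lam) + stats.norm.cdf(-z - lam))


OR_SEARCH_CEILING = 10.0


def min_detectable_or(
    n_total: float,
    case_fraction: float,
    r2: float,
    target_power: float = 0.8,
    alpha: float = 0.05,
) -> float:
    """Smallest OR > 1 reaching ``target_power``, by bisection on ln(OR).

    Returns ``inf`` when even OR = 10 is underpowered (reported downstream
    as ">10"); by symmetry of the power function in ln(OR), the protective
    bound is the reciprocal of the returned value.
    """
    if not 0 < target_power < 1:
        raise ConfigurationError(f"target_power must be in (0, 1), got {target_power}")

    def gap(log_or: float) -> float:
        return power_binary(n_total, case_fraction, r2, math.exp(log_or), alpha) - target_power

    hi = math.log(OR_SEARCH_CEILING)
    if gap(hi) < 0:
        return math.inf
    root = optimize.brentq(gap, 1e-12, hi, xtol=1e-12, rtol=1e-10)
    return float(math.exp(root))


def format_or(value: float) -> str:
    return f">{OR_SEARCH_CEILING:g}" if math.isinf(value) else f"{value:.3f}"


@dataclass(frozen=True)
class PowerReport:
    n_total: float
    case_fraction: float
    r2: float
    min_detectable_or: float
    power_at: dict[float, float]  # OR -> power

    @classmethod
    def compute(
        cls,
        n_total: float,
        case_fraction: float,
        r2: float,
        or_grid: Iterable[float] = (1.1, 1.3, 1.6),
        target_power: float = 0.8,
        alpha: float = 0.05,
    ) -> "PowerReport":
        return cls(
            n_total=n_total,
            case_fraction=case_fraction,
            r2=r2,
            min_detectable_or=min_detectable_or(n_total, case_fraction, r2, target_power, alpha),
            power_at={o: power_binary(n_total, case_fraction, r2, o, alpha) for o in or_grid},
        )


# ---------------------------------------------------------------------------
# Bonferroni tiers
# ---------------------------------------------------------------------------

TIER_ORDER = ["none", "nominal", "bonferroni_exposures", "bonferroni_pairs"]


@dataclass(frozen=True)
class TierResult:
    tier: str
    nominal_threshold: float
    exposure_threshold: float
    pair_threshold: float

    def printed_thresholds(self) -> dict[str, str]:
        """Thresholds rounded to 2 significant figures, as reported."""
        return {
            "nominal": f"{self.nominal_threshold:.2g}",
            "bonferroni_exposures": f"{self.exposure_threshold:.2g}",
            "bonferroni_pairs": f"{self.pair_threshold:.2g}",
        }


def bonferroni_tiers(
    pvalue: float, n_exposures: int, n_outcomes: int, alpha: float = 0.05
) -> TierResult:
    """Nested significance tier of a p-value.

    The exposure tier divides alpha by the number of exposures; the pair
    tier by the number of exposure-outcome pairs in the outcome family
    (n_exposures * n_outcomes). Tiers are nested by construction.
    """
    if n_exposures < 1 or n_outcomes < 1:
        raise ConfigurationError("family sizes must be >= 1")
    t_exp = alpha / n_exposures
    t_pair = alpha / (n_exposures * n_outcomes)
    if pvalue < t_pair:
        tier = "bonferroni_pairs"
    elif pvalue < t_exp:
        tier = "bonferroni_exposures"
    elif pvalue < alpha:
        tier = "nominal"
    else:
        tier = "none"
    return TierResult(tier, alpha, t_exp, t_pair)


# ---------------------------------------------------------------------------
# atlas assembly
# ---------------------------------------------------------------------------

ATLAS_METHODS = ["wald_ratio", "ivw", "weighted_median", "mr_egger"]


def assemble_atlas(grid_results: Sequence[Mapping]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble one row per exposure-outcome pair and per-family tier counts.

    Each element of ``grid_results`` is a flat mapping with at least
    ``exposure``, ``outcome`` and ``family`` keys (reason-coded failures
    carry a ``reason``). Rows are ordered by family, then ascending IVW
    p-value (pairs without an estimate last). Duplicate pairs are an error.
    """
    if not grid_results:
        import warnings

        warnings.warn("assemble_atlas called with an empty grid", stacklevel=2)
        return (
            pd.DataFrame(columns=["exposure", "outcome", "family"]),
            pd.DataFrame(columns=["family", "tier", "count"]),
        )
    df = pd.DataFrame([dict(r) for r in grid_results])
    dup = df.duplicated(subset=["exposure", "outcome"])
    if dup.any():
        pairs = df.loc[dup, ["exposure", "outcome"]].to_records(index=False).tolist()
        raise MrAtlasError(f"duplicate exposure-outcome pairs in grid: {pairs}")
    if "family" not in df.columns:
        df["family"] = "all"
    sort_p = df["ivw_p"] if "ivw_p" in df.columns else pd.Series(np.nan, index=df.index)
    df = (
        df.assign(_p=sort_p.fillna(np.inf))
        .sort_values(["family", "_p", "exposure", "outcome"], kind="mergesort")
        .drop(columns="_p")
        .reset_index(drop=True)
    )
    if "significance_tier" in df.columns:
        counts = (
            df.groupby(["family", "significance_tier"], observed=True)
            .size()
            .rename("count")
            .reset_index()
            .rename(columns={"significance_tier": "tier"})
        )
    else:
        counts = df.groupby("family").size().rename("count").reset_index().assign(tier="untiered")
    return df, counts
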