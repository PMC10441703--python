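"""Causal-effect estimators for a harmonized instrument set.

Four methods on the log-OR-per-SD scale: the single-SNP Wald ratio, the
multiplicative random-effects inverse-variance weighted (IVW) estimator, the
weighted median with parametric-bootstrap standard errors, and MR-Egger
regression with its directional-pleiotropy intercept.

The IVW estimator is weighted regression of the SNP-outcome effects on the
SNP-exposure effects through the origin, weights 1/se_Y^2. "Random effects"
is the multiplicative form common to two-sample MR software: the fixed-effect
standard error is inflated by max(1, sqrt(Q / (k - 1))), so the model
degrades exactly to fixed effects when Cochran's Q does not exceed its
degrees of freedom. MR-Egger inference uses a t reference with k - 2 degrees
of freedom, reflecting the two estimated coefficients on few SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    CollinearityError,
    EmptyInstrumentSetError,
    Unavailable,
    UndefinedRatioError,
)
from .sumstats import HarmonizedInstrument, HarmonizedSet

Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class MrResult:
    """One method's causal estimate (log-OR per 1-SD exposure difference)."""

    method: str
    estimate: float
    se: float
    pvalue: float
    n_snp: int
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)
    reference: str = "normal"  # inference distribution, e.g. "normal", "t(4)"
    inflation: float = 1.0  # multiplicative random-effects SE inflation applied

    def __post_init__(self):
        if np.isnan(self.ci_low):
            object.__setattr__(self, "ci_low", self.estimate - Z95 * self.se)
        if np.isnan(self.ci_high):
            object.__setattr__(self, "ci_high", self.estimate + Z95 * self.se)

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, OR 95% low, OR 95% high)."""
        return (float(np.exp(self.estimate)), float(np.exp(self.ci_low)), float(np.exp(self.ci_high)))


@dataclass(frozen=True)
class EggerIntercept:
    estimate: float
    se: float
    pvalue: float
    reference: str


@dataclass(frozen=True)
class EggerResult:
    slope: MrResult
    intercept: EggerIntercept


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(instrument: HarmonizedInstrument) -> MrResult:
    """Single-SNP causal estimate beta_Y / beta_X with first-order delta SE."""
    if instrument.beta_exposure == 0:
        raise UndefinedRatioError(f"{instrument.snp_id}: beta_exposure is zero")
    est = instrument.beta_outcome / instrument.beta_exposure
    se = instrument.se_outcome / abs(instrument.beta_exposure)
    return MrResult("wald_ratio", est, se, _normal_p(est / se), 1)


def ivw(hset: HarmonizedSet, random_effects: bool = True) -> MrResult:
    """Multiplicative random-effects IVW estimate.

    With a single instrument the result reduces exactly to the Wald ratio.
    """
    k = hset.n_snp
    if k == 0:
        raise EmptyInstrumentSetError(f"{hset.exposure_name} vs {hset.outcome_name}: no instruments")
    bx, _, by, sy = hset.arrays()
    est, se_fixed, q = _ivw_core(bx, by, sy)
    infl = 1.0
    if random_effects and k >= 2:
        infl = max(1.0, float(np.sqrt(q / (k - 1))))
    se = se_fixed * infl
    return MrResult("ivw", est, se, _normal_p(est / se), k, inflation=infl)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """(estimate, fixed-effect SE, Cochran's Q) of origin-constrained WLS."""
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    est = float(np.sum(w * bx * by)) / sxx
    se_fixed = float(np.sqrt(1.0 / sxx))
    q = float(np.sum(w * (by - est * bx) ** 2))
    return est, se_fixed, q


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median of ratio estimates by cumulative-weight interpolation.

    Sort ratios ascending; the cumulative standardized weight at ratio j is
    s_j = (sum_{i<=j} w_i - w_j/2) / sum w_i; the estimate interpolates the
    sorted ratios at s = 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MrResult | Unavailable:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Requires at least three instruments; with fewer an Unavailable marker is
    returned (the atlas records "NA"). Weights are the first-order inverse
    variances of the ratio estimates, (beta_X / se_Y)^2. The SE is the
    standard deviation of the point estimate over ``n_boot`` replicates with
    (beta_X, beta_Y) redrawn from normal(estimate, se); the seed is required
    for reproducibility.
    """
    k = hset.n_snp
    if k < 3:
        return Unavailable("weighted_median", "requires at least 3 instruments", k)
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed for the bootstrap")
    bx, sx, by, sy = hset.arrays()
    est = weighted_median_point(by / bx, (bx / sy) ** 2)

    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, k))
    bys = rng.normal(by, sy, size=(n_boot, k))
    ratios = bys / bxs
    weights = (bxs / sy) ** 2
    order = np.argsort(ratios, axis=1, kind="stable")
    r_sorted = np.take_along_axis(ratios, order, axis=1)
    w_sorted = np.take_along_axis(weights, order, axis=1)
    s = (np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted) / np.sum(w_sorted, axis=1, keepdims=True)
    boots = np.array([np.interp(0.5, s[i], r_sorted[i]) for i in range(n_boot)])
    se = float(np.std(boots, ddof=1))
    return MrResult("weighted_median", est, se, _normal_p(est / se), k)


def mr_egger(hset: HarmonizedSet) -> EggerResult | Unavailable:
    """MR-Egger regression: weighted least squares of beta_Y on beta_X with a
    free intercept, weights 1/se_Y^2, instruments re-oriented so all
    beta_X >= 0 before fitting.

    The slope is the causal estimate; the intercept estimates average
    directional pleiotropy. SEs carry the multiplicative inflation
    max(1, sqrt(Q_egger / (k - 2))); p-values use t(k - 2).
    """
    k = hset.n_snp
    if k < 3:
        return Unavailable("mr_egger", "requires at least 3 instruments", k)
    bx, _, by, sy = hset.arrays()
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise CollinearityError("all exposure effects identical after orientation")

    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    q_egger = float(np.sum(w * resid**2))
    df = k - 2
    infl = max(1.0, float(np.sqrt(q_egger / df)))
    cov = np.linalg.inv(xtwx)
    se_int, se_slope = np.sqrt(np.diag(cov)) * infl
    ref = f"t({df})"

    def _t_p(z):
        return float(2.0 * stats.t.sf(abs(z), df))

    tcrit = float(stats.t.ppf(0.975, df))
    slope = MrResult(
        "mr_egger",
        float(coef[1]),
        float(se_slope),
        _t_p(coef[1] / se_slope),
        k,
        ci_low=float(coef[1] - tcrit * se_slope),
        ci_high=float(coef[1] + tcrit * se_slope),
        reference=ref,
        inflation=infl,
    )
    intercept = EggerIntercept(float(coef[0]), float(se_int), _t_p(coef[0] / se_int), ref)
    return EggerResult(slope, intercept)


def run_all_estimators(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> dict[str, MrResult | Unavailable]:
    """All applicable estimators for one pair, keyed by method name.

    A single-instrument pair reports the Wald ratio under the "ivw" slot as
    well (IVW degenerates to it exactly), so downstream ranking by IVW p is
    defined for every pair.
    """
    out: dict[str, MrResult | Unavailable] = {}
    k = hset.n_snp
    if k == 0:
        raise EmptyInstrumentSetError(f"{hset.exposure_name} vs {hset.outcome_name}: no instruments")
    out["wald_ratio"] = (
        wald_ratio(hset.instruments[0]) if k == 1
        else Unavailable("wald_ratio", "single-SNP method", k)
    )
    out["ivw"] = ivw(hset)
    out["weighted_median"] = weighted_median(hset, n_boot=n_boot, seed=seed)
    egger = mr_egger(hset)
    if isinstance(egger, Unavailable):
        out["mr_egger"] = egger
        out["egger_intercept"] = egger
    else:
        out["mr_egger"] = egger.slope
        out["egger_intercept"] = egger.intercept
    return out
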