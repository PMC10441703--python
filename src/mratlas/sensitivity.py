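"""Heterogeneity and horizontal-pleiotropy battery.

Cochran's Q with I^2, the MR-PRESSO resampling framework (global residual
test, per-SNP outlier test with Bonferroni correction, outlier-corrected
estimate, distortion test), and tidy data tables for funnel and scatter
plots. All Monte-Carlo procedures are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSetError, Unavailable
from .estimators import EggerResult, MrResult, ivw, mr_egger, _ivw_core
from .sumstats import HarmonizedSet


@dataclass(frozen=True)
class QResult:
    q_stat: float
    q_df: int
    q_pvalue: float
    i2: float  # percentage in [0, 100]


def cochran_q(hset: HarmonizedSet) -> QResult | Unavailable:
    """Cochran's Q of the per-SNP ratio estimates around the IVW estimate.

    With weights w_j = (beta_Xj / se_Yj)^2 this equals the weighted residual
    sum of squares of the origin-constrained IVW regression. I^2 is the
    percentage of dispersion beyond chance:
    max(0, (Q - df) / Q) * 100 (0 when Q = 0).
    """
    k = hset.n_snp
    if k < 2:
        return Unavailable("cochran_q", "requires at least 2 instruments", k)
    bx, _, by, sy = hset.arrays()
    _, _, q = _ivw_core(bx, by, sy)
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    return QResult(q, df, p, i2)


@dataclass(frozen=True)
class PressoResult:
    global_rss: float
    global_p: float  # Monte-Carlo proportion, floored at 1/n_sim
    global_p_label: str  # e.g. "0.014" or "<0.001"
    outlier_p: pd.Series  # Bonferroni-corrected per-SNP p, indexed by snp_id
    outliers: tuple[str, ...]
    corrected: MrResult | None  # IVW without outliers; present iff outliers
    distortion_p: float | None
    n_sim: int


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult | Unavailable:
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is the leave-one-out weighted residual sum of
    squares RSS = sum_j w_j (beta_Yj - beta_Xj * b_(-j))^2, w_j = 1/se_Yj^2,
    where b_(-j) is the IVW slope fitted without SNP j. Its null
    distribution comes from ``n_sim`` parametric draws
    beta*_Yj ~ N(beta_Xj * b_(-j), se_Yj), beta*_Xj ~ N(beta_Xj, se_Xj),
    each scored with its own leave-one-out slopes. Per-SNP outlier p-values
    compare each SNP's observed residual contribution against its simulated
    contributions, Bonferroni-corrected by k. The distortion test compares
    the outlier-corrected IVW estimate against estimates obtained by
    removing random instrument subsets of the same size.
    """
    k = hset.n_snp
    if k < 4:
        return Unavailable("mr_presso", "requires at least 4 instruments", k)
    if seed is None:
        raise ValueError("mr_presso requires an explicit seed")
    bx, sx, by, sy = hset.arrays()
    w = 1.0 / sy**2

    loo_b = _loo_slopes(bx[None, :], by[None, :], w)[0]
    obs_contrib = w * (by - bx * loo_b) ** 2
    obs_rss = float(np.sum(obs_contrib))

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, k))
    by_s = rng.normal(bx * loo_b, sy, size=(n_sim, k))
    loo_s = _loo_slopes(bx_s, by_s, w)
    contrib_s = w * (by_s - bx_s * loo_s) ** 2
    rss_s = contrib_s.sum(axis=1)

    exceed = int(np.sum(rss_s >= obs_rss))
    global_p = exceed / n_sim
    if exceed == 0:
        global_p = 1.0 / n_sim
        label = f"<{1.0 / n_sim:g}"
    else:
        label = f"{global_p:g}"

    per_snp_p = np.mean(contrib_s >= obs_contrib, axis=0)
    corrected_p = np.minimum(1.0, per_snp_p * k)
    ids = [inst.snp_id for inst in hset.instruments]
    outlier_mask = corrected_p < outlier_alpha
    outliers = tuple(np.array(ids)[outlier_mask])

    corrected = None
    distortion_p = None
    if outlier_mask.any():
        if outlier_mask.all():
            raise DegenerateSetError("every instrument flagged as an MR-PRESSO outlier")
        kept = HarmonizedSet(
            hset.exposure_name,
            hset.outcome_name,
            [inst for inst, o in zip(hset.instruments, outlier_mask) if not o],
        )
        corrected = ivw(kept)
        distortion_p = _distortion_test(
            bx, by, sy, int(outlier_mask.sum()), corrected.estimate, rng, n_sim
        )
    return PressoResult(
        global_rss=obs_rss,
        global_p=global_p,
        global_p_label=label,
        outlier_p=pd.Series(corrected_p, index=ids, name="presso_outlier_p"),
        outliers=outliers,
        corrected=corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
    )


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized over rows of (bx, by)."""
    sxy = np.sum(w * bx * by, axis=1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _distortion_test(bx, by, sy, n_out, corrected_est, rng, n_sim) -> float:
    """Permutation-style distortion p: how often does removing a random
    subset of ``n_out`` instruments distort the full-set IVW estimate at
    least as much as removing the detected outliers did?"""
    k = len(bx)
    w = 1.0 / sy**2
    full_est, _, _ = _ivw_core(bx, by, sy)
    if full_est == 0:
        return 1.0
    d_obs = abs((corrected_est - full_est) / full_est)
    sxy_tot = np.sum(w * bx * by)
    sxx_tot = np.sum(w * bx * bx)
    count = 0
    for _ in range(n_sim):
        idx = rng.choice(k, size=n_out, replace=False)
        est = (sxy_tot - np.sum(w[idx] * bx[idx] * by[idx])) / (
            sxx_tot - np.sum(w[idx] * bx[idx] * bx[idx])
        )
        if abs((est - full_est) / full_est) >= d_obs:
            count += 1
    return count / n_sim


@dataclass
class SensitivityReport:
    """Full heterogeneity/pleiotropy battery for one exposure-outcome pair."""

    q: QResult | Unavailable
    egger: EggerResult | Unavailable
    presso: PressoResult | Unavailable

    def to_dict(self) -> dict:
        d: dict = {}
        if isinstance(self.q, QResult):
            d.update(q_stat=self.q.q_stat, q_df=self.q.q_df, q_pvalue=self.q.q_pvalue, i2=self.q.i2)
        if isinstance(self.egger, EggerResult):
            d.update(
                egger_intercept=self.egger.intercept.estimate,
                egger_intercept_se=self.egger.intercept.se,
                egger_intercept_p=self.egger.intercept.pvalue,
            )
        if isinstance(self.presso, PressoResult):
            d.update(
                presso_global_p=self.presso.global_p,
                presso_global_p_label=self.presso.global_p_label,
                presso_outliers=",".join(self.presso.outliers),
                presso_distortion_p=self.presso.distortion_p,
            )
            if self.presso.corrected is not None:
                d.update(
                    presso_corrected_b=self.presso.corrected.estimate,
                    presso_corrected_se=self.presso.corrected.se,
                    presso_corrected_p=self.presso.corrected.pvalue,
                )
        return d


def sensitivity_report(
    hset: HarmonizedSet, n_sim: int = 1000, seed: int | None = None, outlier_alpha: float = 0.05
) -> SensitivityReport:
    return SensitivityReport(
        q=cochran_q(hset),
        egger=mr_egger(hset) if hset.n_snp >= 3 else Unavailable("mr_egger", "requires at least 3 instruments", hset.n_snp),
        presso=mr_presso(hset, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)
        if hset.n_snp >= 4
        else Unavailable("mr_presso", "requires at least 4 instruments", hset.n_snp),
    )


# ---------------------------------------------------------------------------
# plot-ready tables
# ---------------------------------------------------------------------------


def funnel_data(hset: HarmonizedSet, results: dict[str, MrResult] | None = None) -> pd.DataFrame:
    """Funnel-plot table: per-SNP ratio estimate against its precision, plus
    one vertical reference line per computed method."""
    bx, _, by, sy = hset.arrays()
    ratio = by / bx
    precision = np.abs(bx) / sy  # 1 / se(ratio), first order
    rows = [
        {"kind": "snp", "snp_id": inst.snp_id, "ratio": r, "precision": p, "method": ""}
        for inst, r, p in zip(hset.instruments, ratio, precision)
    ]
    for name, res in (results or {}).items():
        if isinstance(res, MrResult):
            rows.append(
                {"kind": "reference", "snp_id": "", "ratio": res.estimate, "precision": np.nan,
                 "method": name}
            )
    return pd.DataFrame(rows, columns=["kind", "snp_id", "ratio", "precision", "method"])


def scatter_data(hset: HarmonizedSet, results: dict[str, MrResult] | None = None) -> pd.DataFrame:
    """Scatter-plot table: (beta_X, beta_Y) with SEs, plus per-method fitted
    lines (slope and intercept; intercept nonzero only for MR-Egger)."""
    rows = [
        {
            "kind": "snp",
            "snp_id": inst.snp_id,
            "beta_exposure": inst.beta_exposure,
            "beta_outcome": inst.beta_outcome,
            "se_exposure": inst.se_exposure,
            "se_outcome": inst.se_outcome,
            "method": "",
            "slope": np.nan,
            "intercept": np.nan,
        }
        for inst in hset.instruments
    ]
    for name, res in (results or {}).items():
        if isinstance(res, MrResult):
            rows.append(
                {
                    "kind": "line",
                    "snp_id": "",
                    "beta_exposure": np.nan,
                    "beta_outcome": np.nan,
                    "se_exposure": np.nan,
                    "se_outcome": np.nan,
                    "method": name,
                    "slope": res.estimate,
                    "intercept": 0.0,
                }
            )
    return pd.DataFrame(rows)
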