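"""Reusable validation experiments over the synthetic generator.

Each function runs a replicated study-design experiment (type-I calibration,
intercept uniformity, parameter recovery, power agreement, outlier recall,
coding-flip invariance) and returns plain dictionaries/DataFrames. The
acceptance script and the analysis drivers both call these, so the numbers
they report are always produced by the same code path.

Replicate seeds are spawned from a single base seed via SeedSequence, so
every experiment is reproducible from one integer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import is_unavailable
from .estimators import ivw, mr_egger
from .instruments import clump, select_candidates
from .pipeline import meta_analyze_cohorts
from .sensitivity import mr_presso
from .simulate import CohortSpec, SimulationConfig, empirical_power, preset_config, simulate_study
from .atlas import min_detectable_or, power_binary
from .sumstats import HarmonizedSet, harmonize_pair


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def random_instrument_set(rng: np.random.Generator, k: int | None = None) -> HarmonizedSet:
    """Random harmonized instrument set (k <= 20) for oracle comparisons."""
    from .sumstats import HarmonizedInstrument

    k = k or int(rng.integers(2, 21))
    bx = rng.normal(0.1, 0.05, k)
    bx[np.abs(bx) < 1e-3] = 0.05
    by = rng.normal(0.0, 0.05, k)
    sy = rng.uniform(0.01, 0.08, k)
    sx = rng.uniform(0.005, 0.02, k)
    instruments = [
        HarmonizedInstrument(f"rs{i + 1}", bx[i], sx[i], by[i], sy[i]) for i in range(k)
    ]
    return HarmonizedSet("exp", "out", instruments)


def _meta_outcome(study) -> pd.DataFrame:
    return meta_analyze_cohorts([study.outcomes[c.name] for c in study.config.cohorts])


def harmonize_selected(study, outcome: pd.DataFrame | None = None) -> HarmonizedSet:
    """Full instrument path: significance/MAF selection, clumping, harmonization."""
    if outcome is None:
        outcome = _meta_outcome(study)
    selected = clump(select_candidates(study.exposure), study.ld_panel)
    return harmonize_pair(selected, outcome, study.ld_panel)


def harmonize_truth_instruments(study, outcome: pd.DataFrame | None = None) -> HarmonizedSet:
    """Harmonize the generator's known causal SNPs, bypassing p-value selection.

    Used by estimator-recovery experiments, where re-selecting instruments on
    the same data would add winner's-curse bias that is a property of
    selection, not of the estimators under test.
    """
    if outcome is None:
        outcome = _meta_outcome(study)
    exp = study.exposure[study.exposure["snp_id"].isin(study.truth["causal_ids"])]
    return harmonize_pair(exp, outcome, study.ld_panel)


# ---------------------------------------------------------------------------
# calibration under the null
# ---------------------------------------------------------------------------


def null_calibration(
    n_reps: int = 500, seed: int = 0, alpha: float = 0.05, presso_n_sim: int = 500
) -> dict:
    """Type-I error of the random-effects IVW test and the MR-PRESSO global
    test under the no-effect, no-pleiotropy preset (full selection path)."""
    ivw_rej, presso_rej = [], []
    for sd in _spawn_seeds(seed, n_reps):
        study = simulate_study(preset_config("null", seed=sd))
        hset = harmonize_selected(study)
        if hset.n_snp >= 2:
            ivw_rej.append(ivw(hset).pvalue < alpha)
        if hset.n_snp >= 4:
            presso = mr_presso(hset, n_sim=presso_n_sim, seed=sd + 1)
            presso_rej.append(presso.global_p < alpha)
    ivw_rate = float(np.mean(ivw_rej))
    presso_rate = float(np.mean(presso_rej))
    return {
        "ivw_type1": ivw_rate,
        "ivw_mc_se": float(np.sqrt(ivw_rate * (1 - ivw_rate) / len(ivw_rej))),
        "n_ivw": len(ivw_rej),
        "presso_type1": presso_rate,
        "presso_mc_se": float(np.sqrt(presso_rate * (1 - presso_rate) / max(len(presso_rej), 1))),
        "n_presso": len(presso_rej),
        "alpha": alpha,
    }


def egger_intercept_uniformity(n_reps: int = 500, seed: int = 0) -> dict:
    """KS test of MR-Egger intercept p-values against uniform under balanced
    (mean-zero) pleiotropy, where the intercept null holds but per-SNP
    heterogeneity is real."""
    pvals = []
    for sd in _spawn_seeds(seed, n_reps):
        study = simulate_study(preset_config("balanced_pleio", seed=sd))
        hset = harmonize_selected(study)
        if hset.n_snp >= 3:
            egger = mr_egger(hset)
            if not is_unavailable(egger):
                pvals.append(egger.intercept.pvalue)
    ks = stats.kstest(pvals, "uniform")
    return {"ks_stat": float(ks.statistic), "ks_pvalue": float(ks.pvalue), "n": len(pvals)}


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


def parameter_recovery(
    n_reps: int = 500, seed: int = 0, true_or: float = 1.28, n_snps: int = 6
) -> dict:
    """Mean IVW estimate and 95% CI coverage at a known causal OR per SD.

    The default design shape (six instruments, OR 1.28) mirrors a
    well-supported micronutrient-cancer association."""
    b = float(np.log(true_or))
    ests, cover = [], []
    for sd in _spawn_seeds(seed, n_reps):
        study = simulate_study(
            preset_config("causal", seed=sd, true_log_or=b, n_snps_causal=n_snps)
        )
        hset = harmonize_truth_instruments(study)
        res = ivw(hset)
        ests.append(res.estimate)
        cover.append(res.ci_low <= b <= res.ci_high)
    ests = np.asarray(ests)
    coverage = float(np.mean(cover))
    return {
        "true_log_or": b,
        "true_or": true_or,
        "mean_estimate": float(ests.mean()),
        "mean_or": float(np.exp(ests.mean())),
        "mc_se": float(ests.std(ddof=1) / np.sqrt(len(ests))),
        "coverage": coverage,
        "coverage_mc_se": float(np.sqrt(coverage * (1 - coverage) / len(ests))),
        "n": len(ests),
    }


# ---------------------------------------------------------------------------
# power self-consistency
# ---------------------------------------------------------------------------


def power_agreement(
    seed: int = 0,
    n_reps: int = 500,
    n_grid: tuple[int, ...] = (100_000, 300_000, 600_000),
    or_grid: tuple[float, ...] = (1.1, 1.3, 1.6),
    case_fraction: float = 0.1,
    r2: float = 0.02,
    k: int = 10,
    exposure_n: int = 100_000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Analytic power versus Monte-Carlo rejection rate over an (n, OR) grid."""
    rows = []
    seeds = iter(_spawn_seeds(seed, len(n_grid) * len(or_grid)))
    for n_total in n_grid:
        for or_alt in or_grid:
            analytic = power_binary(n_total, case_fraction, r2, or_alt, alpha)
            config = SimulationConfig(
                seed=next(seeds),
                n_snps_causal=k,
                true_log_or=float(np.log(or_alt)),
                exposure_n=exposure_n,
                exposure_r2=r2,
                cohorts=(CohortSpec("single", n_total, case_fraction),),
            )
            empirical, mc_se = empirical_power(config, n_reps=n_reps, alpha=alpha)
            rows.append(
                {
                    "n_total": n_total,
                    "or_alt": or_alt,
                    "analytic_power": analytic,
                    "empirical_power": empirical,
                    "mc_se": mc_se,
                    "abs_diff": abs(analytic - empirical),
                }
            )
    return pd.DataFrame(rows)


def min_detectable_or_roundtrip(seed: int = 0, n_draws: int = 50) -> dict:
    """power(min_detectable_or(...)) must return the target power.

    Random parameter draws across realistic ranges; returns the worst
    absolute deviation from the 0.8 target."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    checked = 0
    for _ in range(n_draws):
        n_total = float(rng.uniform(2e4, 8e5))
        cf = float(rng.uniform(0.01, 0.5))
        r2 = float(rng.uniform(0.005, 0.05))
        mdor = min_detectable_or(n_total, cf, r2, target_power=0.8)
        if np.isinf(mdor):
            continue
        worst = max(worst, abs(power_binary(n_total, cf, r2, mdor) - 0.8))
        checked += 1
    return {"max_abs_error": worst, "n_checked": checked}


# ---------------------------------------------------------------------------
# robustness plumbing
# ---------------------------------------------------------------------------


def outlier_recall(n_reps: int = 200, seed: int = 0, presso_n_sim: int = 500) -> dict:
    """How often MR-PRESSO flags a planted 10-SE pleiotropic outlier, and how
    often removing it moves the IVW estimate toward the truth."""
    detected, closer = [], []
    for sd in _spawn_seeds(seed, n_reps):
        study = simulate_study(preset_config("outlier", seed=sd))
        hset = harmonize_truth_instruments(study)
        if hset.n_snp < 4:
            continue
        presso = mr_presso(hset, n_sim=presso_n_sim, seed=sd + 1)
        planted = set(study.truth["outlier_ids"])
        hit = bool(planted & set(presso.outliers))
        detected.append(hit)
        if hit and presso.corrected is not None:
            b = study.truth["true_log_or"]
            closer.append(abs(presso.corrected.estimate - b) < abs(ivw(hset).estimate - b))
    rate = float(np.mean(detected))
    return {
        "recall": rate,
        "mc_se": float(np.sqrt(rate * (1 - rate) / len(detected))),
        "n": len(detected),
        "corrected_closer_rate": float(np.mean(closer)) if closer else float("nan"),
    }


def coding_flip_invariance(seed: int = 0) -> dict:
    """IVW estimates from a fully coding-flipped outcome dataset must equal
    the flip-free run exactly after harmonization (same seed, presentation
    stream only differs)."""
    flipped = simulate_study(preset_config("messy_alleles", seed=seed))
    clean = simulate_study(
        preset_config("messy_alleles", seed=seed, allele_flip_fraction=0.0,
                      strand_flip_fraction=0.0)
    )
    res_f = ivw(harmonize_selected(flipped))
    res_c = ivw(harmonize_selected(clean))
    diff = abs(res_f.estimate - res_c.estimate)
    return {
        "estimate_flipped": res_f.estimate,
        "estimate_clean": res_c.estimate,
        "abs_diff": diff,
        "n_snp_flipped": res_f.n_snp,
        "n_snp_clean": res_c.n_snp,
    }
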