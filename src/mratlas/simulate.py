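"""Synthetic paired exposure/outcome GWAS summary statistics with known truth.

The generator emulates the statistical structure two-sample MR assumes:
per-SNP exposure effects on the standardized-trait scale whose variance
explained sums to a target R^2, noisy summary estimates with the standard
binomial-variance standard errors, binary-outcome effects proportional to
the exposure effects through a true causal log-OR, optional horizontal
pleiotropy (balanced or directional) and a planted outlier, equicorrelated
LD blocks with proxy partners, palindromic SNPs with minor allele
frequencies straddling the 0.42 inferability limit, and effect-allele coding
and strand discordance between datasets. Everything is reproducible from a
single integer seed, and a truth record sufficient to score every detection
task is returned alongside the tables.

Summary statistics are simulated directly; no individual-level genotypes are
generated. Independent draws per SNP mean the estimates ignore the sampling
correlation that LD induces between a lead SNP and its partners.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .instruments import LdPanel

_NONPAL_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"), ("G", "A"), ("G", "T"),
                 ("T", "C"), ("T", "G")]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class CohortSpec:
    """One binary-outcome GWAS cohort."""

    name: str
    n_total: int
    case_fraction: float


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated exposure-outcome dataset.

    Defaults mirror a well-powered micronutrient-style design: ten causal
    instruments explaining 2% of the exposure variance in a 100k-participant
    exposure GWAS, two outcome cohorts of biobank scale, and moderate
    allele-bookkeeping mess (palindromes, coding flips, strand flips).
    Pleiotropy magnitudes are expressed as multiples of the median
    outcome-side standard error, so "scale 1.5" means pleiotropic effects
    comparable to, but somewhat larger than, the sampling noise.
    """

    seed: int
    n_snps_causal: int = 10
    n_snps_null: int = 40
    true_log_or: float = 0.0
    exposure_n: int = 100_000
    exposure_r2: float = 0.02
    cohorts: tuple[CohortSpec, ...] = (
        CohortSpec("cohort_a", 300_000, 0.10),
        CohortSpec("cohort_b", 220_000, 0.06),
    )
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_fraction: float = 0.3
    pleiotropy_scale: float = 1.5  # x median outcome se
    outlier_scale: float = 0.0  # x that SNP's outcome se; 0 disables
    ld_partners: int = 2  # proxy partners per causal SNP
    ld_r2: float = 0.9
    palindrome_fraction: float = 0.2
    allele_flip_fraction: float = 0.3  # outcome coded on the other allele
    strand_flip_fraction: float = 0.1  # outcome reported on the other strand
    cohort_heterogeneity_sd: float = 0.0  # cohort-level log-OR noise

    def validate(self) -> None:
        for name in ("pleiotropy_fraction", "palindrome_fraction",
                     "allele_flip_fraction", "strand_flip_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if self.n_snps_causal < 1 or self.exposure_n < 2:
            raise ConfigurationError("need at least one causal SNP and two participants")
        if not 0 < self.exposure_r2 < 1:
            raise ConfigurationError(f"exposure_r2 must be in (0, 1), got {self.exposure_r2}")
        # each causal SNP carries r2/k; 2 f (1-f) beta^2 <= r2/k must admit beta
        if self.exposure_r2 / self.n_snps_causal >= 0.5:
            raise ConfigurationError("exposure_r2 infeasible for the number of causal SNPs")


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    exposure: pd.DataFrame
    outcomes: dict[str, pd.DataFrame]
    ld_panel: LdPanel
    truth: dict

    def write(self, outdir) -> dict[str, Path]:
        """Emit the summary-stat tables, LD panel and truth sidecar as text."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"exposure": outdir / "exposure.tsv"}
        self.exposure.to_csv(paths["exposure"], sep="\t", index=False)
        for name, df in self.outcomes.items():
            paths[name] = outdir / f"outcome_{name}.tsv"
            df.to_csv(paths[name], sep="\t", index=False)
        paths["ld_panel"] = outdir / "ld_panel.tsv"
        self.ld_panel.to_square_file(paths["ld_panel"])
        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_jsonable)
        return paths


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw one complete exposure/outcome study from the configured model.

    Independent random streams drive (a) allele/frequency structure,
    (b) true effects and pleiotropy, (c) exposure sampling noise,
    (d) outcome sampling noise, and (e) presentation (coding and strand
    flips), so changing a presentation fraction leaves the underlying
    effects byte-identical -- the basis of the end-to-end coding-invariance
    checks.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_eff, rng_xnoise, rng_ynoise, rng_present = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    k = config.n_snps_causal
    n_partner = k * config.ld_partners
    m = k + n_partner + config.n_snps_null  # total SNPs

    # --- identifiers, blocks, positions -------------------------------
    ids = np.array([f"rs{100001 + i}" for i in range(m)])
    lead_idx = np.arange(k)
    partner_idx = np.arange(k, k + n_partner)
    null_idx = np.arange(k + n_partner, m)
    block_of = np.full(m, -1)
    block_of[lead_idx] = lead_idx
    if n_partner:
        block_of[partner_idx] = np.repeat(lead_idx, config.ld_partners)
    positions = {}
    offset_in_block = np.zeros(m, int)
    if n_partner:
        offset_in_block[partner_idx] = np.tile(np.arange(1, config.ld_partners + 1), k)
    for i in range(m):
        block = block_of[i] if block_of[i] >= 0 else i
        positions[ids[i]] = int((block + 1) * 1_000_000 + offset_in_block[i] * 1_000)

    # --- alleles and frequencies (structure stream) -------------------
    pal_u = rng_struct.uniform(size=m)
    f_u = rng_struct.uniform(0.05, 0.95, size=m)
    pal_maf = rng_struct.uniform(0.30, 0.50, size=m)  # straddles the 0.42 rule
    side_u = rng_struct.uniform(size=m)
    pair_choice = rng_struct.integers(0, 8, size=m)
    pal_pair_choice = rng_struct.integers(0, 4, size=m)

    is_pal = pal_u < config.palindrome_fraction
    eaf = f_u.copy()
    eaf[is_pal] = np.where(side_u[is_pal] < 0.5, pal_maf[is_pal], 1.0 - pal_maf[is_pal])
    # partners share their lead's frequency (high LD implies similar MAF)
    if n_partner:
        eaf[partner_idx] = eaf[block_of[partner_idx]]
        is_pal[partner_idx] = False  # keep proxies orientable by construction
    ea = np.empty(m, dtype="<U1")
    oa = np.empty(m, dtype="<U1")
    for i in range(m):
        pair = _PAL_PAIRS[pal_pair_choice[i]] if is_pal[i] else _NONPAL_PAIRS[pair_choice[i]]
        ea[i], oa[i] = pair

    # --- true effects (effects stream) --------------------------------
    het = 2.0 * eaf * (1.0 - eaf)
    g = rng_eff.normal(size=k)
    signs = rng_eff.choice([-1.0, 1.0], size=k)
    scale = np.sqrt(config.exposure_r2 / np.sum(het[lead_idx] * g**2))
    beta_x = np.zeros(m)
    beta_x[lead_idx] = signs * np.abs(g) * scale
    if n_partner:
        beta_x[partner_idx] = np.sqrt(config.ld_r2) * beta_x[block_of[partner_idx]]

    se_y_by_cohort = {
        c.name: 1.0 / np.sqrt(het * c.n_total * c.case_fraction * (1.0 - c.case_fraction))
        for c in config.cohorts
    }
    med_se_y = float(np.median(se_y_by_cohort[config.cohorts[0].name][lead_idx]))
    alpha = np.zeros(m)
    pleio_u = rng_eff.uniform(size=k)
    pleio_draw = rng_eff.normal(size=k)
    pleio_ids: list[str] = []
    if config.pleiotropy != "none":
        sel = pleio_u < config.pleiotropy_fraction
        mag = config.pleiotropy_scale * med_se_y
        if config.pleiotropy == "balanced":
            alpha[lead_idx[sel]] = mag * pleio_draw[sel]
        else:  # directional: positive-mean offsets
            alpha[lead_idx[sel]] = mag + 0.5 * mag * np.abs(pleio_draw[sel])
        pleio_ids = list(ids[lead_idx[sel]])
    outlier_pick = int(rng_eff.integers(0, k))
    outlier_ids: list[str] = []
    if config.outlier_scale > 0:
        j = lead_idx[outlier_pick]
        alpha[j] += config.outlier_scale * se_y_by_cohort[config.cohorts[0].name][j]
        outlier_ids = [str(ids[j])]
    if n_partner:
        alpha[partner_idx] = np.sqrt(config.ld_r2) * alpha[block_of[partner_idx]]

    # --- exposure table (exposure-noise stream) -----------------------
    se_x = 1.0 / np.sqrt(het * config.exposure_n)
    bhat_x = beta_x + rng_xnoise.normal(size=m) * se_x
    p_x = 2.0 * stats.norm.sf(np.abs(bhat_x / se_x))
    exposure = pd.DataFrame(
        {
            "snp_id": ids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": bhat_x,
            "se": se_x,
            "pvalue": np.clip(p_x, np.nextafter(0, 1), 1.0),
            "n": config.exposure_n,
        }
    )

    # --- outcome tables (outcome-noise + presentation streams) --------
    beta_y_true = config.true_log_or * beta_x + alpha
    outcomes: dict[str, pd.DataFrame] = {}
    flips: dict[str, list[str]] = {}
    strand: dict[str, list[str]] = {}
    for c in config.cohorts:
        se_y = se_y_by_cohort[c.name]
        cohort_shift = (
            rng_ynoise.normal() * config.cohort_heterogeneity_sd * beta_x
            if config.cohort_heterogeneity_sd > 0
            else 0.0
        )
        bhat_y = beta_y_true + cohort_shift + rng_ynoise.normal(size=m) * se_y
        p_y = 2.0 * stats.norm.sf(np.abs(bhat_y / se_y))
        flip_mask = rng_present.uniform(size=m) < config.allele_flip_fraction
        strand_mask = (rng_present.uniform(size=m) < config.strand_flip_fraction) & ~is_pal
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        c_ea, c_oa = ea.copy(), oa.copy()
        c_eaf, c_beta = eaf.copy(), bhat_y.copy()
        for i in np.nonzero(strand_mask)[0]:
            c_ea[i], c_oa[i] = comp[c_ea[i]], comp[c_oa[i]]
        for i in np.nonzero(flip_mask)[0]:
            c_ea[i], c_oa[i] = c_oa[i], c_ea[i]
            c_beta[i] = -c_beta[i]
            c_eaf[i] = 1.0 - c_eaf[i]
        n_cases = round(c.n_total * c.case_fraction)
        outcomes[c.name] = pd.DataFrame(
            {
                "snp_id": ids,
                "effect_allele": c_ea,
                "other_allele": c_oa,
                "eaf": c_eaf,
                "beta": c_beta,
                "se": se_y,
                "pvalue": np.clip(p_y, np.nextafter(0, 1), 1.0),
                "n": c.n_total,
                "n_cases": n_cases,
                "n_controls": c.n_total - n_cases,
            }
        )
        flips[c.name] = list(ids[flip_mask])
        strand[c.name] = list(ids[strand_mask])

    # --- LD panel ------------------------------------------------------
    r2 = np.eye(m)
    if n_partner:
        for lead in lead_idx:
            members = np.concatenate([[lead], partner_idx[block_of[partner_idx] == lead]])
            for a in members:
                for b in members:
                    if a != b:
                        r2[a, b] = config.ld_r2
    panel = LdPanel(list(ids), r2, positions)

    truth = {
        "true_log_or": config.true_log_or,
        "causal_ids": list(ids[lead_idx]),
        "partner_ids": list(ids[partner_idx]),
        "null_ids": list(ids[null_idx]),
        "true_beta_exposure": {str(s): float(b) for s, b in zip(ids, beta_x)},
        "pleiotropy_offsets": {str(s): float(a) for s, a in zip(ids, alpha) if a != 0.0},
        "pleiotropic_ids": pleio_ids,
        "outlier_ids": outlier_ids,
        "palindromic_ids": list(ids[is_pal]),
        "flipped_ids": flips,
        "strand_flipped_ids": strand,
    }
    return SimulatedStudy(config, exposure, outcomes, panel, truth)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------


def preset_config(name: str, seed: int, **overrides) -> SimulationConfig:
    """Named scenario presets.

    ``null``: no causal effect, no pleiotropy. ``causal``: OR 1.28 per SD
    with six instruments (the headline breast-cancer design shape).
    ``balanced_pleio`` / ``directional_pleio``: pleiotropy on 30% of
    instruments. ``outlier``: a single planted pleiotropic outlier at ten
    outcome standard errors. ``messy_alleles``: every outcome SNP coded on
    the opposite allele plus heavy palindrome/strand mess.
    """
    presets: dict[str, dict] = {
        "null": {},
        "causal": {"true_log_or": float(np.log(1.28)), "n_snps_causal": 6},
        "balanced_pleio": {"pleiotropy": "balanced"},
        "directional_pleio": {"pleiotropy": "directional"},
        "outlier": {"outlier_scale": 10.0},
        "messy_alleles": {
            "allele_flip_fraction": 1.0,
            "strand_flip_fraction": 0.3,
            "palindrome_fraction": 0.3,
        },
    }
    if name not in presets:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    params = dict(presets[name])
    params.update(overrides)
    return SimulationConfig(seed=seed, **params)


PRESET_NAMES = ("null", "causal", "balanced_pleio", "directional_pleio", "outlier", "messy_alleles")


# ---------------------------------------------------------------------------
# empirical power oracle
# ---------------------------------------------------------------------------


def empirical_power(
    config: SimulationConfig,
    n_reps: int,
    alpha: float = 0.05,
    seed: int | None = None,
    random_effects: bool = False,
) -> tuple[float, float]:
    """Monte-Carlo rejection rate of the IVW test under the configured model.

    Returns (rate, Monte-Carlo standard error). The replicate loop is
    vectorized over a reduced model containing only the causal instruments
    (selection and harmonization are exercised elsewhere; with instrument
    F >> 10 they do not move power). Outcome cohorts are pooled per SNP by
    fixed-effect meta-analysis. The fixed-effect IVW p-value is the default
    reference here because the analytic power formula models the
    fixed-effect test; set ``random_effects`` to probe the random-effects
    variant instead.
    """
    if n_reps < 100:
        raise ConfigurationError("empirical_power needs at least 100 replicates")
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    k = config.n_snps_causal
    f = rng.uniform(0.05, 0.95, size=(n_reps, k))
    het = 2.0 * f * (1.0 - f)
    g = rng.normal(size=(n_reps, k))
    bx_true = g * np.sqrt(config.exposure_r2 / np.sum(het * g**2, axis=1, keepdims=True))
    se_x = 1.0 / np.sqrt(het * config.exposure_n)
    bx = bx_true + rng.normal(size=(n_reps, k)) * se_x

    wsum = np.zeros((n_reps, k))
    by_num = np.zeros((n_reps, k))
    for c in config.cohorts:
        se_y = 1.0 / np.sqrt(het * c.n_total * c.case_fraction * (1.0 - c.case_fraction))
        bhat = config.true_log_or * bx_true + rng.normal(size=(n_reps, k)) * se_y
        w = 1.0 / se_y**2
        wsum += w
        by_num += w * bhat
    by = by_num / wsum
    sy2 = 1.0 / wsum

    w = 1.0 / sy2
    sxx = np.sum(w * bx * bx, axis=1)
    est = np.sum(w * bx * by, axis=1) / sxx
    se_fixed = 1.0 / np.sqrt(sxx)
    se = se_fixed
    if random_effects:
        q = np.sum(w * (by - est[:, None] * bx) ** 2, axis=1)
        se = se_fixed * np.maximum(1.0, np.sqrt(q / (k - 1)))
    p = 2.0 * stats.norm.sf(np.abs(est / se))
    rate = float(np.mean(p < alpha))
    mc_se = float(np.sqrt(rate * (1.0 - rate) / n_reps))
    return rate, mc_se


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cohorts"] = [dataclasses.asdict(c) for c in config.cohorts]
    return d
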