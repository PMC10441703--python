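"""Config-driven orchestration of the full exposure-by-outcome MR grid.

select instruments -> clump -> (meta-analyze outcome cohorts) -> harmonize
-> estimate -> sensitivity battery -> power -> tiered atlas. Every pair is
processed independently: a pair that cannot be analyzed (no instruments, no
overlap) yields a reason-coded atlas row, never an aborted grid.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import PowerReport, assemble_atlas, bonferroni_tiers, format_or, meta_fixed
from .errors import ConfigurationError, is_unavailable
from .estimators import MrResult, run_all_estimators
from .instruments import LdPanel, clump, confounder_screen, instrument_strength, select_candidates
from .sensitivity import funnel_data, scatter_data, sensitivity_report
from .sumstats import (
    HarmonizePolicy,
    frame_to_rows,
    harmonize_pair,
    is_palindromic,
    read_summary_stats,
    rows_to_frame,
    _orient_by_frequency,
    align_to_effect_allele,
)

log = logging.getLogger("mratlas")


@dataclass
class ExposureSpec:
    name: str
    path: str


@dataclass
class OutcomeSpec:
    name: str
    family: str
    cohort_paths: list[str]


@dataclass
class RunConfig:
    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    seed: int
    output_dir: str = "mratlas_out"
    ld_panel: str | None = None
    confounders: dict[str, str] = field(default_factory=dict)
    # module thresholds (defaults follow the module-level conventions)
    p_threshold: float = 5e-8
    maf_min: float = 0.01
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    proxy_r2_min: float = 0.8
    confounder_p_flag: float = 1e-5
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    alpha: float = 0.05
    power_or_grid: tuple[float, ...] = (1.1, 1.3, 1.6)
    family_sizes: dict[str, int] = field(default_factory=dict)  # override per family
    emit_plot_data: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunConfig":
        def _resolve(p):
            p = Path(p)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            return str(p)

        try:
            exposures = [ExposureSpec(e["name"], _resolve(e["path"])) for e in raw["exposures"]]
            outcomes = [
                OutcomeSpec(o["name"], o.get("family", "all"), [_resolve(p) for p in o["cohorts"]])
                for o in raw["outcomes"]
            ]
            seed = int(raw["seed"])
        except KeyError as exc:
            raise ConfigurationError(f"run config missing required key: {exc}") from exc
        kwargs = {
            k: raw[k]
            for k in (
                "p_threshold", "maf_min", "clump_r2", "clump_window_kb", "proxy_r2_min",
                "confounder_p_flag", "n_boot", "presso_n_sim", "presso_outlier_alpha",
                "alpha", "family_sizes", "emit_plot_data", "output_dir",
            )
            if k in raw
        }
        if "ld_panel" in raw and raw["ld_panel"]:
            kwargs["ld_panel"] = _resolve(raw["ld_panel"])
        if "confounders" in raw:
            kwargs["confounders"] = {k: _resolve(v) for k, v in raw["confounders"].items()}
        if "power_or_grid" in raw:
            kwargs["power_or_grid"] = tuple(raw["power_or_grid"])
        return cls(exposures=exposures, outcomes=outcomes, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# per-SNP cohort meta-analysis
# ---------------------------------------------------------------------------


def meta_analyze_cohorts(cohort_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect per-SNP meta-analysis of outcome cohorts.

    The first cohort fixes the allele orientation; later cohorts are aligned
    by allele labels (with strand complementation) or, for palindromic SNPs,
    by frequency concordance. SNPs present in only a subset of cohorts are
    pooled over the cohorts that carry them, as METAL-style tools do.
    """
    if len(cohort_tables) == 1:
        return cohort_tables[0].reset_index(drop=True)
    by_snp: dict[str, list] = {}
    order: list[str] = []
    for table in cohort_tables:
        for row in frame_to_rows(table):
            if row.snp_id not in by_snp:
                by_snp[row.snp_id] = []
                order.append(row.snp_id)
            by_snp[row.snp_id].append(row)

    merged = []
    for snp in order:
        rows = by_snp[snp]
        ref = rows[0]
        aligned = [ref]
        for other in rows[1:]:
            pal = is_palindromic(ref)
            if pal.palindromic:
                oriented = _orient_by_frequency(ref, other)
                if oriented is None:
                    aligned.append(other)  # unresolvable strand: trust labels
                else:
                    aligned.append(oriented[0])
            else:
                try:
                    aligned.append(align_to_effect_allele(other, ref.effect_allele).row)
                except Exception:
                    log.warning("cohort meta: allele mismatch at %s, cohort row skipped", snp)
        meta = meta_fixed([(r.beta, r.se) for r in aligned])
        n = sum(r.n for r in aligned)
        ncase = sum(r.n_cases or 0 for r in aligned)
        nctrl = sum(r.n_controls or 0 for r in aligned)
        eafs = [r.eaf for r in aligned if r.eaf is not None]
        ns = [r.n for r in aligned if r.eaf is not None]
        eaf = float(np.average(eafs, weights=ns)) if eafs else None
        merged.append(
            dataclasses.replace(
                ref, beta=meta.beta, se=meta.se, pvalue=meta.pvalue, n=n,
                eaf=eaf, n_cases=ncase or None, n_controls=nctrl or None,
            )
        )
    return rows_to_frame(merged)


# ---------------------------------------------------------------------------
# grid execution
# ---------------------------------------------------------------------------


def _flatten_result(name: str, res) -> dict:
    if is_unavailable(res):
        return {f"{name}_b": np.nan, f"{name}_se": np.nan, f"{name}_p": np.nan}
    assert isinstance(res, MrResult)
    or_, or_lo, or_hi = res.or_scale
    return {
        f"{name}_b": res.estimate,
        f"{name}_se": res.se,
        f"{name}_p": res.pvalue,
        f"{name}_lo95": res.ci_low,
        f"{name}_up95": res.ci_high,
        f"{name}_or": or_,
        f"{name}_or_lo95": or_lo,
        f"{name}_or_up95": or_hi,
    }


def run_atlas(config: RunConfig, write: bool = True):
    """Execute the full grid; returns (atlas DataFrame, run report dict).

    When ``write`` is true the atlas table, tier counts, and a structured
    run report (config echo, seeds, per-pair instrument counts, thresholds
    actually applied) land in ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    panel = LdPanel.from_square_file(config.ld_panel) if config.ld_panel else None
    policy = HarmonizePolicy(proxy_r2_min=config.proxy_r2_min)

    confounder_tables = {}
    for name, path in config.confounders.items():
        confounder_tables[name] = read_summary_stats(path).rows

    # read + select instruments once per exposure
    exposure_instruments: dict[str, pd.DataFrame] = {}
    exposure_strength: dict[str, object] = {}
    read_issues: dict[str, int] = {}
    for exp in config.exposures:
        res = read_summary_stats(exp.path)
        read_issues[exp.name] = len(res.errors)
        cand = select_candidates(res.rows, config.p_threshold, config.maf_min)
        if panel is not None and len(cand):
            cand = clump(cand, panel, config.clump_r2, config.clump_window_kb)
        exposure_instruments[exp.name] = cand
        if len(cand):
            exposure_strength[exp.name] = instrument_strength(cand)

    # outcome tables, meta-analyzed across cohorts
    outcome_tables: dict[str, pd.DataFrame] = {}
    outcome_counts: dict[str, dict] = {}
    for out in config.outcomes:
        cohorts = [read_summary_stats(p).rows for p in out.cohort_paths]
        outcome_tables[out.name] = meta_analyze_cohorts(cohorts)
        tbl = outcome_tables[out.name]
        n_total = float(tbl["n"].max())
        ncase = float(tbl["n_cases"].max()) if tbl["n_cases"].notna().any() else n_total * 0.1
        outcome_counts[out.name] = {"n_total": n_total, "case_fraction": ncase / n_total}

    n_exposures = len(config.exposures)
    family_of = {o.name: o.family for o in config.outcomes}
    family_counts: dict[str, int] = {}
    for o in config.outcomes:
        family_counts[o.family] = family_counts.get(o.family, 0) + 1
    family_counts.update(config.family_sizes)

    seed_seq = np.random.SeedSequence(config.seed)
    pair_seeds = {}
    grid = [(e.name, o.name) for e in config.exposures for o in config.outcomes]
    for (ename, oname), child in zip(grid, seed_seq.spawn(len(grid))):
        pair_seeds[(ename, oname)] = int(child.generate_state(1)[0] % (2**31))

    rows = []
    pair_log = []
    for ename, oname in grid:
        family = family_of[oname]
        base = {"exposure": ename, "outcome": oname, "family": family, "reason": ""}
        instruments = exposure_instruments[ename]
        if not len(instruments):
            rows.append({**base, "nsnp": 0, "reason": "no instruments"})
            pair_log.append({"exposure": ename, "outcome": oname, "nsnp": 0,
                             "reason": "no instruments"})
            continue
        hset = harmonize_pair(
            instruments, outcome_tables[oname], panel, policy,
            exposure_name=ename, outcome_name=oname,
        )
        if hset.n_snp == 0:
            rows.append({**base, "nsnp": 0, "reason": "no instruments after harmonization"})
            pair_log.append({"exposure": ename, "outcome": oname, "nsnp": 0,
                             "reason": "no instruments after harmonization"})
            continue
        seed = pair_seeds[(ename, oname)]
        results = run_all_estimators(hset, n_boot=config.n_boot, seed=seed)
        sens = sensitivity_report(
            hset, n_sim=config.presso_n_sim, seed=seed + 1,
            outlier_alpha=config.presso_outlier_alpha,
        )
        strength = exposure_strength[ename]
        oc = outcome_counts[oname]
        power = PowerReport.compute(
            oc["n_total"], oc["case_fraction"], strength.total_r2,
            or_grid=config.power_or_grid, alpha=config.alpha,
        )
        # rank by IVW p; a single-SNP pair reports the Wald ratio there
        ivw_res = results["ivw"]
        tier = bonferroni_tiers(
            ivw_res.pvalue, n_exposures, family_counts[family], config.alpha
        )
        row = {**base, "nsnp": hset.n_snp, "n_dropped": len(hset.dropped)}
        for m in ("wald_ratio", "ivw", "weighted_median", "mr_egger"):
            row.update(_flatten_result(m, results[m]))
        row.update(sens.to_dict())
        row.update(
            total_r2=strength.total_r2,
            overall_f=strength.overall_f,
            min_f=float(strength.per_snp_f.min()),
            max_f=float(strength.per_snp_f.max()),
            n_outcome=oc["n_total"],
            case_fraction=oc["case_fraction"],
            min_detectable_or=power.min_detectable_or,
            min_detectable_or_label=format_or(power.min_detectable_or),
            **{f"power_or_{o:g}": p for o, p in power.power_at.items()},
            significance_tier=tier.tier,
        )
        rows.append(row)
        pair_log.append({
            "exposure": ename, "outcome": oname, "nsnp": hset.n_snp,
            "dropped": [list(d) for d in hset.dropped], "seed": seed,
        })
        if write and config.emit_plot_data:
            plotdir = outdir / "plot_data"
            plotdir.mkdir(parents=True, exist_ok=True)
            mres = {k: v for k, v in results.items() if isinstance(v, MrResult)}
            funnel_data(hset, mres).to_csv(
                plotdir / f"{ename}__{oname}.funnel.tsv", sep="\t", index=False)
            scatter_data(hset, mres).to_csv(
                plotdir / f"{ename}__{oname}.scatter.tsv", sep="\t", index=False)

    atlas_df, tier_counts = assemble_atlas(rows)

    screens = {}
    if confounder_tables:
        for ename, inst in exposure_instruments.items():
            if len(inst):
                scr = confounder_screen(
                    inst["snp_id"], confounder_tables, config.confounder_p_flag)
                screens[ename] = scr.to_dict("records")

    report = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "n_exposures": n_exposures,
        "family_sizes": family_counts,
        "grid_size": len(grid),
        "thresholds": {
            "p_threshold": config.p_threshold,
            "maf_min": config.maf_min,
            "clump_r2": config.clump_r2,
            "clump_window_kb": config.clump_window_kb,
            "proxy_r2_min": config.proxy_r2_min,
            "bonferroni": {
                fam: bonferroni_tiers(1.0, n_exposures, size, config.alpha).printed_thresholds()
                for fam, size in family_counts.items()
            },
        },
        "read_errors": read_issues,
        "pairs": pair_log,
        "tier_counts": tier_counts.to_dict("records"),
        "confounder_screen": screens,
    }
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        atlas_df.to_csv(outdir / "atlas.tsv", sep="\t", index=False)
        tier_counts.to_csv(outdir / "tier_counts.tsv", sep="\t", index=False)
        with open(outdir / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return atlas_df, report


def _config_echo(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
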