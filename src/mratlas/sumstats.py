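"""GWAS summary-statistic records, file readers, and allele harmonization.

The central objects are :class:`SummaryStatRow` (one SNP's association in one
GWAS), and :class:`HarmonizedSet` (the aligned SNP-exposure / SNP-outcome
effect pairs entering the causal estimators, together with an audit trail of
dropped SNPs).

Harmonization follows standard two-sample MR practice: effect sizes from the
outcome GWAS are re-expressed on the exposure GWAS's effect allele, strand
complements are tried only when direct allele matching fails and never for
palindromic (A/T, C/G) pairs, and palindromic SNPs are oriented by allele
frequency concordance when the minor allele frequency is low enough
(MAF <= 0.42) to make the orientation inferable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlleleMismatchError, ConfigurationError

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: MAF above which a palindromic SNP's strand orientation is not inferable
#: from allele frequency.
PALINDROME_MAF_LIMIT = 0.42

#: Relative disagreement between the stated p-value and the two-sided normal
#: p implied by beta/se beyond which a consistency warning is raised.
P_CONSISTENCY_RTOL = 0.20

CANONICAL_COLUMNS = [
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
    "n_cases",
    "n_controls",
]

#: Default header-name synonyms (GWAS-SSF style plus common short forms),
#: mapped onto canonical column names. Matching is case-insensitive.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp": "snp_id",
    "snp_id": "snp_id",
    "rsid": "snp_id",
    "variant_id": "snp_id",
    "markername": "snp_id",
    "ea": "effect_allele",
    "effect_allele": "effect_allele",
    "a1": "effect_allele",
    "oa": "other_allele",
    "other_allele": "other_allele",
    "a2": "other_allele",
    "eaf": "eaf",
    "effect_allele_frequency": "eaf",
    "freq": "eaf",
    "beta": "beta",
    "b": "beta",
    "se": "se",
    "standard_error": "se",
    "p": "pvalue",
    "pval": "pvalue",
    "pvalue": "pvalue",
    "p_value": "pvalue",
    "n": "n",
    "sample_size": "n",
    "n_cases": "n_cases",
    "ncase": "n_cases",
    "n_controls": "n_controls",
    "ncontrol": "n_controls",
}

MANDATORY = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue", "n"]


@dataclass(frozen=True)
class SummaryStatRow:
    """One SNP's association record in one GWAS.

    ``beta`` is the per-effect-allele estimate: per 1-SD trait units for a
    continuous exposure, log-odds for a binary outcome.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n: float
    eaf: float | None = None
    n_cases: float | None = None
    n_controls: float | None = None

    @property
    def maf(self) -> float | None:
        if self.eaf is None or np.isnan(self.eaf):
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def zscore(self) -> float:
        return self.beta / self.se


class RowIssue(NamedTuple):
    line: int  # 1-based line number in the source file (header = line 1)
    snp_id: str
    kind: str  # "error" or "warning"
    message: str


class ReadResult(NamedTuple):
    rows: pd.DataFrame  # canonical columns, validated rows only
    errors: list[RowIssue]
    warnings: list[RowIssue]


def validate_row(row: SummaryStatRow) -> tuple[list[str], list[str]]:
    """Return (errors, warnings) for one record."""
    errors: list[str] = []
    warnings: list[str] = []
    for label, allele in (("effect_allele", row.effect_allele), ("other_allele", row.other_allele)):
        if allele not in VALID_BASES:
            errors.append(f"{label} {allele!r} is not a single A/C/G/T base")
    if not errors and row.effect_allele == row.other_allele:
        errors.append(f"effect and other allele are both {row.effect_allele!r}")
    if not (row.se > 0):
        errors.append(f"se must be > 0, got {row.se}")
    if not (0 < row.pvalue <= 1):
        errors.append(f"pvalue must be in (0, 1], got {row.pvalue}")
    if not (row.n > 0):
        errors.append(f"sample size must be > 0, got {row.n}")
    if row.eaf is not None and not np.isnan(row.eaf) and not (0 <= row.eaf <= 1):
        errors.append(f"eaf must be in [0, 1], got {row.eaf}")
    if not errors:
        implied = implied_pvalue(row.beta, row.se)
        if implied > 0 and abs(implied - row.pvalue) / row.pvalue > P_CONSISTENCY_RTOL:
            warnings.append(
                f"stated p={row.pvalue:.3g} inconsistent with beta/se "
                f"(|z|={abs(row.zscore):.2f} implies p={implied:.3g})"
            )
    return errors, warnings


def implied_pvalue(beta: float, se: float) -> float:
    """Two-sided p-value implied by a normal Wald test of beta/se."""
    return float(2.0 * stats.norm.sf(abs(beta / se)))


def _resolve_columns(header: Sequence[str], column_map: Mapping[str, str] | None) -> dict[str, str]:
    mapping = {k.lower(): v for k, v in DEFAULT_COLUMN_MAP.items()}
    if column_map:
        mapping.update({k.lower(): v for k, v in column_map.items()})
    resolved: dict[str, str] = {}
    for col in header:
        canon = mapping.get(str(col).lower())
        if canon is not None and canon not in resolved.values():
            resolved[col] = canon
    missing = [c for c in MANDATORY if c not in resolved.values()]
    if missing:
        raise ConfigurationError(
            f"summary-statistics file is missing mandatory columns {missing}; "
            f"found header {list(header)}"
        )
    return resolved


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> ReadResult:
    """Read a delimited summary-statistics table into validated canonical rows.

    The delimiter is inferred (comma/tab/whitespace) unless ``sep`` is given;
    gzip compression is transparent. Rows failing validation are reported in
    ``errors`` with their source line number, never silently dropped.
    """
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=sep)
    resolved = _resolve_columns(df.columns, column_map)
    df = df.rename(columns=resolved)[list(resolved.values())]
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]

    errors: list[RowIssue] = []
    warnings: list[RowIssue] = []
    keep = np.ones(len(df), dtype=bool)
    for i, rec in enumerate(df.to_dict("records")):
        row = row_from_mapping(rec)
        errs, warns = validate_row(row)
        line = i + 2  # header occupies line 1
        for msg in errs:
            errors.append(RowIssue(line, row.snp_id, "error", msg))
        for msg in warns:
            warnings.append(RowIssue(line, row.snp_id, "warning", msg))
        if errs:
            keep[i] = False
    return ReadResult(df.loc[keep].reset_index(drop=True), errors, warnings)


def row_from_mapping(rec: Mapping) -> SummaryStatRow:
    def _opt(key):
        v = rec.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    return SummaryStatRow(
        snp_id=str(rec["snp_id"]),
        effect_allele=str(rec["effect_allele"]).upper(),
        other_allele=str(rec["other_allele"]).upper(),
        beta=float(rec["beta"]),
        se=float(rec["se"]),
        pvalue=float(rec["pvalue"]),
        n=float(rec["n"]),
        eaf=_opt("eaf"),
        n_cases=_opt("n_cases"),
        n_controls=_opt("n_controls"),
    )


def rows_to_frame(rows: Iterable[SummaryStatRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
                "n_cases": np.nan if r.n_cases is None else r.n_cases,
                "n_controls": np.nan if r.n_controls is None else r.n_controls,
            }
            for r in rows
        ],
        columns=CANONICAL_COLUMNS,
    )


def frame_to_rows(df: pd.DataFrame) -> list[SummaryStatRow]:
    return [row_from_mapping(rec) for rec in df.to_dict("records")]


# ---------------------------------------------------------------------------
# palindromes and allele alignment
# ---------------------------------------------------------------------------


class PalindromeStatus(NamedTuple):
    palindromic: bool
    inferable: bool  # meaningful only when palindromic


def is_palindromic(row: SummaryStatRow, maf_limit: float = PALINDROME_MAF_LIMIT) -> PalindromeStatus:
    """Classify a SNP as palindromic (strand-ambiguous) and frequency-inferable.

    A palindromic allele pair is {A,T} or {C,G}. Orientation is inferable
    only when the minor allele frequency is at most ``maf_limit``; a missing
    frequency is treated as non-inferable.
    """
    pal = {row.effect_allele, row.other_allele} in ({"A", "T"}, {"C", "G"})
    if not pal:
        return PalindromeStatus(False, True)
    maf = row.maf
    inferable = maf is not None and maf <= maf_limit
    return PalindromeStatus(True, inferable)


class AlignedRow(NamedTuple):
    row: SummaryStatRow
    swapped: bool  # effect/other alleles exchanged (beta negated)
    complemented: bool  # matched on the opposite strand


def align_to_effect_allele(
    row: SummaryStatRow, target_effect_allele: str, allow_complement: bool = True
) -> AlignedRow:
    """Re-express a record so that ``target_effect_allele`` is the effect allele.

    Swapping alleles negates beta and replaces eaf by 1 - eaf; p, se and n
    are unchanged. Strand complementation is attempted only if direct
    matching fails and never for palindromic pairs, where the complement is
    indistinguishable from a swap.
    """
    target = target_effect_allele.upper()
    ea, oa = row.effect_allele, row.other_allele
    if target == ea:
        return AlignedRow(row, False, False)
    if target == oa:
        return AlignedRow(_swap(row), True, False)
    pal = is_palindromic(row).palindromic
    if allow_complement and not pal:
        cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
        if target == cea:
            return AlignedRow(replace(row, effect_allele=cea, other_allele=coa), False, True)
        if target == coa:
            return AlignedRow(
                _swap(replace(row, effect_allele=cea, other_allele=coa)), True, True
            )
    raise AlleleMismatchError(row.snp_id, (ea, oa), target)


def _swap(row: SummaryStatRow) -> SummaryStatRow:
    return replace(
        row,
        effect_allele=row.other_allele,
        other_allele=row.effect_allele,
        beta=-row.beta,
        eaf=None if row.eaf is None else 1.0 - row.eaf,
    )


# ---------------------------------------------------------------------------
# harmonized pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Aligned SNP-exposure / SNP-outcome effect pair for one instrument."""

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    flipped: bool = False
    proxied_from: str | None = None
    proxy_r2: float | None = None

    def __post_init__(self):
        if (self.proxied_from is None) != (self.proxy_r2 is None):
            raise ValueError("proxy_r2 must be present iff proxied_from is present")


@dataclass
class HarmonizedSet:
    """All harmonized instruments for one exposure-outcome pair plus drops."""

    exposure_name: str
    outcome_name: str
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snp(self) -> int:
        return len(self.instruments)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) arrays."""
        bx = np.array([i.beta_exposure for i in self.instruments])
        sx = np.array([i.se_exposure for i in self.instruments])
        by = np.array([i.beta_outcome for i in self.instruments])
        sy = np.array([i.se_outcome for i in self.instruments])
        return bx, sx, by, sy

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "snp_id": i.snp_id,
                "beta_exposure": i.beta_exposure,
                "se_exposure": i.se_exposure,
                "beta_outcome": i.beta_outcome,
                "se_outcome": i.se_outcome,
                "flipped": i.flipped,
                "proxied_from": i.proxied_from or "",
                "proxy_r2": np.nan if i.proxy_r2 is None else i.proxy_r2,
                "drop_reason": "",
            }
            for i in self.instruments
        ]
        recs += [
            {
                "snp_id": snp,
                "beta_exposure": np.nan,
                "se_exposure": np.nan,
                "beta_outcome": np.nan,
                "se_outcome": np.nan,
                "flipped": False,
                "proxied_from": "",
                "proxy_r2": np.nan,
                "drop_reason": reason,
            }
            for snp, reason in self.dropped
        ]
        return pd.DataFrame(recs)


@dataclass(frozen=True)
class HarmonizePolicy:
    proxy_r2_min: float = 0.8
    palindrome_maf_limit: float = PALINDROME_MAF_LIMIT
    allow_complement: bool = True


def _orient_by_frequency(exp: SummaryStatRow, out: SummaryStatRow) -> tuple[SummaryStatRow, bool] | None:
    """Orient ``out`` so its effect-allele frequency lies on the same side of
    0.5 as the exposure's. Returns (oriented row, flipped flag) or None when
    either frequency is missing or exactly 0.5 (orientation undecidable)."""
    if exp.eaf is None or out.eaf is None or exp.eaf == 0.5 or out.eaf == 0.5:
        return None
    same_side = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
    if same_side:
        return out, False
    return _swap(out), True


def harmonize_pair(
    exposure_rows,
    outcome_rows,
    ld_panel=None,
    policy: HarmonizePolicy = HarmonizePolicy(),
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Harmonize instrument-selected exposure SNPs against an outcome GWAS.

    For each exposure SNP: if present in the outcome and orientable, the
    outcome effect is aligned to the exposure's effect allele; a SNP absent
    from the outcome, or palindromic with a non-inferable frequency, is
    replaced by its best LD proxy (r2 > ``policy.proxy_r2_min``) when the
    panel provides one; otherwise it is dropped with a recorded reason.
    Every input SNP ends up in exactly one of ``instruments`` or ``dropped``.
    """
    from .instruments import proxy_candidates  # local import to avoid a cycle

    exp_rows = _as_rows(exposure_rows)
    out_rows = {r.snp_id: r for r in _as_rows(outcome_rows)}
    hset = HarmonizedSet(exposure_name, outcome_name)

    for exp in exp_rows:
        out = out_rows.get(exp.snp_id)
        needs_proxy_reason = None
        if out is None:
            needs_proxy_reason = "absent from outcome"
        else:
            pal = is_palindromic(exp, policy.palindrome_maf_limit)
            pal_out = is_palindromic(out, policy.palindrome_maf_limit)
            if pal.palindromic and not (pal.inferable and pal_out.inferable):
                needs_proxy_reason = "non-inferable palindrome"

        if needs_proxy_reason is None and out is not None:
            inst = _pair_direct(exp, out, policy)
            if isinstance(inst, HarmonizedInstrument):
                hset.instruments.append(inst)
            else:
                hset.dropped.append((exp.snp_id, inst))
            continue

        # proxy path
        proxied = None
        if ld_panel is not None and exp.snp_id in ld_panel:
            for cand_id, r2 in proxy_candidates(
                exp.snp_id,
                ld_panel,
                out_rows,
                r2_min=policy.proxy_r2_min,
                maf_limit=policy.palindrome_maf_limit,
            ):
                oriented = _orient_by_frequency(exp, out_rows[cand_id])
                if oriented is None:
                    continue  # phase not inferable from frequency; try next
                prow, flipped = oriented
                proxied = HarmonizedInstrument(
                    snp_id=cand_id,
                    beta_exposure=exp.beta,
                    se_exposure=exp.se,
                    beta_outcome=prow.beta,
                    se_outcome=prow.se,
                    flipped=flipped,
                    proxied_from=exp.snp_id,
                    proxy_r2=r2,
                )
                break
        if proxied is not None:
            hset.instruments.append(proxied)
        else:
            hset.dropped.append((exp.snp_id, f"{needs_proxy_reason}, no proxy"))
    return hset


def _pair_direct(exp: SummaryStatRow, out: SummaryStatRow, policy: HarmonizePolicy):
    """Align one present-in-outcome SNP; returns an instrument or a drop reason."""
    pal = is_palindromic(exp, policy.palindrome_maf_limit)
    if pal.palindromic:
        # inferable palindrome: labels cannot resolve strand, frequency can
        oriented = _orient_by_frequency(exp, out)
        if oriented is None:
            return "palindrome with ambiguous frequency"
        orow, flipped = oriented
    else:
        try:
            aligned = align_to_effect_allele(
                out, exp.effect_allele, allow_complement=policy.allow_complement
            )
        except AlleleMismatchError:
            return "allele mismatch with outcome"
        if aligned.row.other_allele != exp.other_allele:
            return "allele mismatch with outcome"
        orow, flipped = aligned.row, aligned.swapped
    return HarmonizedInstrument(
        snp_id=exp.snp_id,
        beta_exposure=exp.beta,
        se_exposure=exp.se,
        beta_outcome=orow.beta,
        se_outcome=orow.se,
        flipped=flipped,
    )


def _as_rows(obj) -> list[SummaryStatRow]:
    if isinstance(obj, pd.DataFrame):
        return frame_to_rows(obj)
    return list(obj)


def write_harmonized(hset: HarmonizedSet, path) -> None:
    hset.to_frame().to_csv(path, sep="\t", index=False)
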