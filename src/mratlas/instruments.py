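"""Instrument selection: significance/MAF filtering, LD clumping, proxy
lookup, instrument-strength metrics (F, R^2) and the confounder screen.

Selection defaults follow conventional two-sample MR practice: genome-wide
significance P < 5e-8, minor allele frequency > 0.01, greedy clumping at
r^2 < 0.001 (optionally restricted to a base-pair window when positions are
available), and proxy replacement at r^2 > 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PanelLookupError
from .sumstats import SummaryStatRow, is_palindromic


class LdPanel:
    """Pairwise r^2 reference panel over a fixed set of SNPs.

    The matrix must be symmetric with a unit diagonal. Base-pair positions
    are optional; when present they enable window-restricted clumping.
    """

    def __init__(self, snp_ids, r2, positions: Mapping[str, int] | None = None):
        self.snp_ids = list(snp_ids)
        r2 = np.asarray(r2, dtype=float)
        if r2.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ConfigurationError("LD matrix shape does not match the SNP id list")
        if not np.allclose(r2, r2.T, atol=1e-12):
            raise ConfigurationError("LD matrix is not symmetric within 1e-12")
        if not np.all(np.diag(r2) == 1.0):
            raise ConfigurationError("LD matrix diagonal must be exactly 1")
        if r2.min() < 0 or r2.max() > 1 + 1e-12:
            raise ConfigurationError("r2 entries must lie in [0, 1]")
        self.r2 = r2
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        self.positions = dict(positions) if positions else None

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def __len__(self) -> int:
        return len(self.snp_ids)

    def r2_between(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise PanelLookupError(f"SNP {exc.args[0]!r} absent from the LD panel") from exc

    def neighbors(self, snp_id: str) -> pd.Series:
        """All panel SNPs' r^2 against ``snp_id`` (self included)."""
        if snp_id not in self._index:
            raise PanelLookupError(f"SNP {snp_id!r} absent from the LD panel")
        return pd.Series(self.r2[self._index[snp_id]], index=self.snp_ids)

    # -- file formats --------------------------------------------------

    @classmethod
    def from_square_file(cls, path, positions=None) -> "LdPanel":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(df.index.astype(str), df.to_numpy(), positions)

    @classmethod
    def from_triplets(cls, triplets, positions=None) -> "LdPanel":
        """Build from long-format (snp_a, snp_b, r2) records or a file path."""
        if not isinstance(triplets, pd.DataFrame):
            try:
                triplets = pd.read_csv(triplets, sep=None, engine="python")
            except (TypeError, ValueError):
                triplets = pd.DataFrame(triplets, columns=["snp_a", "snp_b", "r2"])
        a, b, v = triplets.columns[:3]
        ids = sorted(set(triplets[a].astype(str)) | set(triplets[b].astype(str)))
        idx = {s: i for i, s in enumerate(ids)}
        mat = np.eye(len(ids))
        for _, rec in triplets.iterrows():
            i, j = idx[str(rec[a])], idx[str(rec[b])]
            mat[i, j] = mat[j, i] = float(rec[v])
        return cls(ids, mat, positions)

    def to_square_file(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def select_candidates(
    exposure_rows: pd.DataFrame, p_threshold: float = 5e-8, maf_min: float = 0.01
) -> pd.DataFrame:
    """Keep genome-wide-significant common variants.

    Strict inequalities on both sides: pvalue < ``p_threshold`` and
    MAF > ``maf_min``. Rows with missing frequency pass the MAF filter
    (frequency checks happen again at harmonization). Output is ordered by
    ascending p, then snp_id, for reproducibility.
    """
    df = exposure_rows.copy()
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    keep = (df["pvalue"] < p_threshold) & (maf.isna() | (maf > maf_min))
    out = df.loc[keep].sort_values(["pvalue", "snp_id"], kind="mergesort")
    return out.reset_index(drop=True)


def clump(
    candidates: pd.DataFrame,
    ld_panel: LdPanel,
    r2_threshold: float = 0.001,
    window_kb: float | None = 10_000.0,
) -> pd.DataFrame:
    """Greedy LD clumping: repeatedly keep the lowest-p remaining candidate
    and discard candidates correlated with it at r^2 >= ``r2_threshold``.

    When the panel carries positions and ``window_kb`` is set, only SNPs
    within the window are eligible for discarding. Candidates absent from
    the panel are dropped up front. Ties on p break lexicographically on
    snp_id; output order is selection order.
    """
    present = candidates[candidates["snp_id"].isin(ld_panel.snp_ids)]
    remaining = present.sort_values(["pvalue", "snp_id"], kind="mergesort").reset_index(drop=True)
    kept_rows = []
    while len(remaining):
        lead = remaining.iloc[0]
        kept_rows.append(lead)
        r2 = remaining["snp_id"].map(lambda s: ld_panel.r2_between(lead["snp_id"], s))
        discard = r2 >= r2_threshold
        if window_kb is not None and ld_panel.positions is not None:
            pos = remaining["snp_id"].map(ld_panel.positions)
            lead_pos = ld_panel.positions.get(lead["snp_id"])
            if lead_pos is not None:
                in_window = (pos - lead_pos).abs() <= window_kb * 1000.0
                discard = discard & in_window.fillna(True)
        discard.iloc[0] = True  # the lead itself leaves the pool
        remaining = remaining.loc[~discard].reset_index(drop=True)
    if not kept_rows:
        return present.iloc[0:0].reset_index(drop=True)
    return pd.DataFrame(kept_rows).reset_index(drop=True)


def proxy_candidates(
    snp_id: str,
    ld_panel: LdPanel,
    outcome_rows: Mapping[str, SummaryStatRow],
    r2_min: float = 0.8,
    maf_limit: float = 0.42,
) -> list[tuple[str, float]]:
    """Ranked (snp_id, r2) proxies: r2 strictly above ``r2_min``, present in
    the outcome, and not a non-inferable palindrome. Ordered by descending
    r2 with lexicographic snp_id tie-break."""
    neigh = ld_panel.neighbors(snp_id)
    cands = []
    for other, r2 in neigh.items():
        if other == snp_id or r2 <= r2_min:
            continue
        out = outcome_rows.get(other)
        if out is None:
            continue
        pal = is_palindromic(out, maf_limit)
        if pal.palindromic and not pal.inferable:
            continue
        cands.append((other, float(r2)))
    return sorted(cands, key=lambda t: (-t[1], t[0]))


def find_proxy(
    snp_id: str,
    ld_panel: LdPanel,
    outcome_rows,
    r2_min: float = 0.8,
) -> tuple[str, float] | None:
    """Best qualifying LD proxy for a SNP, or None."""
    if not isinstance(outcome_rows, Mapping):
        from .sumstats import _as_rows

        outcome_rows = {r.snp_id: r for r in _as_rows(outcome_rows)}
    cands = proxy_candidates(snp_id, ld_panel, outcome_rows, r2_min)
    return cands[0] if cands else None


# ---------------------------------------------------------------------------
# instrument strength
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InstrumentStrength:
    per_snp_f: pd.Series  # indexed by snp_id
    per_snp_r2: pd.Series
    total_r2: float
    overall_f: float
    r2_fallback_snps: tuple[str, ...] = ()  # SNPs lacking eaf, se/n formula used


def instrument_strength(selected_rows: pd.DataFrame, n_exposure: float | None = None) -> InstrumentStrength:
    """Instrument strength for an independent (clumped) instrument set.

    Per-SNP variance explained uses the standardized-trait identity
    R^2_j = 2 f_j (1 - f_j) beta_j^2 with beta on the per-SD scale; SNPs
    without a frequency fall back to R^2_j = beta^2 / (beta^2 + n se^2) and
    are flagged. The per-SNP F is (beta/se)^2; the overall F is
    (R^2 / (1 - R^2)) ((n - k - 1) / k).
    """
    df = selected_rows
    if n_exposure is None:
        n_exposure = float(np.median(df["n"]))
    beta = df["beta"].to_numpy(float)
    se = df["se"].to_numpy(float)
    eaf = df["eaf"].to_numpy(float)
    n = df["n"].to_numpy(float)

    r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
    fallback = np.isnan(eaf)
    r2[fallback] = beta[fallback] ** 2 / (beta[fallback] ** 2 + n[fallback] * se[fallback] ** 2)
    per_f = (beta / se) ** 2
    total = float(np.sum(r2))
    k = len(df)
    overall = (total / (1.0 - total)) * ((n_exposure - k - 1) / k) if k else 0.0
    ids = df["snp_id"].astype(str)
    return InstrumentStrength(
        per_snp_f=pd.Series(per_f, index=ids, name="f_stat"),
        per_snp_r2=pd.Series(r2, index=ids, name="r2"),
        total_r2=total,
        overall_f=float(overall),
        r2_fallback_snps=tuple(ids[fallback]),
    )


# ---------------------------------------------------------------------------
# confounder screen
# ---------------------------------------------------------------------------


def confounder_screen(
    instrument_ids: Iterable[str],
    confounder_tables: Mapping[str, pd.DataFrame],
    p_flag: float = 1e-5,
) -> pd.DataFrame:
    """Advisory screen of instruments against confounder GWASs.

    For each instrument x confounder, the SNP is flagged when the confounder
    association has p < ``p_flag``; SNPs absent from a table are recorded as
    untested. Flagged SNPs are reported, never removed.
    """
    records = []
    for name, table in confounder_tables.items():
        lut = table.set_index(table["snp_id"].astype(str))
        for snp in instrument_ids:
            snp = str(snp)
            if snp not in lut.index:
                records.append(
                    {"snp_id": snp, "confounder": name, "beta": np.nan, "pvalue": np.nan,
                     "status": "untested"}
                )
                continue
            rec = lut.loc[snp]
            p = float(rec["pvalue"])
            records.append(
                {"snp_id": snp, "confounder": name, "beta": float(rec["beta"]), "pvalue": p,
                 "status": "flagged" if p < p_flag else "ok"}
            )
    return pd.DataFrame(records, columns=["snp_id", "confounder", "beta", "pvalue", "status"])
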