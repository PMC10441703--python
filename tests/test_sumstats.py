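"""Readers, palindrome logic, allele alignment and harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mratlas.errors import AlleleMismatchError, ConfigurationError
from mratlas.instruments import LdPanel
from mratlas.sumstats import (
    align_to_effect_allele,
    harmonize_pair,
    is_palindromic,
    read_summary_stats,
    rows_to_frame,
)

from conftest import make_row


class TestReadSummaryStats:
    def test_well_formed_table_round_trips(self, sumstats_file):
        res = read_summary_stats(sumstats_file)
        assert len(res.rows) == 3
        assert not res.errors and not res.warnings
        assert list(res.rows["snp_id"]) == ["rs1", "rs2", "rs3"]
        assert res.rows.loc[1, "beta"] == -0.05

    def test_invalid_allele_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("SNP,EA,OA,EAF,BETA,SE,P,N\nrs1,AT,G,0.2,0.1,0.02,5.7e-7,1000\n"
                        "rs2,A,G,0.2,0.1,0.02,5.7e-7,1000\n")
        res = read_summary_stats(path)
        assert len(res.rows) == 1  # rs2 survives
        (err,) = res.errors
        assert err.line == 2 and err.snp_id == "rs1" and "AT" in err.message

    def test_p_beta_se_inconsistency_warns(self, tmp_path):
        # |z| = 5 implies p = 2*Phi(-5) ~ 5.7e-7, far from the stated 0.5
        path = tmp_path / "warn.tsv"
        pd.DataFrame(
            {"SNP": ["rs9"], "EA": ["A"], "OA": ["G"], "EAF": [0.3],
             "BETA": [0.1], "SE": [0.02], "P": [0.5], "N": [1000]}
        ).to_csv(path, sep="\t", index=False)
        res = read_summary_stats(path)
        assert len(res.rows) == 1  # warned about, not dropped
        (warn,) = res.warnings
        implied = 2 * stats.norm.sf(5.0)
        assert f"{implied:.3g}" in warn.message

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        path = tmp_path / "nose.tsv"
        path.write_text("SNP\tEA\tOA\tBETA\tP\tN\nrs1\tA\tG\t0.1\t0.01\t1000\n")
        with pytest.raises(ConfigurationError, match="se"):
            read_summary_stats(path)

    def test_gzip_transparent(self, tmp_path, sumstats_file):
        import gzip, shutil

        gz = tmp_path / "stats.tsv.gz"
        with open(sumstats_file, "rb") as src, gzip.open(gz, "wb") as dst:
            shutil.copyfileobj(src, dst)
        assert len(read_summary_stats(gz).rows) == 3


class TestPalindromes:
    @pytest.mark.parametrize(
        "ea,oa,eaf,palindromic,inferable",
        [
            ("A", "T", 0.10, True, True),  # MAF 0.10 <= 0.42: orientation inferable
            ("A", "G", 0.45, False, True),  # not strand-ambiguous
            ("C", "G", 0.45, True, False),  # MAF 0.45 > 0.42
            ("G", "C", 0.50, True, False),
            ("T", "A", 0.42, True, True),  # boundary: exactly 0.42 is inferable
            ("C", "G", None, True, False),  # missing frequency
        ],
    )
    def test_classification(self, ea, oa, eaf, palindromic, inferable):
        status = is_palindromic(make_row(effect_allele=ea, other_allele=oa, eaf=eaf))
        assert status.palindromic == palindromic
        if palindromic:
            assert status.inferable == inferable


class TestAlignment:
    def test_swap_flips_beta_and_frequency(self):
        row = make_row(effect_allele="G", other_allele="A", beta=-0.05, eaf=0.7)
        aligned = align_to_effect_allele(row, "A")
        assert aligned.swapped and not aligned.complemented
        assert aligned.row.effect_allele == "A" and aligned.row.other_allele == "G"
        assert aligned.row.beta == pytest.approx(0.05)
        assert aligned.row.eaf == pytest.approx(0.3)
        assert (aligned.row.se, aligned.row.pvalue, aligned.row.n) == (row.se, row.pvalue, row.n)

    def test_already_aligned_is_identity(self):
        row = make_row(effect_allele="A", other_allele="G")
        assert align_to_effect_allele(row, "A").row == row

    @pytest.mark.parametrize(
        "ea,oa,target,want_swap,want_comp",
        # the 8 orientations of a C/T SNP against targets on either strand
        [
            ("C", "T", "C", False, False),
            ("C", "T", "T", True, False),
            ("C", "T", "G", False, True),  # complement pair G/A
            ("C", "T", "A", True, True),
            ("T", "C", "C", True, False),
            ("T", "C", "T", False, False),
            ("T", "C", "G", True, True),
            ("T", "C", "A", False, True),
        ],
    )
    def test_all_orientations_resolve(self, ea, oa, target, want_swap, want_comp):
        row = make_row(effect_allele=ea, other_allele=oa, beta=0.1, eaf=0.2)
        aligned = align_to_effect_allele(row, target)
        assert aligned.row.effect_allele == target
        assert aligned.swapped == want_swap
        assert aligned.complemented == want_comp
        # beta sign follows swaps only, never strand relabelling
        assert aligned.row.beta == pytest.approx(-0.1 if want_swap else 0.1)

    def test_mismatch_raises_with_context(self):
        row = make_row(effect_allele="A", other_allele="G")
        with pytest.raises(AlleleMismatchError):
            align_to_effect_allele(row, "C", allow_complement=False)
        with pytest.raises(AlleleMismatchError) as exc:
            align_to_effect_allele(make_row(effect_allele="A", other_allele="C"), "G",
                                   allow_complement=False)
        assert exc.value.target == "G"

    @settings(derandomize=True, max_examples=60)
    @given(
        ea_oa=st.sampled_from([("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T")]),
        beta=st.floats(-1, 1, allow_nan=False),
        eaf=st.floats(0.01, 0.99),
    )
    def test_double_swap_is_identity(self, ea_oa, beta, eaf):
        row = make_row(effect_allele=ea_oa[0], other_allele=ea_oa[1], beta=beta, eaf=eaf)
        there = align_to_effect_allele(row, row.other_allele).row
        back = align_to_effect_allele(there, row.effect_allele).row
        assert (back.effect_allele, back.other_allele, back.beta) == (
            row.effect_allele, row.other_allele, row.beta)
        assert back.eaf == pytest.approx(row.eaf, abs=1e-15)
        assert (back.se, back.pvalue, back.n) == (row.se, row.pvalue, row.n)


class TestHarmonizePair:
    def _clean_pair(self, k=6):
        exp = [make_row(snp_id=f"rs{i}", effect_allele="A", other_allele="G",
                        beta=0.1 + 0.01 * i, eaf=0.3) for i in range(k)]
        out = [make_row(snp_id=f"rs{i}", effect_allele="A", other_allele="G",
                        beta=0.05, se=0.01, eaf=0.31) for i in range(k)]
        return exp, out

    def test_clean_pair_all_harmonized(self):
        exp, out = self._clean_pair()
        hset = harmonize_pair(exp, out)
        assert hset.n_snp == 6 and not hset.dropped
        assert all(not i.flipped and i.proxied_from is None for i in hset.instruments)

    def test_swapped_outcome_coding_is_flipped_back(self):
        exp, out = self._clean_pair(k=1)
        swapped = make_row(snp_id="rs0", effect_allele="G", other_allele="A",
                           beta=-0.05, se=0.01, eaf=0.69)
        hset = harmonize_pair(exp[:1], [swapped])
        (inst,) = hset.instruments
        assert inst.flipped and inst.beta_outcome == pytest.approx(0.05)

    def test_missing_snp_replaced_by_proxy(self):
        exp, out = self._clean_pair(k=2)
        # rs0 absent from outcome; rs9 is its r2=0.9 proxy
        proxy = make_row(snp_id="rs9", effect_allele="C", other_allele="T",
                         beta=0.04, se=0.012, eaf=0.28)
        panel = LdPanel.from_triplets(pd.DataFrame(
            {"snp_a": ["rs0"], "snp_b": ["rs9"], "r2": [0.9]}))
        hset = harmonize_pair(exp[:1], [proxy], ld_panel=panel)
        (inst,) = hset.instruments
        assert inst.snp_id == "rs9" and inst.proxied_from == "rs0"
        assert inst.proxy_r2 == pytest.approx(0.9)
        assert inst.beta_exposure == pytest.approx(0.1)  # original exposure effect kept
        assert inst.beta_outcome == pytest.approx(0.04)  # same minor-allele side

    def test_noninferable_palindrome_without_proxy_dropped(self):
        exp = [make_row(snp_id="rs0", effect_allele="A", other_allele="T", eaf=0.45)]
        out = [make_row(snp_id="rs0", effect_allele="A", other_allele="T", eaf=0.45,
                        beta=0.05, se=0.01)]
        hset = harmonize_pair(exp, out)
        assert hset.n_snp == 0
        assert hset.dropped == [("rs0", "non-inferable palindrome, no proxy")]

    def test_inferable_palindrome_oriented_by_frequency(self):
        exp = [make_row(snp_id="rs0", effect_allele="A", other_allele="T", eaf=0.2)]
        # outcome reports the other side: eaf 0.8 means its A is the major allele
        out = [make_row(snp_id="rs0", effect_allele="A", other_allele="T", eaf=0.8,
                        beta=0.05, se=0.01)]
        (inst,) = harmonize_pair(exp, out).instruments
        assert inst.flipped and inst.beta_outcome == pytest.approx(-0.05)

    def test_conservation_every_snp_accounted_once(self, rng):
        # random mix of present/absent/palindromic SNPs
        pairs = [("A", "G"), ("C", "T"), ("A", "T"), ("C", "G")]
        exp, out = [], []
        for i in range(30):
            ea, oa = pairs[int(rng.integers(4))]
            eaf = float(rng.uniform(0.05, 0.95))
            exp.append(make_row(snp_id=f"rs{i}", effect_allele=ea, other_allele=oa, eaf=eaf))
            if rng.uniform() < 0.7:
                out.append(make_row(snp_id=f"rs{i}", effect_allele=ea, other_allele=oa,
                                    eaf=eaf, beta=0.02, se=0.01))
        hset = harmonize_pair(exp, out)
        kept = {i.proxied_from or i.snp_id for i in hset.instruments}
        dropped = {s for s, _ in hset.dropped}
        assert kept | dropped == {f"rs{i}" for i in range(30)}
        assert not kept & dropped
        assert len(hset.instruments) + len(hset.dropped) == 30

    def test_provenance_table_has_drop_reasons(self):
        exp = [make_row(snp_id="rs0", effect_allele="A", other_allele="T", eaf=0.45)]
        hset = harmonize_pair(exp, [])
        table = hset.to_frame()
        assert set(table.columns) >= {"flipped", "proxied_from", "proxy_r2", "drop_reason"}
        assert table.loc[0, "drop_reason"] == "absent from outcome, no proxy"
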