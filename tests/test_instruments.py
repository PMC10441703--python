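"""Selection thresholds, LD clumping, proxies, instrument strength, screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mratlas.errors import PanelLookupError
from mratlas.instruments import (
    LdPanel,
    clump,
    confounder_screen,
    find_proxy,
    instrument_strength,
    select_candidates,
)
from mratlas.sumstats import rows_to_frame

from conftest import make_row


def _frame(specs):
    return rows_to_frame([make_row(**s) for s in specs])


class TestSelectCandidates:
    def test_threshold_edges(self):
        df = _frame(
            [
                {"snp_id": "rs_over", "pvalue": 6e-8},          # not genome-wide significant
                {"snp_id": "rs_under", "pvalue": 4.9e-8, "eaf": 0.3},
                {"snp_id": "rs_rare", "pvalue": 1e-20, "eaf": 0.995},  # MAF 0.005 <= 0.01
                {"snp_id": "rs_exact", "pvalue": 5e-8},          # strict <
            ]
        )
        kept = select_candidates(df)
        assert list(kept["snp_id"]) == ["rs_under"]

    def test_order_is_p_then_id(self):
        df = _frame(
            [
                {"snp_id": "rs_b", "pvalue": 1e-9},
                {"snp_id": "rs_a", "pvalue": 1e-9},
                {"snp_id": "rs_c", "pvalue": 1e-12},
            ]
        )
        assert list(select_candidates(df)["snp_id"]) == ["rs_c", "rs_a", "rs_b"]

    @settings(derandomize=True, max_examples=30)
    @given(
        p1=st.floats(1e-12, 1e-4), p2=st.floats(1e-12, 1e-4),
        maf1=st.floats(0.001, 0.5), maf2=st.floats(0.001, 0.5),
    )
    def test_relaxing_thresholds_never_shrinks(self, p1, p2, maf1, maf2):
        rng = np.random.default_rng(7)
        df = _frame(
            [{"snp_id": f"rs{i}", "pvalue": float(rng.uniform(1e-12, 1e-4)),
              "eaf": float(rng.uniform(0.001, 0.999))} for i in range(40)]
        )
        tight = select_candidates(df, min(p1, p2), max(maf1, maf2))
        loose = select_candidates(df, max(p1, p2), min(maf1, maf2))
        assert set(tight["snp_id"]) <= set(loose["snp_id"])


class TestClump:
    def test_correlated_pair_keeps_lower_p(self):
        panel = LdPanel(["rs1", "rs2"], [[1.0, 0.5], [0.5, 1.0]])
        df = _frame([{"snp_id": "rs1", "pvalue": 1e-10}, {"snp_id": "rs2", "pvalue": 1e-9}])
        assert list(clump(df, panel, 0.001)["snp_id"]) == ["rs1"]

    def test_independent_snps_all_kept(self):
        panel = LdPanel(["rs1", "rs2", "rs3"], np.eye(3))
        df = _frame([{"snp_id": f"rs{i}", "pvalue": 10.0 ** -(8 + i)} for i in (1, 2, 3)])
        assert len(clump(df, panel, 0.001)) == 3

    def test_two_blocks_keep_per_block_minima(self, two_block_panel):
        # oracle: exhaustively check that the kept set is exactly the per-block
        # p-minimum, whatever order candidates arrive in
        pvals = {f"rs{i}": 10.0 ** -(9 + (i % 5)) for i in range(10)}
        best = {min(grp, key=lambda s: (pvals[s], s)) for grp in
                ([f"rs{i}" for i in range(5)], [f"rs{i}" for i in range(5, 10)])}
        for perm in itertools.islice(itertools.permutations(range(10)), 0, 120, 17):
            df = _frame([{"snp_id": f"rs{i}", "pvalue": pvals[f"rs{i}"]} for i in perm])
            kept = clump(df, two_block_panel, 0.001)
            assert set(kept["snp_id"]) == best

    def test_idempotent_and_pairwise_independent(self, rng, two_block_panel):
        df = _frame([{"snp_id": f"rs{i}", "pvalue": float(rng.uniform(1e-12, 1e-8))}
                     for i in range(10)])
        once = clump(df, two_block_panel, 0.001)
        twice = clump(once, two_block_panel, 0.001)
        pd.testing.assert_frame_equal(once, twice)
        for a, b in itertools.combinations(once["snp_id"], 2):
            assert two_block_panel.r2_between(a, b) < 0.001

    def test_window_limits_discard_range(self):
        # same r2 but positions 1 Mb apart: with a 10 kb window the distant
        # SNP survives; with a 10,000 kb window it is pruned
        panel = LdPanel(["rs1", "rs2"], [[1.0, 0.5], [0.5, 1.0]],
                        positions={"rs1": 1_000_000, "rs2": 2_000_000})
        df = _frame([{"snp_id": "rs1", "pvalue": 1e-10}, {"snp_id": "rs2", "pvalue": 1e-9}])
        assert len(clump(df, panel, 0.001, window_kb=10)) == 2
        assert len(clump(df, panel, 0.001, window_kb=10_000)) == 1

    def test_candidates_absent_from_panel_dropped(self):
        panel = LdPanel(["rs1"], [[1.0]])
        df = _frame([{"snp_id": "rs1", "pvalue": 1e-10}, {"snp_id": "rsX", "pvalue": 1e-20}])
        assert list(clump(df, panel)["snp_id"]) == ["rs1"]


class TestFindProxy:
    def _outcome(self, specs):
        return [make_row(**s) for s in specs]

    def test_argmax_r2(self):
        panel = LdPanel.from_triplets(pd.DataFrame(
            {"a": ["rs0", "rs0"], "b": ["rsA", "rsB"], "r2": [0.85, 0.95]}))
        out = self._outcome([{"snp_id": "rsA"}, {"snp_id": "rsB"}])
        assert find_proxy("rs0", panel, out) == ("rsB", 0.95)

    def test_strictly_greater_than_threshold(self):
        panel = LdPanel.from_triplets(pd.DataFrame(
            {"a": ["rs0"], "b": ["rsA"], "r2": [0.8]}))
        assert find_proxy("rs0", panel, self._outcome([{"snp_id": "rsA"}])) is None

    def test_noninferable_palindromic_proxy_skipped(self):
        # oracle: filter candidates (r2 > 0.8, in outcome, inferable), then argmax
        panel = LdPanel.from_triplets(pd.DataFrame(
            {"a": ["rs0", "rs0"], "b": ["rsA", "rsB"], "r2": [0.95, 0.85]}))
        out = self._outcome([
            {"snp_id": "rsA", "effect_allele": "A", "other_allele": "T", "eaf": 0.45},
            {"snp_id": "rsB"},
        ])
        assert find_proxy("rs0", panel, out) == ("rsB", 0.85)

    def test_absent_snp_is_lookup_error(self):
        panel = LdPanel(["rs1"], [[1.0]])
        with pytest.raises(PanelLookupError, match="rsZ"):
            find_proxy("rsZ", panel, [])


class TestInstrumentStrength:
    def test_single_snp_arithmetic(self):
        df = _frame([{"snp_id": "rs1", "beta": 0.1, "se": 0.02, "eaf": 0.5}])
        s = instrument_strength(df, n_exposure=10_000)
        assert s.per_snp_f["rs1"] == pytest.approx(25.0)
        assert s.per_snp_r2["rs1"] == pytest.approx(0.005)  # 2 * 0.25 * 0.01

    def test_overall_f_formula(self):
        df = _frame([{"snp_id": f"rs{i}", "beta": 0.1, "se": 0.02, "eaf": 0.5}
                     for i in range(4)])
        s = instrument_strength(df, n_exposure=10_000)
        assert s.total_r2 == pytest.approx(0.02)
        assert s.overall_f == pytest.approx((0.02 / 0.98) * (9995 / 4), rel=1e-12)

    def test_missing_eaf_falls_back_and_flags(self):
        df = _frame([{"snp_id": "rs1", "beta": 0.1, "se": 0.02, "eaf": None, "n": 10_000}])
        s = instrument_strength(df, n_exposure=10_000)
        assert s.r2_fallback_snps == ("rs1",)
        assert s.per_snp_r2["rs1"] == pytest.approx(0.01 / (0.01 + 10_000 * 0.0004))

    def test_matches_individual_level_regression(self, rng):
        # simulate genotypes and a standardized trait; the summary-based F and
        # R2 must agree with the per-SNP OLS fit within 5%
        n, k = 20_000, 4
        f = rng.uniform(0.2, 0.8, k)
        beta = np.array([0.08, -0.06, 0.05, 0.07])
        geno = rng.binomial(2, f, size=(n, k)).astype(float)
        y = geno @ beta + rng.normal(size=n)
        y = (y - y.mean()) / y.std()
        specs = []
        for j in range(k):
            g = geno[:, j]
            slope, intercept = np.polyfit(g, y, 1)
            resid = y - (slope * g + intercept)
            se = np.sqrt(resid.var(ddof=2) / (n * g.var()))
            specs.append({"snp_id": f"rs{j}", "beta": float(slope), "se": float(se),
                          "eaf": float(g.mean() / 2), "n": n})
        s = instrument_strength(_frame(specs), n_exposure=n)
        for j in range(k):
            t2 = (specs[j]["beta"] / specs[j]["se"]) ** 2
            assert s.per_snp_f[f"rs{j}"] == pytest.approx(t2, rel=1e-9)
            # F from the regression itself ~ t^2; R2_j ~ t2/(t2+n)
            assert s.per_snp_r2[f"rs{j}"] == pytest.approx(t2 / (t2 + n), rel=0.05)


class TestConfounderScreen:
    def _tables(self):
        bmi = _frame([{"snp_id": "rs1", "pvalue": 1e-6, "beta": 0.03},
                      {"snp_id": "rs2", "pvalue": 0.5, "beta": 0.0}])
        smoking = _frame([{"snp_id": "rs2", "pvalue": 0.9, "beta": 0.0}])
        return {"bmi": bmi, "smoking": smoking}

    def test_flagging_and_partial_coverage(self):
        res = confounder_screen(["rs1", "rs2"], self._tables(), p_flag=1e-5)
        res = res.set_index(["snp_id", "confounder"])
        assert res.loc[("rs1", "bmi"), "status"] == "flagged"
        assert res.loc[("rs2", "bmi"), "status"] == "ok"
        assert res.loc[("rs1", "smoking"), "status"] == "untested"
        assert res.loc[("rs2", "smoking"), "status"] == "ok"

    def test_advisory_only_nothing_removed(self):
        res = confounder_screen(["rs1", "rs2"], self._tables())
        assert set(res["snp_id"]) == {"rs1", "rs2"}
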