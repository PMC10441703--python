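import numpy as np
import pandas as pd
import pytest

from mratlas.instruments import LdPanel
from mratlas.sumstats import HarmonizedInstrument, HarmonizedSet, SummaryStatRow


def make_row(
    snp_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.02,
    pvalue=None,
    n=100_000,
    eaf=0.3,
    **kw,
):
    """SummaryStatRow factory with a self-consistent default p-value."""
    from scipy import stats

    if pvalue is None:
        pvalue = float(2 * stats.norm.sf(abs(beta / se)))
    return SummaryStatRow(snp_id, effect_allele, other_allele, beta, se, pvalue, n, eaf, **kw)


def make_hset(bx, by, sy, sx=None, exposure="exp", outcome="out") -> HarmonizedSet:
    """HarmonizedSet from raw effect arrays (ids rs1..rsk)."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    instruments = [
        HarmonizedInstrument(f"rs{i + 1}", bx[i], sx[i], by[i], sy[i]) for i in range(len(bx))
    ]
    return HarmonizedSet(exposure, outcome, instruments)


def random_hset(rng, k=None) -> HarmonizedSet:
    from mratlas.experiments import random_instrument_set

    return random_instrument_set(rng, k)


@pytest.fixture
def rng():
    return np.random.default_rng(20270101)


@pytest.fixture
def two_block_panel():
    """10 SNPs in two LD blocks (within-block r2 = 0.9, between = 0)."""
    ids = [f"rs{i}" for i in range(10)]
    r2 = np.zeros((10, 10))
    for block in (range(5), range(5, 10)):
        for a in block:
            for b in block:
                r2[a, b] = 0.9
    np.fill_diagonal(r2, 1.0)
    return LdPanel(ids, r2)


def exposure_frame(rows):
    from mratlas.sumstats import rows_to_frame

    return rows_to_frame(rows)


@pytest.fixture
def sumstats_file(tmp_path):
    """Well-formed 3-row summary-statistics file on disk."""
    path = tmp_path / "stats.tsv"
    pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3"],
            "EA": ["A", "C", "T"],
            "OA": ["G", "T", "C"],
            "EAF": [0.2, 0.5, 0.9],
            "BETA": [0.10, -0.05, 0.02],
            "SE": [0.02, 0.01, 0.02],
            "P": [5.7e-7, 5.7e-7, 0.3173],
            "N": [10_000, 10_000, 10_000],
        }
    ).to_csv(path, sep="\t", index=False)
    return path
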