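import numpy as np
import pandas as pd
import pytest

from mrpipe.gwas_io import SummaryDataset, TraitMeta
from mrpipe.instruments import HarmonizedSet


def make_hs(gamma, se_gamma, big_gamma, se_big, n_exp=100_000, n_out=11_240, cf=0.5):
    """Build a HarmonizedSet directly from effect arrays (all kept)."""
    gamma = np.asarray(gamma, float)
    pairs = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(len(gamma))],
            "gamma": gamma,
            "se_gamma": np.broadcast_to(np.asarray(se_gamma, float), gamma.shape),
            "Gamma": np.asarray(big_gamma, float),
            "se_Gamma": np.broadcast_to(np.asarray(se_big, float), gamma.shape),
            "eaf": 0.3,
            "pval_exposure": 1e-9,
            "status": "kept",
        }
    )
    return HarmonizedSet(
        exposure_meta=TraitMeta("exposure", "continuous", n_total=n_exp),
        outcome_meta=TraitMeta("outcome", "binary", n_total=n_out, case_fraction=cf),
        pairs=pairs,
    )


def hs_from_sim(exposure: SummaryDataset, outcome: SummaryDataset) -> HarmonizedSet:
    """Fast pairing of simulated datasets (shared SNPs, identical coding)."""
    return HarmonizedSet.from_aligned(exposure, outcome)


def random_hs(rng: np.random.Generator, j: int = 12):
    """A random harmonized set with spread-out instrument strengths."""
    gamma = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
    se_g = rng.uniform(0.003, 0.01, j)
    se_b = rng.uniform(0.02, 0.1, j)
    big = 0.3 * gamma + rng.normal(0, se_b)
    return make_hs(gamma, se_g, big, se_b)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_summary_df(rng, n=20, p_low_frac=0.5):
    """A well-formed canonical summary table with a mix of p-values."""
    beta = rng.normal(0, 0.05, n)
    se = rng.uniform(0.005, 0.02, n)
    from scipy import stats

    return pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(n)],
            "CHR": [str(1 + i % 22) for i in range(n)],
            "POS": np.arange(1, n + 1) * 1000,
            "EA": "A",
            "OA": "G",
            "EAF": rng.uniform(0.05, 0.95, n),
            "BETA": beta,
            "SE": se,
            "P": 2 * stats.norm.sf(np.abs(beta / se)),
            "N": 50_000,
        }
    )
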