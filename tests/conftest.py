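import numpy as np
import pandas as pd
import pytest

from mrkit import HarmonizedPair, MultiExposureSet, SummaryDataset
from mrkit.sumstats_io import CANONICAL_COLUMNS


def make_dataset(n=5, seed=0, trait_name="exposure", trait_type="continuous",
                 beta=None, se=None, pval=None, eaf=None, alleles=None,
                 chrom=None, pos=None):
    """Small well-formed summary dataset for unit tests."""
    rng = np.random.default_rng(seed)
    if beta is None:
        beta = rng.normal(0, 0.1, n)
    if se is None:
        se = np.full(n, 0.02)
    if eaf is None:
        eaf = rng.uniform(0.1, 0.9, n)
    z = np.abs(np.asarray(beta) / np.asarray(se))
    from scipy import stats
    if pval is None:
        pval = np.clip(2 * stats.norm.sf(z), 1e-300, 1.0)
    if alleles is None:
        pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
        alleles = [pairs[i % len(pairs)] for i in range(n)]
    df = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(n)],
        "chr": chrom if chrom is not None else ["1"] * n,
        "pos": pos if pos is not None else np.arange(1, n + 1) * 100_000,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "eaf": eaf, "beta": beta, "se": se, "pval": pval,
        "n": [10_000] * n,
    })
    return SummaryDataset(trait_name, df[CANONICAL_COLUMNS], trait_type)


def draw_pair(rng, J=50, theta=0.0, gamma_mean=0.1, gamma_sd=0.05,
              se_exp=0.01, se_out=0.05, prop_invalid=0.0,
              alpha_mean=0.0, alpha_sd=0.0):
    """Direct two-sample draw for estimator simulations (no file layer)."""
    gamma = gamma_mean + gamma_sd * rng.standard_normal(J)
    alpha = np.zeros(J)
    n_inv = int(round(prop_invalid * J))
    if n_inv:
        alpha[:n_inv] = rng.normal(alpha_mean, alpha_sd or 1e-12, n_inv)
    g_hat = gamma + rng.normal(0, se_exp, J)
    G_hat = theta * gamma + alpha + rng.normal(0, se_out, J)
    return HarmonizedPair([f"rs{i}" for i in range(J)], g_hat,
                          np.full(J, se_exp), G_hat, np.full(J, se_out))


def draw_multi(rng, J=80, theta=(0.4, 0.0), gamma_sd=0.1, corr=0.0,
               se_exp=0.01, se_out=0.05, intercepts=None):
    """Direct multi-exposure draw for MVMR/BMA simulations."""
    theta = np.asarray(theta, float)
    K = theta.size
    C = np.full((K, K), corr) + (1 - corr) * np.eye(K)
    chol = np.linalg.cholesky(C)
    gamma = (rng.standard_normal((J, K)) @ chol.T) * gamma_sd
    g_hat = gamma + rng.normal(0, se_exp, (J, K))
    G = gamma @ theta
    if intercepts is not None:
        G = G + intercepts
    G_hat = G + rng.normal(0, se_out, J)
    return MultiExposureSet([f"rs{i}" for i in range(J)], g_hat,
                            np.full((J, K), se_exp), G_hat,
                            np.full(J, se_out))


@pytest.fixture
def small_dataset():
    return make_dataset(n=5, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
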