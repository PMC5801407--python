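"""Shared fixtures: small synthetic populations reused across the suite."""

import numpy as np
import pytest

from granos import design_matrix, qc_filter
from granos.simulate import SimConfig, profile_config, simulate_population


@pytest.fixture(scope="session")
def tiny_pop():
    """50 lines x 200 SNPs, 12 families, 2 planted QTL, h2 = 0.8."""
    cfg = profile_config("tiny", seed=3)
    g, pheno, truth, ped = simulate_population(cfg)
    g, _ = qc_filter(g)
    return g, pheno, truth, ped


@pytest.fixture(scope="session")
def null_pop():
    """Same population shape with no genetic signal at all."""
    cfg = profile_config("null", seed=5)
    g, pheno, truth, ped = simulate_population(cfg)
    g, _ = qc_filter(g)
    return g, pheno, truth, ped


@pytest.fixture(scope="session")
def medium_pop():
    """~240 lines x 500 SNPs, polygenic, for calibration-grade checks."""
    cfg = SimConfig(
        n_founders=40, n_families=48, family_sizes=[5] * 48, m=500,
        n_qtl=0, qtl_var_share=0.0, h2=0.8, seed=17,
    )
    g, pheno, truth, ped = simulate_population(cfg)
    g, _ = qc_filter(g)
    return g, pheno, truth, ped


@pytest.fixture(scope="session")
def tiny_design(tiny_pop):
    g, pheno, _, _ = tiny_pop
    X, names = design_matrix(pheno.set_factor)
    return X, names


def paired_architecture_fixture(seed, n=100, m=800):
    """Sparse (5 QTL) and fully polygenic traits on shared markers."""
    rng = np.random.default_rng(900 + seed)
    Z = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    u_s = np.zeros(m)
    u_s[rng.choice(m, 5, replace=False)] = rng.normal(0, 1, 5)
    g_s = Z @ u_s
    g_s *= np.sqrt(8.0 / g_s.var())
    y_s = g_s + rng.normal(0, np.sqrt(2.0), n)
    u_p = rng.normal(0, 1, m)
    g_p = Z @ u_p
    g_p *= np.sqrt(8.0 / g_p.var())
    y_p = g_p + rng.normal(0, np.sqrt(2.0), n)
    return Z, y_s, y_p


@pytest.fixture(scope="session")
def paired_beta_selections():
    """DIC-selected Power-Lasso shapes for 6 paired sparse/poly fixtures."""
    from granos.powerlasso import ChainConfig, select_beta

    grid = (0.2, 0.4, 0.6, 0.8, 1.0)
    cfg = ChainConfig(4_000, 1_500)
    sel_s, sel_p = [], []
    for seed in range(6):
        Z, y_s, y_p = paired_architecture_fixture(seed)
        X = np.ones((len(y_s), 1))
        b_s, _, _ = select_beta(y_s, X, Z, grid, cfg, seed=seed)
        b_p, _, _ = select_beta(y_p, X, Z, grid, cfg, seed=seed)
        sel_s.append(b_s)
        sel_p.append(b_p)
    return sel_s, sel_p


def structured_population(seed, n_families=24, fam_size=5, m=200, h2=0.8,
                          n_qtl=0, qtl_var_share=0.0, **kw):
    """Helper for multi-seed directional harnesses (small but structured)."""
    cfg = SimConfig(
        n_founders=20, n_families=n_families,
        family_sizes=[fam_size] * n_families, m=m, h2=h2, n_qtl=n_qtl,
        qtl_var_share=qtl_var_share, seed=seed, **kw,
    )
    g, pheno, truth, ped = simulate_population(cfg)
    g, _ = qc_filter(g)
    return g, pheno, truth, ped
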