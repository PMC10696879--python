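"""Shared fixtures: small seeded synthetic datasets, reused across modules."""

import numpy as np
import pytest

import hashatac as ha


@pytest.fixture(scope="session")
def hash_experiment():
    cfg = ha.SimConfig(n_cells=800, seed=101)
    matrix, truth = ha.simulate_hash_experiment(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def dose_dataset():
    cfg = ha.SimConfig(n_cells=1200, n_features=150, n_genes=80, seed=202)
    return cfg, ha.simulate_dose_response_dataset(cfg)


@pytest.fixture(scope="session")
def trajectory_dataset():
    cfg = ha.SimConfig(seed=303)
    return cfg, ha.simulate_trajectory_dataset(cfg)


@pytest.fixture(scope="session")
def hash_sample_map():
    return {f"hash{i}": f"sample{i}" for i in range(8)}


# ---------------------------------------------------------------------------
# independent GLM oracles (straightforward IRLS, kept free of package code)

def irls_glm(y, X, family, offset=None, n_iter=200, tol=1e-12):
    """Textbook iteratively reweighted least squares for canonical-link GLMs.

    family: 'binomial' (logit), 'poisson' (log), or ('negbin', alpha) with
    log link. Returns (beta, cov_unscaled).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    off = np.zeros(len(y)) if offset is None else np.asarray(offset, float)
    beta = np.zeros(X.shape[1])
    if family != "binomial":
        beta[0] = np.log(max(np.mean(y), 0.1)) - np.mean(off)
    for _ in range(n_iter):
        eta = np.clip(X @ beta + off, -30, 30)
        if family == "binomial":
            mu = 1.0 / (1.0 + np.exp(-eta))
            var = mu * (1 - mu)
            dmu = var  # dmu/deta for logit link
        else:
            mu = np.exp(eta)
            dmu = mu
            if family == "poisson":
                var = mu
            else:
                alpha = family[1]
                var = mu + alpha * mu**2
        w = dmu**2 / np.maximum(var, 1e-300)
        z = (eta - off) + (y - mu) / np.maximum(dmu, 1e-300)
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta + off
    if family == "binomial":
        mu = 1.0 / (1.0 + np.exp(-eta))
        var = mu * (1 - mu)
        dmu = var
    else:
        mu = np.exp(eta)
        dmu = mu
        var = mu if family == "poisson" else mu + family[1] * mu**2
    w = dmu**2 / np.maximum(var, 1e-300)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, cov


def bh_stepup(p):
    """Hand Benjamini-Hochberg: sorted p*m/rank with cumulative min."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
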