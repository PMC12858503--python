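import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from maihda import CodingScheme, Rule


def make_area_table(
    rng: np.random.Generator,
    n: int,
    outcome: np.ndarray | None = None,
) -> pd.DataFrame:
    """Random but valid area table."""
    if outcome is None:
        outcome = 20.0 + 10.0 * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "area_id": [f"A{i:05d}" for i in range(n)],
            "outcome": outcome,
            "imd_score": rng.gamma(2.0, 10.0, n),
            "pct_minority": np.clip(rng.lognormal(2.0, 1.0, n), 0, 99),
            "pct_degree": np.clip(rng.normal(33, 12, n), 1, 95),
            "urban": rng.integers(0, 2, n),
            "pct_65plus": np.clip(rng.normal(19, 8, n), 0, 70),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_scheme():
    """3 x 2 = 6 possible strata, driven by two covariates."""
    return CodingScheme(
        (
            Rule("ethnicity", "pct_minority", "quantile", 3),
            Rule("urban", "urban", "binary"),
        )
    )


def dense_loglik(y, X, groups, sigma2_u, sigma2_e):
    """Brute-force marginal log-likelihood via the full n x n covariance,
    beta profiled by explicit GLS. Independent of the package's
    sufficient-statistic path."""
    n = len(y)
    V = sigma2_e * np.eye(n) + sigma2_u * (groups[:, None] == groups[None, :])
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=V)


def grid_search_ml(y, X, groups):
    """Dense grid over (sigma2_u, sigma2_e) plus Nelder-Mead refinement of
    the same brute-force likelihood. Returns (loglik, sigma2_u, sigma2_e)."""
    v = np.var(y)
    s2u_grid = np.concatenate(([0.0], np.geomspace(1e-4 * v, 4 * v, 30)))
    s2e_grid = np.geomspace(1e-3 * v, 4 * v, 30)
    best = (-np.inf, 0.0, v)
    for a in s2u_grid:
        for b in s2e_grid:
            ll = dense_loglik(y, X, groups, a, b)
            if ll > best[0]:
                best = (ll, a, b)

    def neg(p):
        return -dense_loglik(y, X, groups, p[0] ** 2, np.exp(p[1]))

    x0 = np.array([np.sqrt(best[1]), np.log(best[2])])
    res = optimize.minimize(
        neg, x0, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 4000}
    )
    return -res.fun, res.x[0] ** 2, np.exp(res.x[1])
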