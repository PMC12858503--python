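"""Synthetic area-level datasets with the two-level structure the analysis
assumes.

Covariates are drawn from a Gaussian copula (latent correlations are
configurable) with skewed marginals, categorised by the default coding
scheme, and the outcome is assembled as

    y = intercept + sum(additive category effects)
        + injected interaction effect (per stratum code, if any)
        + u_code  (stratum draw, N(0, sigma2_u), one per *possible* code)
        + e_i    (area draw, N(0, sigma2_e))

The full truth record (per-code fixed parts, stratum draws, injections) is
returned on a separate channel from the table so that fitting code can
never see it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .strata import CodingScheme, categorize, default_scheme

#: latent-variable order for the copula
_COPULA_VARS = ("imd_score", "pct_minority", "pct_degree", "urban", "pct_65plus")

#: default latent correlations: minority rises with urbanity and education,
#: the 65+ share falls with urbanity; deprivation is mildly urban and
#: anti-correlated with the degree share.
DEFAULT_LATENT_CORR = np.array(
    [
        #  imd   minor  degree urban  65+
        [1.00, 0.25, -0.35, 0.20, -0.20],
        [0.25, 1.00, 0.30, 0.45, -0.30],
        [-0.35, 0.30, 1.00, 0.15, -0.25],
        [0.20, 0.45, 0.15, 1.00, -0.45],
        [-0.20, -0.30, -0.25, -0.45, 1.00],
    ]
)

#: marginal parameters: right-skewed lognormals for score/percent shares
#: (deprivation mean > median, as observed for IMD), gamma for the 65+ share.
DEFAULT_MARGINALS: dict[str, dict] = {
    "imd_score": {"dist": "lognorm", "s": 0.64, "scale": 17.67, "clip": (0.5, 95.0)},
    "pct_minority": {"dist": "lognorm", "s": 1.10, "scale": 8.5, "clip": (0.0, 99.2)},
    "pct_degree": {"dist": "lognorm", "s": 0.36, "scale": 31.4, "clip": (5.0, 95.0)},
    "pct_65plus": {"dist": "gamma", "a": 4.9, "scale": 3.86, "clip": (0.0, 80.0)},
}

#: additive category effects sized to give a realistic outcome spread
DEFAULT_EFFECTS: dict[tuple[str, int], float] = {
    ("deprivation", 2): 0.5,
    ("deprivation", 3): 1.7,
    ("ethnicity", 2): 3.7,
    ("ethnicity", 3): 10.7,
    ("education", 2): 0.0,
    ("education", 3): 0.4,
    ("urban", 1): 5.1,
    ("ageing", 1): -1.8,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one synthetic area table."""

    n_areas: int = 33755
    seed: int = 0
    urban_prevalence: float = 0.83
    latent_corr: np.ndarray = field(default_factory=lambda: DEFAULT_LATENT_CORR.copy())
    marginals: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()})
    intercept: float = 10.8
    effects: dict = field(default_factory=dict)
    sigma2_u: float = 35.0
    sigma2_e: float = 50.0
    interaction_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sigma2_u < 0 or self.sigma2_e <= 0:
            raise ConfigurationError("need sigma2_u >= 0 and sigma2_e > 0")
        if not (0.0 < self.urban_prevalence < 1.0):
            raise ConfigurationError("urban_prevalence must be in (0, 1)")
        corr = np.asarray(self.latent_corr, dtype=float)
        if corr.shape != (5, 5) or not np.allclose(corr, corr.T):
            raise ConfigurationError("latent_corr must be a symmetric 5x5 matrix")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError("latent_corr is not positive semi-definite")


def preset_study_like(n_areas: int = 33755, seed: int = 0, **overrides) -> SimulationConfig:
    """Config whose simulated outcome tracks a realistic national NOx
    surface: mean ~21 ug/m3, SD ~11, ~83% urban areas, uneven occupancy of
    up to 108 strata."""
    cfg = SimulationConfig(
        n_areas=n_areas, seed=seed, effects=dict(DEFAULT_EFFECTS), intercept=10.8
    )
    return replace(cfg, **overrides) if overrides else cfg


def _marginal_transform(name: str, u: np.ndarray, params: dict) -> np.ndarray:
    p = dict(params)
    dist_name = p.pop("dist")
    lo, hi = p.pop("clip")
    dist = getattr(stats, dist_name)
    return np.clip(dist.ppf(u, **p), lo, hi)


def simulate(
    config: SimulationConfig, scheme: CodingScheme | None = None
) -> tuple[pd.DataFrame, dict]:
    """Draw one area table; returns ``(table, truth)``.

    ``truth`` carries the generating parameters, the per-code stratum draws
    and fixed parts — keep it away from any fitting code path."""
    scheme = scheme or default_scheme(include_urban=True)
    n = config.n_areas
    rng_cov = np.random.default_rng([config.seed, 0])
    rng_u = np.random.default_rng([config.seed, 1])
    rng_e = np.random.default_rng([config.seed, 2])

    corr = np.asarray(config.latent_corr, dtype=float)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(5))
    z = rng_cov.standard_normal((n, 5)) @ chol.T

    cols: dict[str, np.ndarray] = {}
    for k, name in enumerate(_COPULA_VARS):
        if name == "urban":
            cols[name] = (z[:, k] > stats.norm.ppf(1.0 - config.urban_prevalence)).astype(int)
        else:
            u = stats.norm.cdf(z[:, k])
            cols[name] = _marginal_transform(name, u, config.marginals[name])

    table = pd.DataFrame(cols)
    table.insert(0, "area_id", [f"A{i:06d}" for i in range(n)])

    assignment = categorize(table, scheme)
    codes = assignment.codes.to_numpy()

    all_codes = scheme.all_possible_codes()
    u_draws = dict(zip(all_codes, np.sqrt(config.sigma2_u) * rng_u.standard_normal(len(all_codes))))

    unreachable = set(config.interaction_effects) - set(codes)
    if unreachable:
        warnings.warn(
            f"interaction effects on unoccupied stratum codes: {sorted(unreachable)}",
            stacklevel=2,
        )

    fixed_parts: dict[str, float] = {}
    for code in all_codes:
        cats = scheme.decode(code)
        fixed_parts[code] = config.intercept + sum(
            config.effects.get((var, cat), 0.0) for var, cat in cats.items()
        )

    per_area_mean = np.array(
        [
            fixed_parts[c] + config.interaction_effects.get(c, 0.0) + u_draws[c]
            for c in codes
        ]
    )
    y = per_area_mean + np.sqrt(config.sigma2_e) * rng_e.standard_normal(n)
    table.insert(1, "outcome", y)

    truth = {
        "intercept": config.intercept,
        "effects": {f"{var}[{cat}]": v for (var, cat), v in config.effects.items()},
        "sigma2_u": config.sigma2_u,
        "sigma2_e": config.sigma2_e,
        "interaction_effects": dict(config.interaction_effects),
        "u": u_draws,
        "fixed_part": fixed_parts,
        "n_areas": n,
        "seed": config.seed,
        "n_strata_occupied": assignment.n_occupied,
    }
    return table, truth
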