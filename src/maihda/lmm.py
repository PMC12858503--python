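"""Maximum-likelihood estimation of the two-level Gaussian random-intercept
model, with areas (level 1) nested in intersectional strata (level 2):

    y_ij = x_j' beta + u_j + e_ij,   u_j ~ N(0, sigma2_u),  e_ij ~ N(0, sigma2_e)

Because every fixed-effect covariate is stratum-defining, the fixed design
has one distinct row pattern per stratum and the marginal likelihood
factorises over strata under the compound-symmetry covariance
V_j = sigma2_e I + sigma2_u J. The implementation works entirely on the
per-stratum sufficient statistics (n_j, ybar_j, within-stratum SS):

* beta is profiled out by GLS, which reduces to WLS on the stratum means
  with weights n_j / (sigma2_e + n_j sigma2_u);
* sigma2_e is profiled analytically given theta = sigma2_u / sigma2_e;
* the remaining 1-D profile likelihood in theta is maximised by a coarse
  log-grid scan plus Brent refinement, with the theta = 0 boundary checked
  explicitly.

Empirical-Bayes stratum residuals use the standard two-level normal
posterior mean: u_hat_j = R_j * rbar_j with reliability
R_j = sigma2_u / (sigma2_u + sigma2_e / n_j) and comparative standard
error sqrt(sigma2_u (1 - R_j)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConsistencyError, FitError
from .strata import CodingScheme, StratumAssignment

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect specification: main-effect terms (categorical, dummy
    coded against each rule's reference category) plus optional two-way
    interactions between named terms. The intercept is always included;
    the null spec is ``ModelSpec()``."""

    terms: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    name: str = ""

    def __post_init__(self):
        for a, b in self.interactions:
            if a not in self.terms or b not in self.terms:
                raise FitError(
                    f"interaction ({a}, {b}) references a term not in the model"
                )

    @property
    def is_null(self) -> bool:
        return not self.terms


def main_effects_spec(scheme: CodingScheme, name: str = "") -> ModelSpec:
    """Spec with every rule of ``scheme`` entered as a main effect."""
    return ModelSpec(terms=scheme.names, name=name)


def build_design(
    assignment: StratumAssignment, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Stratum-level design matrix (one row per occupied stratum, ordered by
    registry index) with named columns; intercept first."""
    scheme = assignment.scheme
    codes = assignment.occupied_codes
    cats = {code: scheme.decode(code) for code in codes}

    cols: list[np.ndarray] = [np.ones(len(codes))]
    names: list[str] = ["intercept"]
    dummies: dict[tuple[str, int], np.ndarray] = {}
    for term in spec.terms:
        rule = scheme.rule(term)
        for cat in rule.categories:
            if cat == rule.reference:
                continue
            col = np.array([1.0 if cats[c][term] == cat else 0.0 for c in codes])
            dummies[(term, cat)] = col
            cols.append(col)
            names.append(f"{term}[{cat}]")
    for a, b in spec.interactions:
        ra, rb = scheme.rule(a), scheme.rule(b)
        for ca in ra.categories:
            if ca == ra.reference:
                continue
            for cb in rb.categories:
                if cb == rb.reference:
                    continue
                cols.append(dummies[(a, ca)] * dummies[(b, cb)])
                names.append(f"{a}[{ca}]:{b}[{cb}]")
    return np.column_stack(cols), names


@dataclass(frozen=True)
class SufficientStats:
    """Per-stratum reductions of the outcome: sizes, means, within-SS."""

    n: np.ndarray        # n_j, ordered by registry index
    ybar: np.ndarray     # stratum means
    ssw: np.ndarray      # within-stratum sum of squares about the mean
    codes: tuple[str, ...]

    @property
    def n_total(self) -> int:
        return int(self.n.sum())

    @property
    def n_strata(self) -> int:
        return len(self.n)


def sufficient_stats(
    table: pd.DataFrame, assignment: StratumAssignment
) -> SufficientStats:
    if set(table["area_id"]) != set(assignment.codes.index):
        raise ConsistencyError("area ids of table and assignment differ")
    y = table["outcome"].to_numpy(dtype=float)
    j = assignment.indices_for(table)
    nj = np.bincount(j, minlength=assignment.n_occupied).astype(float)
    sums = np.bincount(j, weights=y, minlength=assignment.n_occupied)
    ybar = sums / nj
    ssw = np.bincount(j, weights=(y - ybar[j]) ** 2, minlength=assignment.n_occupied)
    return SufficientStats(
        n=nj, ybar=ybar, ssw=ssw, codes=tuple(assignment.occupied_codes)
    )


@dataclass(frozen=True)
class FitResult:
    """ML solution of one model: coefficient table, variance components,
    likelihood, and bookkeeping for downstream consistency checks."""

    params: pd.DataFrame          # name, estimate, se, ci_lo, ci_hi, z, p
    sigma2_u: float
    sigma2_e: float
    loglik: float
    aic: float
    n_areas: int
    n_strata_occupied: int
    converged: bool
    boundary_sigma2_u: bool
    boundary_sigma2_e: bool
    n_iter: int
    spec: ModelSpec = field(default=ModelSpec(), compare=False)
    codes: tuple[str, ...] = field(default=(), compare=False)

    @property
    def beta(self) -> np.ndarray:
        return self.params["estimate"].to_numpy()

    def coef(self, name: str) -> float:
        row = self.params.loc[self.params["name"] == name]
        if row.empty:
            raise KeyError(name)
        return float(row["estimate"].iloc[0])


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns that add no rank when entered left-to-right."""
    bad = []
    rank = 0
    for k in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : k + 1])
        if new_rank == rank:
            bad.append(names[k])
        rank = new_rank
    return bad


def _profile(theta: float, X: np.ndarray, ss: SufficientStats):
    """Profile out beta and sigma2_e at a given theta = sigma2_u/sigma2_e.

    Returns (loglik, beta, sigma2_e)."""
    n = ss.n
    w = n / (1.0 + n * theta)
    xtw = X.T * w
    beta = np.linalg.solve(xtw @ X, xtw @ ss.ybar)
    r = ss.ybar - X @ beta
    q = ss.ssw.sum() + float(w @ r**2)
    ntot = ss.n_total
    if q <= 0.0:
        return math.inf, beta, 0.0
    s2e = q / ntot
    ll = -0.5 * (
        ntot * (_LOG2PI + math.log(s2e)) + float(np.log1p(n * theta).sum()) + ntot
    )
    return ll, beta, s2e


def fit(
    table: pd.DataFrame,
    assignment: StratumAssignment,
    spec: ModelSpec = ModelSpec(),
    *,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> FitResult:
    """Maximise the exact marginal likelihood over (sigma2_u, sigma2_e).

    Raises :class:`FitError` on a singular design (naming the collinear
    columns) or non-convergence, :class:`ConsistencyError` on mismatched
    inputs."""
    ss = sufficient_stats(table, assignment)
    if ss.n_strata < 2 and not spec.is_null:
        raise FitError("need >= 2 occupied strata to fit a random-intercept model")
    X, names = build_design(assignment, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(f"singular design; collinear terms: {_collinear_columns(X, names)}")

    # Degenerate zero-variance input: all outcomes identical.
    y = table["outcome"].to_numpy(dtype=float)
    if float(np.var(y)) == 0.0:
        beta = np.zeros(X.shape[1])
        beta[0] = y[0]
        params = _param_table(names, beta, np.zeros(X.shape[1]))
        return FitResult(
            params=params,
            sigma2_u=0.0,
            sigma2_e=0.0,
            loglik=math.inf,
            aic=-math.inf,
            n_areas=ss.n_total,
            n_strata_occupied=ss.n_strata,
            converged=True,
            boundary_sigma2_u=True,
            boundary_sigma2_e=True,
            n_iter=0,
            spec=spec,
            codes=ss.codes,
        )

    # Coarse scan of the 1-D profile likelihood in log10(theta), then Brent.
    grid = np.concatenate(([0.0], 10.0 ** np.linspace(-8.0, 5.0, 66)))
    lls = np.array([_profile(t, X, ss)[0] for t in grid])
    best = int(np.nanargmax(lls))
    n_evals = len(grid)

    if best == 0:
        theta_hat, ll_hat = 0.0, lls[0]
        boundary_u = True
    else:
        lo = grid[best - 1] if best > 1 else 0.0
        hi = grid[best + 1] if best < len(grid) - 1 else grid[best] * 10.0
        neg = lambda t: -_profile(t, X, ss)[0]
        res = optimize.minimize_scalar(
            neg,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol * max(grid[best], 1.0), "maxiter": max_iter},
        )
        n_evals += res.nfev
        theta_hat, ll_hat = float(res.x), -float(res.fun)
        boundary_u = False
        # Boundary wins if the interior refinement cannot beat theta = 0.
        if lls[0] >= ll_hat:
            theta_hat, ll_hat, boundary_u = 0.0, lls[0], True
        if not res.success and abs(ll_hat - lls[best]) > 1e-6 * abs(lls[best]):
            raise FitError(
                f"variance optimisation did not converge; last state "
                f"theta={theta_hat:.6g}, loglik={ll_hat:.6g}"
            )

    _, beta, s2e = _profile(theta_hat, X, ss)
    s2u = theta_hat * s2e

    # Wald inference for beta at the ML variances.
    w = ss.n / (s2e + ss.n * s2u)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    params = _param_table(names, beta, se)

    p = X.shape[1]
    aic = -2.0 * ll_hat + 2.0 * (p + 2)
    logger.info(
        "fit %s: %d areas, %d strata, %d likelihood evals, "
        "sigma2_u=%.4f sigma2_e=%.4f loglik=%.4f%s",
        spec.name or "(unnamed)",
        ss.n_total,
        ss.n_strata,
        n_evals,
        s2u,
        s2e,
        ll_hat,
        " [sigma2_u at boundary]" if boundary_u else "",
    )
    return FitResult(
        params=params,
        sigma2_u=float(s2u),
        sigma2_e=float(s2e),
        loglik=float(ll_hat),
        aic=float(aic),
        n_areas=ss.n_total,
        n_strata_occupied=ss.n_strata,
        converged=True,
        boundary_sigma2_u=boundary_u,
        boundary_sigma2_e=False,
        n_iter=n_evals,
        spec=spec,
        codes=ss.codes,
    )


def _param_table(names: list[str], beta: np.ndarray, se: np.ndarray) -> pd.DataFrame:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "name": names,
            "estimate": beta,
            "se": se,
            "ci_lo": beta - 1.96 * se,
            "ci_hi": beta + 1.96 * se,
            "z": z,
            "p": pvals,
        }
    )


def loglik_at(
    sigma2_u: float,
    sigma2_e: float,
    table: pd.DataFrame,
    assignment: StratumAssignment,
    spec: ModelSpec = ModelSpec(),
) -> float:
    """Exact marginal log-likelihood at fixed variances, beta profiled by GLS.

    Raises ``ValueError`` for sigma2_e <= 0 or sigma2_u < 0."""
    if sigma2_e <= 0.0:
        raise ValueError(f"sigma2_e must be > 0, got {sigma2_e}")
    if sigma2_u < 0.0:
        raise ValueError(f"sigma2_u must be >= 0, got {sigma2_u}")
    ss = sufficient_stats(table, assignment)
    X, _ = build_design(assignment, spec)
    n = ss.n
    w = n / (sigma2_e + n * sigma2_u)
    xtw = X.T * w
    beta = np.linalg.solve(xtw @ X, xtw @ ss.ybar)
    r = ss.ybar - X @ beta
    logdet = float(ss.n_total * math.log(sigma2_e) + np.log1p(n * sigma2_u / sigma2_e).sum())
    quad = float(ss.ssw.sum() / sigma2_e + w @ r**2)
    return -0.5 * (ss.n_total * _LOG2PI + logdet + quad)


@dataclass(frozen=True)
class StratumEffects:
    """Empirical-Bayes stratum residuals for one fitted model.

    ``table`` columns: code, n, raw_mean_resid, shrinkage, u_hat, se_u,
    ci_lo, ci_hi — one row per occupied stratum, ordered by code."""

    table: pd.DataFrame
    sigma2_u: float
    sigma2_e: float

    def __len__(self) -> int:
        return len(self.table)


def eb_residuals(
    fit_result: FitResult,
    table: pd.DataFrame,
    assignment: StratumAssignment,
    spec: ModelSpec | None = None,
) -> StratumEffects:
    """Shrunken stratum residuals u_hat_j = R_j * rbar_j.

    R_j = sigma2_u / (sigma2_u + sigma2_e / n_j); the comparative SE is
    sqrt(sigma2_u (1 - R_j)). Empty strata never appear here — they are
    listed on the assignment's ``empty_codes``."""
    spec = spec if spec is not None else fit_result.spec
    ss = sufficient_stats(table, assignment)
    if ss.codes != fit_result.codes or ss.n_total != fit_result.n_areas:
        raise ConsistencyError("fit result does not match this table/assignment")
    X, _ = build_design(assignment, spec)
    raw = ss.ybar - X @ fit_result.beta
    s2u, s2e = fit_result.sigma2_u, fit_result.sigma2_e
    if s2u == 0.0:
        R = np.zeros_like(raw)
    else:
        R = s2u / (s2u + s2e / ss.n)
    u_hat = R * raw
    se_u = np.sqrt(s2u * (1.0 - R))
    eff = pd.DataFrame(
        {
            "code": ss.codes,
            "n": ss.n.astype(int),
            "raw_mean_resid": raw,
            "shrinkage": R,
            "u_hat": u_hat,
            "se_u": se_u,
            "ci_lo": u_hat - 1.96 * se_u,
            "ci_hi": u_hat + 1.96 * se_u,
        }
    )
    return StratumEffects(table=eff, sigma2_u=s2u, sigma2_e=s2e)
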