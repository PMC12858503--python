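import math

import numpy as np
import pandas as pd
import pytest

from maihda import (
    CodingScheme,
    ConsistencyError,
    FitError,
    FitResult,
    ModelSpec,
    Rule,
    categorize,
    eb_residuals,
    fit,
    loglik_at,
    main_effects_spec,
)
from maihda.lmm import build_design, sufficient_stats

from conftest import dense_loglik, grid_search_ml, make_area_table


def expand_design(table, assignment, spec):
    """Area-level design and group index for the brute-force oracle."""
    X, _ = build_design(assignment, spec)
    j = assignment.indices_for(table)
    return X[j], j


@pytest.fixture
def fixture_3x4(rng):
    """3 strata x 4 areas with fixed outcomes (frozen fixture)."""
    table = make_area_table(rng, 12)
    table["urban"] = [0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1]
    table["pct_minority"] = list(range(12))
    # strata defined by tertiles of pct_minority only
    scheme = CodingScheme((Rule("ethnicity", "pct_minority", "quantile", 3),))
    table["outcome"] = [
        12.1, 9.8, 11.4, 10.7,
        18.3, 20.1, 17.6, 19.9,
        25.2, 23.8, 26.7, 24.4,
    ]
    return table, categorize(table, scheme)


class TestFit:
    def test_constant_outcome_is_boundary(self, rng, tiny_scheme):
        table = make_area_table(rng, 20, outcome=np.full(20, 7.5))
        assignment = categorize(table, tiny_scheme)
        res = fit(table, assignment)
        assert res.coef("intercept") == 7.5
        assert res.sigma2_u == 0.0
        assert res.sigma2_e == 0.0
        assert res.boundary_sigma2_u and res.boundary_sigma2_e

    def test_matches_grid_search_oracle_null(self, fixture_3x4):
        table, assignment = fixture_3x4
        res = fit(table, assignment)
        X, groups = expand_design(table, assignment, ModelSpec())
        y = table["outcome"].to_numpy()
        ll_o, s2u_o, s2e_o = grid_search_ml(y, X, groups)
        assert res.loglik == pytest.approx(ll_o, abs=1e-6)
        assert res.sigma2_u == pytest.approx(s2u_o, abs=1e-4)
        assert res.sigma2_e == pytest.approx(s2e_o, abs=1e-4)

    def test_matches_grid_search_oracle_random_instances(self, rng, tiny_scheme):
        for k in range(5):
            n = int(rng.integers(15, 50))
            table = make_area_table(rng, n)
            assignment = categorize(table, tiny_scheme)
            spec = ModelSpec() if k % 2 == 0 else ModelSpec(terms=("urban",))
            res = fit(table, assignment, spec)
            X, groups = expand_design(table, assignment, spec)
            ll_o, _, _ = grid_search_ml(table["outcome"].to_numpy(), X, groups)
            assert res.loglik == pytest.approx(ll_o, abs=1e-6)

    def test_balanced_closed_form(self, rng):
        # Balanced one-way, intercept only: sigma2_e = SSW/(N-J),
        # sigma2_u = (SSB/J - sigma2_e)/m  (ML from sufficient statistics).
        J, m = 8, 10
        u = rng.normal(0, 3.0, J)
        y = np.concatenate([20 + u[j] + rng.normal(0, 2.0, m) for j in range(J)])
        table = make_area_table(rng, J * m, outcome=y)
        table["pct_minority"] = np.repeat(np.arange(J), m)
        scheme = CodingScheme((Rule("g", "pct_minority", "quantile", J),))
        assignment = categorize(table, scheme)
        res = fit(table, assignment)

        ybars = y.reshape(J, m).mean(axis=1)
        ssw = ((y.reshape(J, m) - ybars[:, None]) ** 2).sum()
        ssb = m * ((ybars - y.mean()) ** 2).sum()
        s2e_cf = ssw / (J * m - J)
        s2u_cf = (ssb / J - s2e_cf) / m
        assert res.coef("intercept") == pytest.approx(y.mean(), abs=1e-8)
        assert res.sigma2_e == pytest.approx(s2e_cf, rel=1e-6)
        assert res.sigma2_u == pytest.approx(s2u_cf, rel=1e-6)

    def test_shift_invariance(self, fixture_3x4):
        table, assignment = fixture_3x4
        res = fit(table, assignment)
        shifted = table.copy()
        shifted["outcome"] = shifted["outcome"] + 100.0
        res2 = fit(shifted, categorize(shifted, assignment.scheme))
        assert res2.coef("intercept") == pytest.approx(res.coef("intercept") + 100.0, abs=1e-6)
        assert res2.sigma2_u == pytest.approx(res.sigma2_u, rel=1e-6)
        assert res2.sigma2_e == pytest.approx(res.sigma2_e, rel=1e-6)

    def test_singular_design_names_terms(self, rng):
        table = make_area_table(rng, 30)
        table["pct_65plus"] = 60.0 * table["urban"]  # thresholded 65+ duplicates urban
        scheme = CodingScheme(
            (
                Rule("urban", "urban", "binary"),
                Rule("ageing", "pct_65plus", "threshold", 25.0),
            )
        )
        assignment = categorize(table, scheme)
        with pytest.raises(FitError, match="ageing"):
            fit(table, assignment, ModelSpec(terms=("urban", "ageing")))

    def test_aic_formula(self, fixture_3x4):
        table, assignment = fixture_3x4
        res = fit(table, assignment)
        assert res.aic == pytest.approx(-2 * res.loglik + 2 * (1 + 2))

    def test_parameter_recovery_balanced(self):
        # ML has a small O(1/J) downward bias in sigma2_u; allow for it.
        J, m, s2u, s2e, reps = 9, 150, 40.0, 50.0, 40
        est_u, est_e = [], []
        for rep in range(reps):
            r = np.random.default_rng(500 + rep)
            u = r.normal(0, math.sqrt(s2u), J)
            y = (u[:, None] + r.normal(0, math.sqrt(s2e), (J, m))).ravel() + 20
            table = make_area_table(r, J * m, outcome=y)
            table["pct_minority"] = np.repeat(np.arange(J), m)
            scheme = CodingScheme((Rule("g", "pct_minority", "quantile", J),))
            res = fit(table, categorize(table, scheme))
            est_u.append(res.sigma2_u)
            est_e.append(res.sigma2_e)
        se_u = np.std(est_u) / math.sqrt(reps)
        se_e = np.std(est_e) / math.sqrt(reps)
        assert abs(np.mean(est_u) - s2u) <= 1.96 * se_u + s2u / J
        assert abs(np.mean(est_e) - s2e) <= 1.96 * se_e + s2e / (J * m)

    def test_statsmodels_cross_check(self, rng, tiny_scheme):
        sm = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        table = make_area_table(rng, 300)
        assignment = categorize(table, tiny_scheme)
        groups = assignment.indices_for(table)
        u = rng.normal(0, 2.0, assignment.n_occupied)
        table["outcome"] = (
            15 + 2.0 * table["urban"].to_numpy() + u[groups] + rng.normal(0, 3, 300)
        )
        spec = ModelSpec(terms=("urban",))
        res = fit(table, assignment, spec)
        X, _ = expand_design(table, assignment, spec)
        md = sm.MixedLM(table["outcome"].to_numpy(), X, groups=groups)
        smres = md.fit(reml=False)
        assert res.loglik == pytest.approx(smres.llf, abs=1e-4)
        assert res.sigma2_e == pytest.approx(smres.scale, rel=1e-3)
        assert res.sigma2_u == pytest.approx(float(np.asarray(smres.cov_re)[0, 0]), rel=1e-3)
        np.testing.assert_allclose(res.beta, smres.fe_params, rtol=1e-4)


class TestLoglikAt:
    def test_self_consistency_at_optimum(self, fixture_3x4):
        table, assignment = fixture_3x4
        res = fit(table, assignment)
        ll = loglik_at(res.sigma2_u, res.sigma2_e, table, assignment)
        assert ll == pytest.approx(res.loglik, abs=1e-8)

    def test_local_optimality(self, fixture_3x4):
        table, assignment = fixture_3x4
        res = fit(table, assignment)
        for du, de in [(1.1, 1.0), (0.9, 1.0), (1.0, 1.1), (1.0, 0.9)]:
            ll = loglik_at(res.sigma2_u * du, res.sigma2_e * de, table, assignment)
            assert ll < res.loglik

    def test_matches_dense_likelihood(self, fixture_3x4):
        table, assignment = fixture_3x4
        X, groups = expand_design(table, assignment, ModelSpec())
        y = table["outcome"].to_numpy()
        for s2u, s2e in [(0.0, 5.0), (2.0, 3.0), (40.0, 50.0)]:
            assert loglik_at(s2u, s2e, table, assignment) == pytest.approx(
                dense_loglik(y, X, groups, s2u, s2e), abs=1e-8
            )

    def test_two_point_hand_computed(self, rng):
        # J=2, one area each: y_i ~ N(beta0, s2u + s2e), beta0 = mean.
        table = make_area_table(rng, 2, outcome=np.array([4.0, 10.0]))
        table["urban"] = [0, 1]
        scheme = CodingScheme((Rule("urban", "urban", "binary"),))
        assignment = categorize(table, scheme)
        s2u, s2e = 3.0, 2.0
        v = s2u + s2e
        hand = sum(
            -0.5 * (math.log(2 * math.pi * v) + (yi - 7.0) ** 2 / v) for yi in (4.0, 10.0)
        )
        assert loglik_at(s2u, s2e, table, assignment) == pytest.approx(hand, abs=1e-12)

    def test_nonpositive_sigma2_e_rejected(self, fixture_3x4):
        table, assignment = fixture_3x4
        with pytest.raises(ValueError, match="sigma2_e"):
            loglik_at(1.0, 0.0, table, assignment)
        with pytest.raises(ValueError, match="sigma2_u"):
            loglik_at(-1.0, 1.0, table, assignment)


def _intercept_params(beta0=0.0):
    return pd.DataFrame(
        {
            "name": ["intercept"],
            "estimate": [beta0],
            "se": [0.0],
            "ci_lo": [beta0],
            "ci_hi": [beta0],
            "z": [np.nan],
            "p": [np.nan],
        }
    )


class TestEbResiduals:
    def _two_strata_table(self, n_per, means, rng):
        n = 2 * n_per
        table = make_area_table(rng, n)
        table["urban"] = [0] * n_per + [1] * n_per
        table["outcome"] = np.repeat(means, n_per).astype(float)
        scheme = CodingScheme((Rule("urban", "urban", "binary"),))
        return table, categorize(table, scheme)

    def test_closed_form_arithmetic(self, rng):
        # sigma2_u=4, sigma2_e=16, n_j=4, raw mean residual 2 -> R=0.5, u=1, se=sqrt(2)
        table, assignment = self._two_strata_table(4, [-2.0, 2.0], rng)
        fr = FitResult(
            params=_intercept_params(0.0),
            sigma2_u=4.0,
            sigma2_e=16.0,
            loglik=0.0,
            aic=0.0,
            n_areas=8,
            n_strata_occupied=2,
            converged=True,
            boundary_sigma2_u=False,
            boundary_sigma2_e=False,
            n_iter=1,
            spec=ModelSpec(),
            codes=("0", "1"),
        )
        eff = eb_residuals(fr, table, assignment).table.set_index("code")
        assert eff.loc["1", "raw_mean_resid"] == pytest.approx(2.0)
        assert eff.loc["1", "shrinkage"] == pytest.approx(0.5)
        assert eff.loc["1", "u_hat"] == pytest.approx(1.0)
        assert eff.loc["1", "se_u"] == pytest.approx(math.sqrt(2.0))
        assert eff.loc["0", "u_hat"] == pytest.approx(-1.0)

    def test_zero_sigma2_u_gives_zero_residuals(self, rng, tiny_scheme):
        table = make_area_table(rng, 40)
        assignment = categorize(table, tiny_scheme)
        res = fit(table, assignment)
        fr = FitResult(
            params=res.params,
            sigma2_u=0.0,
            sigma2_e=res.sigma2_e,
            loglik=res.loglik,
            aic=res.aic,
            n_areas=res.n_areas,
            n_strata_occupied=res.n_strata_occupied,
            converged=True,
            boundary_sigma2_u=True,
            boundary_sigma2_e=False,
            n_iter=1,
            spec=ModelSpec(),
            codes=res.codes,
        )
        eff = eb_residuals(fr, table, assignment).table
        assert (eff["u_hat"] == 0).all()
        assert (eff["shrinkage"] == 0).all()

    def test_shrinkage_limit_large_stratum(self, rng):
        n_per = 10**6
        table, assignment = self._two_strata_table(1, [-2.0, 2.0], rng)
        # replace stratum '1' with a huge stratum at mean 2
        big = make_area_table(np.random.default_rng(1), n_per)
        big["area_id"] = [f"B{i:07d}" for i in range(n_per)]
        big["urban"] = 1
        big["outcome"] = 2.0 + 0.01 * np.random.default_rng(2).standard_normal(n_per)
        table = pd.concat([table[table["urban"] == 0], big], ignore_index=True)
        scheme = CodingScheme((Rule("urban", "urban", "binary"),))
        assignment = categorize(table, scheme)
        res = fit(table, assignment)
        eff = eb_residuals(res, table, assignment).table.set_index("code")
        assert eff.loc["1", "shrinkage"] > 0.999
        assert eff.loc["1", "u_hat"] == pytest.approx(
            eff.loc["1", "raw_mean_resid"], rel=1e-3
        )

    def test_shrinkage_towards_zero_and_weighted_mean(self, rng, tiny_scheme):
        table = make_area_table(rng, 200)
        assignment = categorize(table, tiny_scheme)
        res = fit(table, assignment)
        eff = eb_residuals(res, table, assignment).table
        assert (eff["u_hat"].abs() <= eff["raw_mean_resid"].abs() + 1e-12).all()
        # GLS normal equations make sum of u_hat exactly zero for intercept models
        assert eff["u_hat"].sum() == pytest.approx(0.0, abs=1e-8)

    def test_mismatched_inputs_rejected(self, rng, tiny_scheme):
        table = make_area_table(rng, 40)
        assignment = categorize(table, tiny_scheme)
        res = fit(table, assignment)
        other = make_area_table(np.random.default_rng(9), 35)
        other_assign = categorize(other, tiny_scheme)
        with pytest.raises(ConsistencyError):
            eb_residuals(res, other, other_assign)


def test_sufficient_stats_match_pandas(rng, tiny_scheme):
    table = make_area_table(rng, 120)
    assignment = categorize(table, tiny_scheme)
    ss = sufficient_stats(table, assignment)
    grouped = table.assign(code=assignment.codes.loc[table["area_id"]].to_numpy()).groupby(
        "code"
    )["outcome"]
    np.testing.assert_allclose(ss.ybar, grouped.mean().to_numpy())
    np.testing.assert_allclose(ss.n, grouped.size().to_numpy())
    np.testing.assert_allclose(
        ss.ssw, grouped.apply(lambda s: ((s - s.mean()) ** 2).sum()).to_numpy()
    )
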