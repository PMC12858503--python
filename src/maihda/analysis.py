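"""Model-sequence orchestration and intersectional summary statistics.

Runs the canonical five-model ladder — null and main-effects models on the
4-variable strata (1a/1b), the same pair on the 5-variable strata including
rural/urban (2a/2b), and optionally the main-effects model plus one two-way
interaction (3) — then derives, per model: the variance partition
coefficient VPC = s2u / (s2u + s2e), the proportional change in variance
PCV = (s2u_null - s2u_model) / s2u_null against the null sharing the same
stratum structure, ranked shrunken stratum predictions, and the list of
strata whose EB residual 95% interval excludes zero ("interaction
effects").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import FitError
from .lmm import (
    FitResult,
    ModelSpec,
    StratumEffects,
    build_design,
    eb_residuals,
    fit,
    main_effects_spec,
)
from .strata import CodingScheme, StratumAssignment, categorize

logger = logging.getLogger(__name__)


def vpc(sigma2_u: float, sigma2_e: float) -> float:
    """Variance partition coefficient, as a proportion in [0, 1]."""
    if sigma2_u < 0 or sigma2_e < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma2_u + sigma2_e
    if tot == 0:
        raise ValueError("VPC undefined: both variance components are zero")
    return sigma2_u / tot


def pcv(sigma2_u_null: float, sigma2_u_adjusted: float) -> float:
    """Proportional change in variance vs the null model (may be negative)."""
    if sigma2_u_null <= 0:
        raise ValueError("PCV undefined: null between-stratum variance must be > 0")
    return (sigma2_u_null - sigma2_u_adjusted) / sigma2_u_null


def format_percent(x: float) -> str:
    """Two-decimal percentage with half-up rounding, e.g. 0.44874 -> '44.87%'."""
    return f"{Decimal(x * 100).quantize(Decimal('0.01'), rounding=ROUND_HALF_UP)}%"


def predict_strata(
    fit_result: FitResult,
    effects: StratumEffects,
    assignment: StratumAssignment,
) -> pd.DataFrame:
    """Per-stratum predicted mean (fixed part + EB residual), ranked.

    The 95% interval reflects EB posterior uncertainty only. Rank 1 is the
    highest prediction; ties break by code lexicographic order."""
    X, _ = build_design(assignment, fit_result.spec)
    fixed = X @ fit_result.beta
    eff = effects.table
    out = pd.DataFrame(
        {
            "code": eff["code"],
            "n": eff["n"],
            "fixed_part": fixed,
            "u_hat": eff["u_hat"],
            "predicted": fixed + eff["u_hat"].to_numpy(),
            "se": eff["se_u"],
        }
    )
    out["ci_lo"] = out["predicted"] - 1.96 * out["se"]
    out["ci_hi"] = out["predicted"] + 1.96 * out["se"]
    out = out.sort_values(["predicted", "code"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def flag_interactions(effects: StratumEffects) -> pd.DataFrame:
    """Strata whose EB 95% interval excludes zero, ordered by u_hat.

    No multiplicity correction is applied."""
    eff = effects.table
    sig = eff[(eff["ci_lo"] > 0) | (eff["ci_hi"] < 0)].copy()
    sig["sign"] = np.where(sig["u_hat"] > 0, "positive", "negative")
    return sig.sort_values(["u_hat", "code"], kind="mergesort").reset_index(drop=True)


def describe_strata(preds: pd.DataFrame, scheme: CodingScheme, k: int = 10) -> dict:
    """Top-k / bottom-k prediction tables with per-digit category labels."""

    def expand(rows: pd.DataFrame) -> pd.DataFrame:
        desc = pd.DataFrame([scheme.describe(c) for c in rows["code"]])
        return pd.concat(
            [rows[["rank", "code", "predicted", "ci_lo", "ci_hi", "n"]].reset_index(drop=True), desc],
            axis=1,
        )

    return {"top": expand(preds.head(k)), "bottom": expand(preds.tail(k))}


@dataclass(frozen=True)
class EimSummary:
    """Headline numbers for one fitted model."""

    label: str
    vpc: float
    pcv: float | None            # None for null models
    sigma2_u: float
    sigma2_e: float
    aic: float
    loglik: float
    n_areas: int
    n_strata_occupied: int
    n_significant: int

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "vpc": self.vpc,
            "vpc_pct": self.vpc * 100,
            "pcv": self.pcv,
            "pcv_pct": None if self.pcv is None else self.pcv * 100,
            "sigma2_u": self.sigma2_u,
            "sigma2_e": self.sigma2_e,
            "aic": self.aic,
            "loglik": self.loglik,
            "n_areas": self.n_areas,
            "n_strata_occupied": self.n_strata_occupied,
            "n_significant": self.n_significant,
        }


@dataclass(frozen=True)
class ModelResult:
    """Everything produced for one model in the sequence."""

    label: str
    spec: ModelSpec
    assignment: StratumAssignment
    fit: FitResult
    effects: StratumEffects
    predictions: pd.DataFrame
    significant: pd.DataFrame
    summary: EimSummary


def _run_one(
    label: str,
    table: pd.DataFrame,
    assignment: StratumAssignment,
    spec: ModelSpec,
    sigma2_u_null: float | None,
) -> ModelResult:
    try:
        fr = fit(table, assignment, spec)
    except FitError as exc:
        raise FitError(f"model {label}: {exc}") from exc
    eff = eb_residuals(fr, table, assignment)
    preds = predict_strata(fr, eff, assignment)
    sig = flag_interactions(eff)
    summary = EimSummary(
        label=label,
        vpc=vpc(fr.sigma2_u, fr.sigma2_e),
        pcv=None if sigma2_u_null is None else pcv(sigma2_u_null, fr.sigma2_u),
        sigma2_u=fr.sigma2_u,
        sigma2_e=fr.sigma2_e,
        aic=fr.aic,
        loglik=fr.loglik,
        n_areas=fr.n_areas,
        n_strata_occupied=fr.n_strata_occupied,
        n_significant=len(sig),
    )
    logger.info(
        "model %s: VPC=%s PCV=%s AIC=%.1f, %d flagged strata",
        label,
        format_percent(summary.vpc),
        "-" if summary.pcv is None else format_percent(summary.pcv),
        summary.aic,
        summary.n_significant,
    )
    return ModelResult(label, spec, assignment, fr, eff, preds, sig, summary)


def run_model_sequence(
    table: pd.DataFrame,
    scheme_without_urban: CodingScheme,
    scheme_with_urban: CodingScheme,
    interaction: tuple[str, str] | None = ("ethnicity", "urban"),
) -> list[ModelResult]:
    """Fit models 1a, 1b, 2a, 2b and (optionally) 3, wiring each PCV to the
    null model that shares its stratum structure (1b vs 1a; 2b and 3 vs 2a)."""
    assign4 = categorize(table, scheme_without_urban)
    assign5 = categorize(table, scheme_with_urban)

    results: list[ModelResult] = []
    m1a = _run_one("1a", table, assign4, ModelSpec(name="1a"), None)
    results.append(m1a)
    results.append(
        _run_one(
            "1b",
            table,
            assign4,
            main_effects_spec(scheme_without_urban, name="1b"),
            m1a.fit.sigma2_u,
        )
    )
    m2a = _run_one("2a", table, assign5, ModelSpec(name="2a"), None)
    results.append(m2a)
    results.append(
        _run_one(
            "2b",
            table,
            assign5,
            main_effects_spec(scheme_with_urban, name="2b"),
            m2a.fit.sigma2_u,
        )
    )
    if interaction is not None:
        spec3 = ModelSpec(
            terms=scheme_with_urban.names, interactions=(tuple(interaction),), name="3"
        )
        results.append(_run_one("3", table, assign5, spec3, m2a.fit.sigma2_u))
    return results
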