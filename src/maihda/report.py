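"""Writers for the per-run report bundle.

Data CSVs carry full precision; ``model_comparison.csv`` is the
human-readable coefficient table (two-decimal estimates, CI brackets,
significance stars) laid out with one column per model.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .analysis import ModelResult, describe_strata, format_percent


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def model_comparison_frame(results: list[ModelResult]) -> pd.DataFrame:
    """Coefficient/variance comparison table, one column per model."""
    rows: dict[str, dict[str, str]] = {}
    order: list[str] = []

    def put(row: str, label: str, value: str):
        if row not in rows:
            rows[row] = {}
            order.append(row)
        rows[row][label] = value

    for res in results:
        label = res.label
        for _, prm in res.fit.params.iterrows():
            name = prm["name"]
            put(name, label, f"{prm['estimate']:.2f}{_stars(prm['p'])}")
            put(f"{name} 95% CI", label, f"[{prm['ci_lo']:.2f} {prm['ci_hi']:.2f}]")
        s = res.summary
        put("Between-stratum variance", label, f"{s.sigma2_u:.2f}")
        put("Within-stratum variance", label, f"{s.sigma2_e:.2f}")
        put("Number of observations", label, f"{s.n_areas:,}")
        put("Number of strata", label, str(s.n_strata_occupied))
        put("AIC", label, f"{s.aic:.1f}")
        put("VPC", label, format_percent(s.vpc))
        put("PCV", label, "-" if s.pcv is None else format_percent(s.pcv))

    labels = [r.label for r in results]
    frame = pd.DataFrame(
        [[rows[r].get(lbl, "-") for lbl in labels] for r in order],
        index=pd.Index(order, name="quantity"),
        columns=labels,
    )
    return frame


def write_report_bundle(results: list[ModelResult], outdir: str | Path) -> list[Path]:
    """Write the full bundle; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = outdir / "model_comparison.csv"
    model_comparison_frame(results).to_csv(path)
    written.append(path)

    for res in results:
        p = outdir / f"stratum_predictions_{res.label}.csv"
        res.predictions.to_csv(p, index=False)
        written.append(p)
        p = outdir / f"interaction_flags_{res.label}.csv"
        res.significant.to_csv(p, index=False)
        written.append(p)
        p = outdir / f"coefficients_{res.label}.csv"
        res.fit.params.to_csv(p, index=False)
        written.append(p)

    summary = {res.label: res.summary.to_dict() for res in results}
    for res in results:
        desc = describe_strata(res.predictions, res.assignment.scheme)
        summary[res.label]["top_strata"] = desc["top"].to_dict(orient="records")
        summary[res.label]["bottom_strata"] = desc["bottom"].to_dict(orient="records")
    path = outdir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, default=float))
    written.append(path)
    return written


def plot_caterpillar(res: ModelResult, path: str | Path) -> Path:
    """Ranked stratum predictions with 95% intervals (simple caterpillar)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    preds = res.predictions.sort_values("rank", ascending=False)
    fig, ax = plt.subplots(figsize=(8, 4))
    x = range(len(preds))
    ax.errorbar(
        x,
        preds["predicted"],
        yerr=1.96 * preds["se"],
        fmt="o",
        ms=2,
        lw=0.6,
        capsize=0,
    )
    ax.set_xlabel("stratum rank")
    ax.set_ylabel("predicted outcome")
    ax.set_title(f"Model {res.label}: stratum predictions")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
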