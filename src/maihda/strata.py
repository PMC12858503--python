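"""Build intersectional strata from area-level covariates.

Continuous covariates are cut into ordinal categories (fixed-proportion
splits or equal-count quantiles), binary covariates pass through or are
thresholded, and each area receives a concatenated digit code — one digit
per rule, in rule order. The cross-classification of those digits defines
the level-2 strata of the multilevel model.

Conventions frozen here:

* cut points are nearest-rank empirical quantiles; a value exactly equal
  to a cut point goes to the *lower* category;
* ordinal categories are labelled 1..k low-to-high on the underlying
  continuous value (for the deprivation score, higher score = more
  deprived, so category 3 is the most deprived block);
* binary categories are labelled 0/1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

#: canonical column names of an area table
AREA_COLUMNS = (
    "area_id",
    "outcome",
    "imd_score",
    "pct_minority",
    "pct_degree",
    "urban",
    "pct_65plus",
)

_PERCENT_COLUMNS = ("pct_minority", "pct_degree", "pct_65plus")


def validate_area_table(table: pd.DataFrame, require_outcome: bool = True) -> None:
    """Check the AreaTable invariants, raising :class:`DataError` on failure."""
    missing = [c for c in AREA_COLUMNS if c not in table.columns and c != "outcome"]
    if missing:
        raise ConfigurationError(f"area table is missing columns: {missing}")
    if table["area_id"].duplicated().any():
        dup = table.loc[table["area_id"].duplicated(), "area_id"].iloc[0]
        raise DataError(f"duplicate area_id {dup!r}", area_id=str(dup))
    if require_outcome:
        if "outcome" not in table.columns:
            raise ConfigurationError("area table is missing columns: ['outcome']")
        if table["outcome"].isna().any():
            aid = table.loc[table["outcome"].isna(), "area_id"].iloc[0]
            raise DataError(f"missing outcome for area {aid!r}", area_id=str(aid))
    for col in _PERCENT_COLUMNS:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals > 100)
        if bad.any():
            aid = table.loc[bad, "area_id"].iloc[0]
            raise DataError(
                f"column {col!r} out of [0, 100] for area {aid!r}", area_id=str(aid)
            )
    urb = table["urban"]
    if not urb.isin([0, 1]).all():
        aid = table.loc[~urb.isin([0, 1]), "area_id"].iloc[0]
        raise DataError(f"column 'urban' not in {{0, 1}} for area {aid!r}", area_id=str(aid))


@dataclass(frozen=True)
class Rule:
    """One categorisation rule: a variable, how to cut it, and its labels.

    kind:
        ``"proportion"``  — fixed-proportion split, ``params`` is the tuple of
        proportions (must sum to 1), categories 1..k low-to-high;
        ``"quantile"``    — equal-count split into ``params`` (an int k) bins,
        categories 1..k;
        ``"threshold"``   — binary, category 1 iff value >= ``params``;
        ``"binary"``      — pass-through of a 0/1 column.
    """

    name: str
    column: str
    kind: str
    params: object = None
    labels: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("proportion", "quantile", "threshold", "binary"):
            raise ConfigurationError(f"unknown rule kind {self.kind!r} for {self.name!r}")
        if self.kind == "proportion":
            props = tuple(self.params)
            if len(props) < 2 or not math.isclose(sum(props), 1.0, abs_tol=1e-9):
                raise ConfigurationError(
                    f"rule {self.name!r}: proportions must sum to 1, got {props}"
                )
        if self.kind == "quantile" and (not isinstance(self.params, int) or self.params < 2):
            raise ConfigurationError(f"rule {self.name!r}: quantile k must be an int >= 2")
        # codes concatenate one digit per rule, so a rule is capped at 9 categories
        if self.n_categories > 9:
            raise ConfigurationError(
                f"rule {self.name!r}: at most 9 categories per rule (one code digit)"
            )

    @property
    def categories(self) -> tuple[int, ...]:
        if self.kind == "proportion":
            return tuple(range(1, len(self.params) + 1))
        if self.kind == "quantile":
            return tuple(range(1, self.params + 1))
        return (0, 1)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def reference(self) -> int:
        """Reference category for dummy coding: lowest label."""
        return self.categories[0]

    def label(self, category: int) -> str:
        return self.labels.get(category, f"{self.name}={category}")


@dataclass(frozen=True)
class CodingScheme:
    """Ordered rules; rule order defines the digit order of stratum codes."""

    rules: tuple[Rule, ...]

    def __post_init__(self):
        if not self.rules:
            raise ConfigurationError("coding scheme has no rules")
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate rule names in scheme: {names}")

    def __iter__(self):
        return iter(self.rules)

    def rule(self, name: str) -> Rule:
        for r in self.rules:
            if r.name == name:
                return r
        raise ConfigurationError(f"no rule named {name!r} in scheme")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.rules)

    def all_possible_codes(self) -> list[str]:
        """Every structurally possible code, in lexicographic order."""
        combos = product(*[r.categories for r in self.rules])
        return ["".join(str(c) for c in combo) for combo in combos]

    def decode(self, code: str) -> dict[str, int]:
        """Map a code back to its per-rule categories."""
        if len(code) != len(self.rules):
            raise ConfigurationError(
                f"code {code!r} has {len(code)} digits, scheme has {len(self.rules)} rules"
            )
        return {r.name: int(d) for r, d in zip(self.rules, code)}

    def describe(self, code: str) -> dict[str, str]:
        """Human-readable category labels for a code."""
        return {r.name: r.label(int(d)) for r, d in zip(self.rules, code)}


def default_scheme(include_urban: bool = True) -> CodingScheme:
    """The study coding: 20/60/20 deprivation, minority & education tertiles,
    optional rural/urban passthrough, and a 25 % ageing threshold."""
    rules = [
        Rule(
            "deprivation",
            "imd_score",
            "proportion",
            (0.2, 0.6, 0.2),
            labels={1: "least deprived", 2: "mid deprived", 3: "most deprived"},
        ),
        Rule(
            "ethnicity",
            "pct_minority",
            "quantile",
            3,
            labels={
                1: "low % minority ethnic",
                2: "medium % minority ethnic",
                3: "high % minority ethnic",
            },
        ),
        Rule(
            "education",
            "pct_degree",
            "quantile",
            3,
            labels={1: "low education", 2: "medium education", 3: "high education"},
        ),
    ]
    if include_urban:
        rules.append(Rule("urban", "urban", "binary", labels={0: "rural", 1: "urban"}))
    rules.append(
        Rule("ageing", "pct_65plus", "threshold", 25.0, labels={0: "not ageing", 1: "ageing"})
    )
    return CodingScheme(tuple(rules))


def count_possible_strata(scheme: CodingScheme) -> int:
    """Product of category counts across rules."""
    n = 1
    for r in scheme.rules:
        n *= r.n_categories
    return n


@dataclass(frozen=True)
class StratumAssignment:
    """Per-area stratum codes plus the occupied-stratum registry.

    ``codes`` is indexed by area_id. ``registry`` has one row per occupied
    code with columns ``(code, index, n)``, sorted by code; ``index`` is the
    0-based stratum index j used by the fitting engine. ``empty_codes``
    lists structurally possible but unoccupied codes.
    """

    scheme: CodingScheme
    codes: pd.Series
    registry: pd.DataFrame
    empty_codes: tuple[str, ...]

    @property
    def n_areas(self) -> int:
        return len(self.codes)

    @property
    def n_occupied(self) -> int:
        return len(self.registry)

    @property
    def occupied_codes(self) -> list[str]:
        return list(self.registry["code"])

    def indices_for(self, table: pd.DataFrame) -> np.ndarray:
        """0-based stratum index for each row of ``table`` (by area_id)."""
        idx = self.registry.set_index("code")["index"]
        return idx.loc[self.codes.loc[table["area_id"]].to_numpy()].to_numpy()


def _nearest_rank_cuts(values: np.ndarray, cum_props: Iterable[float]) -> np.ndarray:
    """Nearest-rank empirical quantiles at cumulative proportions."""
    srt = np.sort(values)
    n = len(srt)
    idx = [min(max(math.ceil(p * n), 1), n) - 1 for p in cum_props]
    return srt[idx]


def _apply_rule(rule: Rule, table: pd.DataFrame) -> np.ndarray:
    if rule.column not in table.columns:
        raise ConfigurationError(
            f"rule {rule.name!r} references missing column {rule.column!r}"
        )
    raw = table[rule.column]
    if rule.kind == "binary":
        if not raw.isin([0, 1]).all():
            aid = table.loc[~raw.isin([0, 1]), "area_id"].iloc[0]
            raise DataError(
                f"binary rule {rule.name!r}: value not 0/1 for area {aid!r}",
                area_id=str(aid),
            )
        return raw.to_numpy(dtype=int)

    vals = pd.to_numeric(raw, errors="coerce")
    if vals.isna().any():
        aid = table.loc[vals.isna(), "area_id"].iloc[0]
        raise DataError(
            f"rule {rule.name!r}: non-numeric value in column {rule.column!r} "
            f"for area {aid!r}",
            area_id=str(aid),
        )
    x = vals.to_numpy(dtype=float)

    if rule.kind == "threshold":
        return (x >= float(rule.params)).astype(int)

    if rule.kind == "proportion":
        props = tuple(rule.params)
        cum = np.cumsum(props)[:-1]
    else:  # quantile
        k = rule.params
        if len(np.unique(x)) < k:
            raise DataError(
                f"rule {rule.name!r}: needs >= {k} distinct values in "
                f"{rule.column!r}, got {len(np.unique(x))}"
            )
        cum = np.arange(1, k) / k
    cuts = _nearest_rank_cuts(x, cum)
    # value <= cut -> lower category; searchsorted(side='left') counts cuts < x
    return 1 + np.searchsorted(cuts, x, side="left").astype(int)


def categorize(table: pd.DataFrame, scheme: CodingScheme) -> StratumAssignment:
    """Assign every area its stratum code under ``scheme``.

    Raises :class:`ConfigurationError` for missing columns and
    :class:`DataError` (naming the offending area) for bad values.
    """
    if "area_id" not in table.columns:
        raise ConfigurationError("area table is missing columns: ['area_id']")
    cats = np.column_stack([_apply_rule(r, table) for r in scheme.rules])
    codes = pd.Series(
        ["".join(row) for row in cats.astype(str)],
        index=pd.Index(table["area_id"], name="area_id"),
        name="stratum_code",
    )
    counts = codes.value_counts().sort_index()
    registry = pd.DataFrame(
        {
            "code": counts.index.to_numpy(),
            "index": np.arange(len(counts)),
            "n": counts.to_numpy(),
        }
    )
    occupied = set(counts.index)
    empty = tuple(c for c in scheme.all_possible_codes() if c not in occupied)
    return StratumAssignment(scheme=scheme, codes=codes, registry=registry, empty_codes=empty)
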