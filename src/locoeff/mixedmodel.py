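"""Mixed-model estimation of load-manipulation effects on LEI change.

Within each weekly readiness subset (bad / normal / good) and for each
weekly load metric, the week-to-week LEI variation is regressed on the
five load-fluctuation categories with a random intercept per player to
absorb repeated measurements.  Effects are contrasts against the
"no variation" reference category, answering: does loading or unloading
next week move readiness more than keeping the load constant?

The model is a linear mixed model (normal outcome, identity link)
estimated by restricted maximum likelihood, with Wald intervals and
p-values.  "Standardized beta" means the outcome is z-scored within
the fitted subset while the 0/1 category indicators are left as is;
full predictor standardization is available by flag.  No small-sample
degrees-of-freedom correction and no multiple-testing adjustment are
applied by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import SubsetTooSmallError
from .periodization import FLUCTUATION_CATEGORIES, LOAD_METRICS, READINESS_STATES

__all__ = [
    "ModelSpec",
    "fit_readiness_model",
    "run_scenario_grid",
    "assemble_report",
    "summarize_descriptives",
]

logger = logging.getLogger(__name__)

REFERENCE_CATEGORY = "no_variation"


@dataclass
class ModelSpec:
    """One cell of the scenario grid: a readiness subset and a metric."""

    readiness: str
    metric: str
    standardize_outcome: bool = True
    standardize_predictors: bool = False
    min_players: int = 2
    min_obs: int = 10

    def __post_init__(self) -> None:
        if self.readiness not in READINESS_STATES:
            raise ValueError(f"unknown readiness state {self.readiness!r}")
        if self.metric not in LOAD_METRICS:
            raise ValueError(f"unknown load metric {self.metric!r}")


def fit_readiness_model(transitions: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Fit one readiness-subset x metric mixed model.

    Returns a coefficient table with one row per occupied fluctuation
    category: ``beta`` (contrast vs the no-variation reference),
    ``ci_low``/``ci_high`` (Wald 95%), ``p_value`` and the category
    count ``n``.  The reference row has beta fixed at 0 with no
    interval; empty categories are absent.  Fit-level quantities
    (random-intercept variance, residual variance, sizes, a boundary
    flag for singular fits) are in ``result.attrs``.
    """
    cat_col = f"category_{spec.metric}"
    sub = transitions[transitions["readiness_ref"] == spec.readiness]
    sub = sub.dropna(subset=[cat_col, "lei_variation"])

    n_obs = len(sub)
    n_players = sub["player_id"].nunique()
    occupied = [c for c in FLUCTUATION_CATEGORIES if (sub[cat_col] == c).any()]
    if n_players < spec.min_players:
        raise SubsetTooSmallError(
            f"{spec.readiness}/{spec.metric}: {n_players} players < {spec.min_players}"
        )
    if n_obs < spec.min_obs:
        raise SubsetTooSmallError(f"{spec.readiness}/{spec.metric}: {n_obs} transitions < {spec.min_obs}")
    if REFERENCE_CATEGORY not in occupied or len(occupied) < 2:
        raise SubsetTooSmallError(
            f"{spec.readiness}/{spec.metric}: needs >= 2 occupied categories including "
            f"{REFERENCE_CATEGORY!r}, got {occupied}"
        )

    y = sub["lei_variation"].to_numpy(dtype=float)
    if spec.standardize_outcome:
        sd = y.std(ddof=1)
        if sd > 0:
            y = (y - y.mean()) / sd

    contrast_cats = [c for c in occupied if c != REFERENCE_CATEGORY]
    X = pd.DataFrame(
        {c: (sub[cat_col] == c).astype(float).to_numpy() for c in contrast_cats},
        index=sub.index,
    )
    if spec.standardize_predictors:
        X = (X - X.mean()) / X.std(ddof=1)
    exog = sm.add_constant(X, has_constant="add")

    boundary = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MixedLM(y, exog, groups=sub["player_id"].to_numpy())
        # L-BFGS can wander into a region where the profiled covariance
        # is numerically singular; fall back to gradient-free methods.
        result = None
        last_err: Exception | None = None
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                result = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError as exc:
                last_err = exc
        if result is None:
            raise SubsetTooSmallError(
                f"{spec.readiness}/{spec.metric}: mixed-model fit failed ({last_err})"
            )
        if any("boundary" in str(w.message).lower() or "singular" in str(w.message).lower()
               for w in caught):
            boundary = True

    re_var = float(np.asarray(result.cov_re)[0, 0])
    if re_var < 1e-10 or not result.converged:
        boundary = True

    z = stats.norm.ppf(0.975)
    rows = []
    counts = sub[cat_col].value_counts()
    for cat in occupied:
        if cat == REFERENCE_CATEGORY:
            rows.append(
                {
                    "readiness": spec.readiness,
                    "metric": spec.metric,
                    "category": cat,
                    "beta": 0.0,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                    "n": int(counts[cat]),
                    "is_reference": True,
                }
            )
        else:
            b = float(result.params[cat])
            se = float(result.bse[cat])
            rows.append(
                {
                    "readiness": spec.readiness,
                    "metric": spec.metric,
                    "category": cat,
                    "beta": b,
                    "ci_low": b - z * se,
                    "ci_high": b + z * se,
                    "p_value": float(result.pvalues[cat]),
                    "n": int(counts[cat]),
                    "is_reference": False,
                }
            )
    table = pd.DataFrame(rows)
    table.attrs.update(
        {
            "re_var": re_var,
            "resid_var": float(result.scale),
            "n_obs": n_obs,
            "n_players": n_players,
            "boundary": boundary,
        }
    )
    return table


def run_scenario_grid(
    transitions: pd.DataFrame,
    standardize_outcome: bool = True,
    standardize_predictors: bool = False,
) -> tuple[dict[tuple[str, str], pd.DataFrame], list[tuple[str, str, str]]]:
    """Fit the full 3 readiness x 3 metric grid.

    Returns ``(tables, skipped)`` where ``tables`` maps
    ``(readiness, metric)`` to a coefficient table and ``skipped``
    lists the cells that could not be fitted with the reason.
    """
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    skipped: list[tuple[str, str, str]] = []
    for readiness in READINESS_STATES:
        for metric in LOAD_METRICS:
            spec = ModelSpec(
                readiness=readiness,
                metric=metric,
                standardize_outcome=standardize_outcome,
                standardize_predictors=standardize_predictors,
            )
            try:
                tables[(readiness, metric)] = fit_readiness_model(transitions, spec)
            except SubsetTooSmallError as exc:
                logger.warning("run_scenario_grid: skipping %s/%s (%s)", readiness, metric, exc)
                skipped.append((readiness, metric, str(exc)))
    return tables, skipped


def assemble_report(tables: dict[tuple[str, str], pd.DataFrame]) -> pd.DataFrame:
    """Concatenate grid tables into one long report, ordered metric >
    readiness > category, with fit-level attrs joined as columns."""
    if not tables:
        return pd.DataFrame(
            columns=["readiness", "metric", "category", "beta", "ci_low", "ci_high",
                     "p_value", "n", "is_reference", "re_var", "resid_var",
                     "n_obs", "n_players", "boundary"]
        )
    parts = []
    for (readiness, metric), tbl in tables.items():
        t = tbl.copy()
        for key in ("re_var", "resid_var", "n_obs", "n_players", "boundary"):
            t[key] = tbl.attrs[key]
        parts.append(t)
    out = pd.concat(parts, ignore_index=True)
    out["metric"] = pd.Categorical(out["metric"], categories=LOAD_METRICS, ordered=True)
    out["readiness"] = pd.Categorical(out["readiness"], categories=READINESS_STATES, ordered=True)
    out["category"] = pd.Categorical(out["category"], categories=FLUCTUATION_CATEGORIES, ordered=True)
    return out.sort_values(["metric", "readiness", "category"]).reset_index(drop=True)


def summarize_descriptives(transitions: pd.DataFrame, season_col: str | None = None) -> pd.DataFrame:
    """Mean (+/- SD) of the week-to-week LEI variation per fluctuation
    category and load metric, optionally split by a season column.

    SD is the sample standard deviation and is reported absent (NaN)
    for single-row cells; empty cells are omitted.
    """
    if transitions.empty:
        raise ValueError("transitions table is empty")
    rows = []
    group_cols = [season_col] if season_col else []
    for metric in LOAD_METRICS:
        cat_col = f"category_{metric}"
        sub = transitions.dropna(subset=[cat_col])
        for keys, grp in sub.groupby(group_cols + [cat_col], sort=False) if group_cols else (
            ((cat,), g) for cat, g in sub.groupby(cat_col, sort=False)
        ):
            keys = keys if isinstance(keys, tuple) else (keys,)
            row = dict(zip(group_cols, keys[:-1]))
            row.update(
                {
                    "metric": metric,
                    "category": keys[-1],
                    "mean": grp["lei_variation"].mean(),
                    "sd": grp["lei_variation"].std(ddof=1) if len(grp) > 1 else np.nan,
                    "n": len(grp),
                }
            )
            rows.append(row)
    out = pd.DataFrame(rows)
    out["metric"] = pd.Categorical(out["metric"], categories=LOAD_METRICS, ordered=True)
    out["category"] = pd.Categorical(out["category"], categories=FLUCTUATION_CATEGORIES, ordered=True)
    return out.sort_values(group_cols + ["metric", "category"]).reset_index(drop=True)
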