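"""Locomotor Efficiency Index engine.

Fits the feature -> PlayerLoad regression, forms the prediction residual
``delta_pl = predicted - actual`` and standardizes it per player into
the LEI (an individual z-score).  A positive LEI means the player
accumulated less body load than expected for the locomotor output of
the session — an efficient, well-recovered state; a negative LEI means
the session cost more body load than its locomotor content predicts.

Predictions are out-of-fold by default: the squad's sessions are split
into K folds and each session is predicted by a model that never saw
it.  An ensemble regressor refit in-sample can near-memorize PlayerLoad
and collapse the residual to ~0, which would destroy the index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .errors import ConfigurationError, SchemaError
from .simulate import PREDICTORS

__all__ = [
    "LoadModel",
    "fit_load_model",
    "compute_delta_pl",
    "standardize_per_player",
    "aggregate_daily",
]

logger = logging.getLogger(__name__)

TARGET = "player_load"


def _make_estimator(model: str, seed: int | None):
    if model == "rf":
        # Ensemble family per standard practice for PL prediction; depth
        # left unconstrained, 200 trees.
        return RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1)
    if model == "linear":
        return LinearRegression()
    raise ConfigurationError(f"unknown model {model!r}; expected 'rf' or 'linear'")


@dataclass
class LoadModel:
    """A fitted feature -> PlayerLoad regressor plus its fit metadata.

    ``estimator`` is refit on all sessions and is what :meth:`predict`
    uses for new data; the out-of-fold predictions returned by
    :func:`fit_load_model` come from the per-fold models instead.
    """

    estimator: object
    features: list[str] = field(default_factory=lambda: list(PREDICTORS))
    scheme: str = "out_of_fold"
    n_folds: int = 5
    seed: int | None = None
    model: str = "rf"
    fold_assignment: np.ndarray | None = None

    def predict(self, sessions: pd.DataFrame) -> np.ndarray:
        X = _feature_matrix(sessions, self.features)
        return np.asarray(self.estimator.predict(X), dtype=float)


def _feature_matrix(sessions: pd.DataFrame, features: list[str]) -> np.ndarray:
    missing = [c for c in features if c not in sessions.columns]
    if missing:
        raise SchemaError(f"sessions table is missing predictor columns: {missing}")
    X = sessions[features].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in predictor columns")
    return X


def fit_load_model(
    sessions: pd.DataFrame,
    scheme: str = "out_of_fold",
    n_folds: int = 5,
    seed: int | None = 0,
    model: str = "rf",
    min_sessions: int = 50,
) -> tuple[LoadModel, pd.Series]:
    """Fit the PlayerLoad model and predict every session.

    Parameters
    ----------
    sessions
        Session table containing the seven predictors and ``player_load``.
    scheme
        ``"out_of_fold"`` (default): each session is predicted by a model
        fit on the other K-1 folds.  ``"in_sample"``: one model fit and
        applied to all sessions (useful for oracle checks only).
    n_folds, seed
        Fold count and the seed controlling both fold shuffling and any
        stochastic estimator.
    model
        ``"rf"`` (random-forest ensemble, default) or ``"linear"``.

    Returns
    -------
    (LoadModel, pl_pred)
        The model refit on all sessions, and one prediction per input
        row (aligned to ``sessions.index``).
    """
    if TARGET not in sessions.columns:
        raise SchemaError(f"sessions table is missing the {TARGET!r} column")
    n = len(sessions)
    if n < min_sessions:
        raise ConfigurationError(f"need at least {min_sessions} sessions, got {n}")
    X = _feature_matrix(sessions, list(PREDICTORS))
    y = sessions[TARGET].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite values in player_load")

    if scheme not in ("out_of_fold", "in_sample"):
        raise ConfigurationError(f"unknown scheme {scheme!r}")

    pred = np.empty(n, dtype=float)
    fold_assignment = None
    if scheme == "out_of_fold":
        if n < n_folds:
            raise ConfigurationError(f"{n} sessions is fewer than {n_folds} folds")
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_assignment = np.empty(n, dtype=int)
        for k, (train_idx, test_idx) in enumerate(kf.split(X)):
            est = _make_estimator(model, seed)
            est.fit(X[train_idx], y[train_idx])
            pred[test_idx] = est.predict(X[test_idx])
            fold_assignment[test_idx] = k
    full = _make_estimator(model, seed)
    full.fit(X, y)
    if scheme == "in_sample":
        pred = np.asarray(full.predict(X), dtype=float)

    load_model = LoadModel(
        estimator=full,
        scheme=scheme,
        n_folds=n_folds,
        seed=seed,
        model=model,
        fold_assignment=fold_assignment,
    )
    return load_model, pd.Series(pred, index=sessions.index, name="pl_pred")


def compute_delta_pl(pl_pred, pl_actual):
    """Prediction residual ``delta_pl = predicted - actual`` PlayerLoad.

    Positive when the measured load fell below expectation (efficient),
    negative when the session cost more load than predicted.
    """
    pred = np.asarray(pl_pred, dtype=float)
    actual = np.asarray(pl_actual, dtype=float)
    if not (np.isfinite(pred).all() and np.isfinite(actual).all()):
        raise ValueError("non-finite PlayerLoad values")
    out = pred - actual
    if np.isscalar(pl_pred) and np.isscalar(pl_actual):
        return float(out)
    return out


def standardize_per_player(
    lei_records: pd.DataFrame,
    min_sessions: int = 20,
    spread_tol: float = 1e-8,
) -> pd.DataFrame:
    """Individually z-score ``delta_pl`` into the LEI.

    For each player, ``lei = (delta_pl - mean) / sd`` with the sample
    (n-1) standard deviation, both computed over the player's entire
    supplied window.  Players with fewer than ``min_sessions`` records
    or with spread below ``spread_tol`` (an essentially perfect model
    leaves no residual signal to standardize) are excluded with a
    logged warning.

    Returns a copy of the retained rows with an added ``lei`` column;
    the excluded players are listed in ``result.attrs["excluded"]`` as
    ``{player_id: reason}``.
    """
    if "delta_pl" not in lei_records.columns:
        raise SchemaError("lei_records must contain a 'delta_pl' column")
    excluded: dict[str, str] = {}
    parts = []
    for pid, grp in lei_records.groupby("player_id", sort=True):
        if len(grp) < min_sessions:
            excluded[pid] = f"only {len(grp)} sessions (< {min_sessions})"
            continue
        mu = grp["delta_pl"].mean()
        sd = grp["delta_pl"].std(ddof=1)
        if not np.isfinite(sd) or sd < spread_tol:
            excluded[pid] = f"delta_pl spread {sd:.3g} below tolerance"
            continue
        out = grp.copy()
        out["lei"] = (grp["delta_pl"] - mu) / sd
        parts.append(out)
    for pid, reason in excluded.items():
        logger.warning("standardize_per_player: excluding %s (%s)", pid, reason)
    if parts:
        result = pd.concat(parts).sort_index()
    else:
        result = lei_records.iloc[0:0].copy()
        result["lei"] = pd.Series(dtype=float)
    result.attrs["excluded"] = excluded
    return result


def aggregate_daily(lei_records: pd.DataFrame) -> pd.DataFrame:
    """Collapse session LEIs to one value per player-day.

    Double-session days contribute the arithmetic mean of their session
    LEIs.  Returns columns ``player_id``, ``date``, ``lei``,
    ``n_sessions``.
    """
    if "lei" not in lei_records.columns:
        raise SchemaError("lei_records must contain a 'lei' column")
    daily = (
        lei_records.groupby(["player_id", "date"], sort=True)["lei"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "lei", "size": "n_sessions"})
    )
    return daily
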