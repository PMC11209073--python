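"""Weekly readiness, load-fluctuation and LEI-variation classification.

Turns daily LEI values and session loads into the three axes of the
training-scenario grid:

* **readiness** — the weekly mean LEI binned into bad / normal / good
  at cutoffs of -0.5 and +0.5;
* **week-to-week load fluctuation** — the percentage change of a weekly
  load metric between consecutive weeks, binned into five categories at
  +/-10% and +/-30%;
* **LEI variation** — the signed difference between consecutive weekly
  mean LEIs.

Weeks are non-overlapping 7-day blocks anchored on a configurable
weekday (Monday by default): week-to-week transitions require disjoint
windows, so a rolling 7-day view is not used here.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, UndefinedChangeError

__all__ = [
    "FLUCTUATION_CATEGORIES",
    "READINESS_STATES",
    "filter_participation",
    "rolling_weekly_loads",
    "week_index",
    "weekly_summaries",
    "pct_change",
    "classify_fluctuation",
    "classify_readiness",
    "lei_variation",
    "build_transitions",
]

logger = logging.getLogger(__name__)

#: Fluctuation categories in their natural order (most negative first).
FLUCTUATION_CATEGORIES = [
    "large_decrease",
    "moderate_decrease",
    "no_variation",
    "moderate_increase",
    "large_increase",
]

READINESS_STATES = ["bad", "normal", "good"]

#: Weekly load metrics carried through the scenario grid.
LOAD_METRICS = ["total_distance", "dist_gt_25_2", "mechanical_load"]

DEFAULT_FLUCTUATION_BOUNDS = (-30.0, -10.0, 10.0, 30.0)
DEFAULT_READINESS_CUTOFFS = (-0.5, 0.5)

_WEEKDAYS = ["monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday"]


def filter_participation(
    sessions: pd.DataFrame,
    schedule: Iterable,
    threshold: float = 0.60,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Drop players with poor training continuity.

    A player is retained when the fraction of scheduled team training
    dates they attended is at least ``threshold`` (attendance of
    exactly the threshold is kept; strictly below it is excluded).

    Parameters
    ----------
    sessions
        Session table with ``player_id``, ``date`` and ``session_type``.
    schedule
        Every team training date (match dates do not count toward
        participation).

    Returns
    -------
    (retained_sessions, excluded)
        The surviving rows, and ``{player_id: attendance_fraction}``
        for each removed player.
    """
    schedule = {pd.Timestamp(d).date().isoformat() for d in schedule}
    if not schedule:
        raise ConfigurationError("team schedule is empty")
    train = sessions[sessions["session_type"] == "training"]
    attended = (
        train.assign(date=train["date"].astype(str))
        .groupby("player_id")["date"]
        .agg(lambda d: len(set(d) & schedule))
    )
    frac = attended.reindex(sessions["player_id"].unique(), fill_value=0) / len(schedule)
    excluded = {pid: float(f) for pid, f in frac.items() if f < threshold}
    for pid, f in excluded.items():
        logger.warning(
            "filter_participation: excluding %s (attended %.0f%% of %d scheduled sessions)",
            pid, 100 * f, len(schedule),
        )
    retained = sessions[~sessions["player_id"].isin(excluded)].copy()
    return retained, excluded


def week_index(dates: pd.Series, anchor: str = "monday") -> tuple[pd.Series, pd.Timestamp]:
    """Assign each date to a non-overlapping 7-day block.

    Block 0 starts on the first ``anchor`` weekday at or before the
    earliest date; returns the block index per row and that origin.
    """
    if anchor.lower() not in _WEEKDAYS:
        raise ConfigurationError(f"unknown week anchor {anchor!r}")
    dt = pd.to_datetime(dates)
    first = dt.min()
    offset = (first.weekday() - _WEEKDAYS.index(anchor.lower())) % 7
    origin = (first - pd.Timedelta(days=int(offset))).normalize()
    idx = ((dt.dt.normalize() - origin).dt.days // 7).astype(int)
    return idx, origin


def classify_readiness(weekly_lei: float, cutoffs=DEFAULT_READINESS_CUTOFFS) -> str:
    """Bin a weekly mean LEI: below the low cutoff is bad, above the
    high cutoff is good, the closed interval between them is normal."""
    low, high = cutoffs
    if not low < high:
        raise ConfigurationError("readiness cutoffs must satisfy low < high")
    if not np.isfinite(weekly_lei):
        raise ValueError("weekly LEI must be finite")
    if weekly_lei < low:
        return "bad"
    if weekly_lei > high:
        return "good"
    return "normal"


def weekly_summaries(
    daily_lei: pd.DataFrame,
    sessions: pd.DataFrame,
    anchor: str = "monday",
    cutoffs=DEFAULT_READINESS_CUTOFFS,
) -> pd.DataFrame:
    """Per player-week load sums, mean LEI and readiness state.

    Loads (total distance, distance above 25.2 km/h, and mechanical
    load = accelerations > 3.5 m/s^2 plus decelerations < -3.5 m/s^2)
    are summed over every training session and match of the week; the
    weekly LEI is the mean of the player's daily LEI values.  Weeks
    with no sessions produce no row.
    """
    needed = {"player_id", "date", "total_distance", "dist_gt_25_2", "n_acc_gt_3_5", "n_dec_lt_m3_5"}
    missing = needed - set(sessions.columns)
    if missing:
        raise SchemaError(f"sessions table is missing columns: {sorted(missing)}")

    sess = sessions.copy()
    all_dates = pd.concat([sess["date"], daily_lei["date"]]).astype(str)
    _, origin = week_index(all_dates, anchor)
    sess["week_index"] = ((pd.to_datetime(sess["date"]).dt.normalize() - origin).dt.days // 7).astype(int)
    sess["mechanical_load"] = sess["n_acc_gt_3_5"] + sess["n_dec_lt_m3_5"]

    loads = (
        sess.groupby(["player_id", "week_index"], sort=True)
        .agg(
            total_distance=("total_distance", "sum"),
            dist_gt_25_2=("dist_gt_25_2", "sum"),
            mechanical_load=("mechanical_load", "sum"),
            n_sessions=("total_distance", "size"),
        )
        .reset_index()
    )

    lei = daily_lei.copy()
    lei["week_index"] = ((pd.to_datetime(lei["date"]).dt.normalize() - origin).dt.days // 7).astype(int)
    weekly_lei = (
        lei.groupby(["player_id", "week_index"], sort=True)["lei"].mean().rename("weekly_lei").reset_index()
    )

    weeks = loads.merge(weekly_lei, on=["player_id", "week_index"], how="inner")
    weeks["readiness"] = weeks["weekly_lei"].map(lambda v: classify_readiness(v, cutoffs))
    weeks.attrs["week_origin"] = origin
    return weeks


def rolling_weekly_loads(sessions: pd.DataFrame) -> pd.DataFrame:
    """Exploratory rolling view: per player-day sums of the three load
    metrics over the trailing 7 days (the day itself included).

    The scenario grid uses disjoint 7-day blocks, not this view —
    week-to-week transitions need non-overlapping windows — but a
    trailing acute-load sum is the natural companion plot.
    """
    needed = {"player_id", "date", "total_distance", "dist_gt_25_2", "n_acc_gt_3_5", "n_dec_lt_m3_5"}
    missing = needed - set(sessions.columns)
    if missing:
        raise SchemaError(f"sessions table is missing columns: {sorted(missing)}")
    sess = sessions.copy()
    sess["date"] = pd.to_datetime(sess["date"])
    sess["mechanical_load"] = sess["n_acc_gt_3_5"] + sess["n_dec_lt_m3_5"]
    daily = (
        sess.groupby(["player_id", "date"])[["total_distance", "dist_gt_25_2", "mechanical_load"]]
        .sum()
        .reset_index()
    )
    parts = []
    for pid, grp in daily.groupby("player_id", sort=True):
        g = grp.set_index("date").sort_index()
        rolled = g[["total_distance", "dist_gt_25_2", "mechanical_load"]].rolling("7D").sum()
        rolled.insert(0, "player_id", pid)
        parts.append(rolled.reset_index())
    return pd.concat(parts, ignore_index=True)


def pct_change(load_w: float, load_w1: float) -> float:
    """Week-to-week percentage change ``(w+1 - w) / w * 100``.

    ``w+1`` is the most recent week; a fall from 200 m to 100 m is a
    50% reduction (-50).  The base week's load must be positive.
    """
    if load_w < 0 or load_w1 < 0:
        raise ValueError("weekly loads must be non-negative")
    if load_w == 0:
        raise UndefinedChangeError("percentage change undefined for zero base-week load")
    return (load_w1 - load_w) / load_w * 100.0


def classify_fluctuation(pct: float, bounds=DEFAULT_FLUCTUATION_BOUNDS) -> str:
    """Bin a percentage change into the five fluctuation categories.

    With the default bounds: (-inf, -30) large_decrease, [-30, -10)
    moderate_decrease, [-10, +10] no_variation, (+10, +30]
    moderate_increase, (+30, inf) large_increase.  The mapping is total
    and mutually exclusive; the "no variation" bin is closed at both
    ends.
    """
    b1, b2, b3, b4 = bounds
    if not b1 < b2 < b3 < b4:
        raise ConfigurationError("fluctuation bounds must be strictly increasing")
    if not np.isfinite(pct):
        raise ValueError("percentage change must be finite")
    if pct < b1:
        return "large_decrease"
    if pct < b2:
        return "moderate_decrease"
    if pct <= b3:
        return "no_variation"
    if pct <= b4:
        return "moderate_increase"
    return "large_increase"


def lei_variation(weekly_lei_w: float, weekly_lei_w1: float) -> float:
    """Signed week-to-week LEI change, most recent week minus previous."""
    return weekly_lei_w1 - weekly_lei_w


def build_transitions(
    weeks: pd.DataFrame,
    min_week_sessions: int = 3,
    bounds=DEFAULT_FLUCTUATION_BOUNDS,
    readiness_ref: str = "from",
) -> pd.DataFrame:
    """One row per player per consecutive week pair.

    Both weeks of a pair must have at least ``min_week_sessions``
    sessions.  Each row carries, for each load metric, the percentage
    change and its fluctuation category; the signed LEI variation; and
    ``readiness_ref`` — the readiness state conditioning the transition
    (``"from"``: week w, the default, matching the prescription question
    "given this week's readiness, load or unload next week?";
    ``"to"``: week w+1).

    Transitions whose base-week load is zero for a metric get NaN for
    that metric's change; the counts of such drops are in
    ``result.attrs["undefined_pct_changes"]``.
    """
    if readiness_ref not in ("from", "to"):
        raise ConfigurationError("readiness_ref must be 'from' or 'to'")
    weeks = weeks.sort_values(["player_id", "week_index"])
    eligible = weeks[weeks["n_sessions"] >= min_week_sessions]

    rows = []
    undefined = {m: 0 for m in LOAD_METRICS}
    for pid, grp in eligible.groupby("player_id", sort=True):
        grp = grp.set_index("week_index")
        for w in grp.index:
            if w + 1 not in grp.index:
                continue
            cur, nxt = grp.loc[w], grp.loc[w + 1]
            row = {
                "player_id": pid,
                "week_from": int(w),
                "week_to": int(w + 1),
                "lei_variation": lei_variation(cur["weekly_lei"], nxt["weekly_lei"]),
                "readiness_ref": cur["readiness"] if readiness_ref == "from" else nxt["readiness"],
            }
            for metric in LOAD_METRICS:
                try:
                    pct = pct_change(cur[metric], nxt[metric])
                    row[f"pct_change_{metric}"] = pct
                    row[f"category_{metric}"] = classify_fluctuation(pct, bounds)
                except UndefinedChangeError:
                    undefined[metric] += 1
                    row[f"pct_change_{metric}"] = np.nan
                    row[f"category_{metric}"] = np.nan
            rows.append(row)

    cols = ["player_id", "week_from", "week_to", "lei_variation", "readiness_ref"]
    for metric in LOAD_METRICS:
        cols += [f"pct_change_{metric}", f"category_{metric}"]
    out = pd.DataFrame(rows, columns=cols)
    out.attrs["undefined_pct_changes"] = undefined
    total_dropped = sum(undefined.values())
    if total_dropped:
        logger.warning("build_transitions: %d metric changes undefined (zero base-week load)", total_dropped)
    return out
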