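"""End-to-end orchestration: sessions CSV -> LEI -> weeks -> transitions
-> mixed-model report, plus configuration and run accounting.

The pipeline is a pure function of (input table, config, seeds): the
same inputs give byte-identical outputs.  Every input row is accounted
for in the run log — retained, or excluded with a reason (participation
below threshold, zero residual spread, short week, zero-base percentage
change).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import lei as lei_mod
from . import mixedmodel, periodization
from .errors import ConfigurationError
from .simulate import SimConfig

__all__ = ["PipelineConfig", "PipelineResult", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and knobs of the analysis chain.

    The speed and acceleration thresholds document the band definitions
    of the session schema (which bands the distance and count columns
    refer to); the analysis itself consumes the banded columns.
    """

    readiness_cutoffs: tuple[float, float] = (-0.5, 0.5)
    fluctuation_bounds: tuple[float, float, float, float] = (-30.0, -10.0, 10.0, 30.0)
    speed_threshold_moderate: float = 7.2   # km/h
    speed_threshold_high: float = 25.2      # km/h
    accel_threshold_low: float = 2.5        # m/s^2
    accel_threshold_high: float = 3.5       # m/s^2
    participation_threshold: float = 0.60
    n_folds: int = 5
    model: str = "rf"
    scheme: str = "out_of_fold"
    seed: int = 0
    week_anchor: str = "monday"
    min_sessions_per_player: int = 20
    min_week_sessions: int = 3
    readiness_ref: str = "from"
    standardize_outcome: bool = True
    standardize_predictors: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.readiness_cutoffs
        if not lo < hi:
            raise ConfigurationError("readiness cutoffs must satisfy low < high")
        b = self.fluctuation_bounds
        if not (b[0] < b[1] < b[2] < b[3]):
            raise ConfigurationError("fluctuation bounds must be strictly increasing")
        if not 0 < self.speed_threshold_moderate < self.speed_threshold_high:
            raise ConfigurationError("speed thresholds must be positive and ordered")
        if not 0 < self.accel_threshold_low < self.accel_threshold_high:
            raise ConfigurationError("acceleration thresholds must be positive and ordered")
        if not 0 < self.participation_threshold <= 1:
            raise ConfigurationError("participation_threshold must be in (0, 1]")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> tuple[SimConfig, PipelineConfig]:
    """Read a YAML config with optional ``simulation:`` and
    ``pipeline:`` sections; missing keys take the defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimConfig(**(raw.get("simulation") or {}))
    pipe_raw = raw.get("pipeline") or {}
    for key in ("readiness_cutoffs", "fluctuation_bounds"):
        if key in pipe_raw:
            pipe_raw[key] = tuple(pipe_raw[key])
    pipe = PipelineConfig(**pipe_raw)
    return sim, pipe


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    lei_records: pd.DataFrame
    daily_lei: pd.DataFrame
    weeks: pd.DataFrame
    transitions: pd.DataFrame
    coefficients: pd.DataFrame
    descriptives: pd.DataFrame
    tables: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)
    log: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.lei_records.to_csv(out / "lei.csv", index=False)
        self.daily_lei.to_csv(out / "daily_lei.csv", index=False)
        self.weeks.to_csv(out / "weeks.csv", index=False)
        self.transitions.to_csv(out / "transitions.csv", index=False)
        self.coefficients.to_csv(out / "coefficients.csv", index=False)
        self.descriptives.to_csv(out / "descriptives.csv", index=False)
        with open(out / "run_log.yaml", "w") as fh:
            yaml.safe_dump(self.log, fh, sort_keys=False)


def run_pipeline(
    sessions: pd.DataFrame | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute score -> weeks -> transitions -> analyze on a session table.

    ``sessions`` may be a DataFrame or a path to a sessions CSV.  When
    ``out_dir`` is given, all intermediate and final tables are written
    there as CSV along with a YAML run log.
    """
    cfg = config or PipelineConfig()
    if not isinstance(sessions, pd.DataFrame):
        sessions = pd.read_csv(sessions)
    n_input = len(sessions)

    # Participation filter against the team schedule (all training dates
    # observed in the data).
    schedule = sorted(sessions.loc[sessions["session_type"] == "training", "date"].astype(str).unique())
    retained, part_excluded = periodization.filter_participation(
        sessions, schedule, cfg.participation_threshold
    )

    model, pl_pred = lei_mod.fit_load_model(
        retained, scheme=cfg.scheme, n_folds=cfg.n_folds, seed=cfg.seed, model=cfg.model
    )
    lei_records = retained[["player_id", "date", "session_index_in_day", "session_type"]].copy()
    lei_records["pl_pred"] = pl_pred
    lei_records["pl_actual"] = retained["player_load"].astype(float)
    lei_records["delta_pl"] = lei_mod.compute_delta_pl(
        lei_records["pl_pred"], lei_records["pl_actual"]
    )
    lei_records = lei_mod.standardize_per_player(
        lei_records, min_sessions=cfg.min_sessions_per_player
    )
    spread_excluded = lei_records.attrs.get("excluded", {})
    scored_sessions = retained[retained["player_id"].isin(lei_records["player_id"].unique())]

    daily = lei_mod.aggregate_daily(lei_records)
    weeks = periodization.weekly_summaries(
        daily, scored_sessions, anchor=cfg.week_anchor, cutoffs=cfg.readiness_cutoffs
    )
    transitions = periodization.build_transitions(
        weeks,
        min_week_sessions=cfg.min_week_sessions,
        bounds=cfg.fluctuation_bounds,
        readiness_ref=cfg.readiness_ref,
    )
    tables, skipped = mixedmodel.run_scenario_grid(
        transitions,
        standardize_outcome=cfg.standardize_outcome,
        standardize_predictors=cfg.standardize_predictors,
    )
    coefficients = mixedmodel.assemble_report(tables)
    descriptives = mixedmodel.summarize_descriptives(transitions) if len(transitions) else pd.DataFrame()

    short_weeks = int((weeks["n_sessions"] < cfg.min_week_sessions).sum())
    log = {
        "input_rows": int(n_input),
        "participation_excluded_players": {k: round(v, 4) for k, v in part_excluded.items()},
        "rows_dropped_participation": int(n_input - len(retained)),
        "zero_spread_excluded_players": dict(spread_excluded),
        "rows_dropped_standardization": int(len(retained) - len(lei_records)),
        "rows_scored": int(len(lei_records)),
        "n_weeks": int(len(weeks)),
        "short_weeks_excluded": short_weeks,
        "n_transitions": int(len(transitions)),
        "undefined_pct_changes": transitions.attrs.get("undefined_pct_changes", {}),
        "grid_cells_fitted": len(tables),
        "grid_cells_skipped": [f"{r}/{m}: {why}" for r, m, why in skipped],
        "config": cfg.to_dict(),
    }
    result = PipelineResult(
        lei_records=lei_records,
        daily_lei=daily,
        weeks=weeks,
        transitions=transitions,
        coefficients=coefficients,
        descriptives=descriptives,
        tables=tables,
        skipped=skipped,
        log=log,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
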