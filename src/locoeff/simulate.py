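"""Synthetic squad simulator with latent fitness-fatigue dynamics.

Generates longitudinal session-level GPS monitoring data for a football
squad in which a hidden per-player fatigue state, driven by an
impulse-response (Banister-type) recurrence, inflates the measured
PlayerLoad relative to the locomotor output.  Because the fatigue series
is emitted alongside the sessions, every downstream stage (residual
scoring, readiness classification, mixed-model inference) can be tested
against known ground truth.

The fatigue state of player *p* evolves daily as::

    F(t) = F(t-1) * exp(-1 / tau_f) + k_f * impulse(t)

where ``impulse(t)`` is the day's total distance normalized by the
player's habitual session volume (dimensionless), ``tau_f`` is the
fatigue time constant in days and ``k_f`` the impulse gain.  Measured
PlayerLoad is a per-player linear combination of session features
multiplied by ``1 + gamma * F`` (pre-session fatigue) plus Gaussian
noise, so higher accumulated load inflates body load relative to the
locomotor work actually performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "PREDICTORS",
    "SESSION_COLUMNS",
    "SimConfig",
    "TruePlayerState",
    "fatigue_update",
    "generate_session_features",
    "true_playerload",
    "simulate_squad",
]

#: The seven session features used to predict PlayerLoad.
PREDICTORS = [
    "total_distance",
    "dist_gt_7_2",
    "n_acc_gt_2_5",
    "n_dec_lt_m2_5",
    "max_speed",
    "max_acc",
    "max_dec",
]

#: Full schema of one emitted session row.
SESSION_COLUMNS = [
    "player_id",
    "date",
    "session_index_in_day",
    "session_type",
    "total_distance",
    "dist_gt_7_2",
    "dist_gt_25_2",
    "n_acc_gt_2_5",
    "n_dec_lt_m2_5",
    "n_acc_gt_3_5",
    "n_dec_lt_m3_5",
    "max_speed",
    "max_acc",
    "max_dec",
    "player_load",
]


@dataclass
class SimConfig:
    """Parameters of the squad simulation.

    Defaults emulate a professional squad monitored over two full
    seasons: ~100 players, ~40 training weeks per season, five training
    sessions plus one weekend match per week.

    Parameters
    ----------
    n_players, n_weeks, sessions_per_week
        Squad size and schedule.  ``sessions_per_week`` counts training
        sessions plus the single weekly match.
    tau_f
        Fatigue decay time constant (days).  Default 3: acute
        neuromuscular fatigue after a match largely dissipates within
        about 72 h, so a week's mean fatigue is dominated by that
        week's own load rather than by carry-over.
    k_f
        Fatigue gain per unit of normalized daily load impulse
        (dimensionless).  ``k_f = 0`` switches fatigue off.
    gamma
        PlayerLoad inflation per unit fatigue: measured PL is the
        fatigue-free value times ``1 + gamma * F``.
    noise_sd
        SD of additive measurement noise on PlayerLoad (arbitrary
        units; a typical session is ~300 AU).
    unload_prob, overload_prob
        Per player-week probability that the week is programmed as a
        taper or an overload block (mutually exclusive draws).
    unload_drop_days, unload_volume_scale
        A taper week drops this many training days and shrinks the
        remaining training sessions by this factor (tapers reduce
        frequency and duration while keeping intensity), cutting the
        weekly volume by roughly 35%.
    overload_extra_sessions, overload_extra_volume
        An overload week adds a second daily session of this relative
        volume on this many training days, raising the weekly volume
        by roughly 35%.  Frequency-based programming keeps individual
        sessions looking ordinary, as in real schedules.
    two_session_prob
        Probability an ordinary training day is split into two
        half-volume sessions.
    match_multiplier
        Volume multiplier of match days relative to a training session.
    attend_prob
        Per-session attendance probability (injuries, rotation).
    base_volume_mean, base_volume_sd
        Squad distribution of habitual per-session volume (m).
    player_effect_sd
        SD of the per-player multiplicative offset on the feature ->
        PlayerLoad map (individual mechanical efficiency).  Zero makes
        the fatigue-free map identical across the squad.
    start_date
        First Monday of the simulated period (ISO string).
    seed
        Seed of the single RNG stream; identical configs give
        byte-identical output.
    """

    n_players: int = 100
    n_weeks: int = 80
    sessions_per_week: int = 6
    tau_f: float = 3.0
    k_f: float = 0.15
    gamma: float = 0.3
    noise_sd: float = 10.0
    unload_prob: float = 0.15
    overload_prob: float = 0.15
    unload_drop_days: int = 2
    unload_volume_scale: float = 0.9
    overload_extra_sessions: int = 3
    overload_extra_volume: float = 0.8
    two_session_prob: float = 0.1
    match_multiplier: float = 1.3
    attend_prob: float = 0.95
    base_volume_mean: float = 5000.0
    base_volume_sd: float = 500.0
    player_effect_sd: float = 0.05
    start_date: str = "2021-07-05"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_players, self.n_weeks, self.sessions_per_week) < 1:
            raise ValueError("n_players, n_weeks and sessions_per_week must be >= 1")
        if self.sessions_per_week > 7:
            raise ValueError("sessions_per_week must be <= 7")
        if self.tau_f <= 0:
            raise ValueError("tau_f must be > 0")
        for name in ("k_f", "gamma", "noise_sd", "player_effect_sd", "base_volume_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("unload_prob", "overload_prob", "two_session_prob", "attend_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.unload_prob + self.overload_prob > 1.0:
            raise ValueError("unload_prob + overload_prob must be <= 1")
        if not 0 <= self.unload_drop_days < self.sessions_per_week - 1:
            raise ValueError("unload_drop_days must leave at least one training day")
        if not 0 < self.unload_volume_scale <= 1.0:
            raise ValueError("unload_volume_scale must be in (0, 1]")
        if not 0 <= self.overload_extra_sessions <= self.sessions_per_week - 1:
            raise ValueError("overload_extra_sessions must fit the training days")
        if self.overload_extra_volume <= 0:
            raise ValueError("overload_extra_volume must be > 0")
        if self.base_volume_mean <= 0:
            raise ValueError("base_volume_mean must be > 0")
        _date.fromisoformat(self.start_date)  # validates format

    def to_dict(self) -> dict:
        return asdict(self)


# Squad-level coefficients of the fatigue-free feature -> PlayerLoad map.
# Scaled so a typical 5 km session lands near 330 AU, with distance the
# dominant contributor (mirroring accelerometer-load correlates).
BASE_COEFFS = {
    "total_distance": 0.045,  # AU per m
    "dist_gt_7_2": 0.020,     # extra AU per m above 7.2 km/h
    "n_acc_gt_2_5": 0.50,     # AU per acceleration
    "n_dec_lt_m2_5": 0.50,    # AU per deceleration
    "max_speed": 0.80,        # AU per km/h
    "max_acc": 2.0,           # AU per m/s^2
    "max_dec": -2.0,          # max_dec is negative, so this adds load
}


@dataclass
class TruePlayerState:
    """Ground-truth latent state of one simulated player."""

    player_id: str
    base_volume: float
    efficiency_coeffs: dict[str, float]
    fatigue: float = 0.0
    fatigue_series: list = field(default_factory=list)


def fatigue_update(f_prev: float, daily_impulse: float, tau_f: float, k_f: float) -> float:
    """One daily step of the fatigue impulse-response recurrence.

    Returns ``f_prev * exp(-1/tau_f) + k_f * daily_impulse``.
    """
    if tau_f <= 0:
        raise ValueError("tau_f must be > 0")
    if f_prev < 0:
        raise ValueError("fatigue must be non-negative")
    return f_prev * math.exp(-1.0 / tau_f) + k_f * daily_impulse


def generate_session_features(
    state: TruePlayerState,
    planned_volume: float,
    rng: np.random.Generator,
    session_type: str = "training",
) -> dict:
    """Draw the feature fields of one session record (without PlayerLoad).

    Distances are drawn as the planned volume times a lognormal jitter,
    with band distances as nested fractions of the total so the ordering
    invariants (high-speed <= moderate-speed <= total) hold by
    construction.  Acceleration counts above the higher threshold are
    binomial thinnings of the counts above the lower threshold.
    """
    if planned_volume <= 0:
        raise ValueError("planned_volume must be > 0")

    total = planned_volume * rng.lognormal(mean=0.0, sigma=0.10)
    frac_7_2 = rng.beta(a=20.0, b=37.0)            # ~35% above 7.2 km/h
    dist_7_2 = total * frac_7_2
    frac_25_2 = rng.beta(a=2.0, b=120.0)           # ~1.6% of moderate-speed
    dist_25_2 = dist_7_2 * frac_25_2

    scale = total / 5000.0
    n_acc_lo = int(rng.poisson(40.0 * scale))
    n_dec_lo = int(rng.poisson(35.0 * scale))
    n_acc_hi = int(rng.binomial(n_acc_lo, 0.45)) if n_acc_lo > 0 else 0
    n_dec_hi = int(rng.binomial(n_dec_lo, 0.45)) if n_dec_lo > 0 else 0

    max_speed = float(np.clip(rng.normal(28.0, 1.5), 20.0, 37.0))
    max_acc = float(np.clip(rng.normal(4.2, 0.3), 2.0, 6.5))
    max_dec = float(np.clip(rng.normal(-4.5, 0.35), -7.0, -2.0))

    return {
        "session_type": session_type,
        "total_distance": total,
        "dist_gt_7_2": dist_7_2,
        "dist_gt_25_2": dist_25_2,
        "n_acc_gt_2_5": n_acc_lo,
        "n_dec_lt_m2_5": n_dec_lo,
        "n_acc_gt_3_5": n_acc_hi,
        "n_dec_lt_m3_5": n_dec_hi,
        "max_speed": max_speed,
        "max_acc": max_acc,
        "max_dec": max_dec,
    }


def true_playerload(
    features: dict,
    efficiency_coeffs: dict[str, float],
    fatigue: float,
    gamma: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> float:
    """Measured PlayerLoad of a session given pre-session fatigue.

    ``(sum_j coeff_j * feature_j) * (1 + gamma * F) + noise``, floored
    at a small positive value so loads stay physical.
    """
    if fatigue < 0:
        raise ValueError("fatigue must be non-negative")
    base = sum(efficiency_coeffs[k] * features[k] for k in efficiency_coeffs)
    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    return max(base * (1.0 + gamma * fatigue) + noise, 1.0)


def _make_player_state(i: int, cfg: SimConfig, rng: np.random.Generator) -> TruePlayerState:
    base_volume = max(float(rng.normal(cfg.base_volume_mean, cfg.base_volume_sd)), 1500.0)
    mult = max(1.0 + rng.normal(0.0, cfg.player_effect_sd), 0.2)
    coeffs = {k: v * mult for k, v in BASE_COEFFS.items()}
    return TruePlayerState(player_id=f"P{i + 1:03d}", base_volume=base_volume, efficiency_coeffs=coeffs)


def simulate_squad(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full squad.

    Returns
    -------
    sessions : DataFrame
        One row per attended session (schema :data:`SESSION_COLUMNS`).
    truth : DataFrame
        Ground-truth fatigue per player-day: columns ``player_id``,
        ``date``, ``fatigue`` (end-of-day, after the impulse update),
        ``week_index`` and ``planned_factor`` (the week's programmed
        volume factor).

    Notes
    -----
    Weekly structure: training on the first weekdays of the week, the
    match on Saturday, Sunday off.  Each player-week is independently
    programmed as a taper (``unload_drop_days`` training days removed,
    the rest shrunk by ``unload_volume_scale``), an overload (a second
    session added on ``overload_extra_sessions`` training days) or a
    nominal block; match volume is never manipulated.  An ordinary
    training day splits into two half-volume sessions with probability
    ``two_session_prob``.  PlayerLoad uses the fatigue carried into
    the day (decayed, before that day's impulse); the emitted truth
    series is end-of-day.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    start = _date.fromisoformat(cfg.start_date)
    decay = math.exp(-1.0 / cfg.tau_f)

    n_train_days = cfg.sessions_per_week - 1 if cfg.sessions_per_week < 7 else 6
    session_rows: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(cfg.n_players):
        state = _make_player_state(i, cfg, rng)
        fatigue = 0.0
        for week in range(cfg.n_weeks):
            u = rng.uniform()
            if u < cfg.unload_prob:
                week_type = "unload"
            elif u < cfg.unload_prob + cfg.overload_prob:
                week_type = "overload"
            else:
                week_type = "nominal"
            dropped: set[int] = set()
            extra: set[int] = set()
            if week_type == "unload" and cfg.unload_drop_days > 0:
                dropped = set(
                    rng.choice(n_train_days, size=min(cfg.unload_drop_days, n_train_days), replace=False)
                )
            elif week_type == "overload" and cfg.overload_extra_sessions > 0:
                extra = set(
                    rng.choice(
                        n_train_days, size=min(cfg.overload_extra_sessions, n_train_days), replace=False
                    )
                )
            train_seen = -1
            for dow in range(7):
                day = start + timedelta(days=7 * week + dow)
                if cfg.sessions_per_week == 7:
                    is_match = dow == 5
                    is_training = not is_match
                else:
                    is_match = dow == 5
                    is_training = dow < n_train_days
                day_sessions: list[tuple[str, float]] = []
                if is_training:
                    train_seen += 1
                    scale = cfg.unload_volume_scale if week_type == "unload" else 1.0
                    if train_seen in dropped:
                        day_sessions = []
                    elif train_seen in extra:
                        day_sessions = [("training", 1.0), ("training", cfg.overload_extra_volume)]
                    elif cfg.two_session_prob > 0 and rng.uniform() < cfg.two_session_prob:
                        day_sessions = [("training", 0.6 * scale), ("training", 0.6 * scale)]
                    else:
                        day_sessions = [("training", scale)]
                elif is_match:
                    day_sessions = [("match", cfg.match_multiplier)]

                pre_fatigue = fatigue * decay
                day_distance = 0.0
                for s_idx, (stype, vol_mult) in enumerate(day_sessions, start=1):
                    if cfg.attend_prob < 1.0 and rng.uniform() >= cfg.attend_prob:
                        continue
                    planned = state.base_volume * vol_mult
                    feats = generate_session_features(state, planned, rng, session_type=stype)
                    pl = true_playerload(
                        feats, state.efficiency_coeffs, pre_fatigue, cfg.gamma, cfg.noise_sd, rng
                    )
                    day_distance += feats["total_distance"]
                    session_rows.append(
                        {
                            "player_id": state.player_id,
                            "date": day.isoformat(),
                            "session_index_in_day": s_idx,
                            **feats,
                            "player_load": pl,
                        }
                    )
                impulse = day_distance / state.base_volume
                fatigue = fatigue_update(fatigue, impulse, cfg.tau_f, cfg.k_f)
                truth_rows.append(
                    {
                        "player_id": state.player_id,
                        "date": day.isoformat(),
                        "fatigue": fatigue,
                        "week_index": week,
                        "week_type": week_type,
                    }
                )

    sessions = pd.DataFrame(session_rows, columns=SESSION_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["player_id", "date", "fatigue", "week_index", "week_type"])
    return sessions, truth
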