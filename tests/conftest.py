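import numpy as np
import pandas as pd
import pytest

import locoeff
from locoeff.periodization import FLUCTUATION_CATEGORIES


@pytest.fixture(scope="session")
def small_squad():
    """A small simulated squad with fatigue coupling on (defaults)."""
    cfg = locoeff.SimConfig(n_players=12, n_weeks=20, seed=7)
    sessions, truth = locoeff.simulate_squad(cfg)
    return cfg, sessions, truth


@pytest.fixture(scope="session")
def scored_squad(small_squad):
    """The small squad pushed through the full default (random-forest,
    out-of-fold) pipeline; shared because the ensemble fit is the
    expensive step."""
    _, sessions, truth = small_squad
    result = locoeff.run_pipeline(sessions, locoeff.PipelineConfig(seed=7))
    return sessions, truth, result


@pytest.fixture(scope="session")
def toy_transitions_factory():
    """Factory for balanced synthetic transition tables: every player
    contributes ``per_category`` rows in every fluctuation category,
    with optional true category effects and player intercepts."""

    def make(
        n_players=10,
        per_category=2,
        effects=None,
        re_sd=0.0,
        noise_sd=0.5,
        seed=0,
        readiness="normal",
    ):
        rng = np.random.default_rng(seed)
        effects = effects or {c: 0.0 for c in FLUCTUATION_CATEGORIES}
        rows = []
        for p in range(n_players):
            intercept = rng.normal(0, re_sd)
            for cat in FLUCTUATION_CATEGORIES:
                for _ in range(per_category):
                    rows.append(
                        {
                            "player_id": f"P{p:02d}",
                            "readiness_ref": readiness,
                            "category_total_distance": cat,
                            "category_dist_gt_25_2": cat,
                            "category_mechanical_load": cat,
                            "lei_variation": effects[cat] + intercept + rng.normal(0, noise_sd),
                        }
                    )
        return pd.DataFrame(rows)

    return make


@pytest.fixture()
def toy_weeks():
    """Hand-set weekly summaries for three players over five weeks.

    Loads are chosen so the expected fluctuation categories are
    obvious by eye; LEI values exercise all readiness states.
    """
    rows = []
    # (player, week, total_distance, hs_distance, mech, weekly_lei, n_sessions)
    data = [
        ("A", 0, 1000.0, 100.0, 50.0, -0.8, 6),
        ("A", 1, 650.0, 100.0, 60.0, 0.0, 6),   # -35% large_decrease / 0% / +20% moderate_increase
        ("A", 2, 1300.0, 89.0, 60.0, 0.6, 6),   # +100% large_increase / -11% mod_dec / 0%
        ("A", 3, 1170.0, 89.0, 30.0, 0.2, 6),   # -10% no_variation / 0% / -50% large_decrease
        ("A", 4, 1170.0, 115.0, 39.0, -0.2, 6),  # 0% / +29.2% moderate_increase / +30% moderate_increase
        ("B", 0, 2000.0, 200.0, 100.0, 0.9, 6),
        ("B", 1, 2500.0, 200.0, 131.0, 0.4, 6),  # +25% moderate_increase / 0% / +31% large_increase
        ("B", 3, 2500.0, 200.0, 131.0, 0.4, 6),  # gap at week 2: no (1,2) or (2,3) pair
        ("C", 0, 1500.0, 150.0, 80.0, -0.5, 6),
        ("C", 1, 1500.0, 150.0, 80.0, -0.6, 2),  # short week: dropped from pairs
        ("C", 2, 1500.0, 150.0, 80.0, 0.5, 6),
    ]
    for pid, w, td, hs, mech, lei, n in data:
        rows.append(
            dict(
                player_id=pid,
                week_index=w,
                total_distance=td,
                dist_gt_25_2=hs,
                mechanical_load=mech,
                weekly_lei=lei,
                readiness=locoeff.classify_readiness(lei),
                n_sessions=n,
            )
        )
    return pd.DataFrame(rows)
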