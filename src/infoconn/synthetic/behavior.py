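"""Synthetic behavioral logs: training sessions and pre/post transfer tasks.

Navigation transfer sessions are 20 trials whose normalized distance
error follows an exponential learning curve; verbal transfer sessions
are up to 5 recall trials of a fixed-length word list with a linear
learning trend. Planted group × session improvements are expressed as
additive boosts to the learning-curve parameters.

The verbal training schedule (list grows on success, shrinks after
repeated failure) is parameterized rather than fixed, because only its
qualitative shape is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..design import StudyDesign
from ..errors import InvalidArgumentError


@dataclass
class BehaviorParams:
    """Learning-curve and schedule parameters for the generators."""

    # navigation transfer: error_t = floor + span * exp(-rate * t) + noise
    n_nav_transfer_trials: int = 20
    nav_floor: float = 0.2
    nav_span: float = 1.5
    nav_rate: float = 0.08
    nav_rate_boost: dict[tuple[str, str], float] = field(default_factory=dict)
    # span multiplier per (group, session); < 1 shrinks early errors,
    # pulling the learning rate toward 0 (the planted improvement)
    nav_span_factor: dict[tuple[str, str], float] = field(default_factory=dict)
    nav_noise_sd: float = 0.1
    nav_optimal_range: tuple[float, float] = (50.0, 150.0)
    # verbal transfer: n_correct_t = base + slope * t + noise (clipped)
    n_verbal_transfer_trials: int = 5
    verbal_list_length: int = 12
    verbal_base: float = 5.0
    verbal_slope: float = 0.8
    verbal_slope_boost: dict[tuple[str, str], float] = field(default_factory=dict)
    verbal_noise_sd: float = 0.8
    # training schedules
    n_training_days: int = 10
    nav_training_trials_per_day: int = 20
    nav_training_shortest_range: tuple[float, float] = (80.0, 200.0)
    nav_training_excess_start: float = 1.0
    nav_training_decay: float = 0.15
    nav_training_noise_sd: float = 0.05
    verbal_training_trials_per_day: int = 15
    verbal_start_length: int = 5
    verbal_growth: int = 1
    verbal_fail_limit: int = 2
    verbal_ability_start: float = 6.0
    verbal_ability_slope: float = 3.0
    verbal_partial_recall: float = 0.8

    def validate(self) -> None:
        for name in ("nav_floor", "nav_span", "nav_rate", "verbal_base", "verbal_slope"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidArgumentError(f"{name} must be finite")
        if self.nav_floor < 0:
            raise InvalidArgumentError("nav_floor must be >= 0")
        if min(self.nav_optimal_range) <= 0 or min(self.nav_training_shortest_range) <= 0:
            raise InvalidArgumentError("path lengths must be positive")
        if self.n_nav_transfer_trials % 2:
            raise InvalidArgumentError("transfer trial count must be even")


@dataclass
class BehaviorLogs:
    """Tidy per-trial behavioral records, one frame per task."""

    nav_transfer: pd.DataFrame
    verbal_transfer: pd.DataFrame
    nav_training: pd.DataFrame
    verbal_training: pd.DataFrame


def _nav_transfer(
    roster: pd.DataFrame,
    sessions: tuple[str, ...],
    p: BehaviorParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    t_idx = np.arange(p.n_nav_transfer_trials)
    for _, part in roster.iterrows():
        for ses in sessions:
            rate = p.nav_rate + p.nav_rate_boost.get((part["group"], ses), 0.0)
            span = p.nav_span * p.nav_span_factor.get((part["group"], ses), 1.0)
            err = p.nav_floor + span * np.exp(-rate * t_idx)
            if p.nav_noise_sd > 0:
                err = np.maximum(err + p.nav_noise_sd * rng.standard_normal(err.size), 0.0)
            optimal = rng.uniform(*p.nav_optimal_range, size=err.size)
            traveled = optimal * (1.0 + err)
            for t in t_idx:
                rows.append(
                    (part["participant"], part["group"], ses, int(t),
                     optimal[t], traveled[t])
                )
    return pd.DataFrame(
        rows, columns=["participant", "group", "session", "trial", "optimal", "traveled"]
    )


def _verbal_transfer(
    roster: pd.DataFrame,
    sessions: tuple[str, ...],
    p: BehaviorParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    for _, part in roster.iterrows():
        for ses in sessions:
            slope = p.verbal_slope + p.verbal_slope_boost.get((part["group"], ses), 0.0)
            for t in range(p.n_verbal_transfer_trials):
                mu = p.verbal_base + slope * t
                if p.verbal_noise_sd > 0:
                    mu += p.verbal_noise_sd * rng.standard_normal()
                n_correct = int(np.clip(round(mu), 0, p.verbal_list_length))
                rows.append(
                    (part["participant"], part["group"], ses, t,
                     p.verbal_list_length, n_correct)
                )
                if n_correct == p.verbal_list_length:
                    break  # perfect recall ends the session early
    return pd.DataFrame(
        rows,
        columns=["participant", "group", "session", "trial", "list_length", "n_correct"],
    )


def _nav_training(
    roster: pd.DataFrame, p: BehaviorParams, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    trained = roster[roster["group"] == "navigation"]
    for _, part in trained.iterrows():
        for day in range(1, p.n_training_days + 1):
            for t in range(p.nav_training_trials_per_day):
                shortest = rng.uniform(*p.nav_training_shortest_range)
                excess = p.nav_training_excess_start * np.exp(-p.nav_training_decay * t)
                if p.nav_training_noise_sd > 0:
                    excess = max(
                        excess + p.nav_training_noise_sd * rng.standard_normal(), 0.0
                    )
                rows.append(
                    (part["participant"], day, chr(ord("A") + (day - 1) % 6), t,
                     shortest, shortest * (1.0 + excess))
                )
    return pd.DataFrame(
        rows,
        columns=["participant", "day", "subsection", "trial", "shortest", "traveled"],
    )


def _verbal_training(
    roster: pd.DataFrame, p: BehaviorParams, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    trained = roster[roster["group"] == "verbal_memory"]
    for _, part in trained.iterrows():
        length = p.verbal_start_length
        for day in range(1, p.n_training_days + 1):
            ability = p.verbal_ability_start + p.verbal_ability_slope * (day - 1)
            fails = 0
            for t in range(p.verbal_training_trials_per_day):
                cur = length
                p_success = 1.0 / (1.0 + np.exp((cur - ability) / 2.0))
                if rng.random() < p_success:
                    n_correct = cur
                    length = cur + p.verbal_growth
                    fails = 0
                else:
                    n_correct = int(rng.binomial(cur, p.verbal_partial_recall))
                    fails += 1
                    if fails >= p.verbal_fail_limit:
                        length = max(1, cur - 1)
                        fails = 0
                rows.append((part["participant"], day, t, cur, n_correct))
    return pd.DataFrame(
        rows, columns=["participant", "day", "trial", "list_length", "n_correct"]
    )


def generate_behavior_logs(
    design: StudyDesign,
    params: BehaviorParams | None = None,
    seed: int = 0,
) -> BehaviorLogs:
    """Generate all behavioral logs for the study roster.

    Deterministic given ``seed``. Transfer logs cover every participant
    and session; training logs cover only the respective trained group.
    """
    p = params or BehaviorParams()
    p.validate()
    rng = np.random.default_rng([seed, 41])
    roster = design.participants()
    return BehaviorLogs(
        nav_transfer=_nav_transfer(roster, design.sessions, p, rng),
        verbal_transfer=_verbal_transfer(roster, design.sessions, p, rng),
        nav_training=_nav_training(roster, p, rng),
        verbal_training=_verbal_training(roster, p, rng),
    )
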