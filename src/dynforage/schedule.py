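"""Concurrent variable-interval (VI) baiting environment and dataset assembly.

This module is the synthetic-data generator of the package.  It simulates the
two-target dynamic foraging task used with behaving primates: on every trial
each *empty* target is baited with a fixed per-trial probability, a baited
target holds its reward until chosen, and the ratio of baiting probabilities
switches at unsignalled block boundaries.  A changeover delay (COD) withholds
the reward on the first choice of a switch until the second consecutive choice
of the new color.

Targets are coded as integers: ``RED = 0``, ``GREEN = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

RED = 0
GREEN = 1

#: Default baiting-ratio set (rich : lean), per the task design.
DEFAULT_RATIO_SET: tuple[tuple[float, float], ...] = ((8, 1), (6, 1), (3, 1), (1, 1))


class ConfigurationError(ValueError):
    """Raised when a schedule or dataset configuration is invalid."""


@dataclass(frozen=True)
class ScheduleConfig:
    """Parameters of the concurrent-VI baiting schedule.

    Parameters
    ----------
    total_bait_rate
        Summed per-trial baiting probability of the two targets
        (default 0.35 rewards/trial, the task's standard value).
    ratio_set
        Candidate (rich, lean) baiting-rate ratios; one is drawn uniformly
        per block and assigned to green/red with a random sign.
    block_length_range
        Inclusive (low, high) range of block lengths in trials; lengths are
        drawn uniformly.
    n_blocks
        Number of blocks in the schedule.
    cod_enabled
        Whether the changeover delay is applied when the environment is
        stepped.
    """

    total_bait_rate: float = 0.35
    ratio_set: tuple[tuple[float, float], ...] = DEFAULT_RATIO_SET
    block_length_range: tuple[int, int] = (100, 200)
    n_blocks: int = 10
    cod_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.total_bait_rate <= 1.0):
            raise ConfigurationError(
                f"total_bait_rate must be in (0, 1], got {self.total_bait_rate}"
            )
        for pair in self.ratio_set:
            if len(pair) != 2 or pair[0] <= 0 or pair[1] <= 0:
                raise ConfigurationError(f"invalid ratio pair {pair!r}")
        lo, hi = self.block_length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"invalid block_length_range {self.block_length_range!r}"
            )
        if self.n_blocks < 0:
            raise ConfigurationError("n_blocks must be >= 0")


@dataclass
class Schedule:
    """A realized schedule: per-trial baiting probabilities and block labels.

    ``p_target[trial, target]`` is the baiting probability of each target on
    each trial (constant within a block, summing to ``total_bait_rate``).
    Baited state is *not* stored here -- it evolves with agent interaction in
    :func:`step_environment`.
    """

    p_target: np.ndarray  # shape (n_trials, 2)
    block_id: np.ndarray  # shape (n_trials,), non-decreasing ints
    config: ScheduleConfig

    @property
    def n_trials(self) -> int:
        return self.p_target.shape[0]

    @property
    def n_blocks(self) -> int:
        return 0 if self.n_trials == 0 else int(self.block_id[-1]) + 1


def generate_schedule(config: ScheduleConfig, rng: np.random.Generator) -> Schedule:
    """Draw a block structure and return the resulting :class:`Schedule`.

    Block ratios are drawn uniformly from ``config.ratio_set``, block lengths
    uniformly (inclusive) from ``config.block_length_range``, and the rich
    side is assigned to green or red with probability 1/2.
    """
    lo, hi = config.block_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_blocks)
    ratio_idx = rng.integers(0, len(config.ratio_set), size=config.n_blocks)
    rich_is_green = rng.random(config.n_blocks) < 0.5

    p_rows = []
    block_rows = []
    for b in range(config.n_blocks):
        rich, lean = config.ratio_set[ratio_idx[b]]
        p_rich = config.total_bait_rate * rich / (rich + lean)
        p_lean = config.total_bait_rate * lean / (rich + lean)
        if rich_is_green[b]:
            p_g, p_r = p_rich, p_lean
        else:
            p_g, p_r = p_lean, p_rich
        n = int(lengths[b])
        p_rows.append(np.tile([p_r, p_g], (n, 1)))
        block_rows.append(np.full(n, b, dtype=np.int64))

    if config.n_blocks == 0:
        p = np.empty((0, 2))
        blocks = np.empty(0, dtype=np.int64)
    else:
        p = np.vstack(p_rows)
        blocks = np.concatenate(block_rows)
    return Schedule(p_target=p, block_id=blocks, config=config)


@dataclass
class EnvState:
    """Mutable interaction state of the environment within a session."""

    baited: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=bool))
    prev_choice: int | None = None
    n_baits_assigned: int = 0
    n_rewards: int = 0


def step_environment(
    schedule: Schedule,
    trial_index: int,
    choice: int,
    state: EnvState,
    rng: np.random.Generator,
    bait_draws: np.ndarray | None = None,
) -> int:
    """Advance the environment one trial and return the delivered reward.

    Bait assignment is applied to both (empty) targets first; the chosen
    target then pays its bait unless the choice is the first of a switch
    under the COD, in which case the bait persists and is delivered on the
    second consecutive choice of the new color.

    ``bait_draws`` may supply the two pre-drawn uniforms for this trial
    (used by :func:`run_session` for reproducible bulk draws).
    """
    if not 0 <= trial_index < schedule.n_trials:
        raise IndexError(f"trial_index {trial_index} outside schedule")
    u = rng.random(2) if bait_draws is None else bait_draws
    p = schedule.p_target[trial_index]
    for tgt in (RED, GREEN):
        if not state.baited[tgt] and u[tgt] < p[tgt]:
            state.baited[tgt] = True
            state.n_baits_assigned += 1

    is_switch = state.prev_choice is not None and choice != state.prev_choice
    reward = 0
    if state.baited[choice] and not (schedule.config.cod_enabled and is_switch):
        reward = 1
        state.baited[choice] = False
        state.n_rewards += 1
    state.prev_choice = choice
    return reward


@dataclass
class SessionData:
    """One session of trials: the universal unit of analysis.

    ``choice`` holds 0 (red) / 1 (green); ``reward`` 0/1; ``free_choice``
    flags the choices retained after COD collapsing (the imposed second
    choice of a switch pair is flagged False); ``block_id`` labels blocks.
    ``meta`` carries session bookkeeping (day index, preceding break length,
    bait counts, ...).
    """

    choice: np.ndarray
    reward: np.ndarray
    free_choice: np.ndarray
    block_id: np.ndarray
    meta: dict = field(default_factory=dict)
    #: the generating model's P(green) per trial, when simulated (else None)
    p_green: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return len(self.choice)

    @property
    def n_baits_assigned(self) -> int:
        return int(self.meta.get("n_baits_assigned", -1))

    def __post_init__(self) -> None:
        n = len(self.choice)
        if not (len(self.reward) == len(self.free_choice) == len(self.block_id) == n):
            raise ValueError("per-trial arrays must share one length")


def _free_choice_flags(choices: np.ndarray) -> np.ndarray:
    """COD collapsing: the second of the two choices marking a switch is
    flagged as not free, so a switch pair counts as a single choice."""
    n = len(choices)
    free = np.ones(n, dtype=bool)
    for t in range(2, n):
        switched_prev = choices[t - 1] != choices[t - 2]
        if switched_prev and choices[t] == choices[t - 1]:
            free[t] = False
    return free


def run_session(
    agent,
    schedule: Schedule,
    rng: np.random.Generator,
    meta: dict | None = None,
    repeat_switch: bool | None = None,
) -> SessionData:
    """Close the agent/environment loop over a full schedule.

    The agent must expose ``choice_prob() -> P(green)`` and
    ``update(choice, reward)``; incomes are updated from the actually
    delivered rewards on every trial.

    ``repeat_switch`` (default: follows ``cod_enabled``) emulates learned
    COD compliance: the trial after a switch repeats the new color (the
    imposed second choice, which collects the withheld bait); the switch
    pair is then collapsed to a single free choice.
    """
    if repeat_switch is None:
        repeat_switch = schedule.config.cod_enabled
    n = schedule.n_trials
    draws = rng.random((n, 3))  # columns: bait red, bait green, choice
    state = EnvState()
    choices = np.empty(n, dtype=np.int8)
    rewards = np.empty(n, dtype=np.int8)
    probs = np.empty(n)
    forced: int | None = None
    for t in range(n):
        p_g = agent.choice_prob()
        if not 0.0 <= p_g <= 1.0 or not np.isfinite(p_g):
            raise RuntimeError(f"agent returned invalid choice probability {p_g}")
        if forced is not None:
            c = forced
            forced = None
        else:
            c = GREEN if draws[t, 2] < p_g else RED
            if repeat_switch and t > 0 and c != choices[t - 1]:
                forced = c
        r = step_environment(schedule, t, c, state, rng, bait_draws=draws[t, :2])
        agent.update(c, r)
        choices[t] = c
        rewards[t] = r
        probs[t] = p_g

    m = dict(meta or {})
    m.setdefault("n_baits_assigned", state.n_baits_assigned)
    m.setdefault("n_baits_pending", int(state.baited.sum()))
    m.setdefault("total_bait_rate", schedule.config.total_bait_rate)
    # maximum collectable rewards: baits an always-harvesting oracle would
    # receive on the same draws (its targets are always empty)
    m.setdefault("n_baits_oracle", int((draws[:, :2] < schedule.p_target).sum()))
    return SessionData(
        choice=choices,
        reward=rewards,
        free_choice=_free_choice_flags(choices),
        block_id=schedule.block_id.copy(),
        meta=m,
        p_green=probs,
    )


@dataclass
class DatasetConfig:
    """Multi-day dataset layout emulating a chronic experiment.

    ``break_lengths`` gives the gap (abstract day units) preceding each
    experimental day; ``weight_drift``, if given, is an
    (n_sessions, n_timescales) array of agent weights applied per session,
    emulating slow drift of the slow-integrator weight across sessions.
    """

    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    n_days: int = 10
    sessions_per_day: int | Callable[[int], int] = 3
    break_lengths: Sequence[float] | None = None
    weight_drift: np.ndarray | None = None
    carry_slow_income: bool = True

    def sessions_on_day(self, day: int) -> int:
        if callable(self.sessions_per_day):
            return int(self.sessions_per_day(day))
        return int(self.sessions_per_day)

    @property
    def n_sessions(self) -> int:
        return sum(self.sessions_on_day(d) for d in range(self.n_days))

    def __post_init__(self) -> None:
        if self.break_lengths is not None:
            if len(self.break_lengths) != self.n_days:
                raise ConfigurationError(
                    "break_lengths must have one entry per day"
                )
            if any(b < 0 for b in self.break_lengths):
                raise ConfigurationError("break lengths must be >= 0")
        if self.weight_drift is not None:
            w = np.asarray(self.weight_drift, dtype=float)
            if w.shape[0] != self.n_sessions:
                raise ConfigurationError(
                    f"weight_drift has {w.shape[0]} rows for "
                    f"{self.n_sessions} sessions"
                )
            if np.any(w < 0) or not np.allclose(w.sum(axis=1), 1.0):
                raise ConfigurationError("weight rows must lie on the simplex")


def generate_dataset(
    dataset_config: DatasetConfig,
    agent_factory: Callable[[int], object],
    rng: np.random.Generator,
) -> list[SessionData]:
    """Generate an ordered multi-day list of sessions.

    ``agent_factory(session_index)`` builds the agent for each session.  If
    ``weight_drift`` is set the agent's ``weights`` attribute is overridden
    per session; if ``carry_slow_income`` is set and the agent exposes
    ``slow_income``/``set_slow_income``, the slowest integrator's income is
    carried from each session's end into the next session's start.
    """
    cfg = dataset_config
    sessions: list[SessionData] = []
    carried = None
    s = 0
    for day in range(cfg.n_days):
        brk = 0.0 if cfg.break_lengths is None else float(cfg.break_lengths[day])
        for k in range(cfg.sessions_on_day(day)):
            agent = agent_factory(s)
            if cfg.weight_drift is not None:
                agent.weights = np.asarray(cfg.weight_drift[s], dtype=float)
            if cfg.carry_slow_income and carried is not None and hasattr(
                agent, "set_slow_income"
            ):
                agent.set_slow_income(carried)
            schedule = generate_schedule(cfg.schedule, rng)
            meta = {
                "day": day,
                "session_in_day": k,
                "session": s,
                "break_before": brk if k == 0 else 0.0,
            }
            if hasattr(agent, "weights"):
                meta["agent_weights"] = np.asarray(agent.weights, float).tolist()
            sess = run_session(agent, schedule, rng, meta=meta)
            sessions.append(sess)
            if hasattr(agent, "slow_income"):
                carried = agent.slow_income()
            s += 1
    return sessions
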