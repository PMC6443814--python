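"""Bias-variance decomposition of leaky-integrator value inference.

The inference task: estimate a piecewise-constant Bernoulli reward
probability ("the bias of a coin") that is fixed within blocks of L trials
and changes across blocks.  The estimator is a convex mixture of a fast and
a slow leaky integrator of the reward stream,

    p_hat[t] = (1 - w) * I_fast[t] + w * I_slow[t],

and its mean squared error decomposes exactly into a squared bias that
grows with the slow weight and a variance that shrinks with it.  The first
and second moments of both filters (and their cross-covariance) obey exact
linear recursions, so the curves are computed deterministically; a Monte
Carlo estimator is provided as an independent check.

Also provided: a full behavioral sweep that simulates the two-timescale
agent on the actual baiting schedule across a grid of slow weights and
collects matching slope, choice variance and harvesting efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import metrics
from .agents import MultiTimescaleAgent
from .schedule import ScheduleConfig, generate_schedule, run_session


class ParameterError(ValueError):
    pass


def default_p_levels(total_rate: float = 0.35) -> np.ndarray:
    """Reward-probability levels mirroring the task's block baiting rates.

    Each ratio pair (8:1, 6:1, 3:1, 1:1) contributes both its rich and lean
    per-trial baiting probability, so a deterministic cycle through the
    levels is symmetric with long-run mean ``total_rate / 2``.
    """
    fracs = []
    for rich, lean in ((8, 1), (6, 1), (3, 1), (1, 1)):
        fracs.extend([rich / (rich + lean), lean / (rich + lean)])
    return total_rate * np.asarray(fracs)


@dataclass(frozen=True)
class EstimationTask:
    """Piecewise-constant Bernoulli estimation task.

    ``block_length`` sets the volatility (short blocks = volatile);
    ``p_levels`` are cycled deterministically for the recursion and drawn
    uniformly for Monte Carlo when ``randomize_blocks`` is set.
    """

    block_length: int = 100
    p_levels: np.ndarray = field(default_factory=default_p_levels)
    burn_in_blocks: int = 10
    randomize_blocks: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.p_levels)
        if self.block_length < 1:
            raise ParameterError("block_length must be >= 1")
        if np.any(p < 0) or np.any(p > 1):
            raise ParameterError("p levels must lie in [0, 1]")

    def p_sequence(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Per-trial p over burn-in plus one full evaluation cycle."""
        levels = np.asarray(self.p_levels, dtype=float)
        n_lev = len(levels)
        n_blocks = self.burn_in_blocks + n_lev
        if self.randomize_blocks:
            if rng is None:
                raise ParameterError("randomized blocks need an rng")
            order = rng.integers(0, n_lev, size=n_blocks)
        else:
            order = np.arange(n_blocks) % n_lev
        return np.repeat(levels[order], self.block_length)

    @property
    def eval_start(self) -> int:
        return self.burn_in_blocks * self.block_length


def _filter_moments(p_seq: np.ndarray, tau: float, m0: float):
    """Time-resolved mean and variance of one leaky integrator.

    With a = 1/tau and Bernoulli(p[t]) observations entering at t+1:
        m[t] = (1-a) m[t-1] + a p[t-1]
        v[t] = (1-a)^2 v[t-1] + a^2 p[t-1](1-p[t-1])
    starting from the deterministic value m0 (v[0] = 0).
    """
    a = 1.0 / tau
    u = p_seq[:-1]
    m = np.empty_like(p_seq)
    m[0] = m0
    m[1:] = lfilter([a], [1.0, -(1.0 - a)], u, zi=[(1.0 - a) * m0])[0]
    pq = u * (1.0 - u)
    v = np.empty_like(p_seq)
    v[0] = 0.0
    v[1:] = lfilter([a**2], [1.0, -((1.0 - a) ** 2)], pq, zi=[0.0])[0]
    return m, v


def _cross_covariance(p_seq: np.ndarray, tau_fast: float, tau_slow: float):
    """Cross-covariance of the two filters (both driven by the same noise)."""
    af, asl = 1.0 / tau_fast, 1.0 / tau_slow
    pq = p_seq[:-1] * (1.0 - p_seq[:-1])
    c = np.empty_like(p_seq)
    c[0] = 0.0
    c[1:] = lfilter(
        [af * asl], [1.0, -((1.0 - af) * (1.0 - asl))], pq, zi=[0.0]
    )[0]
    return c


def moment_recursion(
    task: EstimationTask,
    tau_fast: float,
    tau_slow: float,
    w_slow: float,
) -> tuple[float, float, float]:
    """Exact time-averaged (bias^2, variance, MSE) of the mixed estimator.

    Moments are propagated exactly through the burn-in and averaged over
    one full deterministic cycle of blocks.
    """
    if not 0.0 <= w_slow <= 1.0:
        raise ParameterError("w_slow must be in [0, 1]")
    b2, v, m = sweep_weights(task, tau_fast, tau_slow, np.array([w_slow]))[:3]
    return float(b2[0]), float(v[0]), float(m[0])


@dataclass(frozen=True)
class BiasVarianceCurve:
    """Bias^2 / variance / MSE over a grid of slow weights."""

    w_grid: np.ndarray
    bias2: np.ndarray
    variance: np.ndarray
    mse: np.ndarray

    @property
    def argmin_w(self) -> float:
        return float(self.w_grid[int(np.argmin(self.mse))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "w_slow": self.w_grid,
                "bias2": self.bias2,
                "variance": self.variance,
                "mse": self.mse,
            }
        )


def sweep_weights(
    task: EstimationTask,
    tau_fast: float,
    tau_slow: float,
    grid: np.ndarray | None = None,
):
    """Evaluate the exact recursion across a grid of slow weights.

    Returns ``(bias2, variance, mse, curve)`` where the first three are
    arrays over the grid and ``curve`` is the assembled
    :class:`BiasVarianceCurve`.  The filter moments do not depend on the
    weight, so they are propagated once and combined bilinearly per grid
    point.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 51)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("empty weight grid")
    if tau_fast < 1 or tau_slow < 1:
        raise ParameterError("taus must be >= 1")

    p_seq = task.p_sequence()
    m0 = float(np.mean(task.p_levels))
    mf, vf = _filter_moments(p_seq, tau_fast, m0)
    ms, vs = _filter_moments(p_seq, tau_slow, m0)
    c = _cross_covariance(p_seq, tau_fast, tau_slow)

    s = task.eval_start
    w = grid[:, None]
    mean_est = (1.0 - w) * mf[None, s:] + w * ms[None, s:]
    var_est = (
        (1.0 - w) ** 2 * vf[None, s:]
        + w**2 * vs[None, s:]
        + 2.0 * w * (1.0 - w) * c[None, s:]
    )
    bias2_t = (mean_est - p_seq[None, s:]) ** 2
    bias2 = bias2_t.mean(axis=1)
    variance = var_est.mean(axis=1)
    mse = bias2 + variance
    curve = BiasVarianceCurve(grid, bias2, variance, mse)
    return bias2, variance, mse, curve


def monte_carlo_mse(
    task: EstimationTask,
    tau_fast: float,
    tau_slow: float,
    w_slow: float,
    n_runs: int,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Monte Carlo (bias^2, variance, MSE): the independent check on the
    recursion.  Simulates ``n_runs`` Bernoulli reward streams through both
    filters and measures the estimator's moments empirically."""
    p_seq = task.p_sequence()
    n = len(p_seq)
    rewards = (rng.random((n_runs, n - 1)) < p_seq[:-1]).astype(float)
    af, asl = 1.0 / tau_fast, 1.0 / tau_slow
    m0 = float(np.mean(task.p_levels))
    zi = np.full((n_runs, 1), (1.0 - af) * m0)
    i_fast = lfilter([af], [1.0, -(1.0 - af)], rewards, axis=1, zi=zi)[0]
    zi = np.full((n_runs, 1), (1.0 - asl) * m0)
    i_slow = lfilter([asl], [1.0, -(1.0 - asl)], rewards, axis=1, zi=zi)[0]
    est = np.empty((n_runs, n))
    est[:, 0] = m0
    est[:, 1:] = (1.0 - w_slow) * i_fast + w_slow * i_slow
    s = task.eval_start
    est = est[:, s:]
    p = p_seq[s:]
    mean_est = est.mean(axis=0)
    bias2 = float(np.mean((mean_est - p) ** 2))
    variance = float(np.mean(est.var(axis=0)))
    mse = float(np.mean((est - p[None, :]) ** 2))
    return bias2, variance, mse


def matching_slope_vs_weight(
    schedule_config: ScheduleConfig,
    w_grid,
    seed: int,
    tau_fast: float = 2.0,
    tau_slow: float = 1000.0,
    last_n: int | None = 50,
    min_rewards: int = 5,
) -> pd.DataFrame:
    """Behavioral sweep: simulate the two-timescale agent per slow weight.

    Every weight is run on the *same* schedule realization and the same
    pre-drawn randomness (matched seeds), so differences across weights are
    attributable to the weight alone.  Returns one row per weight with the
    matching slope, sqrt variance of choice, harvesting efficiency and mean
    green-choice probability.
    """
    rows = []
    for w in np.asarray(w_grid, dtype=float):
        rng = np.random.default_rng(seed)
        schedule = generate_schedule(schedule_config, rng)
        agent = MultiTimescaleAgent.from_weights(
            (tau_fast, tau_slow), (1.0 - w, w),
            initial_income=schedule_config.total_bait_rate / 2,
        )
        sess = run_session(agent, schedule, rng)
        blocks = metrics.block_summaries(sess, last_n=last_n)
        try:
            fit = metrics.fit_matching(blocks, min_rewards=min_rewards)
            slope = fit.slope
        except metrics.InsufficientDataError:
            slope = np.nan
        try:
            sqrt_var = metrics.variance_of_choice(sess).sqrt_variance
        except metrics.InsufficientDataError:
            sqrt_var = np.nan
        rows.append(
            {
                "w_slow": w,
                "slope": slope,
                "sqrt_variance": sqrt_var,
                "efficiency": metrics.harvesting_efficiency(sess),
                "mean_choice_green": float(
                    (sess.choice[sess.free_choice] == 1).mean()
                ),
            }
        )
    return pd.DataFrame(rows)
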