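"""Model-independent behavioral statistics for foraging sessions.

Everything here is computed directly from choice/reward records, without
reference to any generative model: the block-wise matching regression and
its slope deficit (undermatching), color choice bias, harvesting
efficiency, the kernel-based variance of choice, and the color reward
imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import GREEN, SessionData


class InsufficientDataError(ValueError):
    """Raised when a statistic is undefined on the given data."""


@dataclass(frozen=True)
class BlockSummary:
    """Per-block green choice and reward fractions over free choices."""

    block_id: int
    choice_fraction: float
    reward_fraction: float
    n_free_choices: int
    n_rewards: int


@dataclass(frozen=True)
class MatchingFit:
    """Block-wise OLS of choice fraction on reward fraction.

    ``undermatching = 1 - slope``; ``color_choice_bias`` is the fitted
    value at reward fraction 0.5, minus 0.5 (a pure intercept measure,
    independent of the slope).
    """

    slope: float
    intercept: float
    n_blocks: int

    @property
    def undermatching(self) -> float:
        return 1.0 - self.slope

    @property
    def color_choice_bias(self) -> float:
        return self.slope * 0.5 + self.intercept - 0.5


def block_summaries(
    session: SessionData, last_n: int | None = None
) -> list[BlockSummary]:
    """Per-block choice/reward fractions, over free choices.

    ``last_n`` restricts each block to its last ``last_n`` trials (used to
    ignore post-transition transients).  Blocks with zero rewards or zero
    free choices are excluded (their reward fraction is undefined).
    """
    out: list[BlockSummary] = []
    for b in np.unique(session.block_id):
        idx = np.flatnonzero(session.block_id == b)
        if last_n is not None:
            idx = idx[-last_n:]
        free = session.free_choice[idx]
        choices = session.choice[idx]
        rewards = session.reward[idx]
        n_free = int(free.sum())
        n_rew = int(rewards.sum())
        if n_free == 0 or n_rew == 0:
            continue
        cf = float((choices[free] == GREEN).mean())
        rf = float(rewards[choices == GREEN].sum() / n_rew)
        out.append(BlockSummary(int(b), cf, rf, n_free, n_rew))
    return out


def fit_matching(
    blocks: Sequence[BlockSummary], min_rewards: int = 5
) -> MatchingFit:
    """OLS regression of block choice fraction on block reward fraction.

    Blocks with fewer than ``min_rewards`` rewards are excluded to limit
    the leverage of extreme, noisy fractions.  Requires at least 3 retained
    blocks with non-degenerate reward-fraction spread.
    """
    kept = [b for b in blocks if b.n_rewards >= min_rewards]
    if len(kept) < 3:
        raise InsufficientDataError(
            f"matching fit needs >= 3 blocks, got {len(kept)}"
        )
    x = np.array([b.reward_fraction for b in kept])
    y = np.array([b.choice_fraction for b in kept])
    if np.ptp(x) < 1e-12:
        raise InsufficientDataError("zero variance in reward fractions")
    res = stats.linregress(x, y)
    return MatchingFit(float(res.slope), float(res.intercept), len(kept))


def harvesting_efficiency(session: SessionData) -> float:
    """Rewards obtained / maximum collectable rewards, in [0, 1].

    The maximum is the number of baits an always-harvesting oracle would
    have received on the same schedule randomness (recorded by the
    simulator as ``n_baits_oracle``).  Baits assigned during the actual
    session are a subset of the oracle's (a still-occupied target cannot be
    re-baited), so the ratio is bounded by 1.  For ingested data lacking
    the oracle count the denominator falls back to its expectation,
    ``total_bait_rate * n_trials``.
    """
    obtained = int(session.reward.sum())
    denom = session.meta.get("n_baits_oracle")
    if denom is None:
        rate = session.meta.get("total_bait_rate")
        if rate is None:
            raise InsufficientDataError(
                "no bait count or bait rate available for efficiency"
            )
        denom = rate * session.n_trials
    if denom == 0:
        raise InsufficientDataError("no baits assigned; efficiency undefined")
    return obtained / denom


def half_gaussian_kernel(sigma: float, span: int = 200) -> np.ndarray:
    """Causal (past-only) half-Gaussian smoothing kernel of length ``span``.

    Weights are proportional to ``exp(-k^2 / (2 sigma^2))`` for lags
    ``k = 0 .. span-1``, renormalized to unit sum.
    """
    k = np.arange(span)
    w = np.exp(-(k**2) / (2.0 * sigma**2))
    return w / w.sum()


@dataclass(frozen=True)
class ChoiceVariance:
    """Variance of the local choice estimate, with its square root."""

    variance: float
    sigma_fast: float = 8.0
    sigma_slow: float = 50.0
    span: int = 200

    @property
    def sqrt_variance(self) -> float:
        return float(np.sqrt(self.variance))


def variance_of_choice(
    session: SessionData,
    sigma_fast: float = 8.0,
    sigma_slow: float = 50.0,
    span: int = 200,
) -> ChoiceVariance:
    """Mean squared distance between fast and slow smoothings of choice.

    The free-choice series (green=1, red=0) is smoothed with two causal
    half-Gaussian kernels (defaults sigma = 8 and 50 trials, span 200); the
    variance is the average of (fast - slow)^2 over trials with a full
    kernel's worth of history.
    """
    c = session.choice[session.free_choice].astype(float)
    if len(c) <= span:
        raise InsufficientDataError(
            f"need more than {span} free choices, got {len(c)}"
        )
    kf = half_gaussian_kernel(sigma_fast, span)
    ks = half_gaussian_kernel(sigma_slow, span)
    # 'valid' convolution with the reversed causal kernel: entry t is the
    # kernel-weighted past of the series ending at t.
    fast = np.convolve(c, kf, mode="valid")
    slow = np.convolve(c, ks, mode="valid")
    v = float(np.mean((fast - slow) ** 2))
    return ChoiceVariance(v, sigma_fast, sigma_slow, span)


def color_reward_imbalance(sessions: SessionData | Iterable[SessionData]) -> float:
    """``(R_G - R_R) / N`` over one session or a pooled window of sessions."""
    if isinstance(sessions, SessionData):
        sessions = [sessions]
    r_g = r_r = n = 0
    for s in sessions:
        green = s.choice == GREEN
        r_g += int(s.reward[green].sum())
        r_r += int(s.reward[~green].sum())
        n += s.n_trials
    if n == 0:
        raise InsufficientDataError("imbalance undefined on zero trials")
    return (r_g - r_r) / n


@dataclass(frozen=True)
class SessionSummary:
    """Session-level scalar statistics used throughout the analysis."""

    slope: float
    undermatching: float
    color_choice_bias: float
    harvesting_efficiency: float
    sqrt_variance: float
    color_reward_imbalance: float
    n_trials: int
    n_blocks: int


def summarize_session(
    session: SessionData,
    last_n: int | None = 50,
    min_rewards: int = 5,
    span: int = 200,
) -> SessionSummary:
    """All per-session statistics in one record.

    Matching is fitted per session over the last ``last_n`` trials of each
    block.  Raises :class:`InsufficientDataError` if the session supports
    no matching fit or is shorter than the smoothing span.
    """
    fit = fit_matching(block_summaries(session, last_n=last_n), min_rewards)
    var = variance_of_choice(session, span=span)
    return SessionSummary(
        slope=fit.slope,
        undermatching=fit.undermatching,
        color_choice_bias=fit.color_choice_bias,
        harvesting_efficiency=harvesting_efficiency(session),
        sqrt_variance=var.sqrt_variance,
        color_reward_imbalance=color_reward_imbalance(session),
        n_trials=session.n_trials,
        n_blocks=fit.n_blocks,
    )


def summarize_dataset(
    sessions: Sequence[SessionData],
    last_n: int | None = 50,
    min_rewards: int = 5,
    span: int = 200,
) -> pd.DataFrame:
    """Per-session summary table for a dataset (one row per session).

    Sessions on which a statistic is undefined get NaN in that column.
    Index is the session order; metadata columns (day, break_before) are
    included when present.
    """
    rows = []
    for i, s in enumerate(sessions):
        row: dict = {
            "session": s.meta.get("session", i),
            "day": s.meta.get("day", np.nan),
            "break_before": s.meta.get("break_before", np.nan),
            "n_trials": s.n_trials,
        }
        try:
            fit = fit_matching(block_summaries(s, last_n=last_n), min_rewards)
            row.update(
                slope=fit.slope,
                undermatching=fit.undermatching,
                color_choice_bias=fit.color_choice_bias,
            )
        except InsufficientDataError:
            row.update(slope=np.nan, undermatching=np.nan, color_choice_bias=np.nan)
        try:
            row["sqrt_variance"] = variance_of_choice(s, span=span).sqrt_variance
        except InsufficientDataError:
            row["sqrt_variance"] = np.nan
        try:
            row["harvesting_efficiency"] = harvesting_efficiency(s)
        except InsufficientDataError:
            row["harvesting_efficiency"] = np.nan
        row["color_reward_imbalance"] = color_reward_imbalance(s)
        rows.append(row)
    return pd.DataFrame(rows)
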