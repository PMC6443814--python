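"""Longest measurable integration timescale (LMIT) and related tests.

The LMIT asks over how many sessions a past imbalance in rewards between
the two colors keeps influencing the color bias of choice.  Per-session
color choice bias and color reward imbalance series are correlated at
session lags 0..-5 within a sliding 25-session reference window; a weighted
least-squares line (weights gamma^lag, gamma = 0.5, favoring the more
reliable small lags) is fitted to the lagged correlations and its zero
crossing, converted to trials via the window's mean session length, is the
LMIT.  It is a lower bound on the slowest reward-integration timescale,
obtained without fitting any generative model.

Significance of correlations between session-level time series is assessed
with a conservative piece-wise permutation test that shuffles blocks of
five consecutive sessions while preserving within-block order, so that
short-range autocorrelation survives under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class LmitConfig:
    """Window, lag and weighting settings of the LMIT estimator."""

    window: int = 25
    lags: tuple[int, ...] = (0, 1, 2, 3, 4, 5)  # magnitudes of backward lags
    gamma: float = 0.5
    exclude_first: int = 25
    ma_windows: int = 10  # moving average span for display series

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.window <= max(self.lags):
            raise ValueError("window must exceed the largest lag")


def lagged_correlations(
    bias_series: np.ndarray,
    imbalance_series: np.ndarray,
    window_start: int,
    window: int = 25,
    lags: tuple[int, ...] = (0, 1, 2, 3, 4, 5),
) -> np.ndarray:
    """Pearson correlation of the window's bias values with the imbalance
    values shifted ``lag`` sessions into the past, one value per lag.

    Returns NaN for a lag whose window has zero variance in either series.
    """
    bias_series = np.asarray(bias_series, dtype=float)
    imbalance_series = np.asarray(imbalance_series, dtype=float)
    if len(bias_series) != len(imbalance_series):
        raise ValueError("series must be aligned by session index")
    if window_start < max(lags):
        raise InsufficientDataError(
            f"window at {window_start} cannot look back {max(lags)} sessions"
        )
    if window_start + window > len(bias_series):
        raise InsufficientDataError("window extends past the series")
    y = bias_series[window_start : window_start + window]
    out = np.empty(len(lags))
    for k, lag in enumerate(lags):
        x = imbalance_series[window_start - lag : window_start - lag + window]
        valid = np.isfinite(x) & np.isfinite(y)
        if valid.sum() < 3 or np.std(x[valid]) == 0 or np.std(y[valid]) == 0:
            out[k] = np.nan
        else:
            out[k] = stats.pearsonr(x[valid], y[valid])[0]
    return out


@dataclass(frozen=True)
class LmitResult:
    """One window's lagged correlations, fitted line and LMIT."""

    correlations: np.ndarray
    lags: tuple[int, ...]
    slope: float
    intercept: float
    raw_lag: float  # zero-crossing lag, sessions
    mean_session_length: float
    lmit_trials: float
    flagged: bool  # crossing was clamped or capped


def estimate_lmit(
    correlations: np.ndarray,
    mean_session_length: float,
    config: LmitConfig = LmitConfig(),
) -> LmitResult:
    """Fit the weighted line over (lag, correlation) and locate its zero.

    Weights are ``gamma^lag``.  A negative crossing is clamped to 0; a
    non-negative slope (unbounded crossing) is capped at the largest lag
    and flagged.
    """
    lags = np.asarray(config.lags, dtype=float)
    corrs = np.asarray(correlations, dtype=float)
    ok = np.isfinite(corrs)
    if ok.sum() < 3:
        raise InsufficientDataError("need >= 3 defined lagged correlations")
    w = config.gamma ** lags[ok]
    # np.polyfit weights multiply residuals, so pass sqrt of the WLS weights
    slope, intercept = np.polyfit(lags[ok], corrs[ok], 1, w=np.sqrt(w))
    flagged = False
    if slope >= 0:
        # no decaying trend: the crossing is unbounded.  A non-positive
        # intercept means the line never rises above zero (no measurable
        # integration -> 0); a positive one is capped at the largest lag.
        raw = 0.0 if intercept <= 0 else float(lags.max())
        flagged = True
    else:
        raw = -intercept / slope
        if raw < 0:
            raw = 0.0
            flagged = True
        elif raw > lags.max():
            raw = float(lags.max())
            flagged = True
    return LmitResult(
        correlations=corrs,
        lags=config.lags,
        slope=float(slope),
        intercept=float(intercept),
        raw_lag=float(raw),
        mean_session_length=float(mean_session_length),
        lmit_trials=float(raw * mean_session_length),
        flagged=flagged,
    )


def n_windows(n_sessions: int, config: LmitConfig = LmitConfig()) -> int:
    """Number of sliding window positions a series of sessions supports."""
    return max(
        0,
        n_sessions - config.exclude_first - config.window - max(config.lags) + 1,
    )


def lmit_series(
    summaries: pd.DataFrame,
    config: LmitConfig = LmitConfig(),
) -> pd.DataFrame:
    """Sliding-window LMIT trajectory over a per-session summary table.

    ``summaries`` must carry columns ``color_choice_bias``,
    ``color_reward_imbalance`` and ``n_trials`` in session order.  The
    first ``exclude_first`` sessions are excluded (training transients);
    windows then advance one session at a time.  Returns one row per
    window with the raw lag, LMIT in trials, the window's last session
    index, and a ``lmit_ma`` moving-average column for display.
    """
    required = {"color_choice_bias", "color_reward_imbalance", "n_trials"}
    if not required <= set(summaries.columns):
        raise InsufficientDataError(f"summary table needs columns {required}")
    bias = summaries["color_choice_bias"].to_numpy(dtype=float)
    imb = summaries["color_reward_imbalance"].to_numpy(dtype=float)
    ntr = summaries["n_trials"].to_numpy(dtype=float)
    n = len(bias)
    first = config.exclude_first + max(config.lags)
    if n_windows(n, config) < 1:
        raise InsufficientDataError(
            f"{n} sessions support no window (need "
            f">= {config.exclude_first + config.window + max(config.lags)})"
        )
    rows = []
    for start in range(first, n - config.window + 1):
        corrs = lagged_correlations(
            bias, imb, start, config.window, config.lags
        )
        msl = float(np.mean(ntr[start : start + config.window]))
        try:
            res = estimate_lmit(corrs, msl, config)
        except InsufficientDataError:
            continue
        rows.append(
            {
                "window_start": start,
                "window_end": start + config.window - 1,
                "raw_lag": res.raw_lag,
                "lmit_trials": res.lmit_trials,
                "mean_session_length": msl,
                "flagged": res.flagged,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["lmit_ma"] = (
            out["lmit_trials"].rolling(config.ma_windows, min_periods=1).mean()
        )
    return out


def block_permutation_indices(
    n: int, block: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Index matrix (n_perm, n) of block-shuffled session orders.

    ``n`` must be a multiple of ``block``.  Blocks of consecutive indices
    are reordered; the order within each block is never perturbed.
    """
    if n % block:
        raise ValueError("n must be a multiple of the block size")
    n_blocks = n // block
    base = np.arange(n).reshape(n_blocks, block)
    perms = np.array([rng.permutation(n_blocks) for _ in range(n_perm)])
    return base[perms].reshape(n_perm, n)


def piecewise_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    block: int = 5,
    n_perm: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided block permutation test of the Pearson correlation.

    Blocks of ``block`` consecutive sessions of ``x`` are shuffled without
    perturbing the order within blocks, preserving short-timescale
    structure under the null.  Returns ``(r_observed, p_value)`` with the
    add-one estimator ``p = (1 + #{|r*| >= |r|}) / (n_perm + 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    n = len(x) - len(x) % block  # trim the ragged tail
    if n < 2 * block:
        raise InsufficientDataError("need at least two full blocks")
    x, y = x[:n], y[:n]
    if np.std(x) == 0 or np.std(y) == 0:
        raise InsufficientDataError("degenerate (constant) series")
    if rng is None:
        rng = np.random.default_rng(0)
    r_obs = float(stats.pearsonr(x, y)[0])

    ys = (y - y.mean()) / y.std()
    idx = block_permutation_indices(n, block, n_perm, rng)
    xp = x[idx]  # blocks reordered, order within each block kept
    xp = (xp - xp.mean(axis=1, keepdims=True)) / xp.std(axis=1, keepdims=True)
    r_perm = xp @ ys / n
    p = (1.0 + np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12)) / (n_perm + 1.0)
    return r_obs, float(p)


def covariate_correlations(
    lmit_df: pd.DataFrame,
    summaries: pd.DataFrame,
    past_days: int = 12,
    block: int = 5,
    n_perm: int = 2000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Correlate the LMIT trajectory with recent schedule covariates.

    For each LMIT window (keyed by its last session) the mean experimental
    day length (trials completed per day) and the mean break length are
    averaged over the ``past_days`` most recent experimental days.
    Returns the two Pearson correlations with block-permutation p-values;
    a covariate with zero variance yields NaN and is reported as such.
    """
    if not {"day", "break_before", "n_trials"} <= set(summaries.columns):
        raise InsufficientDataError("summaries need day/break_before/n_trials")
    per_day = summaries.groupby("day").agg(
        day_length=("n_trials", "sum"), break_before=("break_before", "max")
    )
    days = per_day.index.to_numpy()
    day_of_session = summaries["day"].to_numpy()

    rows = []
    for _, r in lmit_df.iterrows():
        end_day = day_of_session[int(r["window_end"])]
        recent = days[days <= end_day][-past_days:]
        rows.append(
            {
                "lmit_trials": r["lmit_trials"],
                "mean_day_length": float(per_day.loc[recent, "day_length"].mean()),
                "mean_break_length": float(
                    per_day.loc[recent, "break_before"].mean()
                ),
            }
        )
    tbl = pd.DataFrame(rows)
    out: dict = {"table": tbl}
    for key in ("mean_day_length", "mean_break_length"):
        x = tbl[key].to_numpy()
        y = tbl["lmit_trials"].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            out[key] = {"correlation": np.nan, "p_value": np.nan}
            continue
        try:
            r, p = piecewise_permutation_test(
                x, y, block=block, n_perm=n_perm, rng=rng
            )
            out[key] = {"correlation": r, "p_value": p}
        except InsufficientDataError:
            out[key] = {"correlation": np.nan, "p_value": np.nan}
    return out
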