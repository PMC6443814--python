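"""Canonical study protocols, each a self-contained seeded experiment.

Every function here regenerates its own synthetic data from a seed and
returns the summary quantities of one analysis: the slow- and fast-limit
choice statistics, the bias-variance curves, the harvesting-efficiency
sweep, the weight-recovery and confound studies, the LMIT-vs-weight
calibration, the permutation-test calibration, and the cascade
consolidation run.  The test suite and the acceptance script both drive
these protocols, so the problem sizes below are the package's reference
study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import lmit as lmit_mod
from . import metrics
from .agents import BiasAgentParams, MultiTimescaleAgent, RandomBiasAgent
from .bias_variance import EstimationTask, matching_slope_vs_weight, sweep_weights
from .cascade import CascadeParams, run_cascade_experiment
from .fitting import FitConfig, fit_dataset, fit_session
from .schedule import (
    DatasetConfig,
    ScheduleConfig,
    generate_dataset,
    generate_schedule,
    run_session,
)


def batch_se(series: np.ndarray, n_batches: int = 20) -> float:
    """Batch-means standard error of the mean of an autocorrelated series."""
    n = len(series) // n_batches * n_batches
    means = np.asarray(series[:n], dtype=float).reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def slow_limit_mean_choice_probability(
    seed: int,
    n_trials: int = 100_000,
    burn_in: int = 20_000,
    tau_slow: float = 10_000.0,
    n_replicates: int = 6,
) -> dict:
    """Mean P(green) of a purely slow-integrating agent on long schedules.

    With the slow weight at 1 and tau much longer than the block length,
    incomes equalize over blocks and the model's choice probability pins
    near 0.5 regardless of the current reward ratio.  Because P fluctuates
    with a correlation time of order tau, the Monte-Carlo SE is taken
    across independent replicate simulations rather than within one run.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_replicates) % (2**31)
    means = []
    n = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        n_blocks = int(np.ceil(n_trials / 100))
        schedule = generate_schedule(
            ScheduleConfig(n_blocks=n_blocks, block_length_range=(100, 200)), rng
        )
        agent = MultiTimescaleAgent.from_weights((5.0, tau_slow), (0.0, 1.0))
        sess = run_session(agent, schedule, rng)
        p = sess.p_green[burn_in:n_trials]
        means.append(float(p.mean()))
        n += len(p)
    means = np.asarray(means)
    return {
        "mean_p_green": float(means.mean()),
        "se": float(means.std(ddof=1) / np.sqrt(n_replicates)),
        "replicate_means": means,
        "n": int(n),
    }


def fast_limit_matching_slope(
    seed: int,
    n_blocks: int = 500,
    block_length: int = 150,
    tau_fast: float = 5.0,
    last_n: int = 50,
) -> dict:
    """Block-wise matching slope of a purely fast-integrating agent.

    The fast agent tracks local reward fractions, so the OLS slope of
    block choice fraction on block reward fraction approaches the matching
    law's unit slope.
    """
    rng = np.random.default_rng(seed)
    schedule = generate_schedule(
        ScheduleConfig(
            n_blocks=n_blocks, block_length_range=(block_length, block_length)
        ),
        rng,
    )
    agent = MultiTimescaleAgent.from_weights((tau_fast, 10_000.0), (1.0, 0.0))
    sess = run_session(agent, schedule, rng)
    fit = metrics.fit_matching(metrics.block_summaries(sess, last_n=last_n))
    return {"slope": fit.slope, "n_blocks": fit.n_blocks}


def bias_variance_curves(
    block_lengths: tuple[int, int] = (100, 10_000),
    tau_fast: float = 2.0,
    tau_slow: float = 1000.0,
    grid_points: int = 51,
) -> dict:
    """Exact bias-variance curves for a volatile and a stable environment."""
    out = {}
    grid = np.linspace(0.0, 1.0, grid_points)
    for length in block_lengths:
        *_, curve = sweep_weights(
            EstimationTask(block_length=length), tau_fast, tau_slow, grid
        )
        out[length] = curve
    return out


def efficiency_sweep(
    seed: int,
    grid_points: int = 15,
    n_blocks: int = 300,
    tau_fast: float = 2.0,
    tau_slow: float = 1000.0,
) -> pd.DataFrame:
    """Harvesting-efficiency sweep over the slow weight on matched seeds."""
    grid = np.linspace(0.0, 1.0, grid_points)
    return matching_slope_vs_weight(
        ScheduleConfig(n_blocks=n_blocks),
        grid,
        seed=seed,
        tau_fast=tau_fast,
        tau_slow=tau_slow,
    )


def recovery_study(
    seed: int,
    w_slow: float = 0.4,
    n_seeds: int = 20,
    n_blocks: int = 34,
    block_length: int = 150,
) -> dict:
    """Per-session MLE recovery of a known generating slow weight.

    Simulates ``n_seeds`` independent ~5000-trial sessions from a three-
    timescale agent and refits each; reports the recovered slow weights
    and the median absolute error.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_seeds) % (2**31)
    taus = (2.0, 20.0, 1000.0)
    w = ((1.0 - w_slow) * 0.6, (1.0 - w_slow) * 0.4, w_slow)
    recovered = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        schedule = generate_schedule(
            ScheduleConfig(
                n_blocks=n_blocks, block_length_range=(block_length, block_length)
            ),
            rng,
        )
        agent = MultiTimescaleAgent.from_weights(taus, w)
        sess = run_session(agent, schedule, rng)
        res = fit_session(sess, FitConfig(taus=taus, n_restarts=3), rng=rng)
        recovered.append(res.w_slow)
    recovered = np.asarray(recovered)
    return {
        "w_true": w_slow,
        "recovered": recovered,
        "median_error": float(np.median(np.abs(recovered - w_slow))),
        "median_recovered": float(np.median(recovered)),
    }


def confound_study(
    seed: int,
    n_sessions: int = 60,
    bias_max: float = 0.15,
    n_perm: int = 2000,
) -> dict:
    """Fit the integrator model to data generated by the random-bias model.

    Sessions are generated by a fast-only agent whose additive color
    biases are redrawn every session (no slow reward integration at all);
    per-session fits with the multi-timescale model nevertheless produce a
    fitted-w_slow ~ undermatching correlation, reproducing the
    non-identifiability of slow integration at the session level.
    """
    rng = np.random.default_rng(seed)
    dcfg = DatasetConfig(
        schedule=ScheduleConfig(n_blocks=8, block_length_range=(120, 180)),
        n_days=n_sessions // 3,
        sessions_per_day=3,
        carry_slow_income=False,
    )
    biases = rng.uniform(0.0, bias_max, size=(dcfg.n_sessions, 2))

    def factory(s: int) -> RandomBiasAgent:
        return RandomBiasAgent(
            BiasAgentParams(tau=5.0, b_g=biases[s, 0], b_r=biases[s, 1])
        )

    sessions = generate_dataset(dcfg, factory, rng)
    dfit = fit_dataset(
        sessions, FitConfig(n_restarts=3, seed=seed), n_perm=n_perm
    )
    return {
        "correlation": dfit.correlation,
        "p_value": dfit.p_value,
        "table": dfit.table,
        "n_sessions": len(sessions),
    }


@dataclass
class LmitCalibration:
    """LMIT-vs-weight calibration summary."""

    weights: np.ndarray
    lmit_trials: np.ndarray  # from replicate-averaged correlation profiles
    mean_profiles: np.ndarray  # (n_weights, n_lags)
    per_dataset: pd.DataFrame  # columns: w_slow, replicate, lmit_trials
    spearman_rho: float
    spearman_p: float


def lmit_weight_calibration(
    seed: int,
    weights: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7),
    n_replicates: int = 50,
    n_sessions: int = 60,
    tau_slow: float = 400.0,
    burn_in_sessions: int = 5,
) -> LmitCalibration:
    """How the measured LMIT grows with the generating slow weight.

    For each weight, ``n_replicates`` multi-session datasets are simulated
    (sessions of ~500 trials; the slow integrator carries over between
    sessions).  Lagged correlations between per-session color choice bias
    and color reward imbalance are averaged over windows and replicates,
    and the LMIT is read off the averaged profile -- the noise-robust
    estimator; per-dataset LMITs are also returned, and their increase
    with the weight is summarized by a Spearman rank correlation.
    """
    cfg = lmit_mod.LmitConfig(exclude_first=burn_in_sessions)
    ss = np.random.SeedSequence(seed)
    all_seeds = ss.generate_state(len(weights) * n_replicates) % (2**31)
    profiles = np.empty((len(weights), n_replicates, len(cfg.lags)))
    msls = np.empty((len(weights), n_replicates))
    rows = []
    for iw, w in enumerate(weights):
        for r in range(n_replicates):
            rng = np.random.default_rng(int(all_seeds[iw * n_replicates + r]))
            dcfg = DatasetConfig(
                schedule=ScheduleConfig(n_blocks=5, block_length_range=(90, 110)),
                n_days=n_sessions,
                sessions_per_day=1,
                carry_slow_income=True,
            )
            sessions = generate_dataset(
                dcfg,
                lambda s: MultiTimescaleAgent.from_weights(
                    (5.0, tau_slow), (1.0 - w, w)
                ),
                rng,
            )
            summ = metrics.summarize_dataset(sessions, last_n=None)
            bias = summ["color_choice_bias"].to_numpy(float)
            imb = summ["color_reward_imbalance"].to_numpy(float)
            profs = [
                lmit_mod.lagged_correlations(
                    bias, imb, start, cfg.window, cfg.lags
                )
                for start in range(
                    burn_in_sessions + max(cfg.lags),
                    len(bias) - cfg.window + 1,
                )
            ]
            profiles[iw, r] = np.nanmean(profs, axis=0)
            msls[iw, r] = float(summ["n_trials"].mean())
            res = lmit_mod.estimate_lmit(profiles[iw, r], msls[iw, r], cfg)
            rows.append(
                {"w_slow": w, "replicate": r, "lmit_trials": res.lmit_trials}
            )
    mean_profiles = profiles.mean(axis=1)
    lmit_trials = np.array(
        [
            lmit_mod.estimate_lmit(
                mean_profiles[iw], msls[iw].mean(), cfg
            ).lmit_trials
            for iw in range(len(weights))
        ]
    )
    per_dataset = pd.DataFrame(rows)
    rho, p = stats.spearmanr(per_dataset["w_slow"], per_dataset["lmit_trials"])
    return LmitCalibration(
        weights=np.asarray(weights),
        lmit_trials=lmit_trials,
        mean_profiles=mean_profiles,
        per_dataset=per_dataset,
        spearman_rho=float(rho),
        spearman_p=float(p),
    )


def permutation_test_calibration(
    seed: int,
    n_replicates: int = 1000,
    n_sessions: int = 60,
    block: int = 5,
    n_perm: int = 200,
    block_effect: float = 1.0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the block permutation test on a block-structured null.

    Generates independent pairs of session series whose dependence lives
    inside blocks of ``block`` consecutive sessions (a shared block-level
    random effect of SD ``block_effect`` plus unit white noise) and which
    are independent across blocks -- the exchangeability structure the
    block shuffle preserves -- and measures how often the test rejects at
    level ``alpha``.
    """
    rng = np.random.default_rng(seed)
    n_blocks = n_sessions // block
    rejections = 0
    for _ in range(n_replicates):
        levels = rng.standard_normal((2, n_blocks)) * block_effect
        series = np.repeat(levels, block, axis=1)
        series += rng.standard_normal(series.shape)
        _, p = lmit_mod.piecewise_permutation_test(
            series[0], series[1], block=block, n_perm=n_perm, rng=rng
        )
        rejections += p <= alpha
    rate = rejections / n_replicates
    se = float(np.sqrt(alpha * (1 - alpha) / n_replicates))
    return {"type_i_rate": float(rate), "se": se, "n": n_replicates}


def cascade_consolidation_study(
    seed: int,
    n_days: int = 40,
    sessions_per_day: int = 2,
    params: CascadeParams | None = None,
) -> dict:
    """Multi-day cascade run: undermatching growth and the behavior tradeoff.

    A naive (uniformly distributed) metaplastic network practices the task
    for ``n_days`` with unit breaks between days.  Consolidation slows the
    effective learning rate, so undermatching grows from the early to the
    late quarter of sessions while the variance of choice falls.
    """
    rng = np.random.default_rng(seed)
    dcfg = DatasetConfig(
        schedule=ScheduleConfig(n_blocks=6, block_length_range=(100, 150)),
        n_days=n_days,
        sessions_per_day=sessions_per_day,
        break_lengths=[0.0] + [1.0] * (n_days - 1),
    )
    sessions = run_cascade_experiment(dcfg, params or CascadeParams(), rng)
    summ = metrics.summarize_dataset(sessions)
    um = summ["undermatching"].to_numpy(float)
    sv = summ["sqrt_variance"].to_numpy(float)
    ok = np.isfinite(um) & np.isfinite(sv)
    r = float(stats.pearsonr(um[ok], sv[ok])[0])
    q = len(um) // 4
    return {
        "summaries": summ,
        "undermatching_early": float(np.nanmean(um[:q])),
        "undermatching_late": float(np.nanmean(um[-q:])),
        "tradeoff_correlation": r,
        "learning_rates": [
            s.meta["effective_learning_rate"] for s in sessions
        ],
    }
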