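"""Session statistics: matching fits, efficiency, choice variance."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_session
from dynforage import metrics
from dynforage.agents import FixedProbabilityAgent, MultiTimescaleAgent
from dynforage.metrics import (
    BlockSummary,
    InsufficientDataError,
    block_summaries,
    color_reward_imbalance,
    fit_matching,
    half_gaussian_kernel,
    harvesting_efficiency,
    summarize_dataset,
    variance_of_choice,
)
from dynforage.pipeline import make_weight_drift
from dynforage.schedule import (
    DatasetConfig,
    ScheduleConfig,
    generate_dataset,
    generate_schedule,
    run_session,
)


def test_block_summary_fractions():
    # 40 G / 10 R free choices; 8 G / 2 R rewards -> (0.8, 0.8)
    choices = [1] * 40 + [0] * 10
    rewards = [1] * 8 + [0] * 32 + [1] * 2 + [0] * 8
    sess = make_session(choices, rewards)
    (b,) = block_summaries(sess)
    assert b.choice_fraction == pytest.approx(0.8)
    assert b.reward_fraction == pytest.approx(0.8)
    assert b.n_free_choices == 50 and b.n_rewards == 10


def test_zero_reward_block_excluded():
    sess = make_session([1] * 10 + [0] * 10, [0] * 20, block_id=[0] * 10 + [1] * 10)
    assert block_summaries(sess) == []


def test_last_n_restricts_to_block_tail():
    choices = [0] * 100 + [1] * 50
    rewards = [1] + [0] * 99 + [1] * 5 + [0] * 45
    sess = make_session(choices, rewards)
    (b,) = block_summaries(sess, last_n=50)
    assert b.choice_fraction == 1.0 and b.n_free_choices == 50
    assert b.n_rewards == 5  # the reward at trial 0 is outside the tail


def _blocks(xy):
    return [
        BlockSummary(i, y, x, n_free_choices=50, n_rewards=20)
        for i, (x, y) in enumerate(xy)
    ]


def test_fit_matching_diagonal():
    fit = fit_matching(_blocks([(0.1, 0.1), (0.5, 0.5), (0.9, 0.9)]))
    assert fit.slope == pytest.approx(1.0)
    assert fit.undermatching == pytest.approx(0.0, abs=1e-12)
    assert fit.color_choice_bias == pytest.approx(0.0, abs=1e-12)


def test_fit_matching_flat():
    fit = fit_matching(_blocks([(0.1, 0.5), (0.5, 0.5), (0.9, 0.5)]))
    assert fit.slope == pytest.approx(0.0)
    assert fit.undermatching == pytest.approx(1.0)


def test_fit_matching_recovers_noisy_line(rng):
    x = np.tile(np.linspace(0.1, 0.9, 9), 20)
    y = 0.8 * x + 0.1 + rng.normal(0, 0.03, len(x))
    fit = fit_matching(_blocks(zip(x, y)))
    oracle = stats.linregress(x, y)  # independent fit of the same points
    assert fit.slope == pytest.approx(oracle.slope, abs=1e-12)
    assert abs(fit.slope - 0.8) < 0.03


def test_fit_matching_guards():
    with pytest.raises(InsufficientDataError):
        fit_matching(_blocks([(0.2, 0.2), (0.8, 0.8)]))
    with pytest.raises(InsufficientDataError):
        fit_matching(_blocks([(0.5, 0.2), (0.5, 0.6), (0.5, 0.9)]))
    # low-reward blocks are dropped before fitting
    blocks = _blocks([(0.1, 0.1), (0.5, 0.5), (0.9, 0.9)])
    blocks.append(BlockSummary(9, 1.0, 0.0, 10, 1))
    assert fit_matching(blocks, min_rewards=5).n_blocks == 3


def test_fit_matching_color_relabel_symmetry():
    pts = [(0.2, 0.25), (0.5, 0.6), (0.8, 0.75), (0.3, 0.4)]
    fit = fit_matching(_blocks(pts))
    flipped = fit_matching(_blocks([(1 - x, 1 - y) for x, y in pts]))
    assert flipped.slope == pytest.approx(fit.slope)
    assert flipped.color_choice_bias == pytest.approx(-fit.color_choice_bias)


def test_shift_changes_bias_not_slope():
    pts = [(0.2, 0.25), (0.5, 0.6), (0.8, 0.75)]
    fit = fit_matching(_blocks(pts))
    shifted = fit_matching(_blocks([(x, y + 0.05) for x, y in pts]))
    assert shifted.slope == pytest.approx(fit.slope)
    assert shifted.color_choice_bias == pytest.approx(fit.color_choice_bias + 0.05)


def test_efficiency_zero_for_never_collecting(rng):
    sch = generate_schedule(ScheduleConfig(n_blocks=3, cod_enabled=False), rng)

    class Refuser:  # always picks green; schedule only baits red
        def choice_prob(self):
            return 1.0

        def update(self, c, r):
            pass

    sch.p_target[:, 1] = 0.0  # green never baited
    sch.p_target[:, 0] = 0.35
    sess = run_session(Refuser(), sch, rng)
    assert harvesting_efficiency(sess) == 0.0


def test_efficiency_omniscient_near_one_and_maximal(rng):
    """An agent that always takes a baited target collects nearly the
    oracle maximum, and beats ordinary agents on the same draws."""
    from dynforage.schedule import EnvState, GREEN, RED, SessionData, step_environment

    cfg = ScheduleConfig(n_blocks=30, cod_enabled=False)
    sch = generate_schedule(cfg, rng)
    draws = np.random.default_rng(5).random((sch.n_trials, 2))
    state = EnvState()
    rewards = []
    for t in range(sch.n_trials):
        choice = GREEN if state.baited[GREEN] else RED
        rewards.append(
            step_environment(sch, t, choice, state, rng, bait_draws=draws[t])
        )
    oracle = int((draws < sch.p_target).sum())
    sess = SessionData(
        choice=np.zeros(sch.n_trials, np.int8),
        reward=np.array(rewards, np.int8),
        free_choice=np.ones(sch.n_trials, bool),
        block_id=sch.block_id,
        meta={"n_baits_oracle": oracle},
    )
    eff = harvesting_efficiency(sess)
    # simultaneous baits delay re-baiting, so even the omniscient
    # harvester falls ~10% short of the always-empty oracle
    assert 0.85 <= eff <= 1.0


def test_efficiency_fallback_denominator():
    sess = make_session([1] * 100, [1] * 35 + [0] * 65, meta={"total_bait_rate": 0.35})
    assert harvesting_efficiency(sess) == pytest.approx(1.0)


def test_mixed_weight_efficiency_beats_extremes():
    """Inverted-U: the mixed agent out-harvests both pure strategies on
    matched randomness."""
    effs = {}
    for w in (0.0, 0.3, 1.0):
        rng = np.random.default_rng(21)
        sch = generate_schedule(ScheduleConfig(n_blocks=120), rng)
        agent = MultiTimescaleAgent.from_weights((5, 10_000), (1 - w, w))
        effs[w] = harvesting_efficiency(run_session(agent, sch, rng))
    assert effs[0.3] >= effs[0.0] and effs[0.3] >= effs[1.0]


def test_variance_of_choice_constant_series():
    sess = make_session([1] * 300, [0] * 300)
    assert variance_of_choice(sess).variance == pytest.approx(0.0, abs=1e-20)


def test_variance_of_choice_matches_bruteforce():
    rng = np.random.default_rng(3)
    choices = (rng.random(400) < 0.5).astype(int)
    sess = make_session(choices, [0] * 400)
    got = variance_of_choice(sess).variance
    # independent brute-force: loop over trials, weight past choices
    kf = half_gaussian_kernel(8.0, 200)
    ks = half_gaussian_kernel(50.0, 200)
    diffs = []
    for t in range(199, 400):
        past = choices[t - 199 : t + 1][::-1]
        diffs.append((kf @ past - ks @ past) ** 2)
    assert got == pytest.approx(np.mean(diffs), abs=1e-12)


def test_variance_of_choice_alternation_small():
    sess = make_session([0, 1] * 200, [0] * 400)
    v = variance_of_choice(sess)
    assert 0 < v.variance < 1e-3  # both kernels average to ~0.5


def test_variance_requires_span(rng):
    sess = make_session([0, 1] * 50, [0] * 100)
    with pytest.raises(InsufficientDataError):
        variance_of_choice(sess)


def test_slow_agent_has_lower_choice_variance():
    vs = {}
    for w in (0.1, 0.9):
        rng = np.random.default_rng(17)
        sch = generate_schedule(ScheduleConfig(n_blocks=30), rng)
        agent = MultiTimescaleAgent.from_weights((5, 10_000), (1 - w, w))
        vs[w] = variance_of_choice(run_session(agent, sch, rng)).variance
    assert vs[0.9] < vs[0.1]


def test_color_reward_imbalance():
    sess = make_session([1] * 30 + [0] * 170, [1] * 30 + [1] * 10 + [0] * 160)
    assert color_reward_imbalance(sess) == pytest.approx(0.1)  # (30-10)/200
    balanced = make_session([1, 0], [1, 1])
    assert color_reward_imbalance(balanced) == 0.0
    with pytest.raises(InsufficientDataError):
        color_reward_imbalance([])


def test_imbalance_symmetric_agent_near_zero(rng):
    sch = generate_schedule(ScheduleConfig(ratio_set=((1, 1),), n_blocks=60), rng)
    sess = run_session(FixedProbabilityAgent(0.5), sch, rng)
    se = np.sqrt(0.35 / sess.n_trials)
    assert abs(color_reward_imbalance(sess)) < 3 * se


def test_drift_dataset_tradeoff_directions():
    """On a drifting-slow-weight dataset, undermatching rises while the
    variance of choice falls (and efficiency tracks the variance)."""
    rng = np.random.default_rng(6)
    dcfg = DatasetConfig(
        schedule=ScheduleConfig(n_blocks=8, block_length_range=(120, 160)),
        n_days=30,
        sessions_per_day=2,
        carry_slow_income=True,
    )
    ws = np.linspace(0.02, 0.45, dcfg.n_sessions)
    dcfg.weight_drift = make_weight_drift([0.9, 0.1], ws)
    sessions = generate_dataset(
        dcfg, lambda s: MultiTimescaleAgent.from_weights((2, 1000), (0.9, 0.1)), rng
    )
    d = summarize_dataset(sessions, last_n=None).dropna(
        subset=["undermatching", "sqrt_variance", "harvesting_efficiency"]
    )
    assert stats.pearsonr(d.undermatching, d.sqrt_variance)[0] < -0.3
    assert stats.pearsonr(d.harvesting_efficiency, d.sqrt_variance)[0] < 0
    k = len(d) // 3
    assert d.undermatching.iloc[-k:].mean() > d.undermatching.iloc[:k].mean()


def test_summarize_dataset_handles_degenerate_sessions():
    good = make_session(
        [1] * 150 + [0] * 150,
        ([1] * 20 + [0] * 130) * 2,
        block_id=[0] * 100 + [1] * 100 + [2] * 100,
    )
    tiny = make_session([1, 0], [0, 0])
    table = summarize_dataset([good, tiny], last_n=None, span=100)
    assert len(table) == 2
    assert np.isnan(table.loc[1, "slope"])
    assert np.isnan(table.loc[1, "sqrt_variance"])
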