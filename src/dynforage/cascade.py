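"""Decision network with cascade-model metaplastic synapses.

Two plastic pathways (input -> choose-green and input -> choose-red) carry
populations of bounded binary-strength synapses.  Each synapse occupies one
of ``2 m`` states: strength (depressed or potentiated) crossed with an
ordered plasticity level; transition probabilities fall geometrically with
depth (alpha_i = x^i, q_i = x^i), so deeper states are harder to enter and
harder to leave.  Reward-gated plasticity on the chosen pathway potentiates
or depresses via the most-plastic level and consolidates same-strength
states downward; between experimental days a forgetting process flips
strengths back into the plastic top level, re-sensitizing the network.

Consolidation slows the effective learning rate, lengthening the network's
reward-integration timescale; the model therefore develops undermatching
over days of practice and recovers plasticity after long breaks.  The
default engine propagates occupancy fractions (mean field); a stochastic
per-synapse engine is available for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import (
    GREEN,
    RED,
    DatasetConfig,
    SessionData,
    generate_schedule,
    run_session,
)


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class CascadeParams:
    """Cascade-synapse network parameters.

    ``x`` sets the geometric ladder: plasticity rates alpha_i = x^i for
    levels i = 1..m and metaplastic (consolidation) rates
    q_i = q_scale * x^(i-1) for i = 1..m-1; both are strictly ordered
    (alpha_1 >> alpha_2 >> ..., q_1 >> q_2 >> ...).  ``q_scale`` sets how
    strongly consolidation pushes mass below the uniform day-1
    distribution: with q_scale above x the learning equilibrium is
    deep-heavy, so practice slowly consolidates the network and the
    effective learning rate falls over days.  ``temperature`` scales the
    logistic readout of the mean-strength difference; ``forgetting_rate``
    multiplies the per-break-unit flip probability (rate * alpha_i at
    level i).
    """

    n_levels: int = 8
    x: float = 0.35
    q_scale: float = 0.15
    temperature: float = 0.02
    forgetting_rate: float = 1.0
    n_synapses: int = 2000  # stochastic engine only

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ParameterError("need at least one plasticity level")
        if not 0.0 < self.x <= 1.0:
            raise ParameterError("x must be in (0, 1]")
        if not 0.0 < self.q_scale <= 1.0:
            raise ParameterError("q_scale must be in (0, 1]")
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")
        if self.forgetting_rate < 0:
            raise ParameterError("forgetting_rate must be >= 0")

    @property
    def alphas(self) -> np.ndarray:
        return self.x ** np.arange(1, self.n_levels + 1)

    @property
    def qs(self) -> np.ndarray:
        return self.q_scale * self.x ** np.arange(0, self.n_levels - 1)


def uniform_population(n_levels: int) -> np.ndarray:
    """Occupancies spread uniformly over the 2*m states (naive day-1 state)."""
    return np.full((2, n_levels), 1.0 / (2 * n_levels))


def mean_strength(pop: np.ndarray) -> float:
    """Fraction of synapses potentiated (row 1 holds potentiated levels)."""
    return float(pop[1].sum())


def readout_probability(
    pop_g: np.ndarray, pop_r: np.ndarray, temperature: float
) -> float:
    """Logistic readout of the pathway mean-strength difference."""
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    d = (mean_strength(pop_g) - mean_strength(pop_r)) / temperature
    return float(1.0 / (1.0 + np.exp(-d)))


def _validate(pop: np.ndarray) -> np.ndarray:
    pop = np.asarray(pop, dtype=float)
    if pop.ndim != 2 or pop.shape[0] != 2:
        raise ParameterError("population must have shape (2, n_levels)")
    if np.any(pop < -1e-12) or abs(pop.sum() - 1.0) > 1e-8:
        raise ParameterError("occupancies must be non-negative and sum to 1")
    return pop


def learn_step(
    pop: np.ndarray, potentiate: bool, params: CascadeParams
) -> np.ndarray:
    """One reward-gated mean-field plasticity step on a single pathway.

    ``potentiate=True`` (chosen and rewarded): depressed level-i mass moves
    to the most plastic potentiated state with probability alpha_i, and
    potentiated mass consolidates one level deeper with probability q_i.
    ``potentiate=False`` is the mirror image (depression + consolidation of
    depressed states).
    """
    pop = _validate(pop)
    a, q = params.alphas, params.qs
    new = pop.copy()
    src, dst = (0, 1) if potentiate else (1, 0)
    flip = pop[src] * a
    new[src] -= flip
    new[dst, 0] += flip.sum()
    deepen = pop[dst, :-1] * q if params.n_levels > 1 else np.empty(0)
    new[dst, :-1] -= deepen
    new[dst, 1:] += deepen
    return new


def forgetting_matrix(params: CascadeParams) -> np.ndarray:
    """One-break-unit transition matrix over the 2*m states.

    State order: depressed levels 1..m then potentiated levels 1..m.  Each
    state flips to the opposite strength's most plastic level with
    probability ``forgetting_rate * alpha_i`` (capped at 1).
    """
    m = params.n_levels
    flip = np.minimum(1.0, params.forgetting_rate * params.alphas)
    t = np.zeros((2 * m, 2 * m))
    for s in range(2):
        for i in range(m):
            j = s * m + i
            opp0 = (1 - s) * m
            t[j, j] += 1.0 - flip[i]
            t[j, opp0] += flip[i]
    return t


def forget_step(
    pop: np.ndarray, break_length: float, params: CascadeParams
) -> np.ndarray:
    """Apply ``int(break_length)`` rounds of inter-session forgetting."""
    pop = _validate(pop)
    rounds = int(break_length)
    if rounds <= 0:
        return pop.copy()
    m = params.n_levels
    t = np.linalg.matrix_power(forgetting_matrix(params), rounds)
    flat = pop.reshape(2 * m) @ t
    return flat.reshape(2, m)


def forgetting_stationary(params: CascadeParams) -> np.ndarray:
    """Stationary occupancy of the forgetting chain (eigen-analysis)."""
    t = forgetting_matrix(params)
    vals, vecs = np.linalg.eig(t.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v) / np.abs(v).sum()
    return v.reshape(2, params.n_levels)


def stochastic_learn_step(
    counts: np.ndarray,
    potentiate: bool,
    params: CascadeParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-synapse stochastic version of :func:`learn_step` on counts."""
    counts = np.asarray(counts)
    a, q = params.alphas, params.qs
    new = counts.copy()
    src, dst = (0, 1) if potentiate else (1, 0)
    flips = rng.binomial(counts[src], a)
    new[src] -= flips
    new[dst, 0] += flips.sum()
    if params.n_levels > 1:
        deepen = rng.binomial(counts[dst, :-1], q)
        new[dst, :-1] -= deepen
        new[dst, 1:] += deepen
    return new


class CascadeAgent:
    """Choice agent backed by two cascade-synapse populations.

    Exposes the standard ``choice_prob``/``update`` interface so it can run
    on the baiting environment like the integrator agents, plus
    ``forget(break_length)`` for inter-day plasticity recovery.  Plasticity
    follows the chosen pathway only: rewarded choices potentiate it,
    unrewarded choices depress it.
    """

    def __init__(self, params: CascadeParams, pops: np.ndarray | None = None):
        self.params = params
        if pops is None:
            pops = np.stack(
                [uniform_population(params.n_levels) for _ in range(2)]
            )
        self.pops = np.asarray(pops, dtype=float)  # (target, strength, level)

    def choice_prob(self) -> float:
        return readout_probability(
            self.pops[GREEN], self.pops[RED], self.params.temperature
        )

    def update(self, choice: int, reward: int) -> None:
        self.pops[choice] = learn_step(
            self.pops[choice], potentiate=bool(reward), params=self.params
        )

    def forget(self, break_length: float) -> None:
        for tgt in (RED, GREEN):
            self.pops[tgt] = forget_step(
                self.pops[tgt], break_length, self.params
            )

    def effective_learning_rate(self) -> float:
        """Expected change in mean strength per potentiating outcome: a
        shrinking value signals consolidation."""
        out = 0.0
        for tgt in (RED, GREEN):
            before = mean_strength(self.pops[tgt])
            after = mean_strength(
                learn_step(self.pops[tgt], True, self.params)
            )
            out += (after - before) / 2.0
        return out


def run_cascade_experiment(
    dataset_config: DatasetConfig,
    params: CascadeParams,
    rng: np.random.Generator,
) -> list[SessionData]:
    """Simulate the full multi-day protocol with one persistent network.

    Metaplastic states start uniformly distributed (naive network); the
    network learns through every session of a day and forgets across the
    break preceding each day.  Returns sessions consumable by every
    metrics/LMIT routine.
    """
    cfg = dataset_config
    agent = CascadeAgent(params)
    sessions: list[SessionData] = []
    s = 0
    for day in range(cfg.n_days):
        brk = 0.0 if cfg.break_lengths is None else float(cfg.break_lengths[day])
        if day > 0:
            agent.forget(brk)
        for k in range(cfg.sessions_on_day(day)):
            schedule = generate_schedule(cfg.schedule, rng)
            meta = {
                "day": day,
                "session_in_day": k,
                "session": s,
                "break_before": brk if k == 0 else 0.0,
                "effective_learning_rate": agent.effective_learning_rate(),
            }
            sessions.append(run_session(agent, schedule, rng, meta=meta))
            s += 1
    return sessions
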