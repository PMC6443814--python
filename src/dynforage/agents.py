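"""Choice models driven by leaky integration of reward streams.

The core model keeps, for each target, a bank of exponential reward
integrators ("local incomes") with time constants ``tau_i``:

    I[t] = (1 - 1/tau) * I[t-1] + (1/tau) * r[t-1]

where ``r`` is 1 only when that target was chosen *and* rewarded.  The
per-target incomes are combined as a weighted sum (weights on the simplex)
and choices follow the local matching rule

    P(green) = I_G / (I_G + I_R).

A single-timescale agent is the one-integrator special case; the
random-bias agent replaces slow integration with session-constant additive
biases and is used to demonstrate the session-level non-identifiability of
slow reward integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedule import GREEN, RED


class ParameterError(ValueError):
    """Raised for invalid agent parameters."""


def update_income(income: float, reward: float, tau: float) -> float:
    """One convex leaky-integrator step: ``(1-1/tau)*I + (1/tau)*r``."""
    if tau < 1:
        raise ParameterError(f"tau must be >= 1, got {tau}")
    a = 1.0 / tau
    return (1.0 - a) * income + a * reward


def combined_income(incomes, weights) -> float:
    """Weighted sum of one target's per-timescale incomes."""
    incomes = np.asarray(incomes, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if incomes.shape != weights.shape:
        raise ParameterError("incomes and weights must have matching shapes")
    return float(weights @ incomes)


def choice_probability(income_g: float, income_r: float) -> float:
    """Local matching rule ``P_G = I_G / (I_G + I_R)``; 0.5 when both are 0."""
    if income_g < 0 or income_r < 0:
        raise ParameterError("incomes must be non-negative")
    tot = income_g + income_r
    if tot == 0.0:
        return 0.5
    return income_g / tot


def bias_model_probability(
    fast_income_g: float, fast_income_r: float, b_g: float, b_r: float
) -> float:
    """Matching rule with additive session biases:
    ``P_G = (I_G + B_G) / (I_G + I_R + B_G + B_R)``."""
    if min(fast_income_g, fast_income_r, b_g, b_r) < 0:
        raise ParameterError("incomes and biases must be non-negative")
    denom = fast_income_g + fast_income_r + b_g + b_r
    if denom == 0.0:
        return 0.5
    return (fast_income_g + b_g) / denom


def undermatching_approximation(
    w_slow: float, w_fast: float, slow_total_income: float, fast_total_income: float
) -> float:
    """First-order prediction of the matching-slope deficit ``1 - S``.

    In the regime ``w_slow << w_fast`` the slope of the block-wise matching
    regression is attenuated by the factor
    ``(w_slow / w_fast) * (I_tot_slow / I_tot_fast)``, which this function
    returns as the predicted ``1 - slope``.
    """
    if fast_total_income <= 0:
        raise ParameterError("fast total income must be positive")
    if w_fast <= 0:
        raise ParameterError("w_fast must be positive")
    return (w_slow / w_fast) * (slow_total_income / fast_total_income)


def _check_simplex(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-8:
        raise ParameterError(f"weights must lie on the simplex, got {w}")
    return np.clip(w, 0.0, None)


@dataclass
class AgentParams:
    """Time constants, simplex weights and initial incomes of an agent.

    ``lapse`` is a small exploration floor applied to the simulated choice
    probability (clipped to ``[lapse, 1 - lapse]``).  The pure fractional-
    income rule has absorbing boundaries at P = 0 and P = 1 -- once one
    target's income decays to zero it is never sampled again -- and a small
    irreducible lapse rate keeps closed-loop simulations in the matching
    regime, as real subjects are.  It plays no role in likelihoods.
    """

    taus: tuple[float, ...]
    weights: tuple[float, ...]
    initial_income: float = 0.175  # total_bait_rate / 2 per target & timescale
    lapse: float = 0.01

    def __post_init__(self) -> None:
        if any(t < 1 for t in self.taus):
            raise ParameterError("all taus must be >= 1")
        if len(self.taus) != len(self.weights):
            raise ParameterError("taus and weights must have equal length")
        if not 0.0 <= self.lapse < 0.5:
            raise ParameterError("lapse must be in [0, 0.5)")
        _check_simplex(np.asarray(self.weights))


class MultiTimescaleAgent:
    """Agent combining leaky reward integrators on several timescales.

    State is the per-target, per-timescale income matrix
    ``incomes[target, i]`` (targets indexed red=0, green=1).  Incomes start
    at ``initial_income`` (default: half the schedule's total baiting rate,
    an unbiased start at the mean payoff).
    """

    def __init__(self, params: AgentParams):
        self.params = params
        self.taus = np.asarray(params.taus, dtype=float)
        self.weights = np.asarray(params.weights, dtype=float)
        self._alphas = 1.0 / self.taus
        self.lapse = params.lapse
        self.incomes = np.full((2, len(self.taus)), params.initial_income)

    @classmethod
    def from_weights(
        cls, taus, weights, initial_income: float = 0.175, lapse: float = 0.01
    ) -> "MultiTimescaleAgent":
        return cls(AgentParams(tuple(taus), tuple(weights), initial_income, lapse))

    def choice_prob(self) -> float:
        w = _check_simplex(self.weights)
        i_g = float(w @ self.incomes[GREEN])
        i_r = float(w @ self.incomes[RED])
        p = choice_probability(i_g, i_r)
        return min(max(p, self.lapse), 1.0 - self.lapse)

    def act(self, rng: np.random.Generator) -> int:
        return GREEN if rng.random() < self.choice_prob() else RED

    def update(self, choice: int, reward: int) -> None:
        # the update applies to BOTH targets every trial: r = reward only
        # for the rewarded chosen target, 0 otherwise (unchosen incomes decay)
        r = np.zeros(2)
        r[choice] = reward
        self.incomes *= 1.0 - self._alphas
        self.incomes += self._alphas * r[:, None]

    # --- slow-income carryover hooks (used by dataset generation) ---
    def slow_income(self) -> np.ndarray:
        """Incomes of the slowest integrator, per target."""
        i = int(np.argmax(self.taus))
        return self.incomes[:, i].copy()

    def set_slow_income(self, values: np.ndarray) -> None:
        i = int(np.argmax(self.taus))
        self.incomes[:, i] = np.asarray(values, dtype=float)


class SingleTimescaleAgent(MultiTimescaleAgent):
    """One-integrator reduction (the classic local matching model)."""

    def __init__(
        self, tau: float, initial_income: float = 0.175, lapse: float = 0.01
    ):
        super().__init__(AgentParams((tau,), (1.0,), initial_income, lapse))


@dataclass
class BiasAgentParams:
    """Fast integrator time constant plus additive color biases."""

    tau: float = 5.0
    b_g: float = 0.0
    b_r: float = 0.0
    initial_income: float = 0.175
    lapse: float = 0.01

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ParameterError("tau must be >= 1")
        if self.b_g < 0 or self.b_r < 0:
            raise ParameterError("biases must be >= 0")
        if not 0.0 <= self.lapse < 0.5:
            raise ParameterError("lapse must be in [0, 0.5)")


class RandomBiasAgent:
    """Fast-only integration plus session-constant additive color biases.

    The alternative generative model in the confound analysis: any slowly
    varying bias, reward-driven or not, produces the same session-level
    signature as slow reward integration.
    """

    def __init__(self, params: BiasAgentParams):
        self.params = params
        self._alpha = 1.0 / params.tau
        self.lapse = params.lapse
        self.incomes = np.full(2, params.initial_income)

    def choice_prob(self) -> float:
        p = bias_model_probability(
            self.incomes[GREEN], self.incomes[RED], self.params.b_g, self.params.b_r
        )
        return min(max(p, self.lapse), 1.0 - self.lapse)

    def act(self, rng: np.random.Generator) -> int:
        return GREEN if rng.random() < self.choice_prob() else RED

    def update(self, choice: int, reward: int) -> None:
        r = np.zeros(2)
        r[choice] = reward
        self.incomes = (1.0 - self._alpha) * self.incomes + self._alpha * r


class FixedProbabilityAgent:
    """Degenerate agent with a constant P(green); used in tests and nulls."""

    def __init__(self, p_green: float):
        self.p_green = float(p_green)

    def choice_prob(self) -> float:
        return self.p_green

    def update(self, choice: int, reward: int) -> None:
        pass


#: Registry mapping model names to constructors (for YAML-driven configs).
MODEL_REGISTRY = {
    "multi_timescale": MultiTimescaleAgent,
    "single_timescale": SingleTimescaleAgent,
    "random_bias": RandomBiasAgent,
}


def make_agent(name: str, **kwargs):
    """Construct a registered agent from keyword parameters.

    ``multi_timescale`` expects ``taus``, ``weights`` and optional
    ``initial_income``; ``single_timescale`` expects ``tau``;
    ``random_bias`` expects ``tau``, ``b_g``, ``b_r``.
    """
    if name == "multi_timescale":
        return MultiTimescaleAgent(AgentParams(
            tuple(kwargs["taus"]), tuple(kwargs["weights"]),
            kwargs.get("initial_income", 0.175), kwargs.get("lapse", 0.01),
        ))
    if name == "single_timescale":
        return SingleTimescaleAgent(
            kwargs["tau"], kwargs.get("initial_income", 0.175),
            kwargs.get("lapse", 0.01),
        )
    if name == "random_bias":
        return RandomBiasAgent(BiasAgentParams(
            kwargs.get("tau", 5.0), kwargs.get("b_g", 0.0),
            kwargs.get("b_r", 0.0), kwargs.get("initial_income", 0.175),
            kwargs.get("lapse", 0.01),
        ))
    if name == "cascade":
        from .cascade import CascadeAgent, CascadeParams

        return CascadeAgent(CascadeParams(**kwargs))
    raise ParameterError(f"unknown model {name!r}")
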