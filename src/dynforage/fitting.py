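"""Per-session maximum-likelihood estimation of integrator weights.

The generative model is the multi-timescale local matching agent with
fixed time constants (defaults 2, 20 and 1000 trials) and unknown simplex
weights.  Because the income trajectories of each integrator depend only on
the observed choice/reward sequence -- not on the weights -- they are
precomputed once per session; every likelihood evaluation is then a cheap
weighted combination, and the 3-simplex is optimized through a 2-parameter
softmax chart with multiple restarts.

Sessions are fitted independently except that the slow integrator's final
income estimates are carried over as the next session's initial values
(slow estimates are the one state plausibly persisting across sessions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.signal import lfilter

from . import metrics
from .schedule import GREEN, RED, SessionData

_EPS = 1e-6  # probability clipping inside likelihoods only


@dataclass(frozen=True)
class FitConfig:
    """Settings of the per-session MLE."""

    taus: tuple[float, ...] = (2.0, 20.0, 1000.0)
    n_restarts: int = 5
    tol: float = 1e-8
    carryover: bool = True
    use_free_only: bool = True
    initial_income: float = 0.175
    min_free_choices: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.taus) != sorted(self.taus) or len(set(self.taus)) != len(
            self.taus
        ):
            raise ValueError("taus must be strictly increasing")
        if self.n_restarts < 1:
            raise ValueError("need at least one restart")


def _income_paths(
    session: SessionData, taus: Sequence[float], initial_incomes: np.ndarray
) -> np.ndarray:
    """Income trajectories, shape (2 targets, n_taus, n_trials).

    ``paths[x, i, t]`` is the income of target x on timescale i *before*
    the choice of trial t (i.e. the decision variable of trial t).
    ``initial_incomes`` has shape (2, n_taus).
    """
    n = session.n_trials
    out = np.empty((2, len(taus), n))
    for x in (RED, GREEN):
        r = (session.reward * (session.choice == x)).astype(float)[: n - 1]
        for i, tau in enumerate(taus):
            a = 1.0 / tau
            i0 = initial_incomes[x, i]
            out[x, i, 0] = i0
            out[x, i, 1:] = lfilter(
                [a], [1.0, -(1.0 - a)], r, zi=[(1.0 - a) * i0]
            )[0]
    return out


def softmax_weights(theta: np.ndarray) -> np.ndarray:
    """Map unconstrained (m-1)-vector to a point on the m-simplex."""
    z = np.concatenate([np.asarray(theta, dtype=float), [0.0]])
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


class MultiTimescaleModel:
    """Likelihood model for one session's free choices.

    Parameters
    ----------
    session
        The session to fit.
    taus
        Fixed integrator time constants (trials), strictly increasing.
    initial_incomes
        (2, n_taus) starting incomes; default is a flat
        ``initial_income`` for every target and timescale, with the slow
        column optionally overridden for carryover.
    use_free_only
        Score only COD-collapsed free choices (imposed second choices of a
        switch carry no information about preference).
    """

    def __init__(
        self,
        session: SessionData,
        taus: Sequence[float] = (2.0, 20.0, 1000.0),
        initial_incomes: np.ndarray | None = None,
        initial_income: float = 0.175,
        use_free_only: bool = True,
    ):
        if session.n_trials == 0:
            raise ValueError("cannot fit an empty session")
        self.session = session
        self.taus = tuple(float(t) for t in taus)
        if initial_incomes is None:
            initial_incomes = np.full((2, len(self.taus)), initial_income)
        self.initial_incomes = np.asarray(initial_incomes, dtype=float)
        self.use_free_only = use_free_only
        self._paths = _income_paths(session, self.taus, self.initial_incomes)
        self._mask = (
            session.free_choice.astype(bool)
            if use_free_only
            else np.ones(session.n_trials, dtype=bool)
        )
        self._chose_green = (session.choice == GREEN)[self._mask]

    @property
    def n_obs(self) -> int:
        return int(self._mask.sum())

    def choice_probabilities(self, weights) -> np.ndarray:
        """Per-scored-trial P(green) under the given simplex weights."""
        w = np.asarray(weights, dtype=float)
        i_r = w @ self._paths[RED][:, self._mask]
        i_g = w @ self._paths[GREEN][:, self._mask]
        tot = i_r + i_g
        p = np.where(tot > 0, i_g / np.where(tot > 0, tot, 1.0), 0.5)
        return np.clip(p, _EPS, 1.0 - _EPS)

    def loglike(self, weights) -> float:
        p = self.choice_probabilities(weights)
        y = self._chose_green
        return float(np.log(p[y]).sum() + np.log(1.0 - p[~y]).sum())

    def fit(
        self,
        n_restarts: int = 5,
        tol: float = 1e-8,
        rng: np.random.Generator | None = None,
    ) -> "MultiTimescaleResults":
        """Maximize the likelihood over the weight simplex.

        Uses Nelder-Mead on the softmax chart from ``n_restarts`` spread
        starting points (the uniform weights plus random draws).
        """
        if rng is None:
            rng = np.random.default_rng(0)
        m = len(self.taus)

        def nll(theta):
            return -self.loglike(softmax_weights(theta))

        starts = [np.zeros(m - 1)]
        starts += [rng.normal(scale=2.0, size=m - 1) for _ in range(n_restarts - 1)]
        best = None
        n_converged = 0
        for x0 in starts:
            res = optimize.minimize(
                nll, x0, method="Nelder-Mead",
                options={"xatol": tol, "fatol": tol, "maxiter": 4000},
            )
            n_converged += bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        weights = softmax_weights(best.x)
        llf = -best.fun
        boundary = bool(np.any(weights > 1.0 - 1e-4))
        # final incomes of every integrator (for slow-income carryover)
        final = self._final_incomes(weights)
        return MultiTimescaleResults(
            model=self,
            weights=weights,
            llf=llf,
            converged=n_converged > 0,
            boundary=boundary,
            theta=best.x.copy(),
            final_incomes=final,
        )

    def _final_incomes(self, weights) -> np.ndarray:
        """Incomes after the last trial's update, shape (2, n_taus)."""
        n = self.session.n_trials
        out = np.empty((2, len(self.taus)))
        for x in (RED, GREEN):
            r_last = float(
                self.session.reward[n - 1] * (self.session.choice[n - 1] == x)
            )
            for i, tau in enumerate(self.taus):
                a = 1.0 / tau
                out[x, i] = (1.0 - a) * self._paths[x, i, n - 1] + a * r_last
        return out


@dataclass
class MultiTimescaleResults:
    """MLE results for one session."""

    model: MultiTimescaleModel
    weights: np.ndarray
    llf: float
    converged: bool
    boundary: bool
    theta: np.ndarray
    final_incomes: np.ndarray  # (2, n_taus), post-session

    @property
    def w_slow(self) -> float:
        return float(self.weights[-1])

    @property
    def final_slow_incomes(self) -> np.ndarray:
        return self.final_incomes[:, -1]

    def bse(self) -> np.ndarray:
        """Delta-method standard errors of the weights.

        Numerical Hessian of the negative log-likelihood in the softmax
        chart, pushed through the softmax Jacobian.  NaN where the Hessian
        is not positive definite (e.g. boundary solutions).
        """
        m = len(self.weights)
        k = m - 1
        h = 1e-4

        def nll(theta):
            return -self.model.loglike(softmax_weights(theta))

        hess = np.empty((k, k))
        f0 = nll(self.theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.eye(k)[i] * h
                ej = np.eye(k)[j] * h
                hess[i, j] = hess[j, i] = (
                    nll(self.theta + ei + ej)
                    - nll(self.theta + ei - ej)
                    - nll(self.theta - ei + ej)
                    + nll(self.theta - ei - ej)
                ) / (4 * h * h)
        del f0
        try:
            cov_theta = np.linalg.inv(hess)
            if np.any(np.diag(cov_theta) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            return np.full(m, np.nan)
        w = self.weights
        jac = np.empty((m, k))  # d w_i / d theta_j
        for j in range(k):
            ind = np.zeros(m)
            ind[j] = 1.0
            jac[:, j] = w * (ind - w[j])
        cov_w = jac @ cov_theta @ jac.T
        var = np.clip(np.diag(cov_w), 0.0, None)
        return np.sqrt(var)

    def summary(self) -> str:
        """Plain-text fit summary (statsmodels flavored)."""
        from statsmodels.iolib.table import SimpleTable

        bse = self.bse()
        names = [f"w[tau={t:g}]" for t in self.model.taus]
        rows = [
            [f"{w:.4f}", f"{s:.4f}" if np.isfinite(s) else "nan"]
            for w, s in zip(self.weights, bse)
        ]
        tbl = SimpleTable(
            rows, headers=["estimate", "std err"], stubs=names,
            title="Multi-timescale matching model (MLE)",
        )
        extra = (
            f"\nn free choices: {self.model.n_obs}"
            f"\nlog-likelihood: {self.llf:.3f}"
            f"\nconverged: {self.converged}  boundary: {self.boundary}"
        )
        return str(tbl) + extra


def session_log_likelihood(
    session: SessionData,
    weights,
    taus: Sequence[float] = (2.0, 20.0, 1000.0),
    initial_incomes: np.ndarray | None = None,
    initial_income: float = 0.175,
    use_free_only: bool = True,
) -> float:
    """Bernoulli log-likelihood of a session's free choices under given
    weights (forward pass of the integrator model with clipped P)."""
    model = MultiTimescaleModel(
        session, taus, initial_incomes, initial_income, use_free_only
    )
    return model.loglike(weights)


def fit_session(
    session: SessionData,
    config: FitConfig = FitConfig(),
    carryover_income: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> MultiTimescaleResults:
    """Fit one session; ``carryover_income`` seeds the slow integrator.

    Fast integrators always start at ``config.initial_income``; only the
    slowest timescale inherits ``carryover_income`` (per-target pair).
    """
    init = np.full((2, len(config.taus)), config.initial_income)
    if carryover_income is not None:
        init[:, -1] = np.asarray(carryover_income, dtype=float)
    model = MultiTimescaleModel(
        session,
        taus=config.taus,
        initial_incomes=init,
        use_free_only=config.use_free_only,
    )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return model.fit(n_restarts=config.n_restarts, tol=config.tol, rng=rng)


@dataclass
class DatasetFit:
    """Sequential session fits plus the weight/undermatching join."""

    results: list[MultiTimescaleResults]
    table: pd.DataFrame
    correlation: float
    p_value: float


def fit_dataset(
    sessions: Sequence[SessionData],
    config: FitConfig = FitConfig(),
    last_n: int | None = 50,
    min_rewards: int = 5,
    n_perm: int = 2000,
) -> DatasetFit:
    """Fit sessions in temporal order with slow-income carryover.

    Emits the session-wise (w_slow, undermatching) table and their Pearson
    correlation with a block-permutation p-value (blocks of 5 sessions,
    preserving within-block order).
    """
    from .lmit import piecewise_permutation_test

    rng = np.random.default_rng(config.seed)
    results: list[MultiTimescaleResults] = []
    carry = None
    rows = []
    for i, sess in enumerate(sessions):
        res = fit_session(sess, config, carryover_income=carry, rng=rng)
        results.append(res)
        if config.carryover:
            carry = res.final_slow_incomes
        try:
            fit = metrics.fit_matching(
                metrics.block_summaries(sess, last_n=last_n), min_rewards
            )
            um = fit.undermatching
        except metrics.InsufficientDataError:
            um = np.nan
        rows.append(
            {
                "session": sess.meta.get("session", i),
                "w_slow": res.w_slow,
                "llf": res.llf,
                "undermatching": um,
                "converged": res.converged,
                "boundary": res.boundary,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[["w_slow", "undermatching"]].dropna()
    if len(ok) >= 10 and ok["w_slow"].std() > 0 and ok["undermatching"].std() > 0:
        corr = float(stats.pearsonr(ok["w_slow"], ok["undermatching"])[0])
        _, p = piecewise_permutation_test(
            ok["w_slow"].to_numpy(),
            ok["undermatching"].to_numpy(),
            n_perm=n_perm,
            rng=rng,
        )
    else:
        corr, p = np.nan, np.nan
    return DatasetFit(results, table, corr, p)
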