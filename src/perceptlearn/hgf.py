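"""Three-level Hierarchical Gaussian Filter (HGF) for binary inputs.

The filter tracks a binary environmental quantity (here: the tone-rotation
contingency of the reversal-learning task) at three levels:

* level 1 — the binary input itself, predicted by ``mu1hat = s(mu2)``
  where ``s`` is the logistic sigmoid;
* level 2 — a Gaussian random walk on the log-odds of the input, with
  tonic log-volatility ``omega2`` and coupling ``kappa2`` to level 3;
* level 3 — the log-volatility of level 2, itself a Gaussian random walk
  with tonic variance ``exp(omega3)``.

Updates are precision-weighted prediction errors; the level-3 update uses
the standard binary-HGF volatility weighting.  There is no perceptual
uncertainty: inputs are observed exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

_CLAMP = 1e-12  # predictions clamped to [_CLAMP, 1 - _CLAMP] before logs


class HGFNumericalError(ArithmeticError):
    """Non-positive updated precision: the filter became unstable."""


def encode_contingency(tone: str, rotation: str) -> int:
    """Binary coding of the tone-rotation contingency.

    1 for (high, left) and (low, right); 0 for (high, right) and (low, left).
    The filter learns this contingency, not the rotation direction itself.
    """
    if tone not in ("high", "low"):
        raise ValueError(f"invalid tone {tone!r}")
    if rotation not in ("left", "right"):
        raise ValueError(f"invalid rotation {rotation!r}")
    return int((tone == "high") == (rotation == "left"))


@dataclass(frozen=True)
class HGFParams:
    """Learning parameters of the binary HGF.

    Defaults are the fixed values used for the ideal-learner analysis:
    ``mu2_0 = mu3_0 = rho2 = 0``, ``kappa2 = 1``, ``omega2 = -2.28``,
    ``omega3 = -6.14``.  The initial variances are toolbox-style defaults
    (``sigma2_0 = 0.1``, ``sigma3_0 = 1``) and are exposed here because the
    filter is sensitive to them only weakly.
    """

    mu2_0: float = 0.0
    mu3_0: float = 0.0
    sigma2_0: float = 0.1
    sigma3_0: float = 1.0
    rho2: float = 0.0
    kappa2: float = 1.0
    omega2: float = -2.28
    omega3: float = -6.14

    def __post_init__(self) -> None:
        if not (self.sigma2_0 > 0 and self.sigma3_0 > 0):
            raise ValueError("initial variances must be positive")
        for name in ("mu2_0", "mu3_0", "sigma2_0", "sigma3_0", "rho2",
                     "kappa2", "omega2", "omega3"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class BeliefState:
    """Posterior belief after one trial, plus the prediction used on it."""

    mu1hat: float  # prediction of the input on this trial (in (0,1))
    mu2: float
    sigma2: float
    mu3: float
    sigma3: float
    delta1: float  # level-1 prediction error (0 on skipped trials)
    delta2: float  # level-2 volatility prediction error (0 on skipped trials)


def initial_state(params: HGFParams) -> BeliefState:
    """The belief before any input has been seen."""
    return BeliefState(
        mu1hat=float(expit(params.mu2_0 + params.rho2)),
        mu2=params.mu2_0,
        sigma2=params.sigma2_0,
        mu3=params.mu3_0,
        sigma3=params.sigma3_0,
        delta1=0.0,
        delta2=0.0,
    )


@dataclass
class BeliefTrajectory:
    """Per-trial belief states produced by sequential filtering."""

    states: list[BeliefState]
    inputs: list[int | None]

    def __len__(self) -> int:
        return len(self.states)

    @property
    def mu1hat(self) -> np.ndarray:
        return np.array([s.mu1hat for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self.states) + 1),
                "input": [np.nan if u is None else u for u in self.inputs],
                "mu1hat": [s.mu1hat for s in self.states],
                "mu2": [s.mu2 for s in self.states],
                "sigma2": [s.sigma2 for s in self.states],
                "mu3": [s.mu3 for s in self.states],
                "sigma3": [s.sigma3 for s in self.states],
                "delta1": [s.delta1 for s in self.states],
                "delta2": [s.delta2 for s in self.states],
            }
        )


def hgf_step(state: BeliefState, u: int | None, params: HGFParams,
             trial: int | None = None) -> BeliefState:
    """Advance the filter by one trial.

    ``u`` is the binary contingency input, or None for a trial that carries
    no contingency information (the state is propagated with only the
    prediction-step variance inflation).
    """
    p = params
    mu2hat = state.mu2 + p.rho2
    mu1hat = float(expit(mu2hat))
    log_v2 = p.kappa2 * state.mu3 + p.omega2
    if log_v2 > 700.0:  # exp would overflow: the volatility belief diverged
        raise HGFNumericalError(
            "level-2 volatility diverged" + ("" if trial is None else f" at trial {trial}")
        )
    v2 = math.exp(log_v2)  # phasic level-2 variance
    v3 = math.exp(p.omega3)

    if u is None:
        return BeliefState(mu1hat, mu2hat, state.sigma2 + v2,
                           state.mu3, state.sigma3 + v3, 0.0, 0.0)

    if u not in (0, 1):
        raise ValueError(f"input must be 0, 1 or None, got {u!r}")

    where = "" if trial is None else f" at trial {trial}"

    # level 2: precision-weighted prediction error on the input
    pihat2 = 1.0 / (state.sigma2 + v2)
    delta1 = u - mu1hat
    pi2 = pihat2 + mu1hat * (1.0 - mu1hat)
    if pi2 <= 0:
        raise HGFNumericalError(f"non-positive level-2 precision{where}")
    mu2 = mu2hat + delta1 / pi2
    sigma2 = 1.0 / pi2

    # level 3: volatility prediction error with the binary-HGF weighting
    delta2 = (sigma2 + (mu2 - mu2hat) ** 2) * pihat2 - 1.0
    pihat3 = 1.0 / (state.sigma3 + v3)
    w2 = v2 * pihat2
    pi3 = pihat3 + 0.5 * p.kappa2**2 * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
    if pi3 <= 0:
        raise HGFNumericalError(f"non-positive level-3 precision{where}")
    mu3 = state.mu3 + 0.5 * p.kappa2 * w2 * delta2 / pi3
    sigma3 = 1.0 / pi3

    return BeliefState(mu1hat, mu2, sigma2, mu3, sigma3, delta1, delta2)


def hgf_filter(inputs: Sequence[int | None], params: HGFParams | None = None) -> BeliefTrajectory:
    """Run the filter over a full input sequence.

    Missing inputs (None) propagate the belief unchanged apart from the
    prediction-step variance inflation.
    """
    params = params or HGFParams()
    inputs = list(inputs)
    if not inputs:
        raise ValueError("inputs must be non-empty")
    state = initial_state(params)
    states: list[BeliefState] = []
    for t, u in enumerate(inputs, start=1):
        state = hgf_step(state, u, params, trial=t)
        states.append(state)
    return BeliefTrajectory(states, inputs)


def surprise(inputs: Sequence[int | None], params: HGFParams | None = None) -> float:
    """Shannon surprise of the input sequence under the filter's predictions.

    ``sum_t -log P(u_t)`` with ``P(u_t) = mu1hat_t`` for u=1 and
    ``1 - mu1hat_t`` for u=0; missing inputs contribute nothing.
    """
    params = params or HGFParams()
    traj = hgf_filter(inputs, params)
    total = 0.0
    for state, u in zip(traj.states, traj.inputs):
        if u is None:
            continue
        p = state.mu1hat if u == 1 else 1.0 - state.mu1hat
        total += -math.log(min(max(p, _CLAMP), 1.0 - _CLAMP))
    return total


#: Gaussian priors (mean, variance) for the free learning parameters of the
#: ideal-learner pre-fit.  omega3's prior mean follows the individual-fit
#: formulation (-6.13); the fixed-parameter value (-6.14) remains the
#: HGFParams default — both are plain config values.
DEFAULT_LEARNING_PRIORS: dict[str, tuple[float, float]] = {
    "omega2": (-2.28, 1.0),
    "omega3": (-6.13, 1.0),
}


def bayes_optimal_fit(
    inputs: Sequence[int | None],
    free: Sequence[str] = ("omega2", "omega3"),
    priors: Mapping[str, tuple[float, float]] | None = None,
    base: HGFParams | None = None,
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
) -> HGFParams:
    """MAP-estimate learning parameters from the input sequence alone.

    Minimizes ``surprise(inputs, .) + Gaussian prior penalty`` over the
    ``free`` subset of {"omega2", "omega3"} — the parameter values under
    which the stimulus sequence is least surprising.  Multistart BFGS,
    deterministic given ``seed``.
    """
    base = base or HGFParams()
    free = tuple(free)
    if not free:
        return base
    allowed = {"omega2", "omega3"}
    if not set(free) <= allowed:
        raise ValueError(f"free parameters must be a subset of {allowed}")
    priors = dict(DEFAULT_LEARNING_PRIORS, **(priors or {}))

    means = np.array([priors[name][0] for name in free])
    sds = np.sqrt([priors[name][1] for name in free])

    def objective(theta: np.ndarray) -> float:
        params = replace(base, **dict(zip(free, theta)))
        try:
            s = surprise(inputs, params)
        except (HGFNumericalError, OverflowError):
            return 1e10
        penalty = 0.5 * float(np.sum(((theta - means) / sds) ** 2))
        return s + penalty

    rng = np.random.default_rng(seed)
    starts = [means] + [means + sds * rng.standard_normal(len(free))
                        for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="BFGS",
                                options={"gtol": tol})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("ideal-learner fit failed to converge")
    return replace(base, **dict(zip(free, best.x)))
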