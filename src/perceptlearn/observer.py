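"""Bayesian observer model for bistable perception under changing expectations.

On every trial the observer forms three Gaussian priors over the percept
(coded right = 1, left = 0):

* **associative learning** — mean derived from the binary HGF's prediction
  of the tone-rotation contingency and the current tone, precision ``pi_a``;
* **priming** — mean equal to the percept on the immediately preceding
  trial, precision ``pi_p``;
* **sensory memory** — mean equal to the percept on the most recent
  ambiguous trial, precision ``pi_s``.

The priors are fused by precision weighting into a joint prior, which is
combined with the stereodisparity information of a bimodal likelihood
(mean 0, 0.5 or 1; precision ``pi_stereo``).  The probability of perceiving
rightward rotation follows from the ratio of the two likelihood modes at
the combined mean, and a unit-sigmoid response function with exponent
``zeta`` maps it to response probabilities.

Fusing the priors first and the likelihood second, or everything at once,
is mathematically equivalent; the implementation exploits this by computing
the combined mean directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .hgf import HGFParams, encode_contingency, hgf_filter, hgf_step, initial_state
from .task import ResponseRecord, TrialSequence

__all__ = [
    "ObserverParams", "ObserverRun", "RTModel", "ConfidenceModel",
    "assoc_prior_mean", "priming_prior_mean", "memory_prior_mean",
    "joint_prior", "stereo_mean", "posterior_prob", "response_prob",
    "run_observer", "simulate_observer",
]


@dataclass(frozen=True)
class ObserverParams:
    """Perceptual parameters of the observer.

    The four precisions are the free parameters of the model; ``zeta`` is
    the response-noise exponent (1 = probability matching).  Precisions are
    time-invariant within a subject.
    """

    pi_a: float = 0.5
    pi_p: float = 0.5
    pi_s: float = 0.5
    pi_stereo: float = 2.5
    zeta: float = 1.0
    hgf: HGFParams = field(default_factory=HGFParams)
    #: how ambiguous trials feed the contingency filter: "skip" carries the
    #: belief forward, "percept-coded" encodes the subject's own percept.
    ambiguous_input_policy: str = "skip"
    #: history priors before any history exists: "neutral" contributes mean
    #: 0.5 at full precision, "drop" removes the prior until history exists.
    history_init: str = "neutral"
    #: mode-weighting constant of the bimodal likelihood; None uses the
    #: combined precision pi_m of the fused distribution.
    mode_weight: float | None = None

    def __post_init__(self) -> None:
        for name in ("pi_a", "pi_p", "pi_s", "pi_stereo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.zeta > 0:
            raise ValueError("zeta must be > 0")
        if self.ambiguous_input_policy not in ("skip", "percept-coded"):
            raise ValueError(
                f"invalid ambiguous_input_policy {self.ambiguous_input_policy!r}"
            )
        if self.history_init not in ("neutral", "drop"):
            raise ValueError(f"invalid history_init {self.history_init!r}")


def assoc_prior_mean(tone: str, mu1hat: float):
    """Mean of the associative-learning prior given the current tone.

    The HGF predicts the contingency (1 codes high+left / low+right), so the
    probability of rightward rotation is ``mu1hat`` after a low tone and
    ``1 - mu1hat`` after a high tone.
    """
    if isinstance(tone, str):
        if tone == "low":
            return mu1hat
        if tone == "high":
            return 1.0 - mu1hat
        raise ValueError(f"invalid tone {tone!r}")
    tone = np.asarray(tone)
    return np.where(tone == "low", mu1hat, 1.0 - np.asarray(mu1hat))


def priming_prior_mean(previous_percept: int | None) -> float:
    """Mean of the priming prior: the percept on the preceding trial."""
    if previous_percept is None:
        return 0.5
    return float(previous_percept)


def memory_prior_mean(last_ambiguous_percept: int | None) -> float:
    """Mean of the sensory-memory prior: the percept on the last ambiguous trial."""
    if last_ambiguous_percept is None:
        return 0.5
    return float(last_ambiguous_percept)


def joint_prior(mu_a, pi_a, mu_p, pi_p, mu_s, pi_s):
    """Precision-weighted fusion of the three priors.

    Returns ``(mu_prior, pi_prior)`` with ``pi_prior = pi_a + pi_p + pi_s``.
    When every precision is zero there is no prior: returns ``(0.5, 0.0)``
    so the posterior step falls back to the likelihood alone.
    """
    pi_prior = pi_a + pi_p + pi_s
    scalar = np.isscalar(pi_prior)
    pi_arr = np.atleast_1d(np.asarray(pi_prior, dtype=float))
    num = np.atleast_1d(
        np.asarray(pi_a * np.asarray(mu_a) + pi_p * np.asarray(mu_p)
                   + pi_s * np.asarray(mu_s), dtype=float)
    )
    mu = np.where(pi_arr > 0, num / np.where(pi_arr > 0, pi_arr, 1.0), 0.5)
    if scalar:
        return float(mu[0]), float(pi_arr[0])
    return mu, pi_arr


def stereo_mean(trial_type: str, true_rotation: str) -> float:
    """Mean of the stereodisparity distribution: 1 (right), 0.5 (ambiguous), 0 (left)."""
    if trial_type == "ambiguous":
        if true_rotation != "none":
            raise ValueError("ambiguous trials have no true rotation")
        return 0.5
    if trial_type == "unambiguous":
        if true_rotation == "right":
            return 1.0
        if true_rotation == "left":
            return 0.0
        raise ValueError(f"unambiguous trial with rotation {true_rotation!r}")
    raise ValueError(f"invalid trial_type {trial_type!r}")


def posterior_prob(mu_prior, pi_prior, mu_stereo, pi_stereo,
                   mode_weight: float | None = None):
    """Posterior probability of the rightward percept.

    The fused mean ``mu_m = (pi_prior*mu_prior + pi_stereo*mu_stereo)/pi_m``
    (``pi_m = pi_prior + pi_stereo``) sets the odds of the two likelihood
    modes at 0 and 1; with mode-weighting constant ``c`` (default: ``pi_m``)
    the posterior is ``logistic((2*mu_m - 1) * c)`` — strictly increasing in
    ``mu_m`` and exactly 0.5 at the midpoint.
    """
    pi_m = np.asarray(pi_prior, dtype=float) + np.asarray(pi_stereo, dtype=float)
    if np.any(pi_m <= 0):
        raise ValueError("undefined posterior: pi_prior + pi_stereo must be > 0")
    mu_m = (np.asarray(pi_prior) * np.asarray(mu_prior)
            + np.asarray(pi_stereo) * np.asarray(mu_stereo)) / pi_m
    c = pi_m if mode_weight is None else mode_weight
    out = expit((2.0 * mu_m - 1.0) * c)
    if np.isscalar(mu_prior) and np.isscalar(mu_stereo):
        return float(out)
    return out


def response_prob(p, zeta: float = 1.0):
    """Unit-sigmoid response function ``p^zeta / (p^zeta + (1-p)^zeta)``."""
    if not zeta > 0:
        raise ValueError("zeta must be > 0")
    p = np.asarray(p, dtype=float)
    num = p**zeta
    out = num / (num + (1.0 - p) ** zeta)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# trial-table plumbing


def contingency_inputs(
    seq: TrialSequence,
    responses: Sequence[ResponseRecord] | None,
    policy: str = "skip",
) -> list[int | None]:
    """Per-trial contingency inputs for the HGF under the given policy."""
    inputs: list[int | None] = []
    for i, t in enumerate(seq):
        if t.trial_type == "unambiguous":
            inputs.append(encode_contingency(t.tone, t.true_rotation))
        elif policy == "skip":
            inputs.append(None)
        else:  # percept-coded
            percept = responses[i].percept if responses is not None else None
            if percept is None:
                inputs.append(None)
            else:
                rotation = "right" if percept == 1 else "left"
                inputs.append(encode_contingency(t.tone, rotation))
    return inputs


def _history_means(
    seq: TrialSequence, responses: Sequence[ResponseRecord]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(mu_p, mu_s, p_defined, s_defined) from the observed percept history."""
    n = len(seq)
    mu_p = np.full(n, 0.5)
    mu_s = np.full(n, 0.5)
    p_def = np.zeros(n, dtype=bool)
    s_def = np.zeros(n, dtype=bool)
    prev: int | None = None
    last_amb: int | None = None
    for i, t in enumerate(seq):
        if prev is not None:
            mu_p[i], p_def[i] = float(prev), True
        if last_amb is not None:
            mu_s[i], s_def[i] = float(last_amb), True
        percept = responses[i].percept
        if percept is not None:
            prev = percept
            if t.trial_type == "ambiguous":
                last_amb = percept
    return mu_p, mu_s, p_def, s_def


@dataclass
class ObserverRun:
    """Response probabilities and the per-trial prior/posterior trace."""

    p_right: np.ndarray
    trace: pd.DataFrame


def run_observer(
    seq: TrialSequence,
    responses: Sequence[ResponseRecord],
    params: ObserverParams,
) -> ObserverRun:
    """Trial-wise response probabilities for an observed response series.

    The HGF is updated with the tone-rotation contingency on unambiguous
    trials (and per ``ambiguous_input_policy`` otherwise); the priming and
    memory priors condition on the subject's actual percept history.
    Deterministic.
    """
    if len(responses) != len(seq):
        raise ValueError(f"{len(responses)} responses for {len(seq)} trials")
    inputs = contingency_inputs(seq, responses, params.ambiguous_input_policy)
    mu1hat = hgf_filter(inputs, params.hgf).mu1hat
    tones = np.array([t.tone for t in seq])
    mu_a = assoc_prior_mean(tones, mu1hat)
    mu_p, mu_s, p_def, s_def = _history_means(seq, responses)
    mu_stereo = np.array([stereo_mean(t.trial_type, t.true_rotation) for t in seq])

    pi_p = np.where(p_def | (params.history_init == "neutral"), params.pi_p, 0.0)
    pi_s = np.where(s_def | (params.history_init == "neutral"), params.pi_s, 0.0)
    mu_prior, pi_prior = joint_prior(mu_a, params.pi_a, mu_p, pi_p, mu_s, pi_s)
    p_post = posterior_prob(mu_prior, pi_prior, mu_stereo, params.pi_stereo,
                            params.mode_weight)
    p_right = response_prob(p_post, params.zeta)

    pi_m = pi_prior + params.pi_stereo
    mu_m = (pi_prior * mu_prior + params.pi_stereo * mu_stereo) / pi_m
    trace = pd.DataFrame(
        {
            "trial": [t.index for t in seq],
            "mu1hat": mu1hat,
            "mu_a": mu_a,
            "mu_p": mu_p,
            "mu_s": mu_s,
            "mu_prior": mu_prior,
            "pi_prior": pi_prior,
            "mu_stereo": mu_stereo,
            "mu_m": mu_m,
            "pi_m": pi_m,
            "p_right": p_right,
            "percept": [np.nan if r.percept is None else r.percept
                        for r in responses],
        }
    )
    return ObserverRun(p_right=np.asarray(p_right, dtype=float), trace=trace)


# ---------------------------------------------------------------------------
# synthetic observers


@dataclass(frozen=True)
class RTModel:
    """Log-normal reaction times with a congruency speed-up.

    Unambiguous stimuli matching the currently predominant association are
    answered faster by the factor ``congruent_factor`` (< 1), yielding a
    negative normalized motor-adaptation measure of roughly
    ``log(congruent_factor)``.
    """

    median_rt: float = 0.625  # seconds
    sigma: float = 0.2  # log-scale sd
    congruent_factor: float = 0.95

    def sample(self, congruent: bool | None, rng: np.random.Generator) -> float:
        mu = math.log(self.median_rt)
        if congruent:
            mu += math.log(self.congruent_factor)
        return float(rng.lognormal(mean=mu, sigma=self.sigma))


@dataclass(frozen=True)
class ConfidenceModel:
    """Confidence ratings: mostly "very sure" (4), more so on unambiguous trials."""

    p4_unambiguous: float = 0.85
    p4_ambiguous: float = 0.75

    def sample(self, ambiguous: bool, rng: np.random.Generator) -> int:
        p4 = self.p4_ambiguous if ambiguous else self.p4_unambiguous
        rest = 1.0 - p4
        probs = [0.1 * rest, 0.3 * rest, 0.6 * rest, p4]  # levels 1..4
        return int(rng.choice([1, 2, 3, 4], p=probs))


def simulate_observer(
    seq: TrialSequence,
    params: ObserverParams,
    rng_seed: int,
    rt_model: RTModel | None = None,
    confidence_model: ConfidenceModel | None = None,
) -> list[ResponseRecord]:
    """Sample a full response series from the generative observer model.

    Percepts are drawn trial by trial from the model's response
    probabilities, with the observer's own sampled percepts feeding the
    priming/memory priors (and the percept-coded HGF policy) forward.
    Reproducible given ``rng_seed``.
    """
    rt_model = rt_model or RTModel()
    confidence_model = confidence_model or ConfidenceModel()
    rng = np.random.default_rng(rng_seed)
    neutral = params.history_init == "neutral"

    state = initial_state(params.hgf)
    prev: int | None = None
    last_amb: int | None = None
    records: list[ResponseRecord] = []
    for t in seq:
        mu1hat = float(expit(state.mu2 + params.hgf.rho2))
        mu_a = assoc_prior_mean(t.tone, mu1hat)
        pi_p = params.pi_p if (prev is not None or neutral) else 0.0
        pi_s = params.pi_s if (last_amb is not None or neutral) else 0.0
        mu_prior, pi_prior = joint_prior(
            mu_a, params.pi_a,
            priming_prior_mean(prev), pi_p,
            memory_prior_mean(last_amb), pi_s,
        )
        p_post = posterior_prob(mu_prior, pi_prior,
                                stereo_mean(t.trial_type, t.true_rotation),
                                params.pi_stereo, params.mode_weight)
        p_right = response_prob(p_post, params.zeta)
        percept = int(rng.random() < p_right)

        ambiguous = t.trial_type == "ambiguous"
        rt = rt_model.sample(None if ambiguous else t.congruent_with_block, rng)
        confidence = confidence_model.sample(ambiguous, rng)
        if ambiguous:
            correct = None
        else:
            correct = (percept == 1) == (t.true_rotation == "right")
        records.append(ResponseRecord(percept, rt, confidence, correct))

        # advance the contingency filter
        if not ambiguous:
            u = encode_contingency(t.tone, t.true_rotation)
        elif params.ambiguous_input_policy == "percept-coded":
            u = encode_contingency(t.tone, "right" if percept == 1 else "left")
        else:
            u = None
        state = hgf_step(state, u, params.hgf, trial=t.index)

        prev = percept
        if ambiguous:
            last_amb = percept
    return records
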