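"""Subject-level inversion of the observer model.

Free parameters are estimated by MAP on the log scale (precisions are
positive, so their inversion priors are log-normal; the HGF's tonic
log-volatilities ``omega2``/``omega3`` are real-valued and get Gaussian
priors on their native scale).  The log model evidence is approximated by
the Laplace approximation at the MAP estimate — a quasi-Newton optimum
plus a Gaussian posterior approximation, i.e. the operating point of the
variational "negative free energy" schemes commonly used for this class of
model.

Model space: every combination of the associative, priming and memory
priors included (precision free) or excluded (precision structurally pinned
to zero), with the stereodisparity precision always free — 2**3 = 8 models.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .hgf import HGFNumericalError, HGFParams, hgf_filter
from .observer import (
    ObserverParams,
    _history_means,
    assoc_prior_mean,
    contingency_inputs,
    response_prob,
)
from .task import ResponseRecord, TrialSequence

logger = logging.getLogger(__name__)

LOG_2PI = math.log(2.0 * math.pi)
_CLAMP = 1e-12

#: inversion priors (mean, variance); precisions on the log scale
DEFAULT_PARAM_PRIORS: dict[str, tuple[float, float]] = {
    "log_pi_a": (math.log(0.5), 1.0),
    "log_pi_p": (math.log(0.5), 1.0),
    "log_pi_s": (math.log(0.5), 1.0),
    "log_pi_stereo": (math.log(2.5), 1.0),
    "omega2": (-2.28, 1.0),
    "omega3": (-6.13, 1.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """One model of the 2^3 space: which priors are included.

    Excluded priors have their precision pinned structurally to zero
    (equivalent to a degenerate point prior at zero precision); included
    precisions are free on the log scale.
    """

    include_a: bool
    include_p: bool
    include_s: bool
    fit_learning_rate: bool = False
    param_priors: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_PRIORS)
    )

    @property
    def label(self) -> str:
        return "".join(
            ("+" if inc else "-") + tag
            for inc, tag in [(self.include_a, "A"), (self.include_p, "P"),
                             (self.include_s, "S")]
        )

    @property
    def free_names(self) -> tuple[str, ...]:
        names = []
        if self.include_a:
            names.append("log_pi_a")
        if self.include_p:
            names.append("log_pi_p")
        if self.include_s:
            names.append("log_pi_s")
        names.append("log_pi_stereo")
        if self.fit_learning_rate:
            names += ["omega2", "omega3"]
        return tuple(names)

    def prior_mean(self) -> np.ndarray:
        return np.array([self.param_priors[n][0] for n in self.free_names])

    def prior_var(self) -> np.ndarray:
        return np.array([self.param_priors[n][1] for n in self.free_names])

    def to_params(self, theta: np.ndarray, base: ObserverParams) -> ObserverParams:
        """Materialize observer parameters from a free-parameter vector."""
        values = dict(zip(self.free_names, theta))
        hgf = base.hgf
        if self.fit_learning_rate:
            hgf = replace(hgf, omega2=float(values["omega2"]),
                          omega3=float(values["omega3"]))
        return replace(
            base,
            pi_a=math.exp(values["log_pi_a"]) if self.include_a else 0.0,
            pi_p=math.exp(values["log_pi_p"]) if self.include_p else 0.0,
            pi_s=math.exp(values["log_pi_s"]) if self.include_s else 0.0,
            pi_stereo=math.exp(values["log_pi_stereo"]),
            hgf=hgf,
        )


def build_model_space(fit_learning_rate: bool = False) -> list[ModelSpec]:
    """All 8 combinations of the three priors, from +A+P+S to -A-P-S."""
    return [
        ModelSpec(a, p, s, fit_learning_rate=fit_learning_rate)
        for a, p, s in itertools.product([True, False], repeat=3)
    ]


class _SubjectCache:
    """Precomputed design quantities for fast likelihood evaluation.

    For fixed HGF learning parameters the belief trajectory does not depend
    on the precisions, so it is computed once per (omega2, omega3) pair; the
    remaining likelihood is a closed-form vectorized function of the
    precisions.
    """

    def __init__(self, seq: TrialSequence, responses: Sequence[ResponseRecord],
                 base: ObserverParams):
        if len(responses) != len(seq):
            raise ValueError(f"{len(responses)} responses for {len(seq)} trials")
        self.base = base
        self.inputs = contingency_inputs(seq, responses, base.ambiguous_input_policy)
        self.tones_low = np.array([t.tone == "low" for t in seq])
        self.mu_p, self.mu_s, p_def, s_def = _history_means(seq, responses)
        neutral = base.history_init == "neutral"
        self.p_on = p_def | neutral
        self.s_on = s_def | neutral
        from .observer import stereo_mean  # local import to avoid cycle noise
        self.mu_stereo = np.array(
            [stereo_mean(t.trial_type, t.true_rotation) for t in seq]
        )
        percepts = np.array([np.nan if r.percept is None else r.percept
                             for r in responses], dtype=float)
        self.valid = ~np.isnan(percepts)
        if not self.valid.any():
            raise ValueError("no recorded percepts to fit")
        self.y = percepts[self.valid]
        self._mu1hat: dict[tuple[float, float], np.ndarray] = {}

    def mu1hat(self, omega2: float, omega3: float) -> np.ndarray:
        key = (omega2, omega3)
        if key not in self._mu1hat:
            hgf = replace(self.base.hgf, omega2=omega2, omega3=omega3)
            self._mu1hat[key] = hgf_filter(self.inputs, hgf).mu1hat
        return self._mu1hat[key]

    def probabilities(self, params: ObserverParams) -> np.ndarray:
        mu1hat = self.mu1hat(params.hgf.omega2, params.hgf.omega3)
        mu_a = np.where(self.tones_low, mu1hat, 1.0 - mu1hat)
        pi_p = np.where(self.p_on, params.pi_p, 0.0)
        pi_s = np.where(self.s_on, params.pi_s, 0.0)
        pi_prior = params.pi_a + pi_p + pi_s
        num = params.pi_a * mu_a + pi_p * self.mu_p + pi_s * self.mu_s
        mu_prior = np.where(pi_prior > 0, num / np.where(pi_prior > 0, pi_prior, 1.0), 0.5)
        pi_m = pi_prior + params.pi_stereo
        if np.any(pi_m <= 0):
            raise ValueError("undefined posterior: all precisions zero")
        mu_m = (pi_prior * mu_prior + params.pi_stereo * self.mu_stereo) / pi_m
        c = pi_m if params.mode_weight is None else params.mode_weight
        p = expit((2.0 * mu_m - 1.0) * c)
        return response_prob(p, params.zeta)


def negative_log_joint(
    theta: np.ndarray,
    data: tuple[TrialSequence, Sequence[ResponseRecord]],
    spec: ModelSpec,
    base: ObserverParams | None = None,
    cache: _SubjectCache | None = None,
) -> float:
    """Negative log joint: Bernoulli response likelihood plus parameter priors.

    ``theta`` is the free-parameter vector on the inversion scale (log
    precisions; native-scale omegas).  Trials without a recorded percept are
    excluded from the likelihood.
    """
    base = base or ObserverParams()
    if cache is None:
        cache = _SubjectCache(*data, base)
    theta = np.asarray(theta, dtype=float)
    try:
        params = spec.to_params(theta, base)
        p = cache.probabilities(params)[cache.valid]
    except (HGFNumericalError, OverflowError):
        return 1e10
    p = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    nll = -float(np.sum(cache.y * np.log(p) + (1.0 - cache.y) * np.log1p(-p)))
    m, v = spec.prior_mean(), spec.prior_var()
    nlp = 0.5 * float(np.sum((theta - m) ** 2 / v + np.log(2.0 * np.pi * v)))
    out = nll + nlp
    return out if math.isfinite(out) else 1e10


@dataclass(frozen=True)
class FitOptions:
    seed: int = 0
    n_starts: int = 5
    gtol: float = 1e-6
    maxiter: int = 500
    hessian_step: float = 1e-4


@dataclass
class FitResult:
    """MAP estimate and Laplace log evidence for one subject under one model."""

    spec: ModelSpec
    map_params: ObserverParams
    theta: np.ndarray
    log_evidence: float
    converged: bool
    n_restarts_used: int
    hessian_condition: float
    neg_log_joint: float

    def to_dict(self) -> dict:
        return {
            "model": self.spec.label,
            "theta": {n: float(v) for n, v in zip(self.spec.free_names, self.theta)},
            "pi_a": self.map_params.pi_a,
            "pi_p": self.map_params.pi_p,
            "pi_s": self.map_params.pi_s,
            "pi_stereo": self.map_params.pi_stereo,
            "omega2": self.map_params.hgf.omega2,
            "omega3": self.map_params.hgf.omega3,
            "log_evidence": self.log_evidence,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "hessian_condition": self.hessian_condition,
            "neg_log_joint": self.neg_log_joint,
        }


def _numerical_hessian(f, x: np.ndarray, step: float) -> np.ndarray:
    """Central finite-difference Hessian."""
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * step**2)
    return H


def fit_subject(
    data: tuple[TrialSequence, Sequence[ResponseRecord]],
    spec: ModelSpec,
    opts: FitOptions | None = None,
    base: ObserverParams | None = None,
) -> FitResult:
    """MAP-fit one subject under one model; Laplace log evidence at the optimum.

    Quasi-Newton (BFGS) with multistart around the prior mean; deterministic
    given ``opts.seed``.
    """
    opts = opts or FitOptions()
    base = base or ObserverParams()
    seq, responses = data
    cache = _SubjectCache(seq, responses, base)

    def objective(theta: np.ndarray) -> float:
        return negative_log_joint(theta, data, spec, base, cache)

    m = spec.prior_mean()
    sd = np.sqrt(spec.prior_var())
    rng = np.random.default_rng(opts.seed)
    starts = [m] + [m + sd * rng.standard_normal(len(m))
                    for _ in range(opts.n_starts - 1)]

    best = None
    n_used = 0
    any_converged = False
    for x0 in starts:
        n_used += 1
        res = optimize.minimize(objective, x0, method="BFGS",
                                options={"gtol": opts.gtol, "maxiter": opts.maxiter})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    theta = np.asarray(best.x, dtype=float)
    nlj = float(best.fun)

    d = len(theta)
    H = _numerical_hessian(objective, theta, opts.hessian_step)
    H = 0.5 * (H + H.T)
    sign, logdet = np.linalg.slogdet(H)
    eigvals = np.linalg.eigvalsh(H)
    cond = float(abs(eigvals).max() / max(abs(eigvals).min(), 1e-300))
    if sign <= 0 or not math.isfinite(logdet):
        logger.warning("singular/indefinite Hessian for model %s; evidence unavailable",
                       spec.label)
        log_evidence = float("nan")
    else:
        log_evidence = -nlj + 0.5 * d * LOG_2PI - 0.5 * logdet

    return FitResult(
        spec=spec,
        map_params=spec.to_params(theta, base),
        theta=theta,
        log_evidence=log_evidence,
        converged=any_converged,
        n_restarts_used=n_used,
        hessian_condition=cond,
        neg_log_joint=nlj,
    )


def fit_model_space(
    datasets: Sequence[tuple[TrialSequence, Sequence[ResponseRecord]]],
    specs: Sequence[ModelSpec] | None = None,
    opts: FitOptions | None = None,
    base: ObserverParams | None = None,
    subject_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], FitResult]]:
    """Fit every subject under every model.

    Returns the subjects-by-models log-evidence matrix and the grid of
    :class:`FitResult`.  Per-cell failures are logged and recorded as NaN;
    the grid always completes.
    """
    if not datasets:
        raise ValueError("at least one subject required")
    specs = list(specs) if specs is not None else build_model_space()
    opts = opts or FitOptions()
    ids = list(subject_ids) if subject_ids is not None else [
        f"sub-{i+1:02d}" for i in range(len(datasets))
    ]
    evidence = pd.DataFrame(
        np.nan, index=ids, columns=[s.label for s in specs], dtype=float
    )
    fits: dict[tuple[str, str], FitResult] = {}
    for sid, data in zip(ids, datasets):
        for spec in specs:
            try:
                fit = fit_subject(data, spec, opts, base)
            except Exception as exc:  # per-cell failure must not abort the grid
                logger.warning("fit failed for %s / %s: %s", sid, spec.label, exc)
                continue
            fits[(sid, spec.label)] = fit
            evidence.loc[sid, spec.label] = fit.log_evidence
            logger.debug("%s %s logE=%.2f", sid, spec.label, fit.log_evidence)
        logger.info("fitted %s across %d models", sid, len(specs))
    return evidence, fits
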