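"""Random-effects Bayesian model selection (RFX-BMS).

Treats the model identity as a random effect across subjects: model
frequencies ``r`` in the population follow a Dirichlet distribution whose
concentration parameters are estimated from the subjects-by-models
log-evidence matrix by the standard variational scheme.  The exceedance
probability of model k is ``P(r_k > r_j for all j != k)`` under the
Dirichlet posterior, estimated by Monte Carlo.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import psi

logger = logging.getLogger(__name__)


class BMSConvergenceError(RuntimeError):
    """The variational Dirichlet iteration failed to converge."""


@dataclass
class BMSResult:
    """Posterior over model frequencies at the group level."""

    alpha: np.ndarray  # Dirichlet concentration parameters
    expected_prob: np.ndarray  # E[r] = alpha / sum(alpha)
    exceedance_prob: np.ndarray | None
    model_names: list[str]
    n_subjects: int
    n_mc_samples: int
    seed: int | None

    def ranked(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "model": self.model_names,
                "alpha": self.alpha,
                "expected_prob": self.expected_prob,
                "exceedance_prob": (
                    self.exceedance_prob
                    if self.exceedance_prob is not None
                    else np.nan
                ),
            }
        )
        return df.sort_values("expected_prob", ascending=False).reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "models": self.model_names,
            "alpha": self.alpha.tolist(),
            "expected_prob": self.expected_prob.tolist(),
            "exceedance_prob": (
                None if self.exceedance_prob is None
                else self.exceedance_prob.tolist()
            ),
            "n_subjects": self.n_subjects,
            "n_mc_samples": self.n_mc_samples,
            "seed": self.seed,
        }


def exceedance_prob(alpha: np.ndarray, n_samples: int = 1_000_000,
                    seed: int | None = 0) -> np.ndarray:
    """Monte-Carlo exceedance probabilities under Dirichlet(alpha).

    Component k is the probability that model k's population frequency
    exceeds every other model's.  Reproducible given ``seed``.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    if n_samples < 10_000:
        warnings.warn(
            f"n_samples={n_samples} gives large Monte-Carlo error for "
            f"{len(alpha)} models", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    winners = np.zeros(len(alpha))
    # draw in chunks to bound memory at ~tens of MB
    chunk = 200_000
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        r = rng.dirichlet(alpha, size=m)
        idx, counts = np.unique(np.argmax(r, axis=1), return_counts=True)
        winners[idx] += counts
        remaining -= m
    return winners / n_samples


def rfx_bms(
    log_evidence,
    alpha0: np.ndarray | float = 1.0,
    n_samples: int = 1_000_000,
    seed: int | None = 0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    compute_exceedance: bool = True,
) -> BMSResult:
    """Random-effects BMS over a subjects-by-models log-evidence matrix.

    Variational update: subject-wise model responsibilities
    ``u_nk ~ exp(logE_nk + psi(alpha_k) - psi(sum alpha))`` (normalized over
    models) and ``alpha = alpha0 + sum_n u_nk``, iterated to convergence.
    Subjects with any non-finite evidence are dropped with a warning.
    """
    if isinstance(log_evidence, pd.DataFrame):
        names = [str(c) for c in log_evidence.columns]
        lme = log_evidence.to_numpy(dtype=float)
    else:
        lme = np.asarray(log_evidence, dtype=float)
        if lme.ndim == 1:
            lme = lme[None, :]
        names = [f"model-{k+1}" for k in range(lme.shape[1])]

    finite = np.isfinite(lme).all(axis=1)
    if not finite.all():
        warnings.warn(
            f"dropping {int((~finite).sum())} subject(s) with missing "
            "evidence from BMS", stacklevel=2,
        )
        lme = lme[finite]
    n, K = lme.shape
    if n == 0:
        raise ValueError("no subjects with complete evidence")

    alpha0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (K,)).copy()
    if np.any(alpha0 <= 0):
        raise ValueError("alpha0 must be positive")

    alpha = alpha0.copy()
    for iteration in range(max_iter):
        log_u = lme + psi(alpha) - psi(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise BMSConvergenceError(
            f"RFX-BMS did not converge in {max_iter} iterations "
            f"(last alpha = {alpha})"
        )
    logger.debug("RFX-BMS converged in %d iterations", iteration + 1)

    xp = exceedance_prob(alpha, n_samples, seed) if compute_exceedance else None
    return BMSResult(
        alpha=alpha,
        expected_prob=alpha / alpha.sum(),
        exceedance_prob=xp,
        model_names=names,
        n_subjects=n,
        n_mc_samples=n_samples if compute_exceedance else 0,
        seed=seed,
    )
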