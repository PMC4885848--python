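"""End-to-end analysis pipeline on synthetic cohorts.

Stages: simulate a cohort of synthetic observers performing the
reversal-learning task, fit each subject under the 8-model space, compare
the models by random-effects BMS, and summarize the behavioral biases and
their correlation with the fitted precisions.  Every stage derives its
randomness from one global seed via ``numpy.random.SeedSequence`` so that
each stage (and each subject) can be rerun bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import behavior
from .hgf import HGFParams
from .inversion import FitOptions, FitResult, build_model_space, fit_model_space
from .observer import ConfidenceModel, ObserverParams, RTModel, simulate_observer
from .selection import BMSResult, rfx_bms
from .task import DesignConfig, ResponseRecord, TrialSequence, generate_sequence, \
    read_trials, write_trials

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to regenerate an analysis bit-identically."""

    design: DesignConfig = field(default_factory=DesignConfig)
    observer: ObserverParams = field(default_factory=ObserverParams)
    rt_model: RTModel = field(default_factory=RTModel)
    confidence_model: ConfidenceModel = field(default_factory=ConfidenceModel)
    fit_opts: FitOptions = field(default_factory=FitOptions)
    cohort_size: int = 31
    #: log-scale sd of between-subject precision heterogeneity
    precision_spread: float = 0.5
    fit_learning_rate: bool = False
    alpha0: float = 1.0
    bms_samples: int = 1_000_000
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = self.design.to_dict()
        return d


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Fan a global seed out into per-stage/per-subject seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def sample_cohort_params(
    config: PipelineConfig, rng: np.random.Generator
) -> list[ObserverParams]:
    """Draw per-subject precisions around the cohort-level values.

    Heterogeneity is log-normal with sd ``precision_spread`` around the
    configured observer precisions, mirroring the inversion priors' scale.
    """
    base = config.observer
    out = []
    for _ in range(config.cohort_size):
        jit = rng.standard_normal(4) * config.precision_spread
        out.append(
            replace(
                base,
                pi_a=base.pi_a * float(np.exp(jit[0])),
                pi_p=base.pi_p * float(np.exp(jit[1])),
                pi_s=base.pi_s * float(np.exp(jit[2])),
                pi_stereo=base.pi_stereo * float(np.exp(jit[3])),
            )
        )
    return out


@dataclass
class CohortData:
    """A simulated cohort held in memory."""

    sequences: list[TrialSequence]
    responses: list[list[ResponseRecord]]
    true_params: list[ObserverParams]
    subject_ids: list[str]

    def datasets(self) -> list[tuple[TrialSequence, list[ResponseRecord]]]:
        return list(zip(self.sequences, self.responses))


def simulate_cohort(config: PipelineConfig | None = None) -> CohortData:
    """Simulate a cohort of synthetic observers (deterministic given config.seed)."""
    config = config or PipelineConfig()
    seeds = _stage_seeds(config.seed, 2 * config.cohort_size + 1)
    param_rng = np.random.default_rng(seeds[-1])
    true_params = sample_cohort_params(config, param_rng)
    sequences, responses, ids = [], [], []
    for i in range(config.cohort_size):
        seq = generate_sequence(config.design, seed=seeds[2 * i])
        recs = simulate_observer(seq, true_params[i], rng_seed=seeds[2 * i + 1],
                                 rt_model=config.rt_model,
                                 confidence_model=config.confidence_model)
        sequences.append(seq)
        responses.append(recs)
        ids.append(f"sub-{i+1:02d}")
        logger.debug("simulated %s", ids[-1])
    logger.info("simulated cohort of %d subjects x %d trials",
                config.cohort_size, config.design.n_trials)
    return CohortData(sequences, responses, true_params, ids)


def cmd_simulate(config: PipelineConfig, out_dir) -> CohortData:
    """Simulate a cohort and write per-subject trial CSVs plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    for sid, seq, recs in zip(cohort.subject_ids, cohort.sequences, cohort.responses):
        write_trials(seq, out / f"{sid}_trials.csv", recs)
    manifest = {
        "config": config.to_dict(),
        "subjects": cohort.subject_ids,
        "true_params": [
            {"pi_a": p.pi_a, "pi_p": p.pi_p, "pi_s": p.pi_s,
             "pi_stereo": p.pi_stereo}
            for p in cohort.true_params
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cohort


def load_cohort_dir(data_dir) -> tuple[list, list[str]]:
    """Read every subject trial CSV in a directory."""
    paths = sorted(Path(data_dir).glob("*_trials.csv"))
    if not paths:
        raise FileNotFoundError(f"no *_trials.csv files in {data_dir}")
    datasets, ids = [], []
    for p in paths:
        seq, recs = read_trials(p)
        if recs is None:
            logger.warning("%s has no responses; skipping", p.name)
            continue
        datasets.append((seq, recs))
        ids.append(p.name.replace("_trials.csv", ""))
    return datasets, ids


def cmd_fit(data_dir, config: PipelineConfig, out_dir=None):
    """Fit every subject in a data directory under the 8-model space."""
    datasets, ids = load_cohort_dir(data_dir)
    specs = build_model_space(config.fit_learning_rate)
    evidence, fits = fit_model_space(datasets, specs, config.fit_opts,
                                     config.observer, subject_ids=ids)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        evidence.to_csv(out / "evidence.csv", index_label="subject")
        for (sid, label), fit in fits.items():
            path = out / f"{sid}_{label.replace('+', 'p').replace('-', 'm')}.json"
            path.write_text(json.dumps(fit.to_dict(), indent=2))
    return evidence, fits


def cmd_bms(evidence, config: PipelineConfig, out_path=None) -> BMSResult:
    """Random-effects BMS over an evidence matrix (DataFrame or CSV path)."""
    if not isinstance(evidence, pd.DataFrame):
        evidence = pd.read_csv(evidence, index_col=0)
    result = rfx_bms(evidence, alpha0=config.alpha0,
                     n_samples=config.bms_samples, seed=config.seed)
    if out_path is not None:
        Path(out_path).write_text(json.dumps(result.to_dict(), indent=2))
    return result


def cmd_report(
    datasets: Sequence[tuple],
    subject_ids: Sequence[str],
    fits: dict | None = None,
    bms: BMSResult | None = None,
    out_dir=None,
    winning_label: str = "+A+P+S",
):
    """Per-subject behavioral metrics plus bias-precision correlations.

    Returns ``(metrics frame, summary dict)``.  When fits for the winning
    model are available, correlates the associative bias with the fitted
    ``log pi_a`` and with motor adaptation.
    """
    if not datasets:
        raise ValueError("no datasets to report on")
    frames = []
    assoc_bias, adaptation, log_pi_a = [], [], []
    for sid, (seq, recs) in zip(subject_ids, datasets):
        frames.append(behavior.subject_metrics(seq, recs, sid))
        labels = behavior.label_expectations(seq, recs)
        assoc_bias.append(behavior.perceptual_bias(labels, "assoc").bias_percent)
        adaptation.append(behavior.motor_adaptation(seq, recs))
        if fits is not None and (sid, winning_label) in fits:
            pi_a = fits[(sid, winning_label)].map_params.pi_a
            log_pi_a.append(np.log(pi_a) if pi_a > 0 else np.nan)
        else:
            log_pi_a.append(np.nan)
    metrics = pd.concat(frames, ignore_index=True)

    summary: dict = {
        "n_subjects": len(subject_ids),
        "mean_bias_percent": {
            src: float(np.nanmean(
                metrics.query("source == @src and ~high_conf_only")["bias_percent"]
            ))
            for src in behavior.SOURCES
        },
        "mean_motor_adaptation": float(np.nanmean(adaptation)),
    }
    try:
        r, p = behavior.bias_precision_correlation(assoc_bias, adaptation)
        summary["bias_vs_motor_adaptation"] = {"r": r, "p": p}
    except ValueError:
        pass
    if np.isfinite(log_pi_a).sum() >= 3:
        r, p = behavior.bias_precision_correlation(assoc_bias, log_pi_a)
        summary["bias_vs_log_pi_a"] = {"r": r, "p": p}
    if bms is not None:
        ranked = bms.ranked()
        summary["winning_model"] = str(ranked.loc[0, "model"])
        summary["winning_exceedance_prob"] = float(ranked.loc[0, "exceedance_prob"])
        summary["model_ranking"] = ranked["model"].tolist()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return metrics, summary


def run_pipeline(config: PipelineConfig | None = None, out_dir=None):
    """Simulate, fit, select and report in one call; returns the summary dict."""
    config = config or PipelineConfig()
    cohort = simulate_cohort(config)
    specs = build_model_space(config.fit_learning_rate)
    evidence, fits = fit_model_space(cohort.datasets(), specs, config.fit_opts,
                                     config.observer,
                                     subject_ids=cohort.subject_ids)
    bms = rfx_bms(evidence, alpha0=config.alpha0, n_samples=config.bms_samples,
                  seed=config.seed)
    metrics, summary = cmd_report(cohort.datasets(), cohort.subject_ids, fits,
                                  bms, out_dir=out_dir)
    summary["evidence"] = evidence.to_dict()
    return cohort, evidence, fits, bms, metrics, summary
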