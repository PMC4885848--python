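"""Model-free behavioral measures of expectation-induced perceptual biases.

For each ambiguous test trial, an expected rotation direction is defined
from three sources:

* **associative learning** — the direction implied by the current tone and
  the currently predominant tone-rotation association;
* **priming** — the perceived direction on the unambiguous trial directly
  preceding the ambiguous trial;
* **sensory memory** — the perceived direction on the most recent previous
  ambiguous trial.

The perceptual bias for a source is the percentage of ambiguous trials
perceived congruently with the expectation minus the percentage perceived
incongruently.  Motor adaptation is the normalized reaction-time advantage
for expectation-congruent unambiguous stimuli.  Incorrect or missed
responses on unambiguous trials are excluded before labeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import ASSOCIATION_MAP, ResponseRecord, TrialSequence

SOURCES = ("assoc", "priming", "memory")


@dataclass
class BiasSummary:
    """Perceptual bias of one subject for one expectation source."""

    source: str
    bias_percent: float  # congruent% - incongruent%, in [-100, 100]; NaN if undefined
    n_congruent: int
    n_incongruent: int
    high_confidence_only: bool

    @property
    def defined(self) -> bool:
        return self.n_congruent + self.n_incongruent > 0


def _usable(trial, record: ResponseRecord) -> bool:
    """Responses retained for analysis: present, and correct when unambiguous."""
    if record.percept is None:
        return False
    if trial.trial_type == "unambiguous" and record.correct is False:
        return False
    return True


def label_expectations(
    seq: TrialSequence, responses: Sequence[ResponseRecord]
) -> pd.DataFrame:
    """Expected direction per source for every ambiguous trial.

    Returns a frame indexed by trial index with columns ``assoc``,
    ``priming``, ``memory``, ``percept`` and ``confidence``; undefined
    expectations (no usable history yet) are NaN.  The associative label is
    defined on every ambiguous trial.
    """
    if len(responses) != len(seq):
        raise ValueError(f"{len(responses)} responses for {len(seq)} trials")
    rows = []
    last_unamb_percept: float = math.nan
    last_amb_percept: float = math.nan
    for trial, rec in zip(seq, responses):
        if trial.trial_type == "ambiguous":
            expected_rot = ASSOCIATION_MAP[trial.predominant_association][trial.tone]
            rows.append(
                {
                    "trial": trial.index,
                    "assoc": 1.0 if expected_rot == "right" else 0.0,
                    "priming": last_unamb_percept,
                    "memory": last_amb_percept,
                    "percept": math.nan if rec.percept is None else float(rec.percept),
                    "confidence": math.nan if rec.confidence is None else rec.confidence,
                }
            )
        if _usable(trial, rec):
            if trial.trial_type == "unambiguous":
                last_unamb_percept = float(rec.percept)
            else:
                last_amb_percept = float(rec.percept)
    return pd.DataFrame(rows).set_index("trial")


def perceptual_bias(
    labels: pd.DataFrame,
    source: str,
    confidence_filter: str = "all",
) -> BiasSummary:
    """Congruent-minus-incongruent percentage for one expectation source.

    ``confidence_filter`` is "all" or "level4_only" (only trials rated at
    the highest confidence level).  Trials with an undefined label or a
    missing percept never count toward either side.
    """
    if source not in SOURCES:
        raise ValueError(f"source must be one of {SOURCES}, got {source!r}")
    if confidence_filter not in ("all", "level4_only"):
        raise ValueError(f"invalid confidence_filter {confidence_filter!r}")
    df = labels.dropna(subset=[source, "percept"])
    if confidence_filter == "level4_only":
        df = df[df["confidence"] == 4]
    n_con = int((df["percept"] == df[source]).sum())
    n_inc = int((df["percept"] != df[source]).sum())
    total = n_con + n_inc
    bias = 100.0 * (n_con - n_inc) / total if total else math.nan
    return BiasSummary(source, bias, n_con, n_inc,
                       confidence_filter == "level4_only")


def motor_adaptation(
    seq: TrialSequence, responses: Sequence[ResponseRecord]
) -> float:
    """Normalized RT advantage for association-congruent unambiguous stimuli.

    ``(mean RT congruent - mean RT incongruent) / mean RT all unambiguous``;
    negative values mean faster responses to stimuli matching the currently
    predominant association.  Unitless.  NaN when either class is empty.
    """
    con, inc = [], []
    for trial, rec in zip(seq, responses):
        if trial.trial_type != "unambiguous" or not _usable(trial, rec):
            continue
        if rec.rt is None:
            continue
        (con if trial.congruent_with_block else inc).append(rec.rt)
    if not con or not inc:
        return math.nan
    all_rt = con + inc
    return (float(np.mean(con)) - float(np.mean(inc))) / float(np.mean(all_rt))


def bias_precision_correlation(
    biases: Sequence[float], precisions: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between per-subject biases and a model parameter.

    Pairs with an undefined entry are dropped; requires at least 3 complete
    pairs.  Returns ``(r, p)``; ``(nan, nan)`` when either vector has zero
    variance.
    """
    x = np.asarray(biases, dtype=float)
    y = np.asarray(precisions, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, have {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def subject_metrics(
    seq: TrialSequence,
    responses: Sequence[ResponseRecord],
    subject: str = "sub-01",
) -> pd.DataFrame:
    """All bias measures for one subject as a tidy frame."""
    labels = label_expectations(seq, responses)
    rows = []
    adaptation = motor_adaptation(seq, responses)
    for source in SOURCES:
        for flt in ("all", "level4_only"):
            b = perceptual_bias(labels, source, flt)
            rows.append(
                {
                    "subject": subject,
                    "source": source,
                    "bias_percent": b.bias_percent,
                    "n_congruent": b.n_congruent,
                    "n_incongruent": b.n_incongruent,
                    "high_conf_only": b.high_confidence_only,
                    "motor_adaptation": adaptation,
                }
            )
    return pd.DataFrame(rows)
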