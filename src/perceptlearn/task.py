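"""Probabilistic reversal-learning task sequences for bistable perception.

The experiment couples an auditory cue (high- or low-pitched tone) with the
rotation direction of a structure-from-motion sphere.  Within a contingency
block one tone-rotation association predominates (75% of trials), a minority
of unambiguous trials carry the reversed association (12.5%), and ambiguous
test trials without disparity cues (12.5%) probe perception.  The
predominant association reverses between blocks of 16, 24 or 32 trials, and
every ambiguous test trial is preceded by at least three consecutive
unambiguous trials congruent with the current association.

Rotation coding is ``right = 1, left = 0`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

TONES = ("high", "low")
TRIAL_TYPES = ("unambiguous", "ambiguous")
ROTATIONS = ("left", "right", "none")
ASSOCIATIONS = ("highleft", "highright")

#: mapping from predominant association -> {tone: rotation}
ASSOCIATION_MAP = {
    "highleft": {"high": "left", "low": "right"},
    "highright": {"high": "right", "low": "left"},
}

RIGHT, LEFT = 1, 0


class DesignError(ValueError):
    """Raised when a task design is infeasible or violated."""


@dataclass(frozen=True)
class Trial:
    """One trial of the reversal-learning task."""

    run: int
    index: int  # 1-based within the experiment
    tone: str  # "high" | "low"
    trial_type: str  # "unambiguous" | "ambiguous"
    true_rotation: str  # "left" | "right" | "none" (none iff ambiguous)
    block_id: int
    predominant_association: str  # "highleft" | "highright"
    congruent_with_block: bool | None  # None on ambiguous trials

    def __post_init__(self) -> None:
        if (self.trial_type == "ambiguous") != (self.true_rotation == "none"):
            raise DesignError(
                f"trial {self.index}: trial_type {self.trial_type!r} inconsistent "
                f"with true_rotation {self.true_rotation!r}"
            )
        if self.trial_type == "ambiguous" and self.congruent_with_block is not None:
            raise DesignError(
                f"trial {self.index}: congruent_with_block must be None on ambiguous trials"
            )


@dataclass(frozen=True)
class ResponseRecord:
    """A subject's response on one trial.

    ``percept`` uses the right=1/left=0 coding; ``correct`` is None on
    ambiguous trials (there is no objectively correct answer) and None when
    the response is missing.
    """

    percept: int | None  # 1 = rightward, 0 = leftward, None = missed
    rt: float | None  # seconds
    confidence: int | None  # 1..4, 4 = "very sure"
    correct: bool | None

    def __post_init__(self) -> None:
        if self.percept is not None and self.percept not in (0, 1):
            raise ValueError(f"percept must be 0/1/None, got {self.percept!r}")
        if self.confidence is not None and self.confidence not in (1, 2, 3, 4):
            raise ValueError(f"confidence must be in 1..4, got {self.confidence!r}")
        if self.rt is not None and not self.rt > 0:
            raise ValueError(f"rt must be positive, got {self.rt!r}")


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the task design (defaults reproduce the original task)."""

    n_trials: int = 576
    n_runs: int = 6
    block_lengths: tuple[int, ...] = (16, 24, 32)
    p_predominant: float = 0.75
    p_reversed: float = 0.125
    p_ambiguous: float = 0.125
    min_congruent_before_test: int = 3

    def __post_init__(self) -> None:
        total = self.p_predominant + self.p_reversed + self.p_ambiguous
        if abs(total - 1.0) > 1e-12:
            raise DesignError(f"trial-type proportions must sum to 1, got {total}")
        if self.n_trials % self.n_runs != 0:
            raise DesignError("n_trials must be divisible by n_runs")
        for length in self.block_lengths:
            for p in (self.p_predominant, self.p_reversed, self.p_ambiguous):
                count = p * length
                if abs(count - round(count)) > 1e-9:
                    raise DesignError(
                        f"block length {length} does not yield integer trial-type "
                        f"counts for proportion {p}"
                    )

    @property
    def run_length(self) -> int:
        return self.n_trials // self.n_runs

    def block_counts(self, length: int) -> tuple[int, int, int]:
        """(n_predominant, n_reversed, n_ambiguous) for a block of `length`."""
        n_amb = round(self.p_ambiguous * length)
        n_rev = round(self.p_reversed * length)
        return length - n_rev - n_amb, n_rev, n_amb

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_runs": self.n_runs,
            "block_lengths": list(self.block_lengths),
            "p_predominant": self.p_predominant,
            "p_reversed": self.p_reversed,
            "p_ambiguous": self.p_ambiguous,
            "min_congruent_before_test": self.min_congruent_before_test,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        d = dict(d)
        if "block_lengths" in d:
            d["block_lengths"] = tuple(d["block_lengths"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TrialSequence:
    """An ordered experiment design."""

    trials: list[Trial]
    design: DesignConfig | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": [t.run for t in self.trials],
                "trial": [t.index for t in self.trials],
                "tone": [t.tone for t in self.trials],
                "trial_type": [t.trial_type for t in self.trials],
                "true_rotation": [t.true_rotation for t in self.trials],
                "block_id": [t.block_id for t in self.trials],
                "predominant_association": [
                    t.predominant_association for t in self.trials
                ],
            }
        )


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    first_offending_trial: int | None = None
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[ValidationCheck]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __str__(self) -> str:
        lines = []
        for c in self.checks:
            status = "PASS" if c.passed else "FAIL"
            extra = "" if c.passed else f" (first offending trial {c.first_offending_trial}: {c.detail})"
            lines.append(f"[{status}] {c.name}{extra}")
        return "\n".join(lines)


def _run_block_lengths(run_length: int, lengths: Sequence[int], rng: np.random.Generator) -> list[int]:
    """Sample a random tiling of `run_length` with the allowed block lengths."""
    lengths = sorted(set(lengths))
    # representable[s] == True if s can be tiled by the allowed lengths
    representable = np.zeros(run_length + 1, dtype=bool)
    representable[0] = True
    for s in range(1, run_length + 1):
        representable[s] = any(s >= l and representable[s - l] for l in lengths)
    if not representable[run_length]:
        raise DesignError(
            f"run length {run_length} cannot be tiled by block lengths {lengths}"
        )
    out: list[int] = []
    remaining = run_length
    while remaining > 0:
        feasible = [l for l in lengths if l <= remaining and representable[remaining - l]]
        choice = int(rng.choice(feasible))
        out.append(choice)
        remaining -= choice
    return out


def _order_block(
    counts: tuple[int, int, int],
    min_congruent: int,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> list[str]:
    """Order trial kinds within a block.

    Returns a list over {"pred", "rev", "amb"} such that every "amb" is
    preceded (within the block) by at least `min_congruent` consecutive
    "pred" trials.
    """
    n_pred, n_rev, n_amb = counts
    kinds = ["pred"] * n_pred + ["rev"] * n_rev + ["amb"] * n_amb
    if n_amb == 0:
        rng.shuffle(kinds)
        return kinds
    for _ in range(max_attempts):
        rng.shuffle(kinds)
        ok = True
        for i, k in enumerate(kinds):
            if k != "amb":
                continue
            if i < min_congruent or any(
                kinds[j] != "pred" for j in range(i - min_congruent, i)
            ):
                ok = False
                break
        if ok:
            return kinds
    raise DesignError(
        f"could not order a block with counts {counts} under the "
        f">= {min_congruent}-congruent-before-test constraint "
        f"({max_attempts} attempts)"
    )


def generate_sequence(design: DesignConfig | None = None, seed: int = 0) -> TrialSequence:
    """Generate a pseudo-randomized trial sequence satisfying the task design.

    Blocks are nested within runs; the predominant tone-rotation association
    alternates between consecutive blocks, starting from a seeded coin flip.
    Deterministic given ``seed``.
    """
    design = design or DesignConfig()
    rng = np.random.default_rng(seed)
    association = ASSOCIATIONS[int(rng.integers(2))]

    trials: list[Trial] = []
    block_id = 0
    index = 1
    for run in range(1, design.n_runs + 1):
        for length in _run_block_lengths(design.run_length, design.block_lengths, rng):
            block_id += 1
            counts = design.block_counts(length)
            kinds = _order_block(counts, design.min_congruent_before_test, rng)
            mapping = ASSOCIATION_MAP[association]
            reversed_mapping = ASSOCIATION_MAP[
                "highright" if association == "highleft" else "highleft"
            ]
            for kind in kinds:
                tone = TONES[int(rng.integers(2))]
                if kind == "amb":
                    trial = Trial(run, index, tone, "ambiguous", "none",
                                  block_id, association, None)
                else:
                    rot = (mapping if kind == "pred" else reversed_mapping)[tone]
                    trial = Trial(run, index, tone, "unambiguous", rot,
                                  block_id, association, kind == "pred")
                trials.append(trial)
                index += 1
            association = "highright" if association == "highleft" else "highleft"
    return TrialSequence(trials, design=design, seed=seed)


def validate_sequence(seq: TrialSequence) -> ValidationReport:
    """Check a sequence against every design constraint; always returns a report."""
    design = seq.design or DesignConfig(n_trials=len(seq), n_runs=1)
    checks: list[ValidationCheck] = []

    checks.append(
        ValidationCheck(
            "total trial count",
            len(seq) == design.n_trials,
            None if len(seq) == design.n_trials else len(seq),
            f"expected {design.n_trials}, got {len(seq)}",
        )
    )

    # block lengths and per-block composition
    blocks: dict[int, list[Trial]] = {}
    for t in seq:
        blocks.setdefault(t.block_id, []).append(t)
    bad_len = None
    bad_comp = None
    for bid in sorted(blocks):
        block = blocks[bid]
        if len(block) not in design.block_lengths:
            bad_len = bad_len or block[0].index
            continue
        n_pred = sum(1 for t in block if t.congruent_with_block is True)
        n_rev = sum(1 for t in block if t.congruent_with_block is False)
        n_amb = sum(1 for t in block if t.trial_type == "ambiguous")
        if (n_pred, n_rev, n_amb) != design.block_counts(len(block)):
            bad_comp = bad_comp or block[0].index
    checks.append(
        ValidationCheck("block lengths in design set", bad_len is None, bad_len,
                        "block with disallowed length")
    )
    checks.append(
        ValidationCheck("block trial-type proportions", bad_comp is None, bad_comp,
                        "block composition deviates from design proportions")
    )

    # alternation of the predominant association
    bad_alt = None
    order = sorted(blocks)
    for prev, cur in zip(order, order[1:]):
        if blocks[prev][0].predominant_association == blocks[cur][0].predominant_association:
            bad_alt = blocks[cur][0].index
            break
    checks.append(
        ValidationCheck("association alternates between blocks", bad_alt is None,
                        bad_alt, "adjacent blocks share the association")
    )

    # >= min_congruent congruent unambiguous trials directly before each test trial
    bad_cong = None
    m = design.min_congruent_before_test
    for i, t in enumerate(seq):
        if t.trial_type != "ambiguous":
            continue
        window = seq.trials[max(0, i - m): i]
        ok = len(window) == m and all(
            w.trial_type == "unambiguous"
            and w.congruent_with_block is True
            and w.predominant_association == t.predominant_association
            for w in window
        )
        if not ok:
            bad_cong = t.index
            break
    checks.append(
        ValidationCheck(
            f">= {m} congruent unambiguous trials before each test trial",
            bad_cong is None, bad_cong, "insufficient congruent run-up",
        )
    )

    # internal consistency of tone/rotation vs association coding
    bad_code = None
    for t in seq:
        if t.trial_type != "unambiguous":
            continue
        expected = ASSOCIATION_MAP[t.predominant_association][t.tone]
        if (t.true_rotation == expected) != t.congruent_with_block:
            bad_code = t.index
            break
    checks.append(
        ValidationCheck("congruency flag matches tone-rotation coding",
                        bad_code is None, bad_code, "flag inconsistent")
    )
    return ValidationReport(checks)


CSV_COLUMNS = [
    "run", "trial", "tone", "trial_type", "true_rotation", "block_id",
    "predominant_association", "percept", "rt", "confidence",
]


def write_trials(
    seq: TrialSequence,
    path,
    responses: Sequence[ResponseRecord] | None = None,
) -> None:
    """Write a trial table (and optional responses) as CSV."""
    df = seq.to_frame()
    if responses is not None:
        if len(responses) != len(seq):
            raise ValueError(
                f"{len(responses)} responses for {len(seq)} trials"
            )
        df["percept"] = [r.percept for r in responses]
        df["rt"] = [r.rt for r in responses]
        df["confidence"] = [r.confidence for r in responses]
    else:
        df["percept"] = pd.NA
        df["rt"] = pd.NA
        df["confidence"] = pd.NA
    df.to_csv(path, index=False, columns=CSV_COLUMNS, float_format="%.17g")


def _parse_error(row: int, msg: str) -> ValueError:
    return ValueError(f"trial table row {row}: {msg}")


def read_trials(path) -> tuple[TrialSequence, list[ResponseRecord] | None]:
    """Read a trial table written by :func:`write_trials`.

    Returns the sequence and, when any response field is populated, the
    aligned list of :class:`ResponseRecord`.  Raises ``ValueError`` naming
    the first offending row on malformed input.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if df["trial"].duplicated().any():
        row = int(df.index[df["trial"].duplicated()][0])
        raise _parse_error(row, f"duplicated trial index {df['trial'].iloc[row]}")

    trials: list[Trial] = []
    for row, rec in enumerate(df.itertuples(index=False)):
        if rec.tone not in TONES:
            raise _parse_error(row, f"invalid tone {rec.tone!r}")
        if rec.trial_type not in TRIAL_TYPES:
            raise _parse_error(row, f"invalid trial_type {rec.trial_type!r}")
        if rec.true_rotation not in ROTATIONS:
            raise _parse_error(row, f"invalid true_rotation {rec.true_rotation!r}")
        if rec.predominant_association not in ASSOCIATIONS:
            raise _parse_error(
                row, f"invalid predominant_association {rec.predominant_association!r}"
            )
        if rec.trial_type == "unambiguous":
            congruent = (
                ASSOCIATION_MAP[rec.predominant_association][rec.tone]
                == rec.true_rotation
            )
        else:
            congruent = None
        try:
            trials.append(
                Trial(int(rec.run), int(rec.trial), rec.tone, rec.trial_type,
                      rec.true_rotation, int(rec.block_id),
                      rec.predominant_association, congruent)
            )
        except DesignError as exc:
            raise _parse_error(row, str(exc)) from exc

    responses: list[ResponseRecord] | None = None
    if df[["percept", "rt", "confidence"]].notna().any().any():
        responses = []
        for row, rec in enumerate(df.itertuples(index=False)):
            percept = None if pd.isna(rec.percept) else int(rec.percept)
            rt = None if pd.isna(rec.rt) else float(rec.rt)
            conf = None if pd.isna(rec.confidence) else int(rec.confidence)
            if percept is not None and percept not in (0, 1):
                raise _parse_error(row, f"invalid percept {rec.percept!r}")
            if conf is not None and conf not in (1, 2, 3, 4):
                raise _parse_error(row, f"invalid confidence {rec.confidence!r}")
            if rt is not None and rt <= 0:
                raise _parse_error(row, f"invalid rt {rec.rt!r}")
            trial = trials[row]
            if trial.trial_type == "ambiguous" or percept is None:
                correct = None
            else:
                correct = (percept == RIGHT) == (trial.true_rotation == "right")
            responses.append(ResponseRecord(percept, rt, conf, correct))

    inferred = None
    try:
        lengths = {len([t for t in trials if t.block_id == b])
                   for b in {t.block_id for t in trials}}
        inferred = DesignConfig(
            n_trials=len(trials),
            n_runs=len({t.run for t in trials}),
            block_lengths=tuple(sorted(lengths)),
        )
    except DesignError:
        pass  # nonstandard table: leave design unset rather than guess
    return TrialSequence(trials, design=inferred), responses
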