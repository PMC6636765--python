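"""Block and experiment assembly, and expansion into discrete event trains.

A block holds 25 eight-digit sequences: the first is the canonical 1..8, the
remaining 24 form eight contiguous sets of three sequences, each set sampled
at one generative precision.  Timing is fixed: each digit is shown for
250 ms followed by a 250 ms blank, and each sequence ends with a 1 s break
(four blank steps), so one sequence spans 20 quarter-second steps and a block
spans 500 steps (125 s).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import (
    INFINITY_SENTINEL,
    Sequence,
    TransitionModel,
    apply_precision,
    make_combination_sequence,
    sample_sequence,
)

__all__ = [
    "STEP_DURATION",
    "STEPS_PER_SEQUENCE",
    "SEQUENCES_PER_BLOCK",
    "STEPS_PER_BLOCK",
    "DEFAULT_OMEGA_SCHEDULE",
    "BlockSchedule",
    "EventTrain",
    "build_block",
    "build_experiment",
    "expand_to_events",
]

STEP_DURATION = 0.25          # seconds per event step (4 Hz)
STEPS_PER_SEQUENCE = 20       # 8 digit + 8 blank + 4 break steps
SEQUENCES_PER_BLOCK = 25
STEPS_PER_BLOCK = SEQUENCES_PER_BLOCK * STEPS_PER_SEQUENCE  # 500 steps = 125 s

#: Default per-set generative precisions: rising-then-falling volatility.
#: The four levels give on average about 0, 0.8, 1.9 and 2.4 aberrant
#: transitions per accepted sequence (the lowest level saturates below 3
#: because acceptance requires the chain to finish in exactly 20 steps).
DEFAULT_OMEGA_SCHEDULE = (INFINITY_SENTINEL, 0.39, 0.195, 0.04, 0.04, 0.195, 0.39, INFINITY_SENTINEL)


@dataclass
class BlockSchedule:
    """25 ordered sequences with their volatility-set assignment."""

    sequences: list[Sequence]
    set_index: list[int]        # per sequence; -1 for the leading 1..8
    omega: list[float]          # generative precision per sequence
    target_digit: int
    condition: str              # "basic" | "combination"

    def __post_init__(self) -> None:
        if len(self.sequences) != SEQUENCES_PER_BLOCK:
            raise ValueError("a block must contain exactly 25 sequences")
        if self.condition not in ("basic", "combination"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not (1 <= self.target_digit <= 8):
            raise ValueError("target digit must lie in 1..8")

    def with_target(self, target_digit: int) -> "BlockSchedule":
        """Same frozen sequences, different incidental-task target."""
        return dataclasses.replace(self, target_digit=target_digit)


@dataclass
class EventTrain:
    """A block unrolled into 250 ms steps with per-step outcome and flags.

    ``outcome`` holds 1..8 for digits and 0 for blanks (including breaks).
    Flags attach to digit steps only, except ``is_break`` which marks the
    four blank steps of the inter-sequence pause.
    """

    outcome: np.ndarray                # int, 0 = blank
    is_violation: np.ndarray           # bool
    is_likelihood_violation: np.ndarray
    is_target: np.ndarray
    is_break: np.ndarray
    sequence_index: np.ndarray         # 0-based sequence within the train
    omega_gen: np.ndarray              # generative precision of the sequence
    step_duration: float = STEP_DURATION

    @property
    def total_steps(self) -> int:
        return len(self.outcome)

    @property
    def onset_s(self) -> np.ndarray:
        return np.arange(self.total_steps) * self.step_duration

    @property
    def duration_s(self) -> float:
        return self.total_steps * self.step_duration

    @staticmethod
    def concat(trains: list["EventTrain"]) -> "EventTrain":
        """Concatenate block trains into one experiment-long train.

        Sequence indices are re-numbered to stay strictly increasing.
        """
        offset = 0
        seq_idx = []
        for t in trains:
            seq_idx.append(t.sequence_index + offset)
            offset += t.sequence_index.max() + 1
        return EventTrain(
            outcome=np.concatenate([t.outcome for t in trains]),
            is_violation=np.concatenate([t.is_violation for t in trains]),
            is_likelihood_violation=np.concatenate([t.is_likelihood_violation for t in trains]),
            is_target=np.concatenate([t.is_target for t in trains]),
            is_break=np.concatenate([t.is_break for t in trains]),
            sequence_index=np.concatenate(seq_idx),
            omega_gen=np.concatenate([t.omega_gen for t in trains]),
            step_duration=trains[0].step_duration,
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "step_index": np.arange(self.total_steps),
                "onset_s": self.onset_s,
                "outcome": np.where(self.outcome == 0, "blank", self.outcome.astype(str)),
                "is_violation": self.is_violation.astype(int),
                "is_likelihood_violation": self.is_likelihood_violation.astype(int),
                "is_target": self.is_target.astype(int),
                "is_break": self.is_break.astype(int),
                "sequence_index": self.sequence_index,
                "omega_gen": self.omega_gen,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path) -> "EventTrain":
        df = pd.read_csv(path, sep="\t")
        outcome = np.where(df["outcome"].astype(str) == "blank", 0, df["outcome"]).astype(int)
        return EventTrain(
            outcome=outcome,
            is_violation=df["is_violation"].to_numpy(bool),
            is_likelihood_violation=df["is_likelihood_violation"].to_numpy(bool),
            is_target=df["is_target"].to_numpy(bool),
            is_break=df["is_break"].to_numpy(bool),
            sequence_index=df["sequence_index"].to_numpy(int),
            omega_gen=df["omega_gen"].to_numpy(float),
        )


def _canonical_sequence(model: TransitionModel, rng: np.random.Generator) -> Sequence:
    adj = apply_precision(model, INFINITY_SENTINEL)
    return sample_sequence(adj, model, rng)


def build_block(
    model: TransitionModel,
    omega_schedule=DEFAULT_OMEGA_SCHEDULE,
    condition: str = "basic",
    target_digit: int = 1,
    rng: np.random.Generator | None = None,
) -> BlockSchedule:
    """Assemble one 25-sequence block.

    Sequence 1 is always the canonical 1..8; sequences 2-25 fall into eight
    contiguous sets of three, each sampled from the transition matrix
    adjusted to that set's precision.  In the combination condition every
    sequence is post-processed by swapping two digits for different digits.
    The schedule is a frozen object, so it can be reused identically across
    blocks.
    """
    if len(omega_schedule) != 8:
        raise ValueError("omega_schedule must list 8 precisions")
    if any(not om > 0 for om in omega_schedule):
        raise ValueError("all precisions must be positive")
    rng = np.random.default_rng() if rng is None else rng

    sequences = [_canonical_sequence(model, rng)]
    set_index = [-1]
    omegas = [float(INFINITY_SENTINEL)]
    for s, om in enumerate(omega_schedule):
        adj = apply_precision(model, om)
        for _ in range(3):
            sequences.append(sample_sequence(adj, model, rng))
            set_index.append(s)
            omegas.append(float(om))
    if condition == "combination":
        sequences = [make_combination_sequence(seq, rng) for seq in sequences]
    return BlockSchedule(
        sequences=sequences,
        set_index=set_index,
        omega=omegas,
        target_digit=target_digit,
        condition=condition,
    )


def build_experiment(
    model: TransitionModel,
    omega_schedule=DEFAULT_OMEGA_SCHEDULE,
    n_blocks: int = 16,
    rng: np.random.Generator | None = None,
) -> list[BlockSchedule]:
    """Build a full experiment: half basic blocks, half combination blocks.

    One basic schedule is frozen and reused for the first half, and one
    combination schedule (derived from the same digit sequences) for the
    second half, so the stream of numbers is identical across blocks within
    each condition.  Target digits cycle deterministically 1..8 over blocks.
    """
    if n_blocks % 2 != 0:
        raise ValueError("n_blocks must be even (half basic, half combination)")
    rng = np.random.default_rng() if rng is None else rng
    basic = build_block(model, omega_schedule, "basic", target_digit=1, rng=rng)
    combo = BlockSchedule(
        sequences=[make_combination_sequence(seq, rng) for seq in basic.sequences],
        set_index=list(basic.set_index),
        omega=list(basic.omega),
        target_digit=1,
        condition="combination",
    )
    blocks = []
    for b in range(n_blocks):
        proto = basic if b < n_blocks // 2 else combo
        blocks.append(proto.with_target(b % 8 + 1))
    return blocks


def expand_to_events(block: BlockSchedule) -> EventTrain:
    """Unroll a block into its 500-step, 4 Hz event train.

    Each digit occupies one 250 ms step followed by one blank step; each
    sequence ends with four break steps (the 1 s pause).  Violation,
    likelihood-violation and target flags attach to the digit steps.
    """
    n = STEPS_PER_BLOCK
    outcome = np.zeros(n, dtype=int)
    is_violation = np.zeros(n, dtype=bool)
    is_lik = np.zeros(n, dtype=bool)
    is_target = np.zeros(n, dtype=bool)
    is_break = np.zeros(n, dtype=bool)
    seq_idx = np.zeros(n, dtype=int)
    omega_gen = np.zeros(n, dtype=float)

    step = 0
    for q, seq in enumerate(block.sequences):
        for pos, digit in enumerate(seq.digits):
            outcome[step] = digit
            is_violation[step] = seq.violations[pos]
            is_lik[step] = seq.likelihood_violations[pos]
            is_target[step] = digit == block.target_digit
            step += 2  # digit step + trailing blank step
        is_break[step : step + 4] = True
        step += 4
        lo, hi = q * STEPS_PER_SEQUENCE, (q + 1) * STEPS_PER_SEQUENCE
        seq_idx[lo:hi] = q
        omega_gen[lo:hi] = block.omega[q]
    assert step == n
    return EventTrain(
        outcome=outcome,
        is_violation=is_violation,
        is_likelihood_violation=is_lik,
        is_target=is_target,
        is_break=is_break,
        sequence_index=seq_idx,
        omega_gen=omega_gen,
    )
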