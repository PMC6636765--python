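"""Hidden Markov generative model for volatile number sequences.

The stimulus stream is a sequence of digits 1..8 separated by short blanks,
generated by a 20-state hidden Markov chain: eight number states (``n1..n8``),
eight post-number absence states (``a1..a8``) and four break absence states
(``b1..b4``) that make up the 1 s pause between sequences.  Number states emit
their digit; every absence and break state emits a blank.

Volatility is controlled by a precision (inverse-temperature) parameter
``omega`` that exponentiates the source transition matrix column-wise and
renormalises it: high ``omega`` yields near-deterministic dynamics (the
canonical 1..8 sequence), low ``omega`` makes aberrant transitions — a digit
repeating or stepping back — increasingly likely.

Matrices follow the column-stochastic convention ``B[i, j] = P(next = i |
current = j)``: columns sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "N_STATES",
    "N_OUTCOMES",
    "INFINITY_SENTINEL",
    "StateSpace",
    "TransitionModel",
    "AdjustedTransitions",
    "Sequence",
    "SamplingError",
    "build_source_model",
    "apply_precision",
    "sample_sequence",
    "count_violations",
    "make_combination_sequence",
    "matrix_to_csv",
    "matrix_from_csv",
]

N_STATES = 20
N_OUTCOMES = 9

#: Precisions at or above this value are treated as the deterministic
#: (argmax) limit.  Schedules use it as a serialisable stand-in for infinity.
INFINITY_SENTINEL = 1e5

_NUMBER_STATES = [f"n{k}" for k in range(1, 9)]
_ABSENCE_STATES = [f"a{k}" for k in range(1, 9)]
_BREAK_STATES = [f"b{k}" for k in range(1, 5)]

BLANK = "blank"


@dataclass(frozen=True)
class StateSpace:
    """Labels for the 20 hidden states and 9 observable outcomes."""

    labels: tuple[str, ...] = tuple(_NUMBER_STATES + _ABSENCE_STATES + _BREAK_STATES)
    outcome_labels: tuple[str, ...] = tuple(str(d) for d in range(1, 9)) + (BLANK,)

    def __post_init__(self) -> None:
        if len(self.labels) != N_STATES:
            raise ValueError(f"expected {N_STATES} states, got {len(self.labels)}")
        if len(self.outcome_labels) != N_OUTCOMES:
            raise ValueError(f"expected {N_OUTCOMES} outcomes")

    def index(self, label: str) -> int:
        return self.labels.index(label)


STATE_SPACE = StateSpace()

# Convenience indices into the canonical ordering.
_N = {k: k - 1 for k in range(1, 9)}          # n1..n8 -> 0..7
_A = {k: 7 + k for k in range(1, 9)}          # a1..a8 -> 8..15
_B = {k: 15 + k for k in range(1, 5)}         # b1..b4 -> 16..19
BLANK_OUTCOME = 8


@dataclass(frozen=True)
class TransitionModel:
    """Source likelihood (A) and transition (B) matrices of the task.

    ``A`` maps hidden states to outcomes (9 x 20, columns sum to one);
    ``B_source`` holds the source transition probabilities (20 x 20,
    column-stochastic) from which precision-adjusted matrices are derived.
    """

    A: np.ndarray
    B_source: np.ndarray
    p_correct: float
    states: StateSpace = STATE_SPACE

    def __post_init__(self) -> None:
        _check_column_stochastic(self.A, "A")
        _check_column_stochastic(self.B_source, "B_source")


@dataclass(frozen=True)
class AdjustedTransitions:
    """A precision-adjusted, renormalised transition matrix B-bar."""

    B_bar: np.ndarray
    omega: float

    def __post_init__(self) -> None:
        _check_column_stochastic(self.B_bar, "B_bar")


@dataclass
class Sequence:
    """One accepted eight-digit sequence with its hidden path and flags."""

    digits: list[int]
    states: list[int]
    violations: list[bool]
    likelihood_violations: list[bool] = field(default_factory=lambda: [False] * 8)
    omega: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.digits) != 8:
            raise ValueError("a sequence must contain exactly 8 digits")


class SamplingError(RuntimeError):
    """Raised when rejection sampling cannot produce an 8-digit sequence."""


def _check_column_stochastic(M: np.ndarray, name: str, tol: float = 1e-12) -> None:
    if np.any(M < 0):
        raise ValueError(f"{name} has negative entries")
    if not np.allclose(M.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError(f"columns of {name} must sum to 1")


def build_source_model(p_correct: float = 0.99) -> TransitionModel:
    """Construct the 20-state source transition model of the task.

    Number states move to their own absence state with probability one.
    Each absence state ``aK`` moves on to the next number (or, for ``a8``,
    into the break) with probability ``p_correct``; the remaining mass is
    split equally among the allowed alternatives — back to the previous
    number, plus an early entry to the break from ``a5``, ``a6`` and ``a7``
    so that too-long paths can still finish on time.  Break states step
    deterministically ``b1 -> b2 -> b3 -> b4 -> n1``.

    Parameters
    ----------
    p_correct : float
        Probability of the correct (numerically next) transition out of each
        absence state, in ``(0, 1]``.  Default 0.99.
    """
    if not (0.0 < p_correct <= 1.0):
        raise ValueError(f"p_correct must lie in (0, 1], got {p_correct}")

    B = np.zeros((N_STATES, N_STATES))
    # Numbers always give way to their own absence state.
    for k in range(1, 9):
        B[_A[k], _N[k]] = 1.0
    # Absence states: correct transition plus equally weighted alternatives.
    rem = 1.0 - p_correct
    for k in range(1, 8):
        alternatives = [_N[k]] + ([_B[1]] if k in (5, 6, 7) else [])
        B[_N[k + 1], _A[k]] = p_correct
        for alt in alternatives:
            B[alt, _A[k]] += rem / len(alternatives)
    B[_B[1], _A[8]] = p_correct
    B[_N[8], _A[8]] = rem
    # The 1 s break: a deterministic run of four blank states.
    B[_B[2], _B[1]] = 1.0
    B[_B[3], _B[2]] = 1.0
    B[_B[4], _B[3]] = 1.0
    B[_N[1], _B[4]] = 1.0

    A = np.zeros((N_OUTCOMES, N_STATES))
    for k in range(1, 9):
        A[k - 1, _N[k]] = 1.0
    for j in list(_A.values()) + list(_B.values()):
        A[BLANK_OUTCOME, j] = 1.0

    return TransitionModel(A=A, B_source=B, p_correct=p_correct)


def apply_precision(model: TransitionModel | np.ndarray, omega: float) -> AdjustedTransitions:
    """Exponentiate the source transition matrix by ``omega`` and renormalise.

    Each column is raised elementwise to the power ``omega`` on its support
    (zero entries stay exactly zero) and renormalised to sum to one.
    ``omega`` at or above :data:`INFINITY_SENTINEL` — or infinite — returns
    the deterministic one-hot (argmax) limit of each column.

    Parameters
    ----------
    model : TransitionModel or ndarray
        Source model, or a bare column-stochastic matrix.
    omega : float
        Precision (inverse temperature), strictly positive.
    """
    B = model.B_source if isinstance(model, TransitionModel) else np.asarray(model, float)
    if not omega > 0:
        raise ValueError(f"omega must be positive, got {omega}")

    if np.isinf(omega) or omega >= INFINITY_SENTINEL:
        out = np.zeros_like(B)
        out[np.argmax(B, axis=0), np.arange(B.shape[1])] = 1.0
        return AdjustedTransitions(B_bar=out, omega=float(omega))

    out = np.zeros_like(B)
    support = B > 0
    # Powers are taken on the support only: 0**omega diverges for omega < 1
    # under naive log-space exponentiation.
    for j in range(B.shape[1]):
        idx = support[:, j]
        col = B[idx, j] ** omega
        out[idx, j] = col / col.sum()
    return AdjustedTransitions(B_bar=out, omega=float(omega))


def sample_sequence(
    adj: AdjustedTransitions,
    model: TransitionModel,
    rng: np.random.Generator,
    max_iters: int = 20,
    max_retries: int = 1000,
) -> Sequence:
    """Rejection-sample one sequence of exactly eight digits.

    The chain starts in ``n1`` and is iterated ``max_iters`` (default 20)
    steps, emitting outcomes through the likelihood matrix.  A realisation is
    accepted only if it contains exactly eight digit outcomes, so every
    stimulus sequence has the same length; otherwise it is resampled, up to
    ``max_retries`` attempts.
    """
    if max_iters < 20:
        raise ValueError("max_iters must be at least 20")
    B_bar = adj.B_bar
    A = model.A
    cumB = np.cumsum(B_bar, axis=0)

    for _ in range(max_retries):
        path = [_N[1]]
        for _step in range(max_iters - 1):
            u = rng.random()
            path.append(int(np.searchsorted(cumB[:, path[-1]], u)))
        outcomes = [int(np.argmax(A[:, s])) for s in path]
        digits = [o + 1 for o in outcomes if o != BLANK_OUTCOME]
        if len(digits) == 8:
            violations = [False] + [digits[i] != digits[i - 1] + 1 for i in range(1, 8)]
            return Sequence(
                digits=digits,
                states=path,
                violations=violations,
                omega=adj.omega,
            )
    raise SamplingError(
        f"no 8-digit sequence found in {max_retries} attempts at omega={adj.omega}"
    )


def count_violations(seq: Sequence | list[int]) -> int:
    """Count aberrant transitions: digit positions 2..8 that are not previous + 1."""
    digits = seq.digits if isinstance(seq, Sequence) else list(seq)
    if len(digits) != 8:
        raise ValueError("a sequence must contain exactly 8 digits")
    return sum(digits[i] != digits[i - 1] + 1 for i in range(1, 8))


def make_combination_sequence(seq: Sequence, rng: np.random.Generator) -> Sequence:
    """Swap two random digits for different digits (imprecise-likelihood stimuli).

    Exactly two distinct positions are chosen uniformly and each digit is
    replaced by a uniform draw from 1..8 that differs from the digit it
    replaces.  The replaced positions are recorded as likelihood-violation
    flags; the transition-violation flags of the source sequence are kept,
    since they describe the generative path, not the displayed digits.
    """
    digits = list(seq.digits)
    positions = rng.choice(8, size=2, replace=False)
    lik = list(seq.likelihood_violations)
    for pos in positions:
        old = digits[pos]
        new = int(rng.integers(1, 8))  # 7 candidates, skip over the old digit
        if new >= old:
            new += 1
        digits[pos] = new
        lik[pos] = True
    return Sequence(
        digits=digits,
        states=list(seq.states),
        violations=list(seq.violations),
        likelihood_violations=lik,
        omega=seq.omega,
    )


def matrix_to_csv(M: np.ndarray, path, states: StateSpace = STATE_SPACE) -> None:
    """Write a state matrix as CSV with labelled header row and column."""
    if M.shape[0] == N_OUTCOMES:
        index = list(states.outcome_labels)
    else:
        index = list(states.labels)
    pd.DataFrame(M, index=index, columns=list(states.labels)).to_csv(path)


def matrix_from_csv(path) -> np.ndarray:
    """Read a labelled state matrix written by :func:`matrix_to_csv`."""
    return pd.read_csv(path, index_col=0).to_numpy(dtype=float)
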