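"""Ideal Bayesian observer: online inference of hidden states and volatility.

The observer inverts the same hidden Markov model that generates the
stimuli.  State inference is a gradient flow on log-space potentials ``v``
with posteriors ``s = softmax(v)``:

    dv_t = omega * (ln(B_bar @ s_{t-1}) + ln(B_bar.T @ s_{t+1}))
           + ln(A[o_t, :]) - ln(s_t)

where ``omega`` (the inferred transition precision) scales only the
empirical-prior messages from past and future: in a volatile world the
observer leans on sensory evidence, in a stable world on its predictions.

Volatility ``beta = 1 / omega`` is updated on a slower timescale from state
prediction errors ``eps`` accumulated over an inference window (one
sequence by default):

    dbeta = beta0 - sum_t ln(B_bar) . eps_t - beta

so that with zero prediction error the posterior volatility relaxes to the
prior ``beta0``, while surprising transitions (large errors on low
log-probability entries) push it above the prior and lower the inferred
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import BLANK_OUTCOME, TransitionModel, apply_precision

__all__ = [
    "PriorBelief",
    "ObserverSettings",
    "BeliefTrace",
    "infer_states",
    "prediction_errors",
    "update_volatility",
    "run_observer",
    "upsample_trace",
]

OBSERVER_RATE = 4.0   # Hz; one belief state per 250 ms stimulus step
TARGET_RATE = 10.0    # Hz; rate of the preprocessed pupil series

_LOG_FLOOR = -32.0


@dataclass(frozen=True)
class PriorBelief:
    """Prior belief over environmental volatility.

    ``beta0`` is the prior volatility; its inverse ``omega0 = 1 / beta0`` is
    the prior precision.  The implied prior density over precision is
    exponential, ``P(omega) ∝ beta0 * exp(-beta0 * omega)``.
    """

    beta0: float

    def __post_init__(self) -> None:
        if not self.beta0 > 0:
            raise ValueError(f"beta0 must be positive, got {self.beta0}")

    @property
    def omega0(self) -> float:
        return 1.0 / self.beta0

    @classmethod
    def from_precision(cls, omega0: float) -> "PriorBelief":
        return cls(beta0=1.0 / omega0)


@dataclass(frozen=True)
class ObserverSettings:
    """Numerical settings for the belief-updating scheme.

    flow_step : Euler step of the state gradient flow (fraction of the unit
        flow per iteration).
    max_flow_iters : iteration cap per inference window.
    flow_tol : convergence tolerance on the mean absolute change in ``s``.
    beta_step : Euler step of the volatility update (one step per window).
    beta_floor : positivity floor on ``beta``, preventing blow-ups of
        ``omega = 1 / beta``.
    """

    flow_step: float = 0.25
    max_flow_iters: int = 64
    flow_tol: float = 1e-6
    beta_step: float = 0.25
    beta_floor: float = 1e-3


@dataclass
class BeliefTrace:
    """Observer beliefs sampled at every 250 ms step of the stimulus."""

    s: np.ndarray                  # (n_steps, n_states) posterior per step
    o: np.ndarray                  # (n_steps,) observed outcome index
    beta: np.ndarray               # (n_steps,) posterior volatility
    rate: float = OBSERVER_RATE
    converged: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    epsilon: list = field(default_factory=list)   # per-window (T-1, n, n) errors

    @property
    def omega_inferred(self) -> np.ndarray:
        return 1.0 / self.beta

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.beta)) / self.rate

    @property
    def warnings(self) -> int:
        """Number of inference windows that hit the iteration cap."""
        return int((~self.converged).sum()) if self.converged.size else 0

    def to_csv(self, path, include_states: bool = False) -> None:
        data = {"time_s": self.time_s, "omega_inferred": self.omega_inferred, "beta": self.beta}
        if include_states:
            for i in range(self.s.shape[1]):
                data[f"s{i}"] = self.s[:, i]
        pd.DataFrame(data).to_csv(path, index=False)


def _safe_log(x: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(x, np.exp(_LOG_FLOOR)))


def _softmax_cols(v: np.ndarray) -> np.ndarray:
    v = v - v.max(axis=-1, keepdims=True)
    e = np.exp(v)
    return e / e.sum(axis=-1, keepdims=True)


def infer_states(
    outcomes: np.ndarray,
    A: np.ndarray,
    B_bar: np.ndarray,
    omega: float,
    iters: int = 64,
    step: float = 0.25,
    tol: float = 1e-6,
) -> tuple[np.ndarray, bool]:
    """Infer posterior state distributions for a window of outcomes.

    Runs the gradient flow on the log-space potentials until the mean
    absolute change in the posteriors drops below ``tol`` or ``iters`` is
    reached.  Edge steps simply drop the missing past or future message.

    Parameters
    ----------
    outcomes : array of outcome indices, one per 250 ms step.
    A : (n_outcomes, n_states) likelihood matrix.
    B_bar : (n_states, n_states) precision-adjusted transition matrix.
    omega : precision weighting the past/future messages.

    Returns
    -------
    (s, converged) : posteriors of shape (T, n_states) and a convergence flag.
    """
    outcomes = np.asarray(outcomes, dtype=int)
    if outcomes.ndim != 1 or len(outcomes) < 1:
        raise ValueError("outcomes must be a non-empty 1-D array")
    if not omega > 0:
        raise ValueError("omega must be positive")
    T, n = len(outcomes), B_bar.shape[0]
    ln_lik = _safe_log(A[outcomes, :])          # (T, n)

    v = np.zeros((T, n))
    s = _softmax_cols(v)
    converged = False
    for _ in range(iters):
        drive = ln_lik - _safe_log(s)
        if T > 1:
            msg = np.zeros((T, n))
            msg[1:] = _safe_log(s[:-1] @ B_bar.T)    # forward: B_bar @ s_{t-1}
            msg[:-1] += _safe_log(s[1:] @ B_bar)     # backward: B_bar.T @ s_{t+1}
            drive = drive + omega * msg
        v = v + step * drive
        s_new = _softmax_cols(v)
        if np.mean(np.abs(s_new - s)) < tol:
            s = s_new
            converged = True
            break
        s = s_new
    return s, converged


def prediction_errors(s_t: np.ndarray, s_next: np.ndarray, B_bar: np.ndarray) -> np.ndarray:
    """State prediction errors for one transition.

    Column ``i`` holds the difference between the posterior over the next
    state and the transition-predicted distribution given current state
    ``i``, weighted by the posterior probability of being in state ``i``:
    ``eps[:, i] = (s_next - B_bar[:, i]) * s_t[i]``.
    """
    s_t = np.asarray(s_t, float)
    s_next = np.asarray(s_next, float)
    return (s_next[:, None] - B_bar) * s_t[None, :]


def update_volatility(
    beta: float,
    prior: PriorBelief,
    epsilon: np.ndarray,
    B_bar: np.ndarray,
    step: float = 0.25,
    beta_floor: float = 1e-3,
) -> float:
    """One explicit-Euler step of the volatility dynamics.

    ``epsilon`` stacks the per-transition error matrices of an inference
    window, shape (T-1, n, n) (a single (n, n) matrix is accepted).  The
    elementwise log of ``B_bar`` is taken on its support only, with a -32
    floor; the drive is the sum of ``ln(B_bar) * eps`` over the window.
    With zero errors the fixed point is ``beta = beta0``.
    """
    if not beta > 0:
        raise ValueError("beta must be positive")
    eps = np.asarray(epsilon, float)
    if eps.ndim == 2:
        eps = eps[None]
    support = B_bar > 0
    lnB = np.where(support, _safe_log(B_bar), 0.0)
    drive = float(np.sum(lnB[None] * np.where(support[None], eps, 0.0)))
    beta_new = beta + step * (prior.beta0 - drive - beta)
    return max(beta_new, beta_floor)


def run_observer(
    events,
    model: TransitionModel,
    prior: PriorBelief,
    settings: ObserverSettings = ObserverSettings(),
    keep_epsilon: bool = False,
) -> BeliefTrace:
    """Simulate the observer over an event train at 4 Hz.

    Within each sequence window (20 steps including the break) states are
    inferred with the transition matrix adjusted to the current inferred
    precision ``omega = 1 / beta``; the prediction errors of the window then
    drive a single volatility update, so precision inference proceeds on a
    slower timescale than state inference.  Blank steps are treated as
    informative observations of the absence states.
    """
    outcomes = np.where(events.outcome == 0, BLANK_OUTCOME, events.outcome - 1)
    seq_idx = events.sequence_index
    n_steps = len(outcomes)
    n = model.B_source.shape[0]

    s_all = np.zeros((n_steps, n))
    beta_all = np.zeros(n_steps)
    conv = []
    eps_store: list = []

    beta = prior.beta0
    for q in np.unique(seq_idx):
        win = np.flatnonzero(seq_idx == q)
        omega = 1.0 / beta
        B_bar = apply_precision(model, omega).B_bar
        s, ok = infer_states(
            outcomes[win],
            model.A,
            B_bar,
            omega,
            iters=settings.max_flow_iters,
            step=settings.flow_step,
            tol=settings.flow_tol,
        )
        s_all[win] = s
        beta_all[win] = beta
        conv.append(ok)
        if len(win) > 1:
            eps = np.stack(
                [prediction_errors(s[t], s[t + 1], B_bar) for t in range(len(win) - 1)]
            )
            if keep_epsilon:
                eps_store.append(eps)
            beta = update_volatility(
                beta, prior, eps, B_bar, step=settings.beta_step, beta_floor=settings.beta_floor
            )
    return BeliefTrace(
        s=s_all,
        o=outcomes,
        beta=beta_all,
        converged=np.asarray(conv, dtype=bool),
        epsilon=eps_store,
    )


def upsample_trace(
    x: np.ndarray, rate_in: float = OBSERVER_RATE, rate_out: float = TARGET_RATE
) -> np.ndarray:
    """Linearly interpolate a series onto a faster sampling grid.

    The output spans the same total duration ``len(x) / rate_in`` (so a
    500-sample block trace at 4 Hz becomes 1250 samples at 10 Hz); samples
    beyond the last input time hold the final value.  Endpoints are
    preserved exactly.
    """
    x = np.asarray(x, float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to interpolate")
    n_out = int(round(len(x) / rate_in * rate_out))
    t_in = np.arange(len(x)) / rate_in
    t_out = np.arange(n_out) / rate_out
    return np.interp(t_out, t_in, x)
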