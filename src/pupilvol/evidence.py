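"""Convolution GLMs of pupil diameter and Bayesian model comparison.

Six candidate models of the 10 Hz pupil series are built from explanatory
variables convolved with a basis of five gamma-shaped pupillary response
kernels (plus a constant):

1. photic stimulation only (boxcar of digit presence) — the null model;
2. photic + interaction (mean-centred product of inferred precision and the
   photic boxcar);
3. photic + inferred precision;
4. photic + interaction + inferred precision;
5. photic + a slow exponential return to baseline after unexpected events
   (no tonic belief effects);
6. photic + the generative ("adjusted") precision of the stimulus schedule,
   as if the observer knew the volatility without inferring it.

Models are scored by the log marginal likelihood of a Bayesian linear model
with zero-mean coefficient priors, which penalises complexity as well as
rewarding accuracy.  A softmax over the evidences of model 3 across a grid
of prior precisions turns the same machinery into an estimator of a
subject's prior beliefs about volatility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist

from .markov import TransitionModel
from .observer import ObserverSettings, PriorBelief, run_observer, upsample_trace

__all__ = [
    "DEFAULT_GRID",
    "GammaBasis",
    "DesignMatrix",
    "EvidenceSurface",
    "PrecisionPosterior",
    "BayesGLMResult",
    "gamma_kernel",
    "rasterize_boxcar",
    "generative_precision_trace",
    "observer_precision_traces",
    "make_gamma_basis",
    "build_design",
    "bayes_glm",
    "softmax",
    "compare_models",
    "estimate_prior_precision",
    "confusion_matrix",
]

#: Default grid of prior precisions (beta^-1): 40 log-spaced points, 0.3-20.
DEFAULT_GRID = tuple(np.geomspace(0.3, 20.0, 40))

_HIRES_RATE = 1000  # exact rasterisation rate for 250 ms event steps


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = np.asarray(x, float)
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Gamma basis
# ---------------------------------------------------------------------------

def gamma_kernel(peak_time: float, shape: float, rate: float, tail_mass: float = 1e-4) -> np.ndarray:
    """One discrete gamma kernel, peak-normalised.

    ``h(t) ∝ t^(shape-1) exp(-t / theta)`` with the scale chosen so the mode
    sits at ``peak_time`` (mode = (shape - 1) * theta).  The kernel is
    truncated where the remaining distribution mass falls below
    ``tail_mass``.
    """
    if shape <= 1:
        raise ValueError("shape must exceed 1 so the kernel has an interior peak")
    theta = peak_time / (shape - 1.0)
    t_max = gamma_dist.ppf(1.0 - tail_mass, shape, scale=theta)
    t = np.arange(0.0, t_max, 1.0 / rate)
    h = t ** (shape - 1.0) * np.exp(-t / theta)
    return h / h.max()


@dataclass(frozen=True)
class GammaBasis:
    """Five gamma-shaped pupillary response kernels at 10 Hz."""

    kernels: tuple
    peak_times: tuple
    shape: float
    rate: float

    @property
    def widest(self) -> np.ndarray:
        return self.kernels[-1]

    def __len__(self) -> int:
        return len(self.kernels)


def make_gamma_basis(
    peak_times=(0.5, 1.0, 2.0, 4.0, 8.0), shape: float = 3.0, rate: float = 10.0
) -> GammaBasis:
    """Build the basis of five gamma kernels with increasing peak times."""
    peaks = tuple(float(p) for p in peak_times)
    if any(b <= a for a, b in zip(peaks, peaks[1:])):
        raise ValueError("peak times must be strictly increasing")
    kernels = tuple(gamma_kernel(p, shape, rate) for p in peaks)
    return GammaBasis(kernels=kernels, peak_times=peaks, shape=shape, rate=rate)


# ---------------------------------------------------------------------------
# Regressors and design matrices
# ---------------------------------------------------------------------------

def rasterize_boxcar(events, rate: float, mask=None, n_samples: int | None = None) -> np.ndarray:
    """Fractional-occupancy boxcar of flagged 250 ms steps at ``rate``.

    The train is rasterised exactly at 1000 Hz and mean-pooled down, so at
    10 Hz a digit step contributes fractional occupancy at bin edges.  With
    ``mask`` omitted the boxcar encodes digit presence (photic stimulation).
    """
    if _HIRES_RATE % int(rate) != 0:
        raise ValueError(f"rate {rate} must divide {_HIRES_RATE}")
    if mask is None:
        mask = events.outcome > 0
    samples_per_step = int(round(events.step_duration * _HIRES_RATE))
    hi = np.repeat(np.asarray(mask, float), samples_per_step)
    factor = _HIRES_RATE // int(rate)
    out = hi.reshape(-1, factor).mean(axis=1)
    if n_samples is not None:
        if len(out) < n_samples:
            out = np.pad(out, (0, n_samples - len(out)))
        out = out[:n_samples]
    return out


def generative_precision_trace(events, rate: float = 10.0) -> np.ndarray:
    """Step trace of the generative ("adjusted") precision, z-scaled.

    Each sequence contributes a constant level given by minus its generative
    volatility ``1 / omega`` (so the trace is high when the schedule is
    precise and bounded even at the deterministic sentinel), expanded to
    ``rate`` and z-scored.
    """
    level = -1.0 / np.asarray(events.omega_gen, float)
    samples_per_step = int(round(events.step_duration * _HIRES_RATE))
    hi = np.repeat(level, samples_per_step)
    factor = _HIRES_RATE // int(rate)
    out = hi.reshape(-1, factor).mean(axis=1)
    sd = out.std()
    return (out - out.mean()) / sd if sd > 0 else out - out.mean()


@dataclass
class DesignMatrix:
    """Convolved regressors for one candidate model, plus a constant."""

    X: np.ndarray
    column_labels: list
    model_id: int
    beta_inv_prior: float = float("nan")

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.column_labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _convolve_bank(x: np.ndarray, basis: GammaBasis, label: str) -> tuple[np.ndarray, list]:
    cols = [np.convolve(x, k)[: len(x)] for k in basis.kernels]
    labels = [f"{label}*gamma{i + 1}" for i in range(len(basis))]
    return np.column_stack(cols), labels


def _decay_regressor(events, rate: float, tau: float) -> np.ndarray:
    """Exponential return-to-baseline triggered at each unexpected event."""
    onsets = events.onset_s[events.is_violation | events.is_likelihood_violation]
    n = int(round(len(events.outcome) * events.step_duration * rate))
    t = np.arange(n) / rate
    out = np.zeros(n)
    for t0 in onsets:
        lag = t - t0
        out[lag >= 0] += np.exp(-lag[lag >= 0] / tau)
    return out


def build_design(
    model_id: int,
    events,
    precision_trace: np.ndarray | None,
    adjusted_precision: np.ndarray | None,
    basis: GammaBasis,
    beta_inv_prior: float = float("nan"),
    decay_tau: float = 5.0,
) -> DesignMatrix:
    """Build the convolution design matrix for one of the six models.

    Every explanatory variable is convolved with all five gamma kernels
    (causal convolution, truncated to the series length) and a constant
    column is appended, so model 3 — photic stimulation plus inferred
    precision — has 10 regressor columns plus the constant.  Continuous
    variables are mean-centred before convolution; the interaction is the
    mean-centred product of the precision trace and the photic boxcar.
    """
    if model_id not in (1, 2, 3, 4, 5, 6):
        raise ValueError(f"unknown model id {model_id}")
    rate = basis.rate
    photic = rasterize_boxcar(events, rate)
    variables: list[tuple[str, np.ndarray]] = [("photic", photic)]

    if model_id in (2, 3, 4):
        if precision_trace is None:
            raise ValueError(f"model {model_id} requires a precision trace")
        prec = np.asarray(precision_trace, float)[: len(photic)]
        prec_c = prec - prec.mean()
        if model_id in (2, 4):
            # Product of the centred precision and the boxcar, centred again:
            # a constant precision trace yields an identically zero column.
            inter = prec_c * photic
            variables.append(("interaction", inter - inter.mean()))
        if model_id in (3, 4):
            variables.append(("precision", prec_c))
    elif model_id == 5:
        variables.append(("decay", _decay_regressor(events, rate, decay_tau)))
    elif model_id == 6:
        if adjusted_precision is None:
            adjusted_precision = generative_precision_trace(events, rate)
        variables.append(("adjusted_precision", np.asarray(adjusted_precision, float)[: len(photic)]))

    blocks, labels = [], []
    for name, x in variables:
        cols, labs = _convolve_bank(x, basis, name)
        blocks.append(cols)
        labels.extend(labs)
    blocks.append(np.ones((len(photic), 1)))
    labels.append("const")
    return DesignMatrix(
        X=np.column_stack(blocks),
        column_labels=labels,
        model_id=model_id,
        beta_inv_prior=float(beta_inv_prior),
    )


# ---------------------------------------------------------------------------
# Bayesian linear model evidence
# ---------------------------------------------------------------------------

class BayesGLMResult(NamedTuple):
    log_evidence: float
    coefficients: np.ndarray
    r_squared: float


def bayes_glm(
    y: np.ndarray,
    X: "DesignMatrix | np.ndarray",
    prior_sd: float = 10.0,
    noise: str = "marginal",
    a0: float = 1e-3,
    b0: float = 1e-3,
    sigma2: float | None = None,
) -> BayesGLMResult:
    """Closed-form log marginal likelihood of a Gaussian linear model.

    Coefficients carry independent zero-mean normal priors of standard
    deviation ``prior_sd`` (conjugate scaling: in units of the noise
    standard deviation).  By default the noise variance is marginalised
    under a weak inverse-gamma prior (``a0``, ``b0``), giving the
    multivariate-t marginal of the normal-inverse-gamma model;
    ``noise="plugin"`` instead conditions on a fixed ``sigma2`` (the OLS
    residual variance when not given), with the prior sd then fixed in data
    units.

    Returns the log evidence, the posterior mean coefficients, and the R²
    of the posterior-mean fit.
    """
    Xm = X.X if isinstance(X, DesignMatrix) else np.asarray(X, float)
    y = np.asarray(y, float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    if len(y) != Xm.shape[0]:
        raise ValueError("y and X must have the same number of rows")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(Xm))):
        raise ValueError("inputs must be finite")
    if not prior_sd > 0:
        raise ValueError("prior_sd must be positive")

    n, p = Xm.shape
    s2 = prior_sd**2
    G = Xm.T @ Xm
    Xty = Xm.T @ y
    M = np.eye(p) + s2 * G                      # |I_n + s2 X X^T| via Woodbury
    sign, logdetM = np.linalg.slogdet(M)
    assert sign > 0
    Minv_Xty = np.linalg.solve(M, Xty)
    quad = float(y @ y - s2 * Xty @ Minv_Xty)   # y^T (I + s2 X X^T)^-1 y
    quad = max(quad, 0.0)
    coef = s2 * Minv_Xty                        # posterior mean (= ridge estimate)

    if noise == "marginal":
        log_ev = (
            -0.5 * n * np.log(2.0 * np.pi)
            - 0.5 * logdetM
            + a0 * np.log(b0)
            - gammaln(a0)
            + gammaln(a0 + 0.5 * n)
            - (a0 + 0.5 * n) * np.log(b0 + 0.5 * quad)
        )
    elif noise == "plugin":
        if sigma2 is None:
            resid = y - Xm @ np.linalg.lstsq(Xm, y, rcond=None)[0]
            sigma2 = float(resid @ resid) / max(n - p, 1)
        # N(y; 0, sigma2 I + s2 X X^T) through the same Woodbury identities.
        Ms = np.eye(p) + (s2 / sigma2) * G
        _, logdetMs = np.linalg.slogdet(Ms)
        quad_s = (y @ y - (s2 / sigma2) * Xty @ np.linalg.solve(Ms, Xty)) / sigma2
        log_ev = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdetMs + quad_s)
        coef = (s2 / sigma2) * np.linalg.solve(Ms, Xty)
    else:
        raise ValueError(f"unknown noise mode {noise!r}")

    fitted = Xm @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return BayesGLMResult(float(log_ev), coef, r2)


# ---------------------------------------------------------------------------
# Model comparison across the prior-precision grid
# ---------------------------------------------------------------------------

@dataclass
class EvidenceSurface:
    """Log model evidence over (model id x prior-precision grid)."""

    models: tuple
    grid: np.ndarray
    log_evidence: np.ndarray    # (n_models, n_grid)
    r_squared: np.ndarray       # (n_models, n_grid)

    def relative_evidence(self, reference: int = 1) -> np.ndarray:
        """Log evidence relative to a reference model (the null by default)."""
        ref = self.log_evidence[self.models.index(reference)]
        return self.log_evidence - ref[None, :]

    def posterior_model_prob(self) -> np.ndarray:
        """Softmax over models at each grid point (flat model priors)."""
        return softmax(self.log_evidence, axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        post = self.posterior_model_prob()
        rel = self.relative_evidence() if 1 in self.models else self.log_evidence
        for i, m in enumerate(self.models):
            for j, g in enumerate(self.grid):
                rows.append(
                    {
                        "model": m,
                        "beta_inv": g,
                        "log_evidence": self.log_evidence[i, j],
                        "relative_log_evidence": rel[i, j],
                        "posterior_prob": post[i, j],
                        "r_squared": self.r_squared[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PrecisionPosterior:
    """Softmax posterior over the prior-precision grid (model 3 evidence)."""

    grid: np.ndarray
    log_evidence: np.ndarray
    posterior: np.ndarray
    r_squared: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def map_value(self) -> float:
        return float(self.grid[int(np.argmax(self.posterior))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta_inv": self.grid, "log_evidence": self.log_evidence, "posterior": self.posterior}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _as_list(x) -> list:
    return list(x) if isinstance(x, (list, tuple)) else [x]


def observer_precision_traces(
    events,
    model: TransitionModel,
    grid=DEFAULT_GRID,
    settings: ObserverSettings = ObserverSettings(),
    rate: float = 10.0,
) -> dict:
    """Simulate the observer at each prior precision and up-sample to 10 Hz.

    ``events`` may be a single train or a list of block trains; for a list
    the returned dict maps each grid value to one trace per block, so a
    series averaged over blocks can be fitted with per-block designs
    averaged the same way.
    """
    events_list = _as_list(events)
    traces = {}
    for beta_inv in grid:
        per_block = [
            upsample_trace(
                run_observer(ev, model, PriorBelief.from_precision(beta_inv), settings).omega_inferred,
                rate_out=rate,
            )
            for ev in events_list
        ]
        traces[float(beta_inv)] = per_block if len(per_block) > 1 else per_block[0]
    return traces


def _averaged_design(
    model_id: int, events_list: list, prec_list: list, basis: GammaBasis, beta_inv: float
) -> DesignMatrix:
    """Average per-block design matrices (for series averaged over blocks)."""
    Xs, design = [], None
    for ev, prec in zip(events_list, prec_list):
        adjusted = generative_precision_trace(ev, basis.rate) if model_id == 6 else None
        design = build_design(model_id, ev, prec, adjusted, basis, beta_inv)
        Xs.append(design.X)
    return DesignMatrix(
        X=np.mean(Xs, axis=0),
        column_labels=design.column_labels,
        model_id=model_id,
        beta_inv_prior=float(beta_inv),
    )


def _prepare_design(design: DesignMatrix, residualize) -> np.ndarray:
    if residualize is None:
        return design.X
    X = design.X.copy()
    X[:, :-1] = residualize(X[:, :-1])  # the constant column is kept intact
    return X


def _fit_units(y, events, residualize) -> tuple[list, bool]:
    """Normalise (y, events, residualize) into independent fit units.

    Three call shapes are supported: one series with one train; one series
    with a list of block trains (the designs are averaged over blocks,
    matching a block-averaged series); or paired lists of series and trains
    whose log evidences are summed — e.g. one average per stimulus
    condition, which keeps the design exactly consistent with each series.

    The residualiser is applied to the series as well as, later, to the
    design columns: a Frisch-Waugh projection is only consistent when both
    sides are taken to the nuisance-orthogonal complement.
    """

    def prep(yi, r):
        yi = np.asarray(yi, float)
        return r(yi[:, None])[:, 0] if r is not None else yi

    if isinstance(y, (list, tuple)):
        events_list = _as_list(events)
        if len(events_list) != len(y):
            raise ValueError("paired fitting needs one event train per series")
        res_list = (
            list(residualize)
            if isinstance(residualize, (list, tuple))
            else [residualize] * len(y)
        )
        return [
            (prep(yi, r), [ev], r) for yi, ev, r in zip(y, events_list, res_list)
        ], True
    return [(prep(y, residualize), _as_list(events), residualize)], False


def _score_model(
    units: list,
    paired: bool,
    traces_g,
    basis: GammaBasis,
    model_id: int,
    beta_inv: float,
    prior_sd: float,
) -> tuple[float, float]:
    """Total log evidence (summed over units) and mean R2 for one model."""
    total, r2s = 0.0, []
    for k, (yk, evs, resk) in enumerate(units):
        if traces_g is None:
            prec = [None] * len(evs)
        else:
            tl = _as_list(traces_g)
            prec = [tl[k]] if paired else tl
        design = _averaged_design(model_id, evs, prec, basis, beta_inv)
        res = bayes_glm(yk, _prepare_design(design, resk), prior_sd=prior_sd)
        total += res.log_evidence
        r2s.append(res.r_squared)
    return total, float(np.mean(r2s))


def compare_models(
    y: np.ndarray,
    events,
    observer_traces: dict,
    basis: GammaBasis | None = None,
    models=(1, 2, 3, 4, 5, 6),
    prior_sd: float = 10.0,
    residualize=None,
) -> EvidenceSurface:
    """Score models 1-6 at every prior precision on the grid.

    ``observer_traces`` maps each grid value of the prior precision beta^-1
    to the observer's 10 Hz inferred-precision trace for these events.
    Models 1, 5 and 6 do not depend on inferred precision, so their evidence
    is computed once and repeated across the grid.  When the series was
    nuisance-regressed during preprocessing, pass the matching
    ``residualize`` projector (see ``preprocess.nuisance_projector``) so the
    design columns undergo the same projection as the data.
    """
    basis = make_gamma_basis() if basis is None else basis
    units, paired = _fit_units(y, events, residualize)
    grid = np.array(sorted(observer_traces), float)
    models = tuple(models)
    log_ev = np.zeros((len(models), len(grid)))
    r2 = np.zeros_like(log_ev)
    for i, m in enumerate(models):
        if m in (1, 5, 6):
            le, rr = _score_model(units, paired, None, basis, m, float("nan"), prior_sd)
            log_ev[i, :], r2[i, :] = le, rr
        else:
            for j, g in enumerate(grid):
                le, rr = _score_model(
                    units, paired, observer_traces[float(g)], basis, m, g, prior_sd
                )
                log_ev[i, j], r2[i, j] = le, rr
    return EvidenceSurface(models=models, grid=grid, log_evidence=log_ev, r_squared=r2)


def estimate_prior_precision(
    y: np.ndarray,
    events,
    observer_traces: dict,
    basis: GammaBasis | None = None,
    model_id: int = 3,
    prior_sd: float = 10.0,
    residualize=None,
) -> PrecisionPosterior:
    """Posterior over the prior precision beta^-1 from model-3 evidence.

    The log evidences of the chosen model across the grid are passed through
    a softmax (flat prior over grid values).  ``residualize`` applies the
    nuisance projection of the preprocessing to the design columns.
    """
    basis = make_gamma_basis() if basis is None else basis
    units, paired = _fit_units(y, events, residualize)
    grid = np.array(sorted(observer_traces), float)
    if len(grid) < 2:
        raise ValueError("grid must contain at least 2 prior precisions")
    log_ev = np.zeros(len(grid))
    r2 = np.zeros(len(grid))
    for j, g in enumerate(grid):
        log_ev[j], r2[j] = _score_model(
            units, paired, observer_traces[float(g)], basis, model_id, g, prior_sd
        )
    return PrecisionPosterior(grid=grid, log_evidence=log_ev, posterior=softmax(log_ev), r_squared=r2)


def confusion_matrix(
    beta_inv_values,
    n_reps: int = 4,
    noise_sd: float = 0.5,
    rng: np.random.Generator | None = None,
    model: TransitionModel | None = None,
    n_blocks: int = 2,
    basis: GammaBasis | None = None,
    settings: ObserverSettings = ObserverSettings(),
) -> np.ndarray:
    """Simulate-and-recover confusion matrix over prior precisions.

    For each generating value (rows) synthetic participants are simulated,
    pushed through the full preprocessing pipeline, and scored with
    :func:`estimate_prior_precision` over the candidate values (columns);
    posteriors are averaged over repetitions.  Rows sum to one, and diagonal
    dominance demonstrates that prior beliefs are identifiable from the data
    alone.
    """
    from . import synth  # deferred: synth builds its signals with this module
    from .preprocess import nuisance_projector, preprocess_block, zscore_and_average
    from .schedule import build_experiment, expand_to_events
    from .markov import build_source_model

    values = [float(v) for v in beta_inv_values]
    if len(values) < 2:
        raise ValueError("need at least 2 candidate values")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rng = np.random.default_rng() if rng is None else rng
    model = build_source_model() if model is None else model
    basis = make_gamma_basis() if basis is None else basis

    schedules = build_experiment(model, n_blocks=n_blocks, rng=rng)
    events = [expand_to_events(b) for b in schedules]
    # Blocks are scored per condition (basic / combination): the schedule is
    # frozen within each condition, so blocks average cleanly and the
    # candidate observer traces are shared by every repetition and value.
    conditions = sorted({b.condition for b in schedules})
    idx_by_cond = {c: [k for k, b in enumerate(schedules) if b.condition == c] for c in conditions}
    cond_events = [events[idx_by_cond[c][0]] for c in conditions]
    traces = observer_precision_traces(cond_events, model, values, settings)
    residualize = [
        nuisance_projector([events[k] for k in idx_by_cond[c]], basis.rate) for c in conditions
    ]

    out = np.zeros((len(values), len(values)))
    for i, true_val in enumerate(values):
        for _ in range(n_reps):
            cfg = synth.SyntheticConfig(
                beta_inv_true=true_val,
                noise_sd=noise_sd,
                n_blocks=n_blocks,
                seed=int(rng.integers(2**31)),
            )
            participant = synth.generate_participant(cfg, schedules, model, basis=basis)
            cleaned = [
                preprocess_block(ts, ev) for ts, ev in zip(participant.blocks, events)
            ]
            y_by_cond = []
            for c in conditions:
                _, mean_series = zscore_and_average([[cleaned[k] for k in idx_by_cond[c]]])
                y_by_cond.append(mean_series.samples)
            post = estimate_prior_precision(
                y_by_cond, cond_events, traces, basis, residualize=residualize
            )
            out[i] += post.posterior
        out[i] /= n_reps
    return out
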