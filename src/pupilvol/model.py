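"""Model/Results interface tying the pipeline together.

:class:`PupilGLM` is constructed from a preprocessed 10 Hz pupil series and
the event train it was recorded to; :meth:`PupilGLM.fit` simulates the ideal
observer across a grid of prior precisions, scores the six candidate
convolution GLMs by Bayesian model evidence, and returns a
:class:`PupilGLMResults` carrying the evidence surface, the posterior over
the subject's prior precision, fit diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evidence import (
    DEFAULT_GRID,
    GammaBasis,
    compare_models,
    estimate_prior_precision,
    make_gamma_basis,
    observer_precision_traces,
    softmax,
)
from .markov import TransitionModel, build_source_model
from .observer import ObserverSettings
from .preprocess import PupilTimeSeries

__all__ = ["PupilGLM", "PupilGLMResults"]


class PupilGLM:
    """Bayesian convolution-GLM comparison for one pupillometry series.

    Parameters
    ----------
    endog : array-like or PupilTimeSeries
        Preprocessed, z-scored pupil series at 10 Hz (typically the average
        over a participant's blocks).
    events : EventTrain
        The 4 Hz stimulus train the series is aligned to (one block, since
        the schedule repeats across blocks).
    grid : sequence of float
        Prior precisions (beta^-1) to evaluate, default 40 log-spaced
        points spanning 0.3-20.
    models : sequence of int
        Candidate model ids among 1-6.
    """

    def __init__(
        self,
        endog,
        events,
        grid=DEFAULT_GRID,
        models=(1, 2, 3, 4, 5, 6),
        basis: GammaBasis | None = None,
        transition_model: TransitionModel | None = None,
        observer_settings: ObserverSettings = ObserverSettings(),
        residualize_nuisance: bool = True,
    ):
        if isinstance(endog, PupilTimeSeries):
            if endog.rate != 10.0:
                raise ValueError("endog must be sampled at 10 Hz")
            endog = endog.samples
        self.endog = np.asarray(endog, float)
        self.events = events
        self.grid = tuple(float(g) for g in grid)
        self.models = tuple(models)
        self.basis = make_gamma_basis() if basis is None else basis
        self.transition_model = build_source_model() if transition_model is None else transition_model
        self.observer_settings = observer_settings
        # The standard preprocessing regresses nuisance responses out of the
        # data; the designs must then be projected the same way.
        self.residualize_nuisance = residualize_nuisance
        # A list of block trains means endog is a block average; designs are
        # then averaged over blocks the same way.
        ref = events[0] if isinstance(events, (list, tuple)) else events
        n_expected = int(round(ref.duration_s * self.basis.rate))
        if len(self.endog) != n_expected:
            raise ValueError(
                f"series has {len(self.endog)} samples but the events span "
                f"{ref.duration_s} s at {self.basis.rate} Hz ({n_expected})"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, events, pupil_col: str = "pupil", **kwargs):
        """Build from a data frame with ``time_s`` and pupil columns."""
        return cls(df[pupil_col].to_numpy(float), events, **kwargs)

    @classmethod
    def from_raw_blocks(cls, raw_blocks, events_blocks, **kwargs):
        """Preprocess raw 1000 Hz blocks and fit to their z-scored average."""
        from .preprocess import preprocess_block, zscore_and_average

        cleaned = [preprocess_block(ts, ev) for ts, ev in zip(raw_blocks, events_blocks)]
        _, mean_series = zscore_and_average([cleaned])
        return cls(mean_series, list(events_blocks), **kwargs)

    def fit(self, prior_sd: float = 10.0) -> "PupilGLMResults":
        """Run the observer grid, score all models, and estimate beta^-1."""
        from .preprocess import nuisance_projector

        residualize = (
            nuisance_projector(self.events, self.basis.rate) if self.residualize_nuisance else None
        )
        traces = observer_precision_traces(
            self.events,
            self.transition_model,
            self.grid,
            self.observer_settings,
            rate=self.basis.rate,
        )
        surface = compare_models(
            self.endog,
            self.events,
            traces,
            self.basis,
            models=self.models,
            prior_sd=prior_sd,
            residualize=residualize,
        )
        precision_posterior = None
        if 3 in self.models:
            precision_posterior = estimate_prior_precision(
                self.endog,
                self.events,
                traces,
                self.basis,
                model_id=3,
                prior_sd=prior_sd,
                residualize=residualize,
            )
        return PupilGLMResults(self, surface, precision_posterior, traces, prior_sd)


class PupilGLMResults:
    """Fitted evidence surface and prior-precision posterior."""

    def __init__(self, model: PupilGLM, surface, precision_posterior, observer_traces, prior_sd):
        self.model = model
        self.surface = surface
        self.precision_posterior = precision_posterior
        self.observer_traces = observer_traces
        self.prior_sd = prior_sd

    # -- headline quantities -------------------------------------------------

    @property
    def beta_inv_map(self) -> float:
        """Posterior-mode prior precision of the subject (model 3)."""
        if self.precision_posterior is None:
            raise ValueError("model 3 was not in the candidate set")
        return self.precision_posterior.map_value

    @property
    def best_model(self) -> int:
        """Model with the highest evidence, maximised over the grid."""
        best_per_model = self.surface.log_evidence.max(axis=1)
        return int(self.surface.models[int(np.argmax(best_per_model))])

    def model_posterior(self, beta_inv: float | None = None) -> np.ndarray:
        """Posterior model probabilities at one grid point (flat priors)."""
        grid = self.surface.grid
        j = int(np.argmin(np.abs(grid - (beta_inv if beta_inv is not None else self.beta_inv_map))))
        return softmax(self.surface.log_evidence[:, j])

    def summary(self) -> str:
        """Human-readable comparison table, statsmodels-style."""
        rel = self.surface.relative_evidence() if 1 in self.surface.models else None
        lines = [
            "Bayesian convolution-GLM comparison",
            "=" * 54,
            f"observations: {len(self.model.endog)} samples at 10 Hz",
            f"grid: {len(self.surface.grid)} prior precisions "
            f"in [{self.surface.grid.min():g}, {self.surface.grid.max():g}]",
            f"coefficient prior sd: {self.prior_sd:g}",
            "-" * 54,
            f"{'model':>6} {'max log-ev':>12} {'rel to M1':>10} {'best R2':>9}",
        ]
        for i, m in enumerate(self.surface.models):
            j = int(np.argmax(self.surface.log_evidence[i]))
            rel_s = f"{rel[i, j]:10.2f}" if rel is not None else f"{'':>10}"
            lines.append(
                f"{m:>6} {self.surface.log_evidence[i, j]:12.2f} {rel_s} "
                f"{self.surface.r_squared[i, j]:9.3f}"
            )
        lines.append("-" * 54)
        lines.append(f"best model: {self.best_model}")
        if self.precision_posterior is not None:
            lines.append(f"estimated prior precision (beta^-1 MAP): {self.beta_inv_map:g}")
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------------

    def plot_evidence(self, ax=None):
        """Relative log evidence of each model against the prior precision."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rel = self.surface.relative_evidence() if 1 in self.surface.models else self.surface.log_evidence
        for i, m in enumerate(self.surface.models):
            if m == 1:
                continue
            ax.plot(self.surface.grid, rel[i], label=f"model {m}", lw=2 if m == 3 else 1)
        ax.set_xscale("log")
        ax.set_xlabel(r"prior precision $\beta^{-1}$")
        ax.set_ylabel("log evidence relative to model 1")
        ax.legend()
        return ax

    def plot_posterior(self, ax=None):
        """Posterior over the subject's prior precision."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pp = self.precision_posterior
        ax.plot(pp.grid, pp.posterior, marker="o")
        ax.axvline(pp.map_value, color="k", ls="--", lw=1)
        ax.set_xscale("log")
        ax.set_xlabel(r"prior precision $\beta^{-1}$")
        ax.set_ylabel("posterior probability")
        return ax
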