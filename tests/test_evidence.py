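import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.stats import invgamma, multivariate_normal

from pupilvol.evidence import (
    bayes_glm,
    build_design,
    compare_models,
    estimate_prior_precision,
    gamma_kernel,
    generative_precision_trace,
    make_gamma_basis,
    observer_precision_traces,
    rasterize_boxcar,
    softmax,
)


def quadrature_evidence(y, X, prior_sd, a0=1e-3, b0=1e-3):
    """Numerical-integration oracle for the log marginal likelihood.

    Integrates the normal-inverse-gamma model over the noise variance with
    adaptive quadrature, evaluating the conditional Gaussian marginal with
    scipy's multivariate normal — independent of the package's algebra.
    """
    n = len(y)
    C0 = prior_sd**2 * X @ X.T

    def logint(logs2):
        s2 = np.exp(logs2)
        pdf = multivariate_normal.logpdf(
            y, mean=np.zeros(n), cov=s2 * (np.eye(n) + C0), allow_singular=True
        )
        return pdf + invgamma.logpdf(s2, a0, scale=b0) + logs2

    r = minimize_scalar(lambda u: -logint(u), bounds=(-20, 20), method="bounded")
    peak, lmax = r.x, -r.fun
    val, _ = quad(lambda u: np.exp(logint(u) - lmax), peak - 30, peak + 30, limit=1000)
    return lmax + np.log(val)


class TestGammaBasis:
    def test_five_peak_normalised_kernels(self):
        basis = make_gamma_basis()
        assert len(basis) == 5
        for k in basis.kernels:
            assert k.max() == pytest.approx(1.0)
            assert np.all(k >= 0)

    def test_peaks_at_configured_times(self):
        basis = make_gamma_basis()
        for k, peak in zip(basis.kernels, basis.peak_times):
            # analytic mode (shape-1)*theta; within one 10 Hz sample
            assert abs(np.argmax(k) / basis.rate - peak) <= 0.1

    def test_non_increasing_peaks_rejected(self):
        with pytest.raises(ValueError):
            make_gamma_basis(peak_times=(1.0, 0.5, 2.0, 4.0, 8.0))

    def test_kernel_requires_interior_mode(self):
        with pytest.raises(ValueError):
            gamma_kernel(1.0, shape=1.0, rate=10.0)


class TestRegressors:
    def test_photic_boxcar_duty_cycle(self, events):
        box = rasterize_boxcar(events, 10.0)
        assert len(box) == 1250
        assert box.mean() == pytest.approx(0.4)
        # break windows carry no photic drive
        for q in range(25):
            assert np.all(box[q * 50 + 41 : (q + 1) * 50] == 0.0)

    def test_generative_precision_trace_is_z_scored_steps(self, events):
        tr = generative_precision_trace(events, 10.0)
        assert abs(tr.mean()) < 1e-9
        assert tr.std() == pytest.approx(1.0)
        # piecewise constant per sequence: few unique values
        assert len(np.unique(np.round(tr, 9))) <= 10


@pytest.fixture(scope="module")
def basis():
    return make_gamma_basis()


@pytest.fixture(scope="module")
def prec():
    rng = np.random.default_rng(0)
    return 2.0 + 0.3 * np.cumsum(rng.normal(0, 0.05, 1250))


class TestBuildDesign:
    def test_model3_has_ten_columns_plus_constant(self, events, prec, basis):
        d = build_design(3, events, prec, None, basis)
        assert d.n_columns == 11
        assert d.column_labels[-1] == "const"
        assert np.all(d.X[:, -1] == 1.0)

    @pytest.mark.parametrize("model_id,n_vars", [(1, 1), (2, 2), (3, 2), (4, 3), (5, 2), (6, 2)])
    def test_column_counts(self, events, prec, basis, model_id, n_vars):
        d = build_design(model_id, events, prec, None, basis)
        assert d.n_columns == 5 * n_vars + 1

    def test_constant_precision_zeroes_interaction(self, events, basis):
        d = build_design(2, events, np.full(1250, 3.7), None, basis)
        inter = d.X[:, 5:10]
        assert np.allclose(inter, 0.0, atol=1e-12)

    def test_unknown_model_rejected(self, events, prec, basis):
        with pytest.raises(ValueError):
            build_design(7, events, prec, None, basis)

    def test_model5_decay_regressor_is_event_locked(self, events, basis):
        d = build_design(5, events, None, None, basis)
        onsets = events.onset_s[events.is_violation]
        if len(onsets):
            decay_cols = d.X[:, 5:10]
            assert decay_cols.max() > 0

    def test_csv_export(self, tmp_path, events, prec, basis):
        d = build_design(3, events, prec, None, basis)
        d.to_csv(tmp_path / "design.csv")
        import pandas as pd

        back = pd.read_csv(tmp_path / "design.csv")
        assert list(back.columns) == d.column_labels


class TestBayesGLM:
    def test_perfect_fit_r_squared(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 1e-4, 200)
        res = bayes_glm(y, X)
        assert res.r_squared > 0.999

    def test_matches_numerical_integration_oracle(self):
        rng = np.random.default_rng(1)
        for p, n in [(1, 30), (2, 40), (3, 50)]:
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(0, 0.7, n)
            mine = bayes_glm(y, X, prior_sd=5.0).log_evidence
            oracle = quadrature_evidence(y, X, 5.0)
            assert abs(mine - oracle) < 1e-3

    def test_occam_penalty_on_white_noise(self):
        """A constant-only model beats a 10-regressor model on pure noise."""
        rng = np.random.default_rng(2)
        wins = []
        for _ in range(100):
            y = rng.normal(size=150)
            Xc = np.ones((150, 1))
            Xbig = np.column_stack([np.ones(150), rng.normal(size=(150, 10))])
            wins.append(
                bayes_glm(y, Xc).log_evidence - bayes_glm(y, Xbig).log_evidence
            )
        assert np.mean(wins) > 0

    def test_equal_models_split_posterior(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 2))
        y = X @ np.array([1.0, 1.0]) + rng.normal(0, 0.1, 50)
        le = bayes_glm(y, X).log_evidence
        assert np.allclose(softmax(np.array([le, le])), [0.5, 0.5])

    def test_plugin_mode_runs(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 2))
        y = X @ np.array([0.5, -0.5]) + rng.normal(0, 0.3, 60)
        res = bayes_glm(y, X, noise="plugin")
        assert np.isfinite(res.log_evidence)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bayes_glm(np.array([1.0, np.nan]), np.ones((2, 1)))
        with pytest.raises(ValueError):
            bayes_glm(np.ones(3), np.ones((2, 1)))
        with pytest.raises(ValueError):
            bayes_glm(np.ones(3), np.ones((3, 1)), prior_sd=0.0)
        with pytest.raises(ValueError):
            bayes_glm(np.ones(3), np.ones((3, 1)), noise="bogus")


@pytest.fixture(scope="module")
def small_grid_traces(model, events):
    return observer_precision_traces(events, model, [1.0, 2.0, 4.0])


def synth_10hz(events, traces, beta_inv, w_photic=0.5, w_prec=-1.0, noise=0.1, seed=0):
    """Directly composed 10 Hz series from the model-3 regressor structure."""
    basis = make_gamma_basis()
    photic = rasterize_boxcar(events, 10.0)
    om = traces[beta_inv]
    conv = lambda x: np.convolve(x, basis.widest)[: len(x)]
    sig = w_photic * conv(photic) + (w_prec * conv(om - om.mean()) if w_prec else 0.0)
    return sig + np.random.default_rng(seed).normal(0, noise, len(photic))


class TestCompareModels:
    def test_precision_free_models_invariant_across_grid(self, events, small_grid_traces):
        y = synth_10hz(events, small_grid_traces, 2.0)
        surf = compare_models(y, events, small_grid_traces)
        for m in (1, 5, 6):
            row = surf.log_evidence[surf.models.index(m)]
            assert np.ptp(row) == 0.0

    def test_model3_data_recovers_model3_at_true_prior(self, events, small_grid_traces):
        y = synth_10hz(events, small_grid_traces, 2.0, seed=1)
        surf = compare_models(y, events, small_grid_traces)
        best_model = surf.models[int(np.argmax(surf.log_evidence.max(axis=1)))]
        assert best_model == 3
        i3 = surf.models.index(3)
        assert surf.grid[int(np.argmax(surf.log_evidence[i3]))] == pytest.approx(2.0)

    def test_photic_only_data_favours_null_model(self, events, small_grid_traces):
        y = synth_10hz(events, small_grid_traces, 2.0, w_prec=0.0, seed=2)
        surf = compare_models(y, events, small_grid_traces)
        rel = surf.relative_evidence()
        for m in (2, 3, 4):
            assert rel[surf.models.index(m)].max() <= 0.0

    def test_posterior_probabilities_normalised(self, events, small_grid_traces):
        y = synth_10hz(events, small_grid_traces, 2.0, seed=3)
        surf = compare_models(y, events, small_grid_traces)
        assert np.allclose(surf.posterior_model_prob().sum(axis=0), 1.0, atol=1e-9)

    def test_model_selection_robust_to_prior_sd(self, events, small_grid_traces):
        """The winning model and precision estimate survive a tenfold change
        of the coefficient prior sd."""
        y = synth_10hz(events, small_grid_traces, 2.0, seed=4)
        picks = []
        for sd in (10.0, 100.0):
            surf = compare_models(y, events, small_grid_traces, prior_sd=sd)
            best = surf.models[int(np.argmax(surf.log_evidence.max(axis=1)))]
            post = estimate_prior_precision(y, events, small_grid_traces, prior_sd=sd)
            picks.append((best, post.map_value))
        assert picks[0] == picks[1]

    def test_surface_csv(self, tmp_path, events, small_grid_traces):
        y = synth_10hz(events, small_grid_traces, 2.0, seed=5)
        surf = compare_models(y, events, small_grid_traces, models=(1, 3))
        surf.to_csv(tmp_path / "surface.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "surface.csv")
        assert set(df["model"]) == {1, 3}


class TestEstimatePriorPrecision:
    def test_posterior_sums_to_one_and_recovers_truth(self, events, small_grid_traces):
        y = synth_10hz(events, small_grid_traces, 2.0, seed=6)
        post = estimate_prior_precision(y, events, small_grid_traces)
        assert post.posterior.sum() == pytest.approx(1.0)
        assert post.map_value == pytest.approx(2.0)

    def test_flat_evidences_give_uniform_posterior(self):
        assert np.allclose(softmax(np.zeros(5)), 0.2)

    def test_grid_of_one_rejected(self, events, model):
        traces = observer_precision_traces(events, model, [1.0])
        with pytest.raises(ValueError):
            estimate_prior_precision(np.zeros(1250), events, traces)
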