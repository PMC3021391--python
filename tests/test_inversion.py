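"""Variational-Laplace inversion: exactness, identities and recovery."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from motordcm.generative import RegionTimeSeries, simulate_bold
from motordcm.inversion import (
    InversionOptions,
    Priors,
    build_priors,
    connectivity_names,
    free_energy_curve,
    invert,
    make_forward,
    param_names,
    posterior_correlation,
    variational_laplace,
)
from motordcm.model_space import get_model

from conftest import params_for


@pytest.fixture(scope="module")
def linear_toy():
    rng = np.random.default_rng(0)
    T, P = 40, 3
    X = rng.normal(size=(T, P))
    lam = 4.0
    S0 = np.diag([0.5, 0.8, 0.3])
    theta = rng.normal(size=P) * 0.5
    y = X @ theta + rng.normal(0, lam**-0.5, T)

    def forward(th):
        return (np.atleast_2d(th) @ X.T)[:, :, None]

    priors = Priors(names=("a", "b", "c"), mean=np.zeros(P), cov=S0)
    return X, lam, y, forward, priors


class TestLinearGaussianOracle:
    def test_free_energy_equals_closed_form_evidence(self, linear_toy):
        X, lam, y, forward, priors = linear_toy
        post, ev = variational_laplace(
            forward, y[:, None], priors, update_noise=False,
            init_log_precision=np.log(lam), tol=1e-8,
        )
        cov = np.eye(len(y)) / lam + X @ priors.cov @ X.T
        exact = multivariate_normal.logpdf(y, mean=np.zeros(len(y)), cov=cov)
        assert ev.F == pytest.approx(exact, abs=1e-3)

    def test_posterior_matches_conjugate_solution(self, linear_toy):
        X, lam, y, forward, priors = linear_toy
        post, _ = variational_laplace(
            forward, y[:, None], priors, update_noise=False,
            init_log_precision=np.log(lam), tol=1e-8,
        )
        Pi0 = np.linalg.inv(priors.cov)
        Sigma = np.linalg.inv(lam * X.T @ X + Pi0)
        mu = Sigma @ (lam * X.T @ y)
        assert np.allclose(post.Ep, mu, atol=1e-6)
        assert np.allclose(post.Cp, Sigma, atol=1e-6)

    def test_identity_and_nonnegative_complexity(self, linear_toy):
        _, lam, y, forward, priors = linear_toy
        _, ev = variational_laplace(
            forward, y[:, None], priors, update_noise=False,
            init_log_precision=np.log(lam),
        )
        assert ev.F == pytest.approx(ev.accuracy - ev.complexity, abs=1e-10)
        assert ev.complexity >= 0

    def test_free_energy_curve_monotone(self, linear_toy):
        _, lam, y, forward, priors = linear_toy
        post, _ = variational_laplace(
            forward, y[:, None], priors, update_noise=False,
            init_log_precision=np.log(lam),
        )
        curve = free_energy_curve(post)
        assert np.all(np.diff(curve) >= -1e-9)
        assert curve[-1] >= curve[0]


class TestPriors:
    def test_param_names_and_order(self, e2):
        names = param_names(e2)
        assert len(names) == 13 + 2
        assert names[-2:] == ("hemo.log_kappa", "hemo.log_tau")
        assert "A.PFC->preSMA" in names
        assert "B.preSMA->PFC" in names
        assert "C.PFC.u1" in names
        assert len(connectivity_names(e2)) == 13

    def test_prior_variances(self, e2):
        pri = build_priors(e2)
        v = dict(zip(pri.names, np.diag(pri.cov)))
        assert v["A.PFC->PM"] == pytest.approx(1 / 16)
        assert v["B.PFC->preSMA"] == pytest.approx(1 / 16)
        assert v["C.PFC.u1"] == pytest.approx(1 / 32)
        assert v["hemo.log_kappa"] == pytest.approx(1 / 64)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            Priors(names=("a", "b"), mean=np.zeros(2), cov=np.array([[1, 2], [2, 1.0]]))


class TestPosteriorCorrelation:
    def test_diagonal_gives_identity(self):
        corr = posterior_correlation(np.diag([1.0, 2.0, 3.0]))
        assert np.allclose(corr, np.eye(3))

    def test_known_2x2(self):
        corr = posterior_correlation(np.array([[4.0, -2.0], [-2.0, 4.0]]))
        assert corr[0, 1] == pytest.approx(-0.5)

    def test_e2_restriction_has_78_unique_entries(self, e2):
        names = param_names(e2)
        k = len(names)
        Cp = np.eye(k) + 0.01
        corr = posterior_correlation(Cp, names)
        assert corr.shape == (13, 13)
        iu = np.triu_indices(13, 1)
        assert iu[0].size == 78

    def test_zero_variance_flagged(self):
        Cp = np.diag([1.0, 0.0])
        with pytest.warns(RuntimeWarning, match="zero posterior variance"):
            corr = posterior_correlation(Cp)
        assert np.isnan(corr[1, 1])


class TestDcmInversion:
    @pytest.fixture(scope="class")
    def quiet_fit(self, e2, e2_params, short_design):
        clean = simulate_bold(e2, e2_params, short_design, 0.0)
        rng = np.random.default_rng(3)
        y = clean.y + rng.normal(0, 0.02, clean.y.shape)
        data = RegionTimeSeries(y=y, tr=short_design.tr)
        post, ev = invert(e2, data, short_design, opts=InversionOptions(tol=1e-3))
        return post, ev

    def test_recovers_parameters_at_low_noise(self, quiet_fit, e2_params):
        post, _ = quiet_fit
        ep = post.Ep_dict
        assert ep["B.PFC->preSMA"] == pytest.approx(0.06, abs=0.02)
        assert ep["B.preSMA->PFC"] == pytest.approx(0.05, abs=0.02)
        assert ep["C.PFC.u1"] == pytest.approx(0.10, abs=0.02)
        assert ep["A.PFC->preSMA"] == pytest.approx(0.45, abs=0.08)

    def test_identity_and_curve(self, quiet_fit):
        post, ev = quiet_fit
        assert ev.F == pytest.approx(ev.accuracy - ev.complexity, abs=1e-9)
        assert ev.complexity >= 0
        curve = free_energy_curve(post)
        assert np.all(np.diff(curve) >= -1e-9)

    def test_posterior_covariance_psd(self, quiet_fit):
        post, _ = quiet_fit
        assert np.allclose(post.Cp, post.Cp.T)
        assert np.linalg.eigvalsh(post.Cp).min() > 0

    def test_mismatched_data_rejected(self, e2, short_design, e2_params):
        ts = simulate_bold(e2, e2_params, short_design, 0.0)
        bad = RegionTimeSeries(y=ts.y[:-5], tr=short_design.tr)
        with pytest.raises(ValueError, match="volumes"):
            invert(e2, bad, short_design)


def test_weak_data_stays_at_prior(e2, e2_params, short_design):
    """With data simulated at the prior mean and a fixed modest noise
    precision, there is no information gain: the posterior mode stays at
    the prior mean and the complexity stays near zero."""
    zero = params_for("E2", c_u1=0.0)
    zero = type(zero)(A=np.zeros((4, 4)), B=np.zeros((4, 4)), C=np.zeros((4, 2)))
    ts = simulate_bold(e2, zero, short_design, 0.0)  # prior-mean prediction
    opts = InversionOptions(update_noise=False, init_log_precision=np.log(1e-3))
    post, ev = invert(e2, ts, short_design, opts=opts)
    assert np.abs(post.Ep).max() < 1e-6
    assert ev.complexity < 0.05


def test_bilinear_sign_recovered_across_replicates(e2, short_design):
    """A strong positive PFC->preSMA modulation keeps its sign in the
    posterior across noisy replicates at SNR ~ 2."""
    p = params_for("E2", {("PFC", "preSMA"): 0.25, ("preSMA", "PFC"): 0.05})
    clean = simulate_bold(e2, p, short_design, 0.0)
    sd_r = clean.y.std(axis=0)
    signs = []
    for rep in range(6):
        rng = np.random.default_rng(100 + rep)
        y = clean.y + rng.normal(0, 1, clean.y.shape) * (sd_r / 2.0)
        data = RegionTimeSeries(y=y, tr=short_design.tr)
        post, _ = invert(e2, data, short_design)
        signs.append(post.Ep_dict["B.PFC->preSMA"] > 0)
    assert np.mean(signs) >= 0.95


def test_evidence_discrimination_between_modulation_sites(short_design):
    """Data generated from E1 yield median F(E1) > F(E2) and vice versa."""
    e1, e2 = get_model("E1"), get_model("E2")
    wins = {"E1": 0, "E2": 0}
    for truth, model_pair in (("E1", (e1, e2)), ("E2", (e2, e1))):
        truth_model = get_model(truth)
        edges = ((("PFC", "PM"), ("PM", "PFC")) if truth == "E1"
                 else (("PFC", "preSMA"), ("preSMA", "PFC")))
        p = params_for(truth, {edges[0]: 0.25, edges[1]: 0.20})
        clean = simulate_bold(truth_model, p, short_design, 0.0)
        sd_r = clean.y.std(axis=0)
        diffs = []
        for rep in range(5):
            rng = np.random.default_rng(rep)
            y = clean.y + rng.normal(0, 1, clean.y.shape) * (sd_r / 2.0)
            data = RegionTimeSeries(y=y, tr=short_design.tr)
            _, ev_true = invert(truth_model, data, short_design)
            _, ev_other = invert(model_pair[1], data, short_design)
            diffs.append(ev_true.F - ev_other.F)
        assert np.median(diffs) > 0, (truth, diffs)


def test_complexity_penalises_spurious_modulation(short_design):
    """Adding spurious bilinear terms to the truth model does not raise
    the median free energy (complexity correction at work)."""
    e2 = get_model("E2")
    f8 = get_model("F8")  # modulates all ten connections + context input
    p = params_for("E2", {("PFC", "preSMA"): 0.06, ("preSMA", "PFC"): 0.05})
    clean = simulate_bold(e2, p, short_design, 0.0)
    sd_r = clean.y.std(axis=0)
    diffs = []
    for rep in range(3):
        rng = np.random.default_rng(10 + rep)
        y = clean.y + rng.normal(0, 1, clean.y.shape) * (sd_r / 2.0)
        data = RegionTimeSeries(y=y, tr=short_design.tr)
        _, ev_e2 = invert(e2, data, short_design)
        _, ev_f8 = invert(f8, data, short_design)
        diffs.append(ev_f8.F - ev_e2.F)
    assert np.median(diffs) <= 0
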