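import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from autospot import (ModelConfig, ParameterState, SpatialSlice, StudyDataset,
                      build_neighbor_graph, build_slice_covariance,
                      conditional_logit, joint_log_posterior,
                      marginalized_beta_log_prior, missingness_logit,
                      nmig_log_prior, pseudo_log_likelihood)
from autospot.model_core import MU_FLOOR
from autospot.simulator import grid_coords


# ---------------------------------------------------------------- conditionals
@pytest.mark.parametrize(
    "xbeta,eta,frac,u,expected",
    [
        (0.0, 0.0, 0.7, 0.0, 0.5),
        (1.2, 2.0, 0.75, 0.0, 0.9370),   # logit^-1(2.7)
        (0.0, 3.0, 1.0, -3.0, 0.5),      # spatial term cancels the offset
    ],
)
def test_conditional_logit(xbeta, eta, frac, u, expected):
    assert conditional_logit(xbeta, eta, frac, u) == pytest.approx(expected, abs=1e-4)


def _one_spot_slice(xbeta, y):
    coords = np.array([[0.0, 0.0]])
    slc = SpatialSlice("d", "s", coords, np.array([[xbeta]]), ["g0"],
                       np.array([float(y)]), np.array([1]))
    return slc, build_neighbor_graph(coords, 1.0)


def test_pseudo_log_likelihood_isolated_coin_flips():
    coords = np.array([[0.0, 0.0], [5.0, 5.0]])
    slc = SpatialSlice("d", "s", coords, np.zeros((2, 1)), ["g0"],
                       np.array([1.0, 0.0]), np.array([1, 1]))
    g = build_neighbor_graph(coords, 1.0)
    state = ParameterState(beta=[0.0], eta=0.0)
    assert pseudo_log_likelihood(slc, g, state) == pytest.approx(2 * math.log(0.5))


def test_pseudo_log_likelihood_single_spot():
    slc, g = _one_spot_slice(2.7, 1)
    state = ParameterState(beta=[1.0], eta=0.0)
    assert pseudo_log_likelihood(slc, g, state) == pytest.approx(math.log(0.9370), abs=1e-3)


def test_pseudo_log_likelihood_clipped_never_minus_inf():
    slc, g = _one_spot_slice(-1000.0, 1)  # mu saturates at 0 against label 1
    state = ParameterState(beta=[1.0], eta=0.0)
    val = pseudo_log_likelihood(slc, g, state)
    assert np.isfinite(val)
    assert val == pytest.approx(math.log(MU_FLOOR))


def test_pseudo_log_likelihood_rejects_nan_labels():
    slc, g = _one_spot_slice(0.0, 1)
    slc.y = np.array([np.nan])
    with pytest.raises(ValueError, match="impute"):
        pseudo_log_likelihood(slc, g, ParameterState(beta=[0.0]))


# ---------------------------------------------------------------- NMIG priors
def test_nmig_prior_standard_normal_beta_term():
    cfg = ModelConfig(include_intercept=False)
    st1 = ParameterState(beta=[0.0], eta=1.0, iota=[1.0], tau2=[1.0], w=0.5)
    st0 = ParameterState(beta=[10.0], eta=1.0, iota=[1.0], tau2=[1.0], w=0.5)
    # difference isolates the beta log-density: N(0;0,1) vs N(10;0,1)
    diff = nmig_log_prior(st1, cfg) - nmig_log_prior(st0, cfg)
    assert diff == pytest.approx(50.0)
    base = nmig_log_prior(st1, cfg)
    # eta uniform + slab mass log(w) + invgamma(tau2=1) + N(0;0,1)
    assert np.isfinite(base)


def test_nmig_prior_out_of_support_sentinel():
    cfg = ModelConfig(c1=10.0)
    bad = ParameterState(beta=[0.0], eta=11.0)
    assert nmig_log_prior(bad, cfg) == -np.inf
    bad2 = ParameterState(beta=[0.0], eta=1.0, tau2=[-1.0])
    assert nmig_log_prior(bad2, cfg) == -np.inf


def test_nmig_prior_spike_component_is_scaled_normal():
    cfg = ModelConfig(include_intercept=False)
    v0 = cfg.v0
    st_spike = ParameterState(beta=[0.1], eta=1.0, iota=[v0], tau2=[2.0], w=0.5)
    st_slab = ParameterState(beta=[0.1], eta=1.0, iota=[1.0], tau2=[2.0], w=0.5)
    def normal_lpdf(x, var):
        return -0.5 * (math.log(2 * math.pi * var) + x * x / var)
    expected_diff = (normal_lpdf(0.1, v0 * 2.0) + math.log(0.5)) - \
                    (normal_lpdf(0.1, 2.0) + math.log(0.5))
    assert nmig_log_prior(st_spike, cfg) - nmig_log_prior(st_slab, cfg) == pytest.approx(expected_diff)


@pytest.mark.parametrize("w,expected_component", [(1.0, "slab"), (0.0, "spike")])
def test_marginalized_prior_degenerate_mixture(w, expected_component):
    def normal_lpdf(x, var):
        return -0.5 * (math.log(2 * math.pi * var) + x * x / var)
    val = marginalized_beta_log_prior(0.3, 2.0, w, 0.01)
    target = normal_lpdf(0.3, 2.0) if expected_component == "slab" else normal_lpdf(0.3, 0.02)
    assert val == pytest.approx(target)


def test_marginalized_prior_hand_value():
    # 0.5*N(0;0,0.01) + 0.5*N(0;0,1) = 0.5*3.9894 + 0.5*0.3989
    val = marginalized_beta_log_prior(0.0, 1.0, 0.5, 0.01)
    assert val == pytest.approx(0.7850, abs=1e-3)


@settings(max_examples=50, deadline=None)
@given(st.floats(-3, 3), st.floats(0.1, 5.0), st.floats(0.01, 0.99), st.floats(1e-4, 0.5))
def test_marginalized_prior_equals_logsumexp_over_indicator(beta, tau2, w, v0):
    """Marginal = logsumexp over iota in {v0, 1} of conditional + indicator prior."""
    def normal_lpdf(x, var):
        return -0.5 * (math.log(2 * math.pi * var) + x * x / var)
    direct = marginalized_beta_log_prior(beta, tau2, w, v0)
    via_sum = np.logaddexp(math.log(1 - w) + normal_lpdf(beta, v0 * tau2),
                           math.log(w) + normal_lpdf(beta, tau2))
    assert direct == pytest.approx(via_sum, rel=1e-10)


# ---------------------------------------------------------------- covariance
def test_exchangeable_covariance_values():
    S = build_slice_covariance(2.0, 0.5, 3, "exchangeable")
    assert np.allclose(np.diag(S), 2.0)
    off = S[~np.eye(3, dtype=bool)]
    assert np.allclose(off, 1.0)


def test_autoregressive_covariance_values():
    S = build_slice_covariance(1.0, 0.5, 3, "autoregressive")
    assert np.allclose(S[0], [1.0, 0.5, 0.25])


def test_zero_rho_identity_both_structures():
    for s in ("exchangeable", "autoregressive"):
        assert np.allclose(build_slice_covariance(3.0, 0.0, 4, s), 3.0 * np.eye(4))


def test_covariance_pd_bounds_errors():
    with pytest.raises(ValueError, match="rho"):
        build_slice_covariance(1.0, -0.9, 3, "exchangeable")  # below -1/(G-1)
    with pytest.raises(ValueError, match="rho"):
        build_slice_covariance(1.0, 1.0, 3, "autoregressive")
    with pytest.raises(ValueError, match="sigma2"):
        build_slice_covariance(0.0, 0.5, 3, "exchangeable")


@settings(max_examples=40, deadline=None)
@given(st.sampled_from(["exchangeable", "autoregressive"]),
       st.integers(2, 6), st.floats(0.01, 5.0), st.data())
def test_covariance_positive_definite_in_declared_region(structure, G, sigma2, data):
    lo = -1.0 / (G - 1) if structure == "exchangeable" else -1.0
    rho = data.draw(st.floats(lo + 1e-3, 1 - 1e-3))
    S = build_slice_covariance(sigma2, rho, G, structure)
    np.linalg.cholesky(S)  # raises if not PD


# ---------------------------------------------------------------- missingness
def test_missingness_logit_values():
    assert missingness_logit([0, 0, 0], 1, 0.3) == pytest.approx(0.5)
    assert missingness_logit([0.5, -1.0, 2.0], 1, 0.5) == pytest.approx(0.6225, abs=1e-4)


def test_missingness_ignorable_when_gamma1_zero():
    g = [0.4, 0.0, 1.2]
    assert missingness_logit(g, 0, 0.6) == missingness_logit(g, 1, 0.6)


# ---------------------------------------------------------------- joint posterior
def _two_spot_study():
    coords = np.array([[0.0, 0.0], [1.0, 0.0]])
    X = np.array([[0.5], [-0.5]])
    slc = SpatialSlice("d", "s", coords, X, ["g0"], np.array([1.0, 0.0]), np.array([1, 1]))
    return StudyDataset([slc]), build_neighbor_graph(coords, 1.0)


def test_joint_posterior_decomposes_into_likelihood_plus_prior():
    study, g = _two_spot_study()
    cfg = ModelConfig(include_intercept=False)
    state = ParameterState(beta=[0.7], eta=1.2, iota=[1.0], tau2=[1.0], w=0.5)
    total = joint_log_posterior(study, [g], state, cfg)
    assert total == pytest.approx(
        pseudo_log_likelihood(study.slices[0], g, state) + nmig_log_prior(state, cfg))


def test_joint_posterior_hand_summed_two_spots():
    study, g = _two_spot_study()
    cfg = ModelConfig(include_intercept=False)
    state = ParameterState(beta=[1.0], eta=2.0, iota=[1.0], tau2=[1.0], w=0.5)
    # hand sum: mu1 = expit(0.5 + 2*y2) with y2=0 -> expit(0.5); y1=1
    #           mu2 = expit(-0.5 + 2*y1) with y1=1 -> expit(1.5); y2=0
    from scipy.special import expit
    ll = math.log(expit(0.5)) + math.log(1 - expit(1.5))
    assert pseudo_log_likelihood(study.slices[0], g, state) == pytest.approx(ll)
    assert joint_log_posterior(study, [g], state, cfg) == pytest.approx(
        ll + nmig_log_prior(state, cfg))


def test_joint_posterior_propagates_sentinel():
    study, g = _two_spot_study()
    cfg = ModelConfig()
    state = ParameterState(beta=[0.0], eta=-1.0)
    assert joint_log_posterior(study, [g], state, cfg) == -np.inf


def test_missingness_terms_absent_under_ignorable():
    study, g = _two_spot_study()
    state = ParameterState(beta=[0.0], eta=1.0, iota=[1.0], tau2=[1.0], w=0.5,
                           gamma=np.array([0.3, 0.2, 0.1]))
    cfg_ig = ModelConfig(missing_mode="ignorable", include_intercept=False)
    cfg_ni = ModelConfig(missing_mode="nonignorable", include_intercept=False)
    lp_ig = joint_log_posterior(study, [g], state, cfg_ig)
    lp_ni = joint_log_posterior(study, [g], state, cfg_ni)
    # the nonignorable value adds R-likelihood and gamma prior terms
    assert lp_ni != pytest.approx(lp_ig)
    state_nog = ParameterState(beta=[0.0], eta=1.0, iota=[1.0], tau2=[1.0], w=0.5)
    assert joint_log_posterior(study, [g], state_nog, cfg_ig) == pytest.approx(
        lp_ig - float(np.sum(-0.5 * (np.log(2 * np.pi * 100.0)) - 0.5 * state.gamma ** 2 / 100.0)))


def test_eta_zero_reduces_to_independent_logistic():
    """With eta=0 the pseudo-likelihood is the textbook logistic log-likelihood."""
    rng = np.random.default_rng(7)
    n, d = 50, 2
    coords = np.column_stack([np.arange(n), np.zeros(n)])
    X = rng.standard_normal((n, d))
    beta = np.array([0.8, -1.1])
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
    slc = SpatialSlice("d", "s", coords, X, ["a", "b"], y, np.ones(n, dtype=int))
    g = build_neighbor_graph(coords, 1.0)
    state = ParameterState(beta=beta, eta=0.0)
    eta_ll = pseudo_log_likelihood(slc, g, state)
    xb = X @ beta
    ref = float(np.sum(y * xb - np.log1p(np.exp(xb))))
    assert eta_ll == pytest.approx(ref)


# ---------------------------------------------------------------- gradients
def test_unconstrained_gradient_matches_finite_differences():
    """Analytic gradients agree with central differences, all features on."""
    from autospot import SimulationConfig, simulate_study
    from autospot._posterior import UnconstrainedPosterior
    from autospot.inference import initial_missing_labels
    from autospot.simulator import layout_graph

    sc = SimulationConfig(layout="grid", L=5, d=3, n_true=2, eta_true=1.0, C=2, G=3,
                          sigma2_true=0.5, rho_true=0.4, missing_mode="nonignorable",
                          gamma_true=np.array([1.0, 0.5, 1.0]), n_sweeps=30, seed=1)
    study = simulate_study(sc)
    graphs = [layout_graph(sc)] * study.n_slices
    cfg = ModelConfig(missing_mode="nonignorable")
    post = UnconstrainedPosterior(study, graphs, cfg)
    for s, (slc, g) in enumerate(zip(study.slices, graphs)):
        post.set_labels(s, initial_missing_labels(slc, g))
    rng = np.random.default_rng(0)
    z = rng.normal(0, 0.5, post.n_params)
    _, grad = post.value_and_grad(z)
    h = 1e-5
    for i in range(post.n_params):
        zp, zm = z.copy(), z.copy()
        zp[i] += h
        zm[i] -= h
        num = (post.logp(zp) - post.logp(zm)) / (2 * h)
        assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-6)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(c1=-1.0)
    with pytest.raises(ValueError):
        ModelConfig(v0=1.5)
    with pytest.raises(ValueError):
        ModelConfig(corr_structure="banded")
    with pytest.raises(ValueError):
        ModelConfig(b5=0.9, b6=0.1)
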