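"""Likelihood and prior building blocks of the spatial autologistic model.

The response model is a restricted autologistic regression: the disease
status of spot *i* is Bernoulli with

    logit(mu_i) = beta' x_i + (eta / |N(i)|) * sum_{j in N(i)} y_j  [+ U_cg]

so a single nonnegative coupling ``eta`` is shared isotropically over the
neighborhood and divided by the neighbor count to absorb boundary effects.
The likelihood used throughout is the product of these per-spot conditional
Bernoulli terms (a pseudo-likelihood): the joint Markov-random-field
normalizing constant is never computed.  On layouts with constant neighbor
count (torus) the conditionals coincide with a genuine Ising joint; on
bounded grids they are the standard Besag-type approximation.

Gene coefficients carry a normal-mixture-of-inverse-gamma (NMIG)
spike-and-slab prior: beta_k | iota_k, tau_k^2 ~ N(0, iota_k * tau_k^2) with
iota_k equal to a small spike factor v0 (probability 1-w) or 1 (probability
w), tau_k^{-2} ~ Gamma(b1, b2) (shape/rate, so tau_k^2 is inverse-gamma),
and w ~ Uniform(0, 1).  Multi-slice studies add a slice-level random
intercept U_cg with exchangeable or AR(1) correlation across slices of a
donor.  Missing spots can follow a nonignorable observation model
logit P(R_i = 1) = gamma0 + gamma1 y_i + gamma2 * (observed neighbor
fraction); gamma1 = 0 recovers the ignorable case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .io_preprocess import SpatialSlice, StudyDataset
from .spatial_graph import NeighborGraph, neighbor_fractions

__all__ = [
    "ModelConfig",
    "ParameterState",
    "conditional_logit",
    "pseudo_log_likelihood",
    "nmig_log_prior",
    "marginalized_beta_log_prior",
    "build_slice_covariance",
    "missingness_logit",
    "joint_log_posterior",
    "MU_FLOOR",
]

# probabilities are clipped to [MU_FLOOR, 1 - MU_FLOOR] inside log terms so a
# label opposing a saturated mu contributes log(MU_FLOOR), never -inf/NaN
MU_FLOOR = 1e-12

NEG_INF = -np.inf


@dataclass
class ModelConfig:
    """Hyperparameters and structural switches of the model.

    Defaults are deliberately weakly informative: ``c1`` bounds the uniform
    prior on the spatial coupling, ``v0`` is the spike variance factor,
    ``(b1, b2)`` are the shape/rate of the Gamma prior on ``tau_k^{-2}``,
    ``(b3, b4)`` likewise for the random-effect precision, and ``(b5, b6)``
    bound the uniform prior on the across-slice correlation ``rho``.
    ``eta_fixed`` / ``w_fixed`` / ``tau2_fixed`` pin the corresponding
    parameter instead of sampling it (``eta_fixed=0`` is the naive
    non-spatial model); ``gamma_fixed`` maps component index -> value for
    the missingness coefficients.
    """

    c1: float = 10.0
    v0: float = 0.005
    b1: float = 5.0
    b2: float = 5.0
    b3: float = 2.0
    b4: float = 2.0
    b5: float = 0.0
    b6: float = 0.99
    delta: float = 1.0
    corr_structure: str = "exchangeable"
    missing_mode: str = "none"
    include_intercept: bool = True
    intercept_prior_sd: float = 10.0
    gamma_prior_sd: float = 10.0
    eta_fixed: float | None = None
    w_fixed: float | None = None
    tau2_fixed: float | None = None
    gamma_fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.c1 <= 0:
            raise ValueError("c1 must be positive")
        if not 0 < self.v0 < 1:
            raise ValueError("v0 must lie in (0, 1)")
        for name in ("b1", "b2", "b3", "b4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.corr_structure not in ("exchangeable", "autoregressive"):
            raise ValueError("corr_structure must be 'exchangeable' or 'autoregressive'")
        if self.missing_mode not in ("none", "ignorable", "nonignorable"):
            raise ValueError("missing_mode must be none, ignorable or nonignorable")
        if not self.b5 < self.b6:
            raise ValueError("need b5 < b6")
        if self.corr_structure == "autoregressive" and (self.b5 < -1 or self.b6 > 1):
            raise ValueError("autoregressive rho prior bounds must lie within (-1, 1)")
        if self.corr_structure == "exchangeable" and self.b6 > 1:
            raise ValueError("exchangeable rho prior upper bound must not exceed 1")

    def rho_bounds(self, G: int) -> tuple:
        """Prior bounds intersected with the positive-definiteness region."""
        eps = 1e-6
        if self.corr_structure == "exchangeable":
            lo = -1.0 / (G - 1) + eps if G > 1 else -1.0 + eps
        else:
            lo = -1.0 + eps
        return max(self.b5, lo), min(self.b6, 1.0 - eps)


@dataclass
class ParameterState:
    """One point in parameter space (constrained scale)."""

    beta: np.ndarray
    eta: float = 0.0
    iota: np.ndarray = None
    tau2: np.ndarray = None
    w: float = 0.5
    intercept: float = 0.0
    U: np.ndarray = None        # C x G random intercepts
    sigma2: np.ndarray = None   # per-donor random-effect variance
    rho: float = 0.0
    gamma: np.ndarray = None    # missingness coefficients (gamma0, gamma1, gamma2)

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.tau2 is None:
            self.tau2 = np.ones_like(self.beta)
        self.tau2 = np.broadcast_to(np.asarray(self.tau2, dtype=float), self.beta.shape).copy()
        if self.iota is not None:
            self.iota = np.broadcast_to(np.asarray(self.iota, dtype=float), self.beta.shape).copy()


def conditional_logit(xbeta, eta, nbr_fraction, u=0.0):
    """Conditional disease probability logit^-1(x'beta + eta * fraction + u)."""
    return expit(np.asarray(xbeta, dtype=float) + eta * np.asarray(nbr_fraction, dtype=float) + u)


def _bernoulli_loglik(y, mu):
    mu = np.clip(mu, MU_FLOOR, 1.0 - MU_FLOOR)
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))


def pseudo_log_likelihood(slc: SpatialSlice, graph: NeighborGraph, state: ParameterState, u=0.0):
    """Sum of conditional Bernoulli log-terms over the observed spots.

    Any missing labels must already have been imputed into ``slc.y`` (or the
    slice must be fully observed); neighbor fractions are computed from the
    full label vector, observed and imputed alike.  Saturated probabilities
    are clipped at ``MU_FLOOR`` so the value is always finite.
    """
    y = np.asarray(slc.y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("labels contain NaN; impute missing labels before evaluating")
    f = neighbor_fractions(graph, y)
    obs = slc.observed
    xb = slc.X[obs] @ state.beta + state.intercept
    mu = conditional_logit(xb, state.eta, f[obs], u)
    return _bernoulli_loglik(y[obs], mu)


def _normal_logpdf(x, var):
    return -0.5 * (math.log(2.0 * math.pi) + np.log(var)) - 0.5 * np.asarray(x) ** 2 / var


def marginalized_beta_log_prior(beta_k, tau2_k, w, v0):
    """Log of the two-component NMIG mixture with the spike indicator summed out.

    ``log[(1-w) N(beta; 0, v0 tau^2) + w N(beta; 0, tau^2)]`` — the form the
    gradient-based backends use, since they cannot carry the discrete
    indicator.  Vectorized over ``beta_k`` / ``tau2_k``.
    """
    beta_k = np.asarray(beta_k, dtype=float)
    tau2_k = np.asarray(tau2_k, dtype=float)
    with np.errstate(divide="ignore"):
        log_spike = np.log1p(-w) + _normal_logpdf(beta_k, v0 * tau2_k) if w < 1 else np.full(beta_k.shape, -np.inf)
        log_slab = np.log(w) + _normal_logpdf(beta_k, tau2_k) if w > 0 else np.full(beta_k.shape, -np.inf)
    return np.logaddexp(log_spike, log_slab)


def _invgamma_logpdf(x, shape, rate):
    """log density of X when 1/X ~ Gamma(shape, rate)."""
    x = np.asarray(x, dtype=float)
    return shape * math.log(rate) - gammaln(shape) - (shape + 1.0) * np.log(x) - rate / x


def build_slice_covariance(sigma2_c, rho, G, structure="exchangeable"):
    """G x G covariance of the slice random effects for one donor.

    ``exchangeable``: off-diagonal correlation is a constant ``rho``
    (positive definite for ``-1/(G-1) < rho < 1``).  ``autoregressive``:
    correlation decays as ``rho^{|s-t|}`` (``|rho| < 1``).
    """
    if sigma2_c <= 0:
        raise ValueError("sigma2_c must be positive")
    if structure == "exchangeable":
        if G > 1 and not (-1.0 / (G - 1) < rho < 1.0):
            raise ValueError(
                f"exchangeable correlation needs -1/(G-1) = {-1.0 / (G - 1):.4f} < rho < 1, got {rho}"
            )
        R = np.full((G, G), float(rho))
        np.fill_diagonal(R, 1.0)
    elif structure == "autoregressive":
        if not -1.0 < rho < 1.0:
            raise ValueError(f"autoregressive correlation needs |rho| < 1, got {rho}")
        lag = np.abs(np.subtract.outer(np.arange(G), np.arange(G)))
        R = np.asarray(float(rho) ** lag, dtype=float)
    else:
        raise ValueError("structure must be 'exchangeable' or 'autoregressive'")
    return sigma2_c * R


def missingness_logit(gamma, y_i, nbr_obs_fraction):
    """P(R_i = 1) = logit^-1(gamma0 + gamma1 y_i + gamma2 * observed-neighbor fraction)."""
    gamma = np.asarray(gamma, dtype=float)
    return expit(gamma[0] + gamma[1] * np.asarray(y_i, dtype=float) + gamma[2] * np.asarray(nbr_obs_fraction, dtype=float))


def nmig_log_prior(state: ParameterState, config: ModelConfig, n_donors=None, G=None):
    """Log prior of the full (unmarginalized) hierarchy at ``state``.

    Returns ``-inf`` (a sentinel, never an exception) for states outside the
    support, so samplers can reject them gracefully.  Random-effect terms are
    included only when ``state.U`` is present.
    """
    if not (0.0 <= state.eta <= config.c1):
        return NEG_INF
    if not (0.0 <= state.w <= 1.0):
        return NEG_INF
    if np.any(state.tau2 <= 0):
        return NEG_INF
    lp = -math.log(config.c1)  # eta ~ Uniform(0, c1); w ~ Uniform(0,1) adds 0

    iota = state.iota if state.iota is not None else np.ones_like(state.beta)
    valid_spike = np.isclose(iota, config.v0)
    valid_slab = np.isclose(iota, 1.0)
    if not np.all(valid_spike | valid_slab):
        return NEG_INF
    with np.errstate(divide="ignore"):
        lp += float(np.sum(np.where(valid_slab, np.log(state.w) if state.w > 0 else -np.inf,
                                    np.log1p(-state.w) if state.w < 1 else -np.inf)))
    if not np.isfinite(lp):
        return NEG_INF
    lp += float(np.sum(_normal_logpdf(state.beta, iota * state.tau2)))
    lp += float(np.sum(_invgamma_logpdf(state.tau2, config.b1, config.b2)))
    if config.include_intercept:
        lp += float(_normal_logpdf(state.intercept, config.intercept_prior_sd ** 2))

    if state.U is not None:
        U = np.atleast_2d(state.U)
        C, G_ = U.shape
        sigma2 = np.broadcast_to(np.atleast_1d(state.sigma2), (C,))
        if np.any(sigma2 <= 0):
            return NEG_INF
        lo, hi = config.rho_bounds(G_)
        if G_ > 1 and not (lo <= state.rho <= hi):
            return NEG_INF
        for c in range(C):
            Sigma = build_slice_covariance(sigma2[c], state.rho if G_ > 1 else 0.0, G_, config.corr_structure)
            sign, logdet = np.linalg.slogdet(Sigma)
            quad = U[c] @ np.linalg.solve(Sigma, U[c])
            lp += -0.5 * (G_ * math.log(2 * math.pi) + logdet + quad)
            lp += float(_invgamma_logpdf(sigma2[c], config.b3, config.b4))
        if G_ > 1:
            lp += -math.log(hi - lo)
    if state.gamma is not None:
        lp += float(np.sum(_normal_logpdf(state.gamma, config.gamma_prior_sd ** 2)))
    return lp


def joint_log_posterior(study: StudyDataset, graphs, state: ParameterState, config: ModelConfig):
    """Unnormalized log posterior: pseudo-likelihood + priors (+ missingness terms).

    ``graphs`` is one :class:`NeighborGraph` per slice.  Missing labels must
    be carried as imputed values inside each slice's ``y``.  Under
    ``missing_mode='nonignorable'`` the observation-indicator likelihood is
    added; under ``'ignorable'``/``'none'`` it is absent (MCAR factorization).
    """
    lp = nmig_log_prior(state, config)
    if not np.isfinite(lp):
        return NEG_INF
    idx = study.donor_slice_index()
    for slc, graph, (c, g) in zip(study.slices, graphs, idx):
        u = float(np.atleast_2d(state.U)[c, g]) if state.U is not None else 0.0
        lp += pseudo_log_likelihood(slc, graph, state, u=u)
        if config.missing_mode == "nonignorable":
            if state.gamma is None:
                raise ValueError("nonignorable mode requires state.gamma")
            f_r = neighbor_fractions(graph, slc.r.astype(float))
            pi = np.clip(missingness_logit(state.gamma, slc.y, f_r), MU_FLOOR, 1 - MU_FLOOR)
            lp += float(np.sum(slc.r * np.log(pi) + (1 - slc.r) * np.log1p(-pi)))
    return lp
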