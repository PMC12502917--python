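"""Differentiable unconstrained parameterization of the model posterior.

The gradient-based backends (NUTS, ADVI) work on an unconstrained vector
``z``.  This module maps ``z`` to the constrained parameters, evaluates the
log posterior (pseudo-likelihood + priors + Jacobians of the transforms,
with the discrete spike indicators marginalized out) and returns analytic
gradients.  Transforms:

* ``eta = c1 * sigmoid(z)``            (uniform prior on (0, c1))
* ``tau_k^2 = exp(z)``                 (inverse-gamma prior)
* ``w = sigmoid(z)``                   (uniform prior on (0, 1))
* ``sigma_c^2 = exp(z)``               (inverse-gamma prior)
* ``rho = lo + (hi - lo) * sigmoid(z)`` with (lo, hi) the prior bounds
  intersected with the positive-definiteness region
* ``beta``, intercept, ``U``, ``gamma`` live on the real line unchanged.

Missing labels are *not* part of ``z``: they are held as the current
imputed values inside the cached per-slice data and refreshed by the
data-augmentation sweeps between sampling epochs (``set_labels``).

The gradients are exercised against central finite differences in the test
suite, with every model feature switched on.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit

from .model_core import MU_FLOOR, ModelConfig, ParameterState, build_slice_covariance
from .spatial_graph import neighbor_fractions

LOG2PI = math.log(2.0 * math.pi)


def _log_sigmoid(x):
    # log sigma(x) and log(1 - sigma(x)), overflow-safe
    return -np.logaddexp(0.0, -x), -np.logaddexp(0.0, x)


class UnconstrainedPosterior:
    """Caches data and exposes ``value_and_grad`` over the free parameters."""

    def __init__(self, study, graphs, config: ModelConfig):
        self.config = config
        self.graphs = list(graphs)
        self.study = study
        self.d = len(study.gene_names)
        self.donors = study.donors
        self.C = len(self.donors)
        idx = study.donor_slice_index()
        self.slice_cg = idx
        self.G = max(g for _, g in idx) + 1
        self.use_random_effects = study.n_slices > 1
        self.use_rho = self.use_random_effects and self.G > 1
        self.use_gamma = config.missing_mode == "nonignorable"

        self._slices = []
        for slc, graph in zip(study.slices, self.graphs):
            y = np.asarray(slc.y, dtype=float).copy()
            miss = np.isnan(y)
            y[miss] = 0.0
            obs = slc.r == 1
            entry = {
                "X": slc.X[obs],
                "obs": obs,
                "y_obs": np.asarray(slc.y, dtype=float)[obs],
                "y_full": y,
                "graph": graph,
                "f": None,
                "r": slc.r.astype(float),
                "f_r": neighbor_fractions(graph, slc.r.astype(float)),
            }
            entry["f"] = neighbor_fractions(graph, y)
            self._slices.append(entry)

        # layout of the free vector
        layout = {}
        pos = 0

        def block(name, size):
            nonlocal pos
            layout[name] = slice(pos, pos + size)
            pos += size

        block("beta", self.d)
        if config.include_intercept:
            block("intercept", 1)
        if config.eta_fixed is None:
            block("z_eta", 1)
        if config.tau2_fixed is None:
            block("z_logtau2", self.d)
        if config.w_fixed is None:
            block("z_w", 1)
        if self.use_random_effects:
            block("U", self.C * self.G)
            block("z_logsigma2", self.C)
            if self.use_rho:
                block("z_rho", 1)
        if self.use_gamma:
            self.free_gamma = [k for k in range(3) if k not in config.gamma_fixed]
            block("gamma", len(self.free_gamma))
        self.layout = layout
        self.n_params = pos
        if self.use_rho:
            self.rho_lo, self.rho_hi = config.rho_bounds(self.G)

    # -- label augmentation hooks -------------------------------------------------
    def set_labels(self, slice_idx, y_full):
        """Install imputed labels for one slice and refresh neighbor fractions."""
        e = self._slices[slice_idx]
        e["y_full"] = np.asarray(y_full, dtype=float)
        e["f"] = neighbor_fractions(e["graph"], e["y_full"])

    def current_labels(self, slice_idx):
        return self._slices[slice_idx]["y_full"].copy()

    # -- parameter mapping --------------------------------------------------------
    def initial_z(self):
        z = np.zeros(self.n_params)
        return z

    def unpack(self, z) -> ParameterState:
        cfg = self.config
        g = lambda name: z[self.layout[name]]
        beta = g("beta").copy()
        intercept = float(g("intercept")[0]) if "intercept" in self.layout else 0.0
        eta = cfg.eta_fixed if cfg.eta_fixed is not None else cfg.c1 * expit(float(g("z_eta")[0]))
        tau2 = (np.full(self.d, cfg.tau2_fixed) if cfg.tau2_fixed is not None
                else np.exp(g("z_logtau2")))
        w = cfg.w_fixed if cfg.w_fixed is not None else float(expit(g("z_w")[0]))
        U = sigma2 = None
        rho = 0.0
        if self.use_random_effects:
            U = g("U").reshape(self.C, self.G).copy()
            sigma2 = np.exp(g("z_logsigma2"))
            if self.use_rho:
                rho = self.rho_lo + (self.rho_hi - self.rho_lo) * expit(float(g("z_rho")[0]))
        gamma = None
        if self.use_gamma:
            gamma = np.zeros(3)
            for k, v in cfg.gamma_fixed.items():
                gamma[k] = v
            gamma[self.free_gamma] = g("gamma")
        return ParameterState(beta=beta, eta=float(eta), tau2=tau2, w=w,
                              intercept=intercept, U=U, sigma2=sigma2, rho=float(rho),
                              gamma=gamma)

    # -- log posterior and gradient ----------------------------------------------
    def value_and_grad(self, z):
        cfg = self.config
        st = self.unpack(z)
        grad = np.zeros_like(z)
        lp = 0.0
        L = self.layout

        # transform intermediates
        if cfg.eta_fixed is None:
            z_eta = float(z[L["z_eta"]][0])
            s_eta = expit(z_eta)
        if cfg.w_fixed is None:
            z_w = float(z[L["z_w"]][0])
            s_w = expit(z_w)
        grad_eta = 0.0          # w.r.t. constrained eta
        grad_w = 0.0            # w.r.t. constrained w
        grad_tau2 = np.zeros(self.d)  # w.r.t. constrained tau2

        # ---- pseudo-likelihood over slices ----
        for e, (c, gidx) in zip(self._slices, self.slice_cg):
            u = st.U[c, gidx] if st.U is not None else 0.0
            f_obs = e["f"][e["obs"]]
            a = e["X"] @ st.beta + st.intercept + st.eta * f_obs + u
            mu = expit(a)
            mu_c = np.clip(mu, MU_FLOOR, 1 - MU_FLOOR)
            y = e["y_obs"]
            lp += float(np.sum(y * np.log(mu_c) + (1 - y) * np.log1p(-mu_c)))
            resid = y - mu
            grad[L["beta"]] += e["X"].T @ resid
            if "intercept" in L:
                grad[L["intercept"]] += resid.sum()
            grad_eta += float(resid @ f_obs)
            if st.U is not None:
                grad[L["U"]][c * self.G + gidx] += resid.sum()

            if self.use_gamma:
                gm = st.gamma
                yf = e["y_full"]
                pi = expit(gm[0] + gm[1] * yf + gm[2] * e["f_r"])
                pi_c = np.clip(pi, MU_FLOOR, 1 - MU_FLOOR)
                r = e["r"]
                lp += float(np.sum(r * np.log(pi_c) + (1 - r) * np.log1p(-pi_c)))
                rres = r - pi
                full_g = np.array([rres.sum(), float(rres @ yf), float(rres @ e["f_r"])])
                grad[L["gamma"]] += full_g[self.free_gamma]

        # ---- beta prior (spike indicator marginalized) ----
        tau2 = st.tau2
        v0 = cfg.v0
        w = st.w
        b = st.beta
        var_sp = v0 * tau2
        var_sl = tau2
        logN_sp = -0.5 * (LOG2PI + np.log(var_sp)) - 0.5 * b * b / var_sp
        logN_sl = -0.5 * (LOG2PI + np.log(var_sl)) - 0.5 * b * b / var_sl
        if w >= 1.0:
            logm = logN_sl
            p_sl = np.ones(self.d)
        elif w <= 0.0:
            logm = logN_sp
            p_sl = np.zeros(self.d)
        else:
            A = np.log1p(-w) + logN_sp
            Bv = np.log(w) + logN_sl
            logm = np.logaddexp(A, Bv)
            p_sl = np.exp(Bv - logm)
        p_sp = 1.0 - p_sl
        lp += float(np.sum(logm))
        grad[L["beta"]] += -b * (p_sp / var_sp + p_sl / var_sl)
        grad_tau2 += (p_sp * (-0.5 / tau2 + 0.5 * b * b / (v0 * tau2 * tau2))
                      + p_sl * (-0.5 / tau2 + 0.5 * b * b / (tau2 * tau2)))
        if cfg.w_fixed is None and 0.0 < w < 1.0:
            grad_w += float(np.sum(np.exp(logN_sl - logm) - np.exp(logN_sp - logm)))

        # ---- tau2 prior + jacobian ----
        if cfg.tau2_fixed is None:
            lp += float(np.sum(-(cfg.b1 + 1.0) * np.log(tau2) - cfg.b2 / tau2
                               + cfg.b1 * math.log(cfg.b2)))
            lp += float(np.sum(np.log(tau2)))  # jacobian of exp
            grad[L["z_logtau2"]] += grad_tau2 * tau2 + (-cfg.b1 + cfg.b2 / tau2)

        # ---- eta uniform prior: jacobian only ----
        if cfg.eta_fixed is None:
            ls, l1ms = _log_sigmoid(z_eta)
            lp += math.log(cfg.c1) + ls + l1ms
            grad[L["z_eta"]] += grad_eta * cfg.c1 * s_eta * (1 - s_eta) + (1.0 - 2.0 * s_eta)

        # ---- w uniform prior: jacobian only ----
        if cfg.w_fixed is None:
            ls, l1ms = _log_sigmoid(z_w)
            lp += ls + l1ms
            grad[L["z_w"]] += grad_w * s_w * (1 - s_w) + (1.0 - 2.0 * s_w)

        # ---- intercept prior ----
        if cfg.include_intercept:
            v = cfg.intercept_prior_sd ** 2
            lp += -0.5 * (LOG2PI + math.log(v)) - 0.5 * st.intercept ** 2 / v
            grad[L["intercept"]] += -st.intercept / v

        # ---- random effects ----
        if self.use_random_effects:
            sigma2 = st.sigma2
            rho = st.rho
            G = self.G
            if G > 1:
                R = build_slice_covariance(1.0, rho, G, cfg.corr_structure)
                if cfg.corr_structure == "exchangeable":
                    dR = np.ones((G, G)) - np.eye(G)
                else:
                    lag = np.abs(np.subtract.outer(np.arange(G), np.arange(G)))
                    with np.errstate(divide="ignore", invalid="ignore"):
                        dR = np.where(lag > 0, lag * rho ** np.maximum(lag - 1, 0), 0.0)
            else:
                R = np.eye(1)
                dR = np.zeros((1, 1))
            Rinv = np.linalg.inv(R)
            sign, logdetR = np.linalg.slogdet(R)
            grad_rho = 0.0
            for c in range(self.C):
                u = st.U[c]
                Rinv_u = Rinv @ u
                quad = float(u @ Rinv_u)
                lp += -0.5 * (G * (LOG2PI + math.log(sigma2[c])) + logdetR + quad / sigma2[c])
                grad[L["U"]][c * G:(c + 1) * G] += -Rinv_u / sigma2[c]
                dlp_dsig2 = -0.5 * G / sigma2[c] + 0.5 * quad / sigma2[c] ** 2
                # inverse-gamma prior + log jacobian
                lp += (-(cfg.b3 + 1.0) * math.log(sigma2[c]) - cfg.b4 / sigma2[c]
                       + cfg.b3 * math.log(cfg.b4) + math.log(sigma2[c]))
                grad[L["z_logsigma2"]][c] += dlp_dsig2 * sigma2[c] + (-cfg.b3 + cfg.b4 / sigma2[c])
                if self.use_rho:
                    grad_rho += 0.5 * float(Rinv_u @ dR @ Rinv_u) / sigma2[c] \
                        - 0.5 * float(np.sum(Rinv * dR))
            if self.use_rho:
                z_r = float(z[L["z_rho"]][0])
                s_r = expit(z_r)
                width = self.rho_hi - self.rho_lo
                ls, l1ms = _log_sigmoid(z_r)
                lp += math.log(width) + ls + l1ms
                grad[L["z_rho"]] += grad_rho * width * s_r * (1 - s_r) + (1.0 - 2.0 * s_r)

        # ---- gamma prior ----
        if self.use_gamma:
            v = cfg.gamma_prior_sd ** 2
            gfree = st.gamma[self.free_gamma]
            lp += float(np.sum(-0.5 * (LOG2PI + math.log(v)) - 0.5 * gfree ** 2 / v))
            grad[L["gamma"]] += -gfree / v

        return lp, grad

    def logp(self, z):
        return self.value_and_grad(z)[0]
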