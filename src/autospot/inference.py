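"""Posterior estimation: NUTS and ADVI backends, augmentation, summaries.

Both backends operate on the same analytically differentiated unconstrained
pseudo-posterior (see ``_posterior``).  The spike indicators are marginalized
out of the coefficient prior; the posterior inclusion probability of each
gene is recovered per draw from the conditional odds of the slab component
and averaged.  Missing disease labels are treated by data augmentation:
between sampling epochs they are resampled from the neighbor-fraction
conditional (weighted by the observation model in the nonignorable case) and
held fixed as conditioning values within an epoch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from ._advi import fit_advi_meanfield
from ._nuts import sample_nuts
from ._posterior import UnconstrainedPosterior
from .model_core import ModelConfig, ParameterState, missingness_logit
from .spatial_graph import neighbor_fractions

__all__ = [
    "PosteriorSummary",
    "fit_map",
    "fit_nuts",
    "fit_advi",
    "fit",
    "run_data_augmentation",
    "initial_missing_labels",
    "summarize",
    "diagnostics",
]

AUGMENT_EPOCH_DRAWS = 25   # NUTS draws between label-augmentation rounds
AUGMENT_SWEEPS = 5         # Gibbs sweeps over the missing set per round


@dataclass
class PosteriorSummary:
    """Draws plus the per-parameter summaries downstream analyses consume."""

    draws: dict
    mean: dict
    sd: dict
    cri_low: dict
    cri_high: dict
    std_effect: np.ndarray
    inclusion_prob: np.ndarray
    gene_names: list
    backend: str
    diagnostics: pd.DataFrame = None
    level: float = 0.95
    config: ModelConfig = None

    @property
    def beta_mean(self):
        return self.mean["beta"]

    @property
    def eta_mean(self):
        return float(np.asarray(self.mean["eta"]).ravel()[0]) if "eta" in self.mean else 0.0

    @property
    def intercept_mean(self):
        return float(np.asarray(self.mean["intercept"]).ravel()[0]) if "intercept" in self.mean else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.mean.items():
            m = np.atleast_1d(m)
            sd = np.atleast_1d(self.sd[name])
            lo = np.atleast_1d(self.cri_low[name])
            hi = np.atleast_1d(self.cri_high[name])
            for k in range(m.size):
                label = name if m.size == 1 else (
                    f"beta[{self.gene_names[k]}]" if name == "beta" and k < len(self.gene_names)
                    else f"{name}[{k}]")
                rows.append({"parameter": label, "mean": m[k], "sd": sd[k],
                             "cri_low": lo[k], "cri_high": hi[k]})
        return pd.DataFrame(rows)


def initial_missing_labels(slc, graph):
    """Deterministic starting imputation: observed-neighbor majority, else slice rate."""
    y = np.asarray(slc.y, dtype=float).copy()
    obs = slc.r == 1
    rate = float(y[obs].mean()) if obs.any() else 0.5
    fill = np.round(rate)
    for i in np.where(~obs)[0]:
        nbrs = graph.neighbor_sets[i]
        nbr_obs = nbrs[obs[nbrs]] if len(nbrs) else nbrs
        if len(nbr_obs):
            frac = y[nbr_obs].mean()
            y[i] = 1.0 if frac > 0.5 else 0.0 if frac < 0.5 else fill
        else:
            y[i] = fill
    return y


def imputation_fraction(graph, y, k, fallback=0.5):
    """The imputation law's success probability mu*_k for missing spot ``k``.

    The disease fraction among the neighbors of ``k`` under the current label
    assignment (observed values where observed, imputed values elsewhere);
    ``fallback`` is returned for isolated spots.
    """
    nbrs = graph.neighbor_sets[k]
    if len(nbrs) == 0:
        return float(fallback)
    return float(np.asarray(y, dtype=float)[nbrs].mean())


def run_data_augmentation(state: ParameterState, study, graphs, config: ModelConfig,
                          seed=0, labels=None, n_sweeps=AUGMENT_SWEEPS):
    """Resample missing labels by Gibbs sweeps over the neighbor-fraction law.

    Each missing spot *k* draws ``Y_k ~ Bernoulli(mu*_k)`` where ``mu*_k`` is
    the current disease fraction among its neighbors (observed and imputed
    alike); isolated missing spots fall back on the slice-wide observed rate.
    Under ``missing_mode='nonignorable'`` the spot's own observation term
    ``P(R_k = 0 | y_k)`` reweights the two outcomes.  Returns one label
    vector per slice.
    """
    if config.missing_mode == "none":
        raise ValueError("no augmentation when missing_mode='none'")
    rng = np.random.default_rng(seed)
    out = []
    for s, (slc, graph) in enumerate(zip(study.slices, graphs)):
        y = (np.asarray(labels[s], dtype=float).copy() if labels is not None
             else initial_missing_labels(slc, graph))
        miss = np.where(slc.r == 0)[0]
        if len(miss) == 0:
            out.append(y)
            continue
        obs = slc.r == 1
        rate = float(np.asarray(slc.y, dtype=float)[obs].mean()) if obs.any() else 0.5
        use_r = (config.missing_mode == "nonignorable" and state is not None
                 and state.gamma is not None)
        if use_r:
            f_r = neighbor_fractions(graph, slc.r.astype(float))
        for _ in range(n_sweeps):
            order = rng.permutation(len(miss))
            us = rng.random(len(miss))
            for t, ki in enumerate(order):
                k = miss[ki]
                mu_star = imputation_fraction(graph, y, k, fallback=rate)
                if use_r:
                    p1 = mu_star * (1.0 - missingness_logit(state.gamma, 1.0, f_r[k]))
                    p0 = (1.0 - mu_star) * (1.0 - missingness_logit(state.gamma, 0.0, f_r[k]))
                    tot = p1 + p0
                    mu_star = p1 / tot if tot > 0 else mu_star
                y[k] = 1.0 if us[t] < mu_star else 0.0
        out.append(y)
    return out


def _augmented_posterior(study, graphs, config):
    post = UnconstrainedPosterior(study, graphs, config)
    if config.missing_mode != "none":
        for s, (slc, graph) in enumerate(zip(study.slices, graphs)):
            post.set_labels(s, initial_missing_labels(slc, graph))
    return post


def fit_map(study, graphs, config: ModelConfig, max_iter=500):
    """Posterior mode on the unconstrained scale via L-BFGS (plug-in imputation).

    With a flat-ish slab-only prior and ``eta_fixed=0`` this reduces to
    (penalized) logistic regression.
    """
    post = _augmented_posterior(study, graphs, config)

    def neg(z):
        lp, g = post.value_and_grad(z)
        return -lp, -g

    res = minimize(neg, post.initial_z(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    return post.unpack(res.x), post, res


def _collect_draws(post: UnconstrainedPosterior, z_chains):
    """Map unconstrained chain draws to named constrained draw arrays."""
    chains, n, _ = z_chains.shape
    cfg = post.config
    d = post.d
    out = {"beta": np.empty((chains, n, d)), "tau2": np.empty((chains, n, d)),
           "eta": np.empty((chains, n)), "w": np.empty((chains, n))}
    if cfg.include_intercept:
        out["intercept"] = np.empty((chains, n))
    if post.use_random_effects:
        out["U"] = np.empty((chains, n, post.C, post.G))
        out["sigma2"] = np.empty((chains, n, post.C))
        if post.use_rho:
            out["rho"] = np.empty((chains, n))
    if post.use_gamma:
        out["gamma"] = np.empty((chains, n, 3))
    for ci in range(chains):
        for t in range(n):
            st = post.unpack(z_chains[ci, t])
            out["beta"][ci, t] = st.beta
            out["tau2"][ci, t] = st.tau2
            out["eta"][ci, t] = st.eta
            out["w"][ci, t] = st.w
            if cfg.include_intercept:
                out["intercept"][ci, t] = st.intercept
            if post.use_random_effects:
                out["U"][ci, t] = st.U
                out["sigma2"][ci, t] = st.sigma2
                if post.use_rho:
                    out["rho"][ci, t] = st.rho
            if post.use_gamma:
                out["gamma"][ci, t] = st.gamma
    return out


def _inclusion_probability(draws, v0):
    """Posterior P(slab) per gene: conditional odds of iota_k = 1, averaged over draws."""
    beta = draws["beta"]
    tau2 = draws["tau2"]
    w = draws["w"][..., None]
    log_slab = -0.5 * np.log(tau2) - 0.5 * beta ** 2 / tau2
    log_spike = -0.5 * np.log(v0 * tau2) - 0.5 * beta ** 2 / (v0 * tau2)
    with np.errstate(divide="ignore"):
        a = np.log(np.clip(w, 1e-300, None)) + log_slab
        b = np.log(np.clip(1 - w, 1e-300, None)) + log_spike
    p = np.where(w >= 1.0, 1.0, np.where(w <= 0.0, 0.0, expit(a - b)))
    return p.mean(axis=(0, 1))


def summarize(draws: dict, level: float = 0.95, gene_names=None, v0=0.005,
              backend="nuts", config=None) -> PosteriorSummary:
    """Equal-tailed posterior summaries from named draw arrays.

    ``draws`` maps parameter name to an array shaped (chains, draws, *shape*).
    Standardized effects |mean|/sd are computed for the gene coefficients;
    a constant draw stream yields sd = 0 and a NaN standardized effect.
    """
    for k, v in draws.items():
        if v.shape[0] * v.shape[1] < 2:
            raise ValueError("need at least two draws per parameter")
    alpha = (1.0 - level) / 2.0
    mean, sd, lo, hi = {}, {}, {}, {}
    for name, arr in draws.items():
        flat = arr.reshape(-1, *arr.shape[2:])
        mean[name] = flat.mean(axis=0)
        sd[name] = flat.std(axis=0, ddof=1)
        lo[name] = np.quantile(flat, alpha, axis=0)
        hi[name] = np.quantile(flat, 1 - alpha, axis=0)
    beta_mean = np.atleast_1d(mean["beta"])
    beta_sd = np.atleast_1d(sd["beta"])
    with np.errstate(divide="ignore", invalid="ignore"):
        std_effect = np.where(beta_sd > 0, np.abs(beta_mean) / beta_sd, np.nan)
    if config is not None and config.w_fixed in (0.0, 1.0):
        incl = np.full(beta_mean.size, float(config.w_fixed >= 1.0))
    elif "tau2" in draws and "w" in draws:
        incl = _inclusion_probability(draws, v0)
    else:
        incl = np.full(beta_mean.size, np.nan)
    if gene_names is None:
        gene_names = [f"g{k}" for k in range(beta_mean.size)]
    return PosteriorSummary(draws=draws, mean=mean, sd=sd, cri_low=lo, cri_high=hi,
                            std_effect=std_effect, inclusion_prob=incl,
                            gene_names=list(gene_names), backend=backend,
                            level=level, config=config)


def diagnostics(draws: dict) -> pd.DataFrame:
    """Split-chain potential scale reduction and effective sample size per parameter.

    Values are computed with arviz; the documented convergence threshold is
    rhat <= 1.01.  A single chain is split in half first (with a warning).
    """
    import arviz as az

    rows = []
    for name, arr in draws.items():
        a = arr
        if a.shape[0] == 1:
            warnings.warn("single chain: using split-chain diagnostics")
            half = a.shape[1] // 2
            a = np.concatenate([a[:, :half], a[:, half:2 * half]], axis=0)
        ds = az.convert_to_dataset({name: a})
        rh = np.atleast_1d(np.asarray(az.rhat(ds)[name]).ravel())
        es = np.atleast_1d(np.asarray(az.ess(ds)[name]).ravel())
        for k in range(rh.size):
            label = name if rh.size == 1 else f"{name}[{k}]"
            rows.append({"parameter": label, "rhat": float(rh[k]), "ess": float(es[k]),
                         "converged": bool(rh[k] <= 1.01)})
    return pd.DataFrame(rows)


def _finalize(post, z_chains, backend, level, extra_diag=None):
    draws = _collect_draws(post, z_chains)
    summ = summarize(draws, level=level, gene_names=post.study.gene_names,
                     v0=post.config.v0, backend=backend, config=post.config)
    if backend == "nuts":
        try:
            summ.diagnostics = diagnostics({k: draws[k] for k in ("beta", "eta")
                                            if k in draws})
        except Exception:  # diagnostics are best-effort reporting
            summ.diagnostics = pd.DataFrame()
    else:
        # variational draws are iid from q; chain convergence metrics do not apply
        summ.diagnostics = pd.DataFrame()
    if extra_diag and summ.diagnostics is not None:
        summ.diagnostics.attrs.update(extra_diag)
    return summ


def fit_nuts(study, graphs, config: ModelConfig, n_warmup=400, n_draws=600,
             chains=2, seed=0, target_accept=0.8, level=0.95) -> PosteriorSummary:
    """NUTS sampling of the continuous parameters (spike indicators marginalized).

    With missing spots, warmup runs on the initial imputation and sampling
    proceeds in epochs of ``AUGMENT_EPOCH_DRAWS`` draws with the missing
    labels re-drawn between epochs.  A high divergence fraction is reported
    in the diagnostics, never raised.
    """
    post = _augmented_posterior(study, graphs, config)
    has_missing = config.missing_mode != "none" and any((s.r == 0).any() for s in study.slices)
    all_chains = []
    total_div = 0
    for ci in range(chains):
        chain_seed = seed + 1000003 * ci
        if not has_missing:
            zs, info, _ = sample_nuts(post.value_and_grad, post.initial_z(),
                                      n_warmup, n_draws, seed=chain_seed,
                                      target_accept=target_accept)
            total_div += info["divergences"]
        else:
            zs_w, info, st = sample_nuts(post.value_and_grad, post.initial_z(),
                                         n_warmup, 1, seed=chain_seed,
                                         target_accept=target_accept)
            total_div += info["divergences"]
            z = zs_w[-1]
            segs = []
            labels = [post.current_labels(s) for s in range(study.n_slices)]
            n_epochs = max(1, math.ceil(n_draws / AUGMENT_EPOCH_DRAWS))
            for e in range(n_epochs):
                state = post.unpack(z)
                labels = run_data_augmentation(state, study, graphs, config,
                                               seed=chain_seed + 7 * e + 1, labels=labels)
                for s, y in enumerate(labels):
                    post.set_labels(s, y)
                k = min(AUGMENT_EPOCH_DRAWS, n_draws - len(np.concatenate(segs)) if segs else n_draws)
                zs, info, st = sample_nuts(post.value_and_grad, z, 0, k,
                                           state=st, adapt=False)
                total_div += info["divergences"]
                z = zs[-1]
                segs.append(zs)
            zs = np.concatenate(segs)[:n_draws]
        all_chains.append(zs)
    z_chains = np.stack(all_chains)
    frac_div = total_div / max(1, chains * (n_warmup + n_draws))
    if frac_div > 0.05:
        warnings.warn(f"divergent transitions in {frac_div:.1%} of iterations")
    return _finalize(post, z_chains, "nuts", level,
                     extra_diag={"divergences": total_div})


def fit_advi(study, graphs, config: ModelConfig, n_iter=3000, learning_rate=0.02,
             n_mc_draws=2, n_out_draws=1000, seed=0, level=0.95,
             init_at_map=True) -> PosteriorSummary:
    """Mean-field Gaussian variational fit; draws are sampled from the fitted q.

    The variational mean starts at the (cheap) MAP point by default.  With
    missing spots, labels are re-augmented every 50 optimizer iterations and
    once more before the final posterior draws are taken.
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    post = _augmented_posterior(study, graphs, config)
    has_missing = config.missing_mode != "none" and any((s.r == 0).any() for s in study.slices)
    z0 = post.initial_z()
    if init_at_map:
        def neg(z):
            lp, g = post.value_and_grad(z)
            return -lp, -g
        res = minimize(neg, z0, jac=True, method="L-BFGS-B", options={"maxiter": 200})
        z0 = res.x

    cb = None
    if has_missing:
        labels = [post.current_labels(s) for s in range(study.n_slices)]
        holder = {"m": z0, "labels": labels, "e": 0}

        def cb(it):
            state = post.unpack(holder["m"])
            holder["labels"] = run_data_augmentation(
                state, study, graphs, config, seed=seed + 17 * holder["e"] + 3,
                labels=holder["labels"])
            holder["e"] += 1
            for s, y in enumerate(holder["labels"]):
                post.set_labels(s, y)

    def value_grad(z):
        if has_missing:
            holder["m"] = z
        return post.value_and_grad(z)

    m, s, trace = fit_advi_meanfield(value_grad, z0, n_iter=n_iter,
                                     learning_rate=learning_rate, n_mc=n_mc_draws,
                                     seed=seed, epoch_callback=cb)
    rng = np.random.default_rng(seed + 999331)
    zs = m + s * rng.standard_normal((n_out_draws, m.size))
    z_chains = zs[None, :, :]
    summ = _finalize(post, z_chains, "advi", level,
                     extra_diag={"final_elbo": float(trace["elbo"][-10:].mean())})
    return summ


def fit(study, graphs, config, backend="advi", **kwargs):
    """Dispatch to :func:`fit_nuts` or :func:`fit_advi`."""
    if backend == "nuts":
        return fit_nuts(study, graphs, config, **kwargs)
    if backend == "advi":
        return fit_advi(study, graphs, config, **kwargs)
    raise ValueError(f"unknown backend {backend!r}; choose 'nuts' or 'advi'")
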