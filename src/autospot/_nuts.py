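"""No-U-Turn sampler with dual-averaging step-size and diagonal metric adaptation.

A self-contained implementation of the slice-variant NUTS recursion over an
arbitrary differentiable log density.  Warmup adapts the step size toward a
target acceptance statistic throughout, and estimates a diagonal mass matrix
once from the middle stretch of warmup draws; both are then frozen for
sampling.  Trajectories are capped at ``max_treedepth`` doublings and a
divergence is flagged when the Hamiltonian error exceeds 1000.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["sample_nuts", "NutsState"]

DIVERGENCE_THRESHOLD = 1000.0


class NutsState:
    """Frozen sampler settings carried between epochs of one chain."""

    def __init__(self, step_size, inv_metric, rng):
        self.step_size = step_size
        self.inv_metric = inv_metric
        self.rng = rng


def _leapfrog(value_grad, z, p, grad, eps, inv_metric):
    p = p + 0.5 * eps * grad
    z = z + eps * inv_metric * p
    lp, grad = value_grad(z)
    p = p + 0.5 * eps * grad
    return z, p, lp, grad


def _hamiltonian(lp, p, inv_metric):
    return lp - 0.5 * float(p @ (inv_metric * p))


def _find_reasonable_step(value_grad, z, rng, inv_metric):
    eps = 1.0
    lp, grad = value_grad(z)
    p = rng.standard_normal(z.size) / np.sqrt(inv_metric)
    h0 = _hamiltonian(lp, p, inv_metric)
    z1, p1, lp1, _ = _leapfrog(value_grad, z, p, grad, eps, inv_metric)
    dh = _hamiltonian(lp1, p1, inv_metric) - h0
    if not np.isfinite(dh):
        dh = -np.inf
    a = 1.0 if dh > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** a
        z1, p1, lp1, _ = _leapfrog(value_grad, z, p, grad, eps, inv_metric)
        dh = _hamiltonian(lp1, p1, inv_metric) - h0
        if not np.isfinite(dh):
            dh = -np.inf
        if (a == 1.0 and dh <= math.log(0.5)) or (a == -1.0 and dh >= math.log(0.5)):
            break
    return eps


def _build_tree(value_grad, z, p, grad, log_u, direction, depth, eps, inv_metric, h0, stats):
    if depth == 0:
        z1, p1, lp1, grad1 = _leapfrog(value_grad, z, p * direction, grad, eps, inv_metric)
        p1 = p1 * direction
        h1 = _hamiltonian(lp1, p1, inv_metric)
        if not np.isfinite(h1):
            h1 = -np.inf
        n1 = 1 if log_u <= h1 - h0 else 0
        diverged = (h0 - h1) + log_u > DIVERGENCE_THRESHOLD or not np.isfinite(h1)
        stats["accept_sum"] += min(1.0, math.exp(min(0.0, h1 - h0)))
        stats["accept_n"] += 1
        return z1, p1, grad1, z1, p1, grad1, z1, grad1, lp1, n1, (not diverged), diverged
    (zm, pm, gm, zp, pp, gp, zprop, gprop, lpprop, n1, cont, div) = _build_tree(
        value_grad, z, p, grad, log_u, direction, depth - 1, eps, inv_metric, h0, stats)
    if cont:
        if direction == 1:
            (_, _, _, zp, pp, gp, zprop2, gprop2, lpprop2, n2, cont2, div2) = _build_tree(
                value_grad, zp, pp, gp, log_u, direction, depth - 1, eps, inv_metric, h0, stats)
        else:
            (zm, pm, gm, _, _, _, zprop2, gprop2, lpprop2, n2, cont2, div2) = _build_tree(
                value_grad, zm, pm, gm, log_u, direction, depth - 1, eps, inv_metric, h0, stats)
        if n1 + n2 > 0 and stats["rng"].random() < n2 / (n1 + n2):
            zprop, gprop, lpprop = zprop2, gprop2, lpprop2
        dz = zp - zm
        cont = cont2 and (dz @ (inv_metric * pm) >= 0) and (dz @ (inv_metric * pp) >= 0)
        n1 += n2
        div = div or div2
    return zm, pm, gm, zp, pp, gp, zprop, gprop, lpprop, n1, cont, div


def _transition(value_grad, z, lp, grad, eps, inv_metric, rng, max_treedepth):
    p0 = rng.standard_normal(z.size) / np.sqrt(inv_metric)
    h0 = _hamiltonian(lp, p0, inv_metric)
    # slice variable relative to the initial Hamiltonian: include a state
    # when log_u <= h(state) - h0
    log_u = math.log(max(rng.random(), 1e-300))
    stats = {"accept_sum": 0.0, "accept_n": 0, "rng": rng}
    zm = zp = z
    pm = pp = p0
    gm = gp = grad
    zprop, gprop, lpprop = z, grad, lp
    n = 1
    diverged = False
    for depth in range(max_treedepth):
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            (_, _, _, zp, pp, gp, zc, gc, lpc, n1, cont, div) = _build_tree(
                value_grad, zp, pp, gp, log_u, 1, depth, eps, inv_metric, h0, stats)
        else:
            (zm, pm, gm, _, _, _, zc, gc, lpc, n1, cont, div) = _build_tree(
                value_grad, zm, pm, gm, log_u, -1, depth, eps, inv_metric, h0, stats)
        diverged = diverged or div
        if cont and n1 > 0 and rng.random() < min(1.0, n1 / n):
            zprop, gprop, lpprop = zc, gc, lpc
        n += n1
        dz = zp - zm
        if (not cont) or (dz @ (inv_metric * pm) < 0) or (dz @ (inv_metric * pp) < 0):
            break
    accept = stats["accept_sum"] / max(stats["accept_n"], 1)
    return zprop, lpprop, gprop, accept, diverged


def sample_nuts(value_grad, z0, n_warmup, n_draws, seed=0, target_accept=0.8,
                max_treedepth=10, state: NutsState = None, adapt=True):
    """Run one NUTS chain; returns (draws, info dict, NutsState).

    When ``state`` is given (and ``adapt=False``) the chain continues with
    frozen step size / metric — used for epoch-wise interleaving with label
    augmentation.
    """
    z = np.asarray(z0, dtype=float).copy()
    dim = z.size
    rng = np.random.default_rng(seed) if state is None else state.rng
    inv_metric = np.ones(dim) if state is None else state.inv_metric
    lp, grad = value_grad(z)
    if not np.isfinite(lp):
        raise ValueError("non-finite log posterior at the initial point")

    divergences = 0
    accepts = []

    if adapt:
        eps = _find_reasonable_step(value_grad, z, rng, inv_metric)
        mu = math.log(10.0 * eps)
        log_eps_bar, h_bar = 0.0, 0.0
        gamma, t0, kappa = 0.05, 10.0, 0.75
        win_lo, win_hi = max(1, int(0.3 * n_warmup)), max(2, int(0.85 * n_warmup))
        window = []
        t_adapt = 0
        for t in range(n_warmup):
            z, lp, grad, accept, div = _transition(value_grad, z, lp, grad, eps, inv_metric, rng, max_treedepth)
            divergences += div
            t_adapt += 1
            h_bar = (1 - 1 / (t_adapt + t0)) * h_bar + (target_accept - accept) / (t_adapt + t0)
            log_eps = mu - math.sqrt(t_adapt) / gamma * h_bar
            wt = t_adapt ** (-kappa)
            log_eps_bar = wt * log_eps + (1 - wt) * log_eps_bar
            eps = math.exp(log_eps)
            if win_lo <= t < win_hi:
                window.append(z.copy())
            if t == win_hi - 1 and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0, ddof=1) + 1e-6
                inv_metric = var
                eps = _find_reasonable_step(value_grad, z, rng, inv_metric)
                mu = math.log(10.0 * eps)
                log_eps_bar, h_bar, t_adapt = 0.0, 0.0, 0
        eps = math.exp(log_eps_bar) if n_warmup > 0 else eps
    else:
        eps = state.step_size

    draws = np.empty((n_draws, dim))
    for t in range(n_draws):
        z, lp, grad, accept, div = _transition(value_grad, z, lp, grad, eps, inv_metric, rng, max_treedepth)
        divergences += div
        accepts.append(accept)
        draws[t] = z
    info = {
        "divergences": divergences,
        "mean_accept": float(np.mean(accepts)) if accepts else float("nan"),
        "step_size": eps,
    }
    return draws, info, NutsState(eps, inv_metric, rng)
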