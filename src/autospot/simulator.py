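"""Synthetic spatial transcriptomics studies with known ground truth.

The generator draws expression, then binary disease labels from the
autologistic conditionals by random-scan Gibbs sweeps, optionally layered
with donor/slice random effects and (MCAR or spatially autocorrelated
nonignorable) missingness.  Two layouts are offered:

* ``torus`` — an L x L grid with wrap-around distance.  Every spot then has
  exactly four neighbors, the per-spot conditionals are consistent with a
  joint Ising law with edge weight ``eta/4`` and fields ``x_i' beta``, and
  the chain's stationary distribution can be enumerated exactly on tiny
  instances.  All oracle tests use this layout.
* ``grid`` — a bounded L x L grid, matching real slides (boundary spots have
  fewer neighbors).  Here the conditionals are the usual Besag-type
  approximation and no exact joint exists.

Everything is reproducible bit-for-bit under a fixed seed and sweep count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import SpatialSlice, StudyDataset
from .model_core import ModelConfig, ParameterState, build_slice_covariance, missingness_logit
from .spatial_graph import NeighborGraph, build_neighbor_graph, neighbor_fractions
from scipy.special import expit

try:  # optional JIT of the sweep kernel; the fallback is semantically identical
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = lambda *a, **k: (lambda f: f)


@_njit
def _gibbs_sweeps(y, b, eta, nbr_idx, nbr_ptr, counts, orders, us):
    """Random-scan Gibbs updates of y ~ Bernoulli(sigmoid(b_i + eta * nbr_fraction)).

    ``orders``/``us`` carry the pre-drawn visit permutations and uniforms for
    every sweep, so the kernel itself is deterministic.
    """
    n_sweeps = orders.shape[0]
    for s in range(n_sweeps):
        for t in range(orders.shape[1]):
            i = orders[s, t]
            tot = 0.0
            for p in range(nbr_ptr[i], nbr_ptr[i + 1]):
                tot += y[nbr_idx[p]]
            frac = tot / counts[i] if counts[i] > 0 else 0.0
            z = b[i] + eta * frac
            prob = 1.0 / (1.0 + np.exp(-z))
            y[i] = 1.0 if us[s, t] < prob else 0.0
    return y

__all__ = [
    "SimulationConfig",
    "grid_coords",
    "simulate_expression",
    "simulate_autologistic_labels",
    "simulate_study",
    "apply_missingness",
]


@dataclass
class SimulationConfig:
    """Ground-truth generative settings for one synthetic study."""

    layout: str = "torus"
    L: int = 20
    d: int = 50
    n_true: int = 5
    beta_true: np.ndarray = None
    eta_true: float = 1.0
    intercept_true: float = 0.0
    n_sweeps: int = 1000
    C: int = 1
    G: int = 1
    sigma2_true: float = 0.0
    rho_true: float = 0.0
    corr_structure: str = "exchangeable"
    missing_mode: str = "none"
    mcar_rate: float = 0.2
    gamma_true: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 2.0]))
    expression: str = "normal"   # or "lognormal_counts"
    seed: int = 0

    def __post_init__(self):
        if self.layout not in ("grid", "torus"):
            raise ValueError("layout must be 'grid' or 'torus'")
        if self.n_true > self.d:
            raise ValueError("n_true cannot exceed d")
        if not 0.0 <= self.mcar_rate <= 1.0:
            raise ValueError("mcar_rate must lie in [0, 1]")
        if self.beta_true is None:
            beta = np.zeros(self.d)
            signs = np.resize([1.0, -1.0], self.n_true)
            beta[: self.n_true] = signs
            self.beta_true = beta
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.beta_true.shape != (self.d,):
            raise ValueError("beta_true must have length d")
        self.gamma_true = np.asarray(self.gamma_true, dtype=float)


def grid_coords(L: int):
    """Unit-grid coordinates of an L x L lattice, row-major."""
    xs, ys = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


def layout_graph(config: SimulationConfig) -> NeighborGraph:
    coords = grid_coords(config.L)
    period = (config.L, config.L) if config.layout == "torus" else None
    return build_neighbor_graph(coords, delta=1.0, period=period)


def simulate_expression(config: SimulationConfig, rng=None) -> np.ndarray:
    """n x d expression matrix: standard-normal entries by default.

    ``expression='lognormal_counts'`` instead draws Poisson counts with
    log-normal rates and applies log1p, mimicking a real count pipeline.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.L * config.L
    if config.d == 0:
        return np.zeros((n, 0))
    if config.expression == "normal":
        return rng.standard_normal((n, config.d))
    if config.expression == "spatial":
        # smooth Gaussian fields: iid noise repeatedly averaged with the
        # neighborhood mean, then re-standardized per gene.  Mimics the
        # spatial autocorrelation of real expression, which is what makes
        # ignoring the label coupling costly.
        graph = layout_graph(config)
        X = rng.standard_normal((n, config.d))
        idx, _ = graph.flat()
        owner = np.repeat(np.arange(n), graph.neighbor_counts)
        for _ in range(3):
            nbr_mean = np.zeros_like(X)
            np.add.at(nbr_mean, owner, X[idx])
            nz = graph.neighbor_counts > 0
            nbr_mean[nz] /= graph.neighbor_counts[nz, None]
            X = 0.5 * (X + nbr_mean)
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        return X
    if config.expression == "lognormal_counts":
        rates = np.exp(rng.normal(1.0, 0.8, size=(n, config.d)))
        return np.log1p(rng.poisson(rates).astype(float))
    raise ValueError(f"unknown expression model {config.expression!r}")


def simulate_autologistic_labels(X, graph: NeighborGraph, beta, eta, u=0.0,
                                 n_sweeps=200, seed=0, intercept=0.0, extra_field=None,
                                 rng=None, init=None):
    """Draw one label field by random-scan Gibbs over the autologistic conditionals.

    Each sweep visits every spot in a fresh random permutation, resampling
    ``y_i ~ Bernoulli(expit(x_i' beta + intercept + eta * nbr_fraction + u))``.
    The final sweep's state is returned (not an average).  ``extra_field``
    adds a fixed per-spot offset to the linear predictor (used for
    interaction-effect simulations).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    n = graph.n_spots
    b = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float) + intercept + u
    if extra_field is not None:
        b = b + np.asarray(extra_field, dtype=float)
    y = (rng.random(n) < expit(b)).astype(float) if init is None else np.asarray(init, dtype=float).copy()
    nbr_idx, nbr_ptr = graph.flat()
    orders = np.empty((n_sweeps, n), dtype=np.int64)
    for s in range(n_sweeps):
        orders[s] = rng.permutation(n)
    us = rng.random((n_sweeps, n))
    return _gibbs_sweeps(y, b, float(eta), nbr_idx, nbr_ptr,
                         graph.neighbor_counts.astype(np.int64), orders, us)


def simulate_study(config: SimulationConfig):
    """Generate a full study plus its ground-truth parameter state.

    Random effects ``U_c ~ MVN(0, Sigma_c)`` are drawn per donor (skipped
    when ``sigma2_true = 0``), then per-slice expression and labels.  Returns
    ``StudyDataset`` with ``.truth`` holding the generating
    :class:`~autospot.model_core.ParameterState`.
    """
    rng = np.random.default_rng(config.seed)
    graph = layout_graph(config)
    coords = grid_coords(config.L)
    gene_names = [f"g{k}" for k in range(config.d)]
    U = np.zeros((config.C, config.G))
    if config.sigma2_true > 0:
        Sigma = build_slice_covariance(config.sigma2_true,
                                       config.rho_true if config.G > 1 else 0.0,
                                       config.G, config.corr_structure)
        U = rng.multivariate_normal(np.zeros(config.G), Sigma, size=config.C,
                                    method="cholesky")
    slices = []
    for c in range(config.C):
        for g in range(config.G):
            X = simulate_expression(config, rng=rng)
            y = simulate_autologistic_labels(
                X, graph, config.beta_true, config.eta_true, u=U[c, g],
                n_sweeps=config.n_sweeps, intercept=config.intercept_true, rng=rng)
            slices.append(SpatialSlice(
                donor_id=f"donor{c}", slice_id=f"slice{g}", coords=coords,
                X=X, gene_names=list(gene_names), y=y,
                r=np.ones(graph.n_spots, dtype=int)))
    truth = ParameterState(
        beta=config.beta_true.copy(), eta=config.eta_true,
        intercept=config.intercept_true,
        U=U if config.sigma2_true > 0 else None,
        sigma2=np.full(config.C, config.sigma2_true) if config.sigma2_true > 0 else None,
        rho=config.rho_true,
        gamma=config.gamma_true.copy() if config.missing_mode == "nonignorable" else None)
    study = StudyDataset(slices=slices, truth=truth)
    if config.missing_mode != "none":
        study = apply_missingness(study, config, rng=rng)
    return study


def simulate_two_region_slice(L=20, d=10, beta_region=2.0, eta=1.0, noise_sd=0.5,
                              n_sweeps=1000, seed=0, slice_id="slice0"):
    """One torus slice with a disease region occupying the left half.

    Gene 0 tracks the region (+1 inside, -1 outside, plus noise), the other
    genes are pure noise, and labels follow the autologistic conditionals
    with coefficient ``beta_region`` on gene 0.  Returns (slice, graph,
    region indicator, true beta).  Spots in the two columns on either side
    of each region boundary have mixed neighborhoods, which is where
    prediction uncertainty should concentrate.
    """
    rng = np.random.default_rng(seed)
    coords = grid_coords(L)
    graph = build_neighbor_graph(coords, 1.0, period=(L, L))
    region = (coords[:, 0] < L // 2).astype(float)
    X = rng.standard_normal((L * L, d))
    X[:, 0] = (2.0 * region - 1.0) + noise_sd * rng.standard_normal(L * L)
    beta = np.zeros(d)
    beta[0] = beta_region
    y = simulate_autologistic_labels(X, graph, beta, eta, n_sweeps=n_sweeps, rng=rng)
    slc = SpatialSlice("donor0", slice_id, coords, X,
                       [f"g{k}" for k in range(d)], y,
                       np.ones(L * L, dtype=int))
    return slc, graph, region, beta


def boundary_mask(coords, L):
    """Spots in the columns adjacent to the two region boundaries of the half-split torus."""
    col = coords[:, 0]
    half = L // 2
    return np.isin(col, [0, half - 1, half, L - 1])


def apply_missingness(study: StudyDataset, config: SimulationConfig, rng=None) -> StudyDataset:
    """Mask spots per the configured mechanism; masked spots lose X, y.

    ``mcar`` drops each spot independently with probability ``mcar_rate``.
    ``nonignorable`` Gibbs-samples the observation field from the conditional
    logit ``gamma0 + gamma1 y_i + gamma2 * observed-neighbor fraction``,
    producing spatially clumped missingness whose rate depends on the labels.
    The pre-masking labels stay available in ``study.truth_labels``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    graph = layout_graph(config)
    truth_labels = []
    new_slices = []
    for slc in study.slices:
        if np.isnan(slc.y).any():
            raise ValueError("labels must be fully observed before masking")
        truth_labels.append(slc.y.copy())
        n = slc.n_spots
        if config.missing_mode == "mcar":
            r = (rng.random(n) >= config.mcar_rate).astype(int)
        elif config.missing_mode == "nonignorable":
            gm = config.gamma_true
            r = (rng.random(n) < 0.5).astype(float)
            for _ in range(50):
                order = rng.permutation(n)
                us = rng.random(n)
                for t, i in enumerate(order):
                    nbrs = graph.neighbor_sets[i]
                    frac = r[nbrs].sum() / graph.neighbor_counts[i] if graph.neighbor_counts[i] else 0.0
                    p = missingness_logit(gm, slc.y[i], frac)
                    r[i] = 1.0 if us[t] < p else 0.0
            r = r.astype(int)
        else:
            raise ValueError(f"apply_missingness called with missing_mode={config.missing_mode!r}")
        y = slc.y.copy()
        X = slc.X.copy()
        y[r == 0] = np.nan
        X[r == 0] = 0.0
        from dataclasses import replace
        new_slices.append(replace(slc, y=y, X=X, r=r))
    out = StudyDataset(slices=new_slices, truth=study.truth)
    out.truth_labels = truth_labels
    return out
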