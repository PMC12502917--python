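import numpy as np
import pytest
from hypothesis import settings

from autospot import (ModelConfig, SpatialSlice, StudyDataset, build_neighbor_graph,
                      simulate_autologistic_labels)

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def ring10():
    """10-spot ring: every spot has exactly two neighbors."""
    n = 10
    theta = 2 * np.pi * np.arange(n) / n
    R = 1 / (2 * np.sin(np.pi / n))
    coords = np.column_stack([R * np.cos(theta), R * np.sin(theta)])
    return build_neighbor_graph(coords, delta=1.01), coords


@pytest.fixture
def ring_study(ring10):
    """Single-gene slice on the ring with autologistic labels."""
    graph, coords = ring10
    rng = np.random.default_rng(3)
    X = rng.standard_normal((10, 1))
    y = simulate_autologistic_labels(X, graph, [1.5], 1.0, n_sweeps=200, seed=5)
    slc = SpatialSlice("d0", "s0", coords, X, ["g0"], y, np.ones(10, dtype=int))
    return StudyDataset([slc]), graph


@pytest.fixture
def slab_config():
    """Slab-only fixed-scale prior: the 2-parameter (beta, eta) model."""
    return ModelConfig(w_fixed=1.0, tau2_fixed=1.0, include_intercept=False, c1=10.0)


def quadrature_posterior_means(study, graph, y=None, c1=10.0):
    """Dense 2-D grid quadrature of the (beta, eta) pseudo-posterior.

    Independent oracle for the slab-only single-gene model: slab prior
    N(0, 1) on beta, uniform (0, c1) on eta.
    """
    from scipy.special import expit

    from autospot.spatial_graph import neighbor_fractions

    slc = study.slices[0]
    yv = slc.y if y is None else y
    f = neighbor_fractions(graph, yv)
    X = slc.X[:, 0]

    bs = np.linspace(-6, 6, 241)
    es = np.linspace(0, c1, 201)
    B, E = np.meshgrid(bs, es, indexing="ij")
    lp = np.empty_like(B)
    for i, b in enumerate(bs):
        mu = expit(np.outer(X * b + 0, np.ones_like(es)) + np.outer(f, es))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        lp[i] = (yv[:, None] * np.log(mu) + (1 - yv[:, None]) * np.log1p(-mu)).sum(axis=0)
        lp[i] += -0.5 * b * b
    p = np.exp(lp - lp.max())
    p /= p.sum()
    return float((p.sum(axis=1) * bs).sum()), float((p.sum(axis=0) * es).sum())
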