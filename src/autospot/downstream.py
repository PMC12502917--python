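"""Downstream analyses: gene ranking, interaction discovery, prediction, imputation.

1. *Gene ranking* orders genes by the standardized effect size |posterior
   mean| / posterior SD (a Z-score-like statistic) and labels each by the
   sign of its coefficient (upregulated in disease vs downregulated).
2. *Interaction discovery* refits the model with pairwise products of the
   selected genes appended as extra columns; pairs whose standardized
   interaction effect exceeds 1.96 are retained and can be exported as a
   weighted edge list.
3. *Prediction* Gibbs-samples the fully unlabeled field of a new slice from
   the autologistic conditionals with plug-in posterior-mean coefficients,
   reporting per-spot disease probabilities.
4. *Imputation* runs the same machinery over the missing spots only,
   conditioning on the observed labels around them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import PosteriorSummary, fit, run_data_augmentation
from .io_preprocess import SpatialSlice, StudyDataset
from .model_core import ModelConfig
from .spatial_graph import NeighborGraph

__all__ = [
    "GeneRanking",
    "PredictionResult",
    "rank_genes",
    "interaction_scan",
    "interaction_edge_list",
    "predict_slice",
    "impute_missing",
]


@dataclass
class GeneRanking:
    """Genes ordered by standardized effect (ties broken by gene name)."""

    table: pd.DataFrame

    @property
    def gene_names(self):
        return self.table["gene"].tolist()

    def __len__(self):
        return len(self.table)


@dataclass
class PredictionResult:
    """Per-spot posterior disease probability and the thresholded call."""

    mu_hat: np.ndarray
    call: np.ndarray
    draws_mu: np.ndarray = None

    def to_frame(self, spot_ids=None):
        df = pd.DataFrame({"mu_hat": self.mu_hat, "call": self.call})
        if spot_ids is not None:
            df.insert(0, "spot_id", spot_ids)
        return df


def rank_genes(summary: PosteriorSummary, k: int = 30) -> GeneRanking:
    """Top-k genes by standardized effect size, with direction labels."""
    d = len(summary.gene_names)
    if k > d:
        warnings.warn(f"requested top {k} genes but only {d} are present; returning all")
        k = d
    df = pd.DataFrame({
        "gene": summary.gene_names,
        "mean": np.atleast_1d(summary.mean["beta"]),
        "sd": np.atleast_1d(summary.sd["beta"]),
        "cri_low": np.atleast_1d(summary.cri_low["beta"]),
        "cri_high": np.atleast_1d(summary.cri_high["beta"]),
        "std_effect": summary.std_effect,
        "inclusion_prob": summary.inclusion_prob,
    })
    df["direction"] = np.sign(df["mean"]).astype(int)
    df = df.sort_values(["std_effect", "gene"], ascending=[False, True],
                        kind="mergesort").head(k).reset_index(drop=True)
    return GeneRanking(table=df)


def _augment_with_interactions(study: StudyDataset, selected):
    """Append centered pairwise products of the selected genes as new columns."""
    pairs = list(itertools.combinations(selected, 2))
    new_slices = []
    for slc in study.slices:
        idx = {g: slc.gene_names.index(g) for g in selected}
        obs = slc.observed
        cols = []
        for a, b in pairs:
            xa = slc.X[:, idx[a]].copy()
            xb = slc.X[:, idx[b]].copy()
            # center on observed spots before multiplying to limit collinearity
            xa[obs] -= xa[obs].mean()
            xb[obs] -= xb[obs].mean()
            col = xa * xb
            col[~obs] = 0.0
            cols.append(col)
        Xint = np.column_stack(cols) if cols else np.zeros((slc.n_spots, 0))
        new_slices.append(replace(
            slc, X=np.hstack([slc.X, Xint]),
            gene_names=list(slc.gene_names) + [f"{a}:{b}" for a, b in pairs]))
    return StudyDataset(slices=new_slices, truth=study.truth), pairs


def interaction_scan(study: StudyDataset, graphs, selected_genes, config: ModelConfig,
                     backend="advi", max_genes=30, **fit_kwargs):
    """Refit with all pairwise products of the selected genes; flag strong pairs.

    Returns a table with one row per pair: posterior mean, SD, standardized
    effect and ``retained`` (standardized effect > 1.96).  Main effects and
    interaction coefficients share the spike-and-slab prior family.
    """
    missing = [g for g in selected_genes if g not in study.gene_names]
    if missing:
        raise ValueError(f"selected genes not in study: {missing}")
    if len(selected_genes) > max_genes:
        raise ValueError(
            f"{len(selected_genes)} genes selected; limit is {max_genes} "
            "(pair count grows quadratically — reduce the selection)")
    aug_study, pairs = _augment_with_interactions(study, list(selected_genes))
    summary = fit(aug_study, graphs, config, backend=backend, **fit_kwargs)
    d0 = len(study.gene_names)
    mean = np.atleast_1d(summary.mean["beta"])[d0:]
    sd = np.atleast_1d(summary.sd["beta"])[d0:]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(sd > 0, np.abs(mean) / sd, np.nan)
    df = pd.DataFrame({
        "gene_a": [a for a, _ in pairs],
        "gene_b": [b for _, b in pairs],
        "mean": mean,
        "sd": sd,
        "std_effect": se,
        "retained": se > 1.96,
    })
    df.attrs["summary"] = summary
    return df


def interaction_edge_list(table: pd.DataFrame) -> pd.DataFrame:
    """Retained pairs as a weighted edge list (weight = effect magnitude)."""
    kept = table[table["retained"]]
    return pd.DataFrame({"gene_a": kept["gene_a"], "gene_b": kept["gene_b"],
                         "weight": kept["std_effect"]}).reset_index(drop=True)


def predict_slice(new_slice: SpatialSlice, graph: NeighborGraph,
                  summary: PosteriorSummary, n_sweeps=400, burn_in=100,
                  seed=0, use_draws=False, n_posterior_draws=50) -> PredictionResult:
    """Posterior disease probabilities for a fully unlabeled slice.

    All labels are unknown, so the label field is Gibbs-sampled from the
    autologistic conditionals with plug-in posterior means (beta-hat,
    eta-hat, intercept); ``mu_hat`` is the average of the sampled labels over
    the retained sweeps.  With ``eta_hat = 0`` the spots decouple and the
    probabilities are computed in closed form.  ``use_draws=True`` repeats
    the procedure over thinned posterior draws and averages, exposing
    posterior uncertainty in ``draws_mu``.
    """
    if new_slice.gene_names != summary.gene_names:
        missing = [g for g in summary.gene_names if g not in new_slice.gene_names]
        raise ValueError(f"gene sets differ between training fit and new slice; "
                         f"missing from new slice: {missing}")

    def one_run(beta, eta, intercept, seed_):
        b = new_slice.X @ beta + intercept
        if eta == 0.0:
            return expit(b)
        from .simulator import _gibbs_sweeps

        rng = np.random.default_rng(seed_)
        n = graph.n_spots
        y = (rng.random(n) < expit(b)).astype(float)
        nbr_idx, nbr_ptr = graph.flat()
        counts = graph.neighbor_counts.astype(np.int64)
        acc = np.zeros(n)
        kept = 0
        for sweep in range(n_sweeps):
            order = rng.permutation(n)[None, :]
            us = rng.random((1, n))
            y = _gibbs_sweeps(y, b, float(eta), nbr_idx, nbr_ptr, counts, order, us)
            if sweep >= burn_in:
                acc += y
                kept += 1
        return acc / max(kept, 1)

    if not use_draws:
        mu = one_run(summary.beta_mean, summary.eta_mean, summary.intercept_mean, seed)
        draws_mu = None
    else:
        beta_d = summary.draws["beta"].reshape(-1, len(summary.gene_names))
        eta_d = summary.draws["eta"].reshape(-1)
        int_d = (summary.draws["intercept"].reshape(-1)
                 if "intercept" in summary.draws else np.zeros_like(eta_d))
        take = np.linspace(0, len(eta_d) - 1, min(n_posterior_draws, len(eta_d))).astype(int)
        mus = [one_run(beta_d[t], float(eta_d[t]), float(int_d[t]), seed + 31 * j)
               for j, t in enumerate(take)]
        draws_mu = np.asarray(mus)
        mu = draws_mu.mean(axis=0)
    return PredictionResult(mu_hat=mu, call=(mu > 0.5).astype(int), draws_mu=draws_mu)


def impute_missing(slc: SpatialSlice, graph: NeighborGraph,
                   summary: PosteriorSummary = None, n_sweeps=500, burn_in=100,
                   seed=0, config: ModelConfig = None) -> pd.DataFrame:
    """Posterior disease probability for each missing spot.

    Gibbs-samples the missing labels from the neighbor-fraction conditional
    (observed labels held fixed) and reports the retained-sweep frequency of
    disease per missing spot.  Isolated missing spots receive the slice-wide
    observed disease rate.  Returns an empty table (with a note in
    ``attrs``) when the slice is fully observed.
    """
    miss = np.where(slc.r == 0)[0]
    if len(miss) == 0:
        out = pd.DataFrame(columns=["spot_id", "spot_index", "p_disease"])
        out.attrs["note"] = "slice fully observed; nothing to impute"
        return out
    cfg = config or ModelConfig(missing_mode="ignorable")
    if cfg.missing_mode == "none":
        cfg = ModelConfig(**{**cfg.__dict__, "missing_mode": "ignorable"})
    state = None
    if summary is not None and "gamma" in summary.mean:
        from .model_core import ParameterState
        state = ParameterState(beta=summary.beta_mean, gamma=np.atleast_1d(summary.mean["gamma"]))
    study = StudyDataset(slices=[slc])
    rng = np.random.default_rng(seed)
    labels = None
    acc = np.zeros(len(miss))
    kept = 0
    for sweep in range(n_sweeps):
        labels = run_data_augmentation(state, study, [graph], cfg,
                                       seed=int(rng.integers(2 ** 31)),
                                       labels=labels, n_sweeps=1)
        if sweep >= burn_in:
            acc += labels[0][miss]
            kept += 1
    p = acc / max(kept, 1)
    # isolated missing spots have no neighborhood signal: report the
    # slice-wide observed disease rate exactly rather than its MC estimate
    obs = slc.r == 1
    rate = float(np.asarray(slc.y, dtype=float)[obs].mean()) if obs.any() else 0.5
    for j, i in enumerate(miss):
        if graph.neighbor_counts[i] == 0:
            p[j] = rate
    return pd.DataFrame({"spot_id": [slc.spot_ids[i] for i in miss],
                         "spot_index": miss, "p_disease": p})
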