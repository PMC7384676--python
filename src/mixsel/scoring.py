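"""Posterior gene effects and constraint scores.

After fitting, the gene-level random effect u_j is inferred from the
gene's own occurrence data: the posterior over u_j is evaluated on the
Gauss-Hermite nodes of the prior N(0, sigma) and normalized in log space.
The variant constraint score of mutation i is the posterior-expected
reduction of its relative occurrence probability,

    score_i = 1 - E[ logistic(z_i + u_j) | data_j ],

and the gene constraint score is the arithmetic mean of the variant
scores over the gene's candidate missense mutations. Both lie in [0, 1];
higher means stronger inferred negative selection. For a gene with no
occurrence evidence (or when scoring a gene held out from training), the
posterior reduces to the prior, so the random effect contributes its
genome-wide average of zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .dme import (
    DMEParams,
    DMEResults,
    GeneBatch,
    _gh_nodes,
    _node_ll_sums,
    forward_fixed_effect,
)


class PosteriorUnderflowError(RuntimeError):
    pass


@dataclass
class PosteriorU:
    """Discrete posterior of one gene's random effect on quadrature nodes."""

    gene_id: str
    nodes: np.ndarray
    log_weights: np.ndarray  # normalized: logsumexp == 0
    mean: float
    sd: float

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)


@dataclass
class GeneScoreSet:
    gene_id: str
    variant_scores: dict
    gene_score: float | None
    posterior: PosteriorU

    def __post_init__(self):
        vals = list(self.variant_scores.values())
        if vals and not all(0.0 <= v <= 1.0 for v in vals):
            raise ValueError(f"gene {self.gene_id}: scores must lie in [0,1]")


def _posterior_from_logmass(gene_id, nodes, logmass) -> PosteriorU:
    total = logsumexp(logmass)
    if not np.isfinite(total):
        raise PosteriorUnderflowError(
            f"gene {gene_id}: posterior mass underflowed at every node; "
            "increase the quadrature order"
        )
    logw = logmass - total
    w = np.exp(logw)
    mean = float(np.dot(w, nodes))
    var = float(np.dot(w, (nodes - mean) ** 2))
    return PosteriorU(gene_id, nodes, logw, mean, float(np.sqrt(max(var, 0.0))))


def posterior_u(
    batch: GeneBatch,
    params: DMEParams,
    order: int = 20,
    z: np.ndarray | None = None,
) -> PosteriorU:
    """Quadrature posterior of u_j given the gene's occurrence data.

    Node masses are proportional to (quadrature weight) x (gene likelihood
    at that node). ``batch.X`` must already be standardized unless ``z``
    is supplied. A gene with zero variants recovers the discretized prior.
    """
    x, logw = _gh_nodes(order)
    nodes = np.sqrt(2.0) * params.sigma * x
    if batch.n_variants == 0:
        return _posterior_from_logmass(batch.gene_id, nodes, logw)
    if z is None:
        z = forward_fixed_effect(batch.X, params, mode="infer")
    return _posterior_from_logmass(
        batch.gene_id, nodes, logw + _node_ll_sums(z, batch.mu, batch.Y, nodes)
    )


def prior_posterior(gene_id: str, params: DMEParams, order: int = 20) -> PosteriorU:
    """The no-evidence posterior: the prior N(0, sigma) on quadrature nodes."""
    x, logw = _gh_nodes(order)
    return _posterior_from_logmass(gene_id, np.sqrt(2.0) * params.sigma * x, logw)


def posterior_u_dense(
    batch: GeneBatch,
    params: DMEParams,
    n_points: int = 20001,
    span: float = 10.0,
    z: np.ndarray | None = None,
) -> PosteriorU:
    """Dense-grid posterior over u in [-span*sigma, span*sigma].

    Brute-force reference backend, kept for validating the quadrature
    route; quadratically slower and used only in tests and diagnostics.
    """
    u = np.linspace(-span * params.sigma, span * params.sigma, n_points)
    log_prior = norm.logpdf(u, scale=params.sigma)
    if batch.n_variants == 0:
        logmass = log_prior
    else:
        if z is None:
            z = forward_fixed_effect(batch.X, params, mode="infer")
        logmass = log_prior + _node_ll_sums(z, batch.mu, batch.Y, u)
    return _posterior_from_logmass(batch.gene_id, u, logmass)


def variant_constraint_score(z, posterior: PosteriorU):
    """1 - E[eta | data]: per-variant constraint score(s), in [0, 1]."""
    z = np.asarray(z, dtype=float)
    w = posterior.weights
    e = expit(z[..., None] + posterior.nodes) @ w
    return 1.0 - e


def gene_constraint_score(variant_scores: Sequence[float]) -> float | None:
    """Arithmetic mean of a gene's variant scores; None for an empty gene."""
    scores = np.asarray(list(variant_scores), dtype=float)
    if scores.size == 0:
        return None
    return float(scores.mean())


def score_gene(
    batch: GeneBatch,
    results: DMEResults,
    use_posterior: bool = True,
    order: int | None = None,
) -> GeneScoreSet:
    """Score one gene's candidate variants under a fitted model.

    ``batch`` carries raw (unstandardized) features; the fit's
    standardization record is applied before the forward pass. With
    ``use_posterior=False`` (or when the batch carries no occurrence data)
    the random effect is integrated against its prior, matching how a gene
    unseen during training is scored.
    """
    order = order or results.model.config.quadrature_order
    z = results.fixed_effects(batch.X) if batch.n_variants else np.empty(0)
    if use_posterior and batch.n_variants:
        post = posterior_u(batch, results.params, order, z=z)
    else:
        post = prior_posterior(batch.gene_id, results.params, order)
    scores = variant_constraint_score(z, post) if batch.n_variants else np.empty(0)
    keys = batch.variant_keys or list(range(batch.n_variants))
    return GeneScoreSet(
        gene_id=batch.gene_id,
        variant_scores=dict(zip(keys, scores.tolist())),
        gene_score=gene_constraint_score(scores),
        posterior=post,
    )


def score_genes(
    batches: Sequence[GeneBatch],
    results: DMEResults,
    use_posterior: bool = True,
    order: int | None = None,
) -> list[GeneScoreSet]:
    return [score_gene(b, results, use_posterior, order) for b in batches]


def scores_to_frames(
    score_sets: Sequence[GeneScoreSet],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format per-variant and per-gene score tables."""
    vrows, grows = [], []
    for s in score_sets:
        for key, sc in s.variant_scores.items():
            row = {"gene_id": s.gene_id, "score": sc}
            if isinstance(key, tuple) and len(key) == 4:
                row.update(dict(zip(("chrom", "pos", "ref", "alt"), key)))
            else:
                row["variant"] = key
            vrows.append(row)
        grows.append(
            {
                "gene_id": s.gene_id,
                "n_variants": len(s.variant_scores),
                "posterior_mean": s.posterior.mean,
                "posterior_sd": s.posterior.sd,
                "gene_score": np.nan if s.gene_score is None else s.gene_score,
            }
        )
    return pd.DataFrame(vrows), pd.DataFrame(grows)


# ---------------------------------------------------------------------------
# Feature contributions (linear surrogate)


@dataclass
class ContributionReport:
    feature_names: list[str]
    contributions: np.ndarray  # negated linear weights
    random_effect_contribution: float  # -sigma

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.feature_names + ["gene_random_effect"],
                "contribution": np.append(
                    self.contributions, self.random_effect_contribution
                ),
            }
        )


def contribution_scores(
    linear_params: DMEParams, feature_names: Sequence[str] | None = None
) -> ContributionReport:
    """Per-feature contributions from a *linear* mixed model.

    The contribution of a feature is the negated regression weight (a
    feature that lowers the occurrence probability raises inferred
    selection); the random effect contributes -sigma. For a nonlinear
    model, fit a linear surrogate on the same data and interpret that.
    """
    if linear_params.hidden_units != 0:
        raise ValueError(
            "contribution scores are defined for the linear model only; "
            "train a linear surrogate (hidden_units=0) for interpretation"
        )
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"feat_{k}" for k in range(len(linear_params.W_output))]
    )
    if len(names) != len(linear_params.W_output):
        raise ValueError("feature_names length must match weight vector")
    return ContributionReport(
        feature_names=names,
        contributions=-linear_params.W_output.copy(),
        random_effect_contribution=-float(linear_params.sigma),
    )
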