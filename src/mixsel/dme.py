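"""Deep mixed-effects model of missense occurrence.

The relative occurrence probability of candidate missense mutation i in
gene j, compared with its neutral expectation mu_ij, is

    eta_ij = logistic(z_ij + u_j),

where the variant-level fixed effect z_ij is a feedforward network (one
ReLU hidden layer with inverted dropout, or a pure linear map when
``hidden_units=0``) of the standardized feature vector X_ij, and the
gene-level random effect u_j ~ N(0, sigma) absorbs constraint not
explained by the features. The marginal likelihood of one gene's data

    L_j = int prod_i (eta_ij mu_ij)^Y_ij (1 - eta_ij mu_ij)^(1-Y_ij) N(u; 0, sigma) du

is integrated by Gauss-Hermite quadrature (change of variables
u = sqrt(2) sigma x) and maximized by Adam over per-gene minibatches with
early stopping on a held-out gene split. sigma is optimized on the log
scale. Everything is plain numpy; gradients are analytic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from numpy.polynomial.hermite import hermgauss

_LOG_SQRT_PI = 0.5 * np.log(np.pi)


class ShapeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Data containers


@dataclass
class GeneBatch:
    """All candidate missense mutations of one gene."""

    gene_id: str
    X: np.ndarray  # (n_variants, n_features)
    mu: np.ndarray  # neutral occurrence probabilities, in (0,1)
    Y: np.ndarray  # binary occurrence indicators
    variant_keys: list | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.mu = np.asarray(self.mu, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        n = self.X.shape[0]
        if self.mu.shape != (n,) or self.Y.shape != (n,):
            raise ShapeError(f"gene {self.gene_id}: row counts disagree")
        if np.any((self.mu <= 0) | (self.mu >= 1)):
            raise ValueError(f"gene {self.gene_id}: mu must lie strictly in (0,1)")

    @property
    def n_variants(self) -> int:
        return self.X.shape[0]


def batches_from_frame(
    df: pd.DataFrame,
    feature_columns: Sequence[str] | None = None,
    gene_column: str = "gene_id",
    mu_column: str = "mu",
    y_column: str = "observed",
) -> list[GeneBatch]:
    """Group a long-format variant table into per-gene batches.

    Gene order follows first appearance in the table; row order within a
    gene is preserved.
    """
    if feature_columns is None:
        feature_columns = [c for c in df.columns if c.startswith("feat_")]
    key_cols = [c for c in ("chrom", "pos", "ref", "alt") if c in df.columns]
    batches = []
    for gene_id, g in df.groupby(gene_column, sort=False):
        keys = list(g[key_cols].itertuples(index=False, name=None)) if key_cols else None
        batches.append(
            GeneBatch(
                gene_id=str(gene_id),
                X=g[feature_columns].to_numpy(dtype=float),
                mu=g[mu_column].to_numpy(dtype=float),
                Y=g[y_column].to_numpy(dtype=float),
                variant_keys=keys,
            )
        )
    return batches


# ---------------------------------------------------------------------------
# Feature standardization


@dataclass
class Standardization:
    """Per-column centering/scaling record, reused verbatim at scoring time."""

    mean: np.ndarray
    sd: np.ndarray
    kinds: list[str]  # "continuous" | "binary"

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist(), "kinds": self.kinds}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardization":
        return cls(np.array(d["mean"]), np.array(d["sd"]), list(d["kinds"]))


def detect_feature_kinds(X: np.ndarray) -> list[str]:
    return [
        "binary" if np.all(np.isin(X[:, j], (0.0, 1.0))) else "continuous"
        for j in range(X.shape[1])
    ]


def standardize_features(
    X: np.ndarray, feature_kinds: Sequence[str] | None = None
) -> tuple[np.ndarray, Standardization]:
    """Center/scale continuous columns to mean 0, sd 1 (population sd).

    Binary columns pass through untouched. A continuous column with zero
    variance cannot be scaled and raises, naming the column.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    kinds = list(feature_kinds) if feature_kinds is not None else detect_feature_kinds(X)
    if len(kinds) != X.shape[1]:
        raise ShapeError("feature_kinds length must match number of columns")
    mean = np.zeros(X.shape[1])
    sd = np.ones(X.shape[1])
    for j, kind in enumerate(kinds):
        if kind == "continuous":
            m, s = X[:, j].mean(), X[:, j].std()  # population (denominator n)
            if s == 0:
                raise ValueError(f"continuous feature column {j} has zero variance")
            mean[j], sd[j] = m, s
    rec = Standardization(mean=mean, sd=sd, kinds=kinds)
    return rec.apply(X), rec


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class DMEParams:
    """Network weights plus the random-effect scale sigma.

    ``hidden_units=0`` selects the linear model: no hidden layer, the
    output weights act directly on the features and the model is an
    ordinary generalized linear mixed model.
    """

    W_output: np.ndarray
    b_output: float
    sigma: float
    W_hidden: np.ndarray | None = None
    B_hidden: np.ndarray | None = None
    hidden_units: int = 0
    dropout_rate: float = 0.5

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self.W_output = np.asarray(self.W_output, dtype=float).ravel()
        if self.hidden_units == 0:
            if self.W_hidden is not None or self.B_hidden is not None:
                raise ShapeError("linear model must not carry hidden-layer weights")
        else:
            self.W_hidden = np.asarray(self.W_hidden, dtype=float)
            self.B_hidden = np.asarray(self.B_hidden, dtype=float).ravel()
            if self.W_hidden.shape[1] != self.hidden_units:
                raise ShapeError("W_hidden column count must equal hidden_units")
            if self.B_hidden.shape != (self.hidden_units,):
                raise ShapeError("B_hidden length must equal hidden_units")
            if self.W_output.shape != (self.hidden_units,):
                raise ShapeError("W_output length must equal hidden_units")

    @property
    def n_features(self) -> int:
        return len(self.W_output) if self.hidden_units == 0 else self.W_hidden.shape[0]

    def to_dict(self) -> dict:
        return {
            "W_output": self.W_output.tolist(),
            "b_output": float(self.b_output),
            "sigma": float(self.sigma),
            "W_hidden": None if self.W_hidden is None else self.W_hidden.tolist(),
            "B_hidden": None if self.B_hidden is None else self.B_hidden.tolist(),
            "hidden_units": int(self.hidden_units),
            "dropout_rate": float(self.dropout_rate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DMEParams":
        d = dict(d)
        if d["W_hidden"] is not None:
            d["W_hidden"] = np.array(d["W_hidden"], dtype=float)
            d["B_hidden"] = np.array(d["B_hidden"], dtype=float)
        return cls(**d)


def init_params(
    n_features: int, hidden_units: int, rng: np.random.Generator,
    dropout_rate: float = 0.5, sigma0: float = 0.5,
) -> DMEParams:
    """Glorot-uniform weights, zero biases, sigma at its starting value."""

    def glorot(fan_in, fan_out, shape):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    if hidden_units == 0:
        return DMEParams(
            W_output=glorot(n_features, 1, n_features),
            b_output=0.0,
            sigma=sigma0,
            hidden_units=0,
            dropout_rate=dropout_rate,
        )
    return DMEParams(
        W_output=glorot(hidden_units, 1, hidden_units),
        b_output=0.0,
        sigma=sigma0,
        W_hidden=glorot(n_features, hidden_units, (n_features, hidden_units)),
        B_hidden=np.zeros(hidden_units),
        hidden_units=hidden_units,
        dropout_rate=dropout_rate,
    )


# ---------------------------------------------------------------------------
# Forward pass


def forward_fixed_effect(
    X_std: np.ndarray,
    params: DMEParams,
    mode: str = "infer",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fixed effects z for standardized features.

    ``mode="train"`` applies inverted dropout after the ReLU layer (mask
    drawn from ``rng``, activations scaled by 1/(1-rate)); ``"infer"`` is
    deterministic with no dropout.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    z, _ = _forward_cached(X_std, params, mode, rng)
    return z


def _forward_cached(X_std, params, mode, rng):
    X_std = np.atleast_2d(np.asarray(X_std, dtype=float))
    if X_std.shape[1] != params.n_features:
        raise ShapeError(
            f"feature count {X_std.shape[1]} does not match model ({params.n_features})"
        )
    if mode not in ("train", "infer"):
        raise ValueError("mode must be 'train' or 'infer'")
    if params.hidden_units == 0:
        z = X_std @ params.W_output + params.b_output
        return z, {"X": X_std, "H": None, "mask": None, "pre": None}
    pre = X_std @ params.W_hidden + params.B_hidden
    H = np.maximum(pre, 0.0)
    mask = None
    if mode == "train" and params.dropout_rate > 0:
        if rng is None:
            raise ValueError("train mode with dropout needs an rng")
        keep = 1.0 - params.dropout_rate
        mask = (rng.random(H.shape) < keep) / keep
        H = H * mask
    z = H @ params.W_output + params.b_output
    return z, {"X": X_std, "H": H, "mask": mask, "pre": pre}


def eta(z, u):
    """Relative occurrence probability logistic(z + u)."""
    return expit(np.asarray(z) + np.asarray(u))


# ---------------------------------------------------------------------------
# Marginal likelihood and gradients


from functools import lru_cache


@lru_cache(maxsize=32)
def _gh_nodes(order: int):
    if order < 2:
        raise ValueError("quadrature order must be >= 2")
    x, w = hermgauss(order)
    return x, np.log(w) - _LOG_SQRT_PI


def _node_ll_sums(z, mu, Y, u_nodes):
    """Gene log-likelihood summed over variants, per random-effect value.

    Returns the length-K vector sum_i log P(Y_i | u_k) for t = z_i + u_k,
    p = eta(t) * mu_i. Observed and unobserved variants are handled in
    separate blocks so only the needed branch is evaluated.
    """
    obs = Y > 0.5
    out = np.zeros(len(u_nodes))
    if obs.any():
        t = z[obs][:, None] + u_nodes
        out += (np.log(mu[obs])[:, None] - np.logaddexp(0.0, -t)).sum(axis=0)
    if not obs.all():
        t = z[~obs][:, None] + u_nodes
        p = expit(t) * mu[~obs][:, None]
        out += np.log1p(-np.clip(p, None, 1.0 - 1e-300)).sum(axis=0)
    return out


def gene_log_marginal_likelihood(
    batch: GeneBatch, params: DMEParams, order: int = 20,
    z: np.ndarray | None = None,
) -> float:
    """log L_j with the gene random effect integrated out by quadrature.

    ``z`` may be supplied to skip the forward pass (e.g. during training);
    otherwise it is computed in inference mode from ``batch.X``, which must
    then already be standardized.
    """
    if z is None:
        z = forward_fixed_effect(batch.X, params, mode="infer")
    if batch.n_variants == 0:
        return 0.0
    x, logw = _gh_nodes(order)
    u_nodes = np.sqrt(2.0) * params.sigma * x
    return float(logsumexp(logw + _node_ll_sums(z, batch.mu, batch.Y, u_nodes)))


def _ll_sums_and_grad(z, mu, Y, u_nodes):
    """Node-wise summed log likelihood and the per-variant d ll / d t matrix."""
    n, K = len(z), len(u_nodes)
    sums = np.zeros(K)
    g = np.empty((n, K))
    obs = Y > 0.5
    if obs.any():
        t = z[obs][:, None] + u_nodes
        et = expit(t)
        sums += (np.log(mu[obs])[:, None] - np.logaddexp(0.0, -t)).sum(axis=0)
        g[obs] = 1.0 - et
    if not obs.all():
        t = z[~obs][:, None] + u_nodes
        et = expit(t)
        p = et * mu[~obs][:, None]
        np.clip(p, None, 1.0 - 1e-300, out=p)
        sums += np.log1p(-p).sum(axis=0)
        g[~obs] = -(p * (1.0 - et)) / (1.0 - p)
    return sums, g


def _gene_nll_and_grads(batch, params, order, cache, z):
    """Negative log marginal likelihood and analytic gradients.

    Returns (nll, grads) with grads keyed like the Adam state: dz is
    backpropagated through the cached forward pass; sigma's gradient is on
    the log scale.
    """
    x, logw = _gh_nodes(order)
    u_nodes = np.sqrt(2.0) * params.sigma * x
    ll_sums, g = _ll_sums_and_grad(z, batch.mu, batch.Y, u_nodes)
    a = logw + ll_sums
    logL = logsumexp(a)
    pk = np.exp(a - logL)
    dz = g @ pk  # (n,)
    # u_k = sqrt(2) sigma x_k moves with sigma
    dsigma = float(np.sqrt(2.0) * np.dot(pk * x, g.sum(axis=0)))
    dlogsigma = params.sigma * dsigma
    grads = _backprop(dz, params, cache)
    grads["log_sigma"] = -dlogsigma
    return -float(logL), grads


def _backprop(dz, params, cache):
    """Map d logL / dz to parameter gradients of the *negative* logL."""
    X, H = cache["X"], cache["H"]
    if params.hidden_units == 0:
        return {"W_output": -(X.T @ dz), "b_output": -float(dz.sum())}
    gW_out = H.T @ dz
    dH = np.outer(dz, params.W_output)
    if cache["mask"] is not None:
        dH = dH * cache["mask"]
    dpre = dH * (cache["pre"] > 0)
    return {
        "W_output": -gW_out,
        "b_output": -float(dz.sum()),
        "W_hidden": -(X.T @ dpre),
        "B_hidden": -dpre.sum(axis=0),
    }


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    hidden_units: int = 0
    dropout_rate: float = 0.5
    quadrature_order: int = 20
    patience: int = 5
    max_epochs: int = 200
    min_improvement: float = 1e-6
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    sigma0: float = 0.5
    refine_sigma: bool = True
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    hyper_grid: dict = field(
        default_factory=lambda: {
            "learning_rate": [1e-2, 1e-3, 1e-4],
            "hidden_units": [64, 128, 256, 512, 0],
        }
    )
    selection_split: str = "validation"  # or "test"

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.quadrature_order < 2:
            raise ValueError("quadrature order must be >= 2")


def split_genes(
    gene_ids: Sequence[str], fractions, seed: int
) -> dict[str, list[str]]:
    """Seeded random train/validation/test partition over genes."""
    ids = list(gene_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(fractions[0] * len(ids)))
    n_val = int(round(fractions[1] * len(ids)))
    shuffled = [ids[i] for i in order]
    split = {
        "train": shuffled[:n_train],
        "validation": shuffled[n_train : n_train + n_val],
        "test": shuffled[n_train + n_val :],
    }
    if any(len(v) == 0 for k, v in split.items() if fractions[("train", "validation", "test").index(k)] > 0):
        raise ValueError("a requested split is empty; need more genes")
    return split


class _Adam:
    def __init__(self, shapes: Mapping[str, tuple], lr, betas, eps):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, values: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for k, g in grads.items():
            g = np.asarray(g, dtype=float)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            out[k] = values[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def _params_to_values(params: DMEParams) -> dict:
    vals = {
        "W_output": params.W_output.copy(),
        "b_output": float(params.b_output),
        "log_sigma": float(np.log(params.sigma)),
    }
    if params.hidden_units:
        vals["W_hidden"] = params.W_hidden.copy()
        vals["B_hidden"] = params.B_hidden.copy()
    return vals


def _values_to_params(vals: dict, template: DMEParams) -> DMEParams:
    return DMEParams(
        W_output=np.asarray(vals["W_output"]).copy(),
        b_output=float(vals["b_output"]),
        sigma=float(np.exp(vals["log_sigma"])),
        W_hidden=np.asarray(vals["W_hidden"]).copy() if template.hidden_units else None,
        B_hidden=np.asarray(vals["B_hidden"]).copy() if template.hidden_units else None,
        hidden_units=template.hidden_units,
        dropout_rate=template.dropout_rate,
    )


def train(
    dataset: Sequence[GeneBatch],
    config: TrainConfig,
    split: Mapping[str, Sequence[str]] | None = None,
) -> tuple[DMEParams, list[dict]]:
    """Fit by Adam over per-gene minibatches with early stopping.

    ``dataset`` batches must carry standardized features. Returns the
    parameters from the best-validation epoch and a per-epoch log of
    train/validation objectives (mean negative log marginal likelihood per
    gene). Deterministic for a fixed config and split on one thread.
    """
    by_id = {b.gene_id: b for b in dataset}
    if split is None:
        split = split_genes(list(by_id), config.split_fractions, config.seed)
    train_b = [by_id[g] for g in split["train"]]
    val_b = [by_id[g] for g in split["validation"]]
    if not train_b or not val_b:
        raise ValueError("empty train or validation split")
    n_features = train_b[0].X.shape[1]

    ss = np.random.SeedSequence(config.seed)
    init_rng, shuffle_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    params = init_params(
        n_features, config.hidden_units, init_rng,
        dropout_rate=config.dropout_rate, sigma0=config.sigma0,
    )
    values = _params_to_values(params)
    adam = _Adam(
        {k: np.shape(v) for k, v in values.items()},
        config.learning_rate, config.adam_betas, config.adam_eps,
    )

    def objective(batches, p):
        tot = sum(
            -gene_log_marginal_likelihood(b, p, config.quadrature_order) for b in batches
        )
        return tot / max(len(batches), 1)

    log: list[dict] = []
    best_val = np.inf
    best_values = {k: np.copy(v) for k, v in values.items()}
    best_epoch = 0
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(len(train_b))
        epoch_obj = 0.0
        for idx in order:
            b = train_b[idx]
            p = _values_to_params(values, params)
            z, cache = _forward_cached(b.X, p, "train", drop_rng)
            nll, grads = _gene_nll_and_grads(b, p, config.quadrature_order, cache, z)
            if not np.isfinite(nll):
                raise FloatingPointError(
                    f"non-finite objective at gene {b.gene_id} (epoch {epoch})"
                )
            epoch_obj += nll
            values = adam.step(values, grads)
        p = _values_to_params(values, params)
        val_obj = objective(val_b, p)
        log.append(
            {
                "epoch": epoch,
                "train_objective": epoch_obj / len(train_b),
                "validation_objective": val_obj,
                "sigma": p.sigma,
            }
        )
        if val_obj < best_val - config.min_improvement:
            best_val = val_obj
            best_values = {k: np.copy(v) for k, v in values.items()}
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    best_params = _values_to_params(best_values, params)
    if config.refine_sigma:
        best_params = _profile_sigma(train_b, best_params, config.quadrature_order)
    for entry in log:
        entry["best_epoch"] = best_epoch
    return best_params, log


def _profile_sigma(
    batches: Sequence[GeneBatch], params: DMEParams, order: int
) -> DMEParams:
    """Replace sigma by its conditional MLE at the fitted fixed effects.

    Adam moves sigma slowly when per-gene gradients are noisy (its
    per-parameter normalization caps the drift at roughly the learning
    rate times the gradient signal-to-noise ratio), so the joint
    optimization can stop before sigma has converged. The fixed effects do
    not depend on sigma, so a deterministic one-dimensional profile
    optimization of the training objective finishes the job exactly.
    """
    from scipy.optimize import minimize_scalar

    zs = [forward_fixed_effect(b.X, params, mode="infer") for b in batches]

    def nll(log_sigma: float) -> float:
        p = replace(params, sigma=float(np.exp(log_sigma)))
        return -sum(
            gene_log_marginal_likelihood(b, p, order, z=z)
            for b, z in zip(batches, zs)
        )

    res = minimize_scalar(
        nll,
        bounds=(np.log(1e-4), np.log(50.0)),
        method="bounded",
        options={"xatol": 1e-9},
    )
    refined = float(np.exp(res.x))
    if nll(np.log(refined)) <= nll(np.log(params.sigma)):
        return replace(params, sigma=refined)
    return params


def grid_search(
    dataset: Sequence[GeneBatch],
    config: TrainConfig,
    split: Mapping[str, Sequence[str]] | None = None,
) -> tuple[DMEParams, pd.DataFrame]:
    """Train one model per (learning rate, hidden units) grid cell.

    Selection minimizes the held-out objective on ``config.selection_split``
    genes; ties break toward fewer hidden units, then smaller learning
    rate. Failed cells are recorded with their error and skipped.
    """
    grid = config.hyper_grid
    if not grid.get("learning_rate") or "hidden_units" not in grid:
        raise ValueError("hyper_grid must list learning_rate and hidden_units")
    by_id = {b.gene_id: b for b in dataset}
    if split is None:
        split = split_genes(list(by_id), config.split_fractions, config.seed)
    sel = split[config.selection_split]
    sel_b = [by_id[g] for g in sel]
    if not sel_b:
        raise ValueError(f"selection split {config.selection_split!r} is empty")

    rows = []
    results = {}
    for hu in grid["hidden_units"]:
        for lr in grid["learning_rate"]:
            cell = replace(config, learning_rate=lr, hidden_units=hu)
            try:
                params, log = train(dataset, cell, split=split)
                obj = sum(
                    -gene_log_marginal_likelihood(b, params, config.quadrature_order)
                    for b in sel_b
                ) / len(sel_b)
                rows.append(
                    {
                        "hidden_units": hu,
                        "learning_rate": lr,
                        "selection_objective": obj,
                        "epochs": len(log),
                        "error": "",
                    }
                )
                results[(hu, lr)] = params
            except Exception as e:
                rows.append(
                    {
                        "hidden_units": hu,
                        "learning_rate": lr,
                        "selection_objective": np.nan,
                        "epochs": 0,
                        "error": str(e),
                    }
                )
    report = pd.DataFrame(rows)
    ok = report.dropna(subset=["selection_objective"])
    if ok.empty:
        raise RuntimeError("every grid cell failed")
    best = ok.sort_values(
        ["selection_objective", "hidden_units", "learning_rate"]
    ).iloc[0]
    return results[(best.hidden_units, best.learning_rate)], report


# ---------------------------------------------------------------------------
# Model / Results facade


class DeepMixedEffectsModel:
    """Mixed-effects occurrence model over per-gene variant batches.

    Standardizes continuous features on construction (the record is kept
    on the results object and reused verbatim when scoring new variants).
    """

    def __init__(
        self,
        dataset: Sequence[GeneBatch],
        config: TrainConfig | None = None,
        feature_kinds: Sequence[str] | None = None,
        feature_names: Sequence[str] | None = None,
        standardize: bool = True,
    ):
        if not dataset:
            raise ValueError("empty dataset")
        self.config = config or TrainConfig()
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"feat_{k}" for k in range(dataset[0].X.shape[1])]
        )
        if standardize:
            X_all = np.vstack([b.X for b in dataset])
            _, self.standardization = standardize_features(X_all, feature_kinds)
            self.dataset = [
                replace(b, X=self.standardization.apply(b.X)) for b in dataset
            ]
        else:
            n = dataset[0].X.shape[1]
            self.standardization = Standardization(
                np.zeros(n), np.ones(n), ["continuous"] * n
            )
            self.dataset = list(dataset)
        self.split = split_genes(
            [b.gene_id for b in self.dataset],
            self.config.split_fractions,
            self.config.seed,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        config: TrainConfig | None = None,
        feature_columns: Sequence[str] | None = None,
        **kwargs,
    ) -> "DeepMixedEffectsModel":
        if feature_columns is None:
            feature_columns = [c for c in df.columns if c.startswith("feat_")]
        batches = batches_from_frame(df, feature_columns)
        return cls(batches, config=config, feature_names=list(feature_columns), **kwargs)

    def fit(self) -> "DMEResults":
        params, log = train(self.dataset, self.config, split=self.split)
        return DMEResults(self, params, log)

    def fit_grid(self) -> tuple["DMEResults", pd.DataFrame]:
        params, report = grid_search(self.dataset, self.config, split=self.split)
        return DMEResults(self, params, []), report


class DMEResults:
    """Fitted deep mixed-effects model; scoring lives in mixsel.scoring."""

    def __init__(self, model: DeepMixedEffectsModel, params: DMEParams, log: list[dict]):
        self.model = model
        self.params = params
        self.log = log
        self.standardization = model.standardization
        self.split = model.split
        self.feature_names = model.feature_names

    def fixed_effects(self, X_raw: np.ndarray) -> np.ndarray:
        """Deterministic z for raw (unstandardized) feature rows."""
        return forward_fixed_effect(
            self.standardization.apply(np.atleast_2d(np.asarray(X_raw, dtype=float))),
            self.params,
            mode="infer",
        )

    def total_nll(self, split: str = "test") -> float:
        by_id = {b.gene_id: b for b in self.model.dataset}
        genes = self.split[split]
        return sum(
            -gene_log_marginal_likelihood(
                by_id[g], self.params, self.model.config.quadrature_order
            )
            for g in genes
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": 1,
            "params": self.params.to_dict(),
            "standardization": self.standardization.to_dict(),
            "feature_names": self.feature_names,
            "split": self.split,
            "config": {
                "learning_rate": self.model.config.learning_rate,
                "hidden_units": self.model.config.hidden_units,
                "quadrature_order": self.model.config.quadrature_order,
                "seed": self.model.config.seed,
            },
            "log": self.log,
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def load_params(path: str | Path) -> tuple[DMEParams, Standardization, list[str]]:
        payload = json.loads(Path(path).read_text())
        return (
            DMEParams.from_dict(payload["params"]),
            Standardization.from_dict(payload["standardization"]),
            payload["feature_names"],
        )

    def summary(self) -> str:
        p = self.params
        arch = (
            "linear (generalized linear mixed model)"
            if p.hidden_units == 0
            else f"{p.hidden_units} hidden units (dropout {p.dropout_rate})"
        )
        lines = [
            "Deep mixed-effects occurrence model",
            "===================================",
            f"architecture:  {arch}",
            f"features:      {p.n_features}",
            f"sigma (gene random-effect sd): {p.sigma:.4f}",
            f"genes (train/val/test): "
            f"{len(self.split['train'])}/{len(self.split['validation'])}/{len(self.split['test'])}",
        ]
        if self.log:
            lines.append(
                f"epochs run: {len(self.log)} (best epoch {self.log[-1]['best_epoch']})"
            )
            lines.append(
                f"final validation objective: {self.log[-1]['validation_objective']:.6f}"
            )
        if p.hidden_units == 0:
            width = max(len(n) for n in self.feature_names)
            lines.append("fixed-effect weights:")
            for name, w in zip(self.feature_names, p.W_output):
                lines.append(f"  {name:<{width}} {w:+.4f}")
            lines.append(f"  {'(bias)':<{width}} {p.b_output:+.4f}")
        return "\n".join(lines)
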