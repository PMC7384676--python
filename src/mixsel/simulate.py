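"""Synthetic data with the exact generative structure the models assume.

The generator mirrors the fitted likelihoods — Bernoulli occurrence with a
context/depth-driven neutral probability, and a logistic selection layer
with Gaussian gene effects — rather than running a population-genetic
forward simulation. That is precisely what parameter-recovery testing
needs: data whose true parameters are known and live in the model family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .dme import GeneBatch
from .io import RegionMask, VariantRecord, extract_context7, ContextError
from .mutation_model import MutabilityEntry, MutabilityTable, MutationModelParams

BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Ground truth recorded alongside every generated dataset."""

    weights: np.ndarray
    bias: float
    sigma_true: float
    u_true: dict[str, float]
    seed: int
    mutation_params_true: MutationModelParams | None = None
    mu_beta: tuple[float, float] = (2.0, 50.0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": np.asarray(self.weights).tolist(),
            "bias": self.bias,
            "sigma_true": self.sigma_true,
            "u_true": self.u_true,
            "seed": self.seed,
            "mutation_params_true": (
                None
                if self.mutation_params_true is None
                else self.mutation_params_true.to_dict()
            ),
            "mu_beta": list(self.mu_beta),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        mp = d.pop("mutation_params_true")
        return cls(
            weights=np.array(d["weights"]),
            bias=d["bias"],
            sigma_true=d["sigma_true"],
            u_true=d["u_true"],
            seed=d["seed"],
            mutation_params_true=None if mp is None else MutationModelParams.from_dict(mp),
            mu_beta=tuple(d["mu_beta"]),
        )


# ---------------------------------------------------------------------------
# Genome and neutral layer


def simulate_genome(
    n_contigs: int,
    contig_length: int,
    gc: float = 0.41,
    seed: int = 0,
    n_exons_per_contig: int = 2,
    exon_length: int = 150,
    exon_spacing: int = 0,
) -> tuple[dict[str, str], dict[str, tuple[str, int, int]], RegionMask]:
    """Random contigs with non-overlapping exons placed uniformly.

    Returns ``(genome, exons, exon_mask)`` where ``exons`` maps exon_id to
    a half-open interval. ``exon_spacing`` enforces a minimum gap between
    exons (set it above twice the local-fit window to make windows
    disjoint).
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome: dict[str, str] = {}
    exons: dict[str, tuple[str, int, int]] = {}
    intervals = []
    for c in range(n_contigs):
        chrom = f"chr{c + 1}"
        genome[chrom] = "".join(rng.choice(BASES, size=contig_length, p=p))
        slot = exon_length + exon_spacing
        if n_exons_per_contig * slot > contig_length:
            raise ValueError(
                f"cannot place {n_exons_per_contig} exons of {exon_length} bp "
                f"with spacing {exon_spacing} on a {contig_length} bp contig"
            )
        # sample non-overlapping starts by spacing a sorted uniform draw
        free = contig_length - n_exons_per_contig * slot
        gaps = np.sort(rng.integers(0, free + 1, size=n_exons_per_contig))
        for k in range(n_exons_per_contig):
            start = int(gaps[k] + k * slot)
            exon_id = f"{chrom}_exon{k + 1}"
            exons[exon_id] = (chrom, start, start + exon_length)
            intervals.append((chrom, start, start + exon_length))
    return genome, exons, RegionMask(label="coding_exon", intervals=intervals)


def simulate_mutability_table(
    keys: Sequence[tuple[str, str]],
    seed: int = 0,
    f_mean: float = 0.05,
    F_sd: float = 1.0,
) -> MutabilityTable:
    """Synthetic ground-truth mutability with logits spread around logit(f_mean)."""
    rng = np.random.default_rng(seed)
    table = MutabilityTable(pseudocount=0.0)
    base = float(logit(f_mean))
    for key in keys:
        F = float(rng.normal(base, F_sd))
        f = float(expit(F))
        table.entries[key] = MutabilityEntry(1, 0, f, F)
    return table


def _ensure_mutability(table: MutabilityTable, key, rng, f_mean=0.05, F_sd=1.0):
    if key not in table.entries:
        F = float(rng.normal(logit(f_mean), F_sd))
        table.entries[key] = MutabilityEntry(1, 0, float(expit(F)), F)
    return table.entries[key].F


def _intercept_for_pos(chrom, pos0, params: MutationModelParams, exons):
    for exon_id, a3 in params.alpha3.items():
        c, s, e = exons[exon_id]
        if c == chrom and s - params.window_bp <= pos0 < e + params.window_bp:
            return exon_id, a3
    return "none", params.alpha0


_ALT_CHOICES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def simulate_neutral_variants(
    genome: Mapping[str, str],
    mask: RegionMask,
    params: MutationModelParams,
    mutability: MutabilityTable,
    n_sites: int,
    seed: int = 0,
    exons: Mapping[str, tuple[str, int, int]] | None = None,
    depth_meanlog: float = np.log(30.0),
    depth_sdlog: float = 0.3,
) -> list[VariantRecord]:
    """Neutral whole-genome records drawn under the occurrence model.

    Sites are sampled uniformly from the mask (with replacement across
    draws); each gets a random alternate allele, a log-normal mean depth,
    and an occurrence indicator Y ~ Bernoulli(logistic(a + alpha1 log d +
    alpha2 F)), with the intercept a taken from the local exon window when
    ``exons`` are supplied and the site falls inside one (alpha0
    otherwise). Missing mutability keys are extended on the fly so the
    truth table covers the draw. Sites whose 7-mer window leaves the
    contig or contains a non-ACGT base are redrawn.
    """
    if not mask.intervals:
        raise ValueError("empty mask")
    rng = np.random.default_rng(seed)
    ivs = mask.intervals
    lens = np.array([e - s for _, s, e in ivs], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lens)])
    seq_arrays = {
        c: np.frombuffer(s.upper().encode(), dtype="S1") for c, s in genome.items()
    }
    chroms_list = list(genome)
    chrom_index = {c: i for i, c in enumerate(chroms_list)}

    out_chrom: list[str] = []
    out_pos0 = []
    guard = 0
    while len(out_pos0) < n_sites:
        guard += 1
        if guard > 200:
            raise RuntimeError("mask too fragmented to draw the requested sites")
        m = int((n_sites - len(out_pos0)) * 1.2) + 16
        offs = rng.integers(0, cum[-1], size=m)
        iv_idx = np.searchsorted(cum, offs, side="right") - 1
        for j, o in zip(iv_idx, offs):
            chrom, s, _ = ivs[j]
            pos0 = int(s + (o - cum[j]))
            seq = seq_arrays[chrom]
            if pos0 < 3 or pos0 > len(seq) - 4:
                continue
            window = seq[pos0 - 3 : pos0 + 4]
            if not np.isin(window, BASES.astype("S1")).all():
                continue
            out_chrom.append(chrom)
            out_pos0.append(pos0)
            if len(out_pos0) == n_sites:
                break
    pos0_arr = np.array(out_pos0)
    depth = np.exp(rng.normal(depth_meanlog, depth_sdlog, size=n_sites))
    alt_pick = rng.integers(0, 3, size=n_sites)
    # per-site intercepts: alpha0 unless inside an exon's local window
    intercepts = np.full(n_sites, params.alpha0)
    exon_ids = np.array(["none"] * n_sites, dtype=object)
    if exons is not None:
        chrom_arr = np.array([chrom_index[c] for c in out_chrom])
        for exon_id, (c, s, e) in exons.items():
            if exon_id not in params.alpha3:
                continue
            hit = (
                (chrom_arr == chrom_index[c])
                & (pos0_arr >= s - params.window_bp)
                & (pos0_arr < e + params.window_bp)
            )
            intercepts[hit] = params.alpha3[exon_id]
            exon_ids[hit] = exon_id

    records = []
    F_vals = np.empty(n_sites)
    ctxs, refs, alts = [], [], []
    for i in range(n_sites):
        seq = seq_arrays[out_chrom[i]]
        ctx = seq[pos0_arr[i] - 3 : pos0_arr[i] + 4].tobytes().decode()
        ref = ctx[3]
        alt = _ALT_CHOICES[ref][alt_pick[i]]
        ctxs.append(ctx)
        refs.append(ref)
        alts.append(alt)
        F_vals[i] = _ensure_mutability(mutability, (ctx, alt), rng)
    p_occ = expit(intercepts + params.alpha1 * np.log(depth) + params.alpha2 * F_vals)
    Y = rng.random(n_sites) < p_occ
    for i in range(n_sites):
        records.append(
            VariantRecord(
                chrom=out_chrom[i],
                pos=int(pos0_arr[i]) + 1,
                ref=refs[i],
                alt=alts[i],
                gene_id="neutral",
                exon_id=str(exon_ids[i]),
                context7=ctxs[i],
                depth=float(depth[i]),
                observed=int(Y[i]),
                consequence="noncoding",
            )
        )
    return records


def simulate_synonymous_variants(
    genome: Mapping[str, str],
    exons: Mapping[str, tuple[str, int, int]],
    params: MutationModelParams,
    mutability: MutabilityTable,
    n_sites: int,
    seed: int = 0,
    depth_meanlog: float = np.log(30.0),
    depth_sdlog: float = 0.3,
) -> list[VariantRecord]:
    """Synonymous exome records with Y ~ Bernoulli(logistic(beta0 + q))."""
    rng = np.random.default_rng(seed)
    exon_ids = list(exons)
    records = []
    attempts = 0
    while len(records) < n_sites and attempts < 50 * n_sites:
        attempts += 1
        exon_id = exon_ids[int(rng.integers(len(exon_ids)))]
        chrom, s, e = exons[exon_id]
        pos = int(rng.integers(s, e)) + 1
        try:
            ctx = extract_context7(genome, chrom, pos)
        except ContextError:
            continue
        ref = ctx[3]
        alt = str(rng.choice(BASES[BASES != ref]))
        depth = float(np.exp(rng.normal(depth_meanlog, depth_sdlog)))
        F = _ensure_mutability(mutability, (ctx, alt), rng)
        a3 = params.alpha3.get(exon_id, params.alpha0)
        q = a3 + params.alpha1 * np.log(depth) + params.alpha2 * F
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene_id=exon_id.rsplit("_", 1)[0],
                exon_id=exon_id,
                context7=ctx,
                depth=depth,
                observed=int(rng.random() < expit(params.beta0 + q)),
                consequence="synonymous",
            )
        )
    if len(records) < n_sites:
        raise RuntimeError("could not draw the requested synonymous sites")
    return records


# ---------------------------------------------------------------------------
# Missense layer


def simulate_missense_dataset(
    n_genes: int,
    variants_per_gene: int,
    n_features: int,
    weights: np.ndarray | None = None,
    bias: float = 0.0,
    sigma_true: float = 1.0,
    mu_beta: tuple[float, float] = (2.0, 50.0),
    feature_corr: float = 0.0,
    gene_size_lognormal_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[GeneBatch], SimTruth]:
    """Per-gene missense batches from the mixed-effects generative process.

    Features are standard normal (optionally sharing a single latent
    factor with loading sqrt(feature_corr)); z = X w + b; u_j ~ N(0,
    sigma_true); the neutral probability mu is Beta(*mu_beta*)-distributed
    (default mean ~0.04, the rare-variant occurrence regime); and
    Y ~ Bernoulli(logistic(z + u_j) * mu).
    """
    if min(n_genes, variants_per_gene, n_features) < 1:
        raise ValueError("all sizes must be >= 1")
    if not (0 < mu_beta[0] and 0 < mu_beta[1]):
        raise ValueError("mu_beta parameters must be positive")
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = rng.normal(0.0, 0.7, size=n_features)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n_features,):
        raise ValueError("weights length must equal n_features")
    batches = []
    u_true: dict[str, float] = {}
    for j in range(n_genes):
        gene_id = f"g{j:04d}"
        if gene_size_lognormal_sd > 0:
            n_i = max(1, int(round(np.exp(rng.normal(np.log(variants_per_gene), gene_size_lognormal_sd)))))
        else:
            n_i = variants_per_gene
        if feature_corr > 0:
            factor = rng.normal(size=(n_i, 1))
            lam = np.sqrt(feature_corr)
            X = lam * factor + np.sqrt(1 - feature_corr) * rng.normal(size=(n_i, n_features))
        else:
            X = rng.normal(size=(n_i, n_features))
        u = float(rng.normal(0.0, sigma_true)) if sigma_true > 0 else 0.0
        u_true[gene_id] = u
        z = X @ weights + bias
        mu = rng.beta(*mu_beta, size=n_i)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        Y = (rng.random(n_i) < expit(z + u) * mu).astype(float)
        keys = [(f"chr0", j * 10**6 + i + 1, "A", "C") for i in range(n_i)]
        batches.append(GeneBatch(gene_id=gene_id, X=X, mu=mu, Y=Y, variant_keys=keys))
    truth = SimTruth(
        weights=weights,
        bias=float(bias),
        sigma_true=float(sigma_true),
        u_true=u_true,
        seed=seed,
        mu_beta=mu_beta,
    )
    return batches, truth


# ---------------------------------------------------------------------------
# Labeled benchmarks


def make_labeled_benchmark(
    scores: Mapping[str, float],
    truth_values: Mapping[str, float],
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    pos_quantile: float = 0.8,
    neg_quantile: float = 0.2,
) -> "pd.DataFrame":
    """Balanced labeled table for downstream ROC/enrichment tests.

    Positives are items whose truth value (e.g. -u_true, or true z) lies at
    or above the ``pos_quantile`` of the truth distribution; negatives at
    or below ``neg_quantile``. ``n_pos``/``n_neg`` items are sampled
    without replacement from each class.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    ids = [i for i in scores if i in truth_values]
    tv = np.array([truth_values[i] for i in ids])
    hi, lo = np.quantile(tv, pos_quantile), np.quantile(tv, neg_quantile)
    pos_pool = [i for i, t in zip(ids, tv) if t >= hi]
    neg_pool = [i for i, t in zip(ids, tv) if t <= lo]
    if len(pos_pool) < n_pos or len(neg_pool) < n_neg:
        raise ValueError(
            f"insufficient class members (pos pool {len(pos_pool)}, "
            f"neg pool {len(neg_pool)})"
        )
    pos = rng.choice(pos_pool, size=n_pos, replace=False)
    neg = rng.choice(neg_pool, size=n_neg, replace=False)
    rows = [{"id": i, "score": scores[i], "label": 1} for i in pos]
    rows += [{"id": i, "score": scores[i], "label": 0} for i in neg]
    return pd.DataFrame(rows)
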