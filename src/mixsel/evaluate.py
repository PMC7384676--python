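"""Benchmarking utilities: balanced AUC, enrichment odds ratios,
length-matched gene negatives, and median splits.

These mirror the standard evaluation recipes for variant- and gene-level
constraint scores: class-balanced ROC/AUC against labeled variant sets,
log2 odds-ratio enrichment of top-ranked variants at percentile cutoffs,
gene negatives matched on (log) gene length, and splitting a gene set in
half on its constraint score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

LN2 = np.log(2.0)


def balanced_auc(
    pos_scores, neg_scores, seed: int = 0
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """AUC after downsampling the larger class to the smaller.

    Sampling is without replacement with a seeded generator. The AUC is
    the normalized Mann-Whitney U statistic (ties count 0.5): the
    probability that a random positive outranks a random negative.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    rng = np.random.default_rng(seed)
    n = min(pos.size, neg.size)
    if pos.size > n:
        pos = rng.choice(pos, size=n, replace=False)
    if neg.size > n:
        neg = rng.choice(neg, size=n, replace=False)
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size)), (pos, neg)


@dataclass
class EnrichmentResult:
    cutoff_percentile: float
    table: np.ndarray  # [[case_above, case_below], [control_above, control_below]]
    log2_or: float
    se_log2_or: float
    flagged: bool = False  # degenerate pooled distribution


def percentile_enrichment(
    case_scores, control_scores, percentile: float, seed: int = 0
) -> EnrichmentResult:
    """Enrichment of cases above a top-``percentile`` pooled-score cutoff.

    ``percentile`` is the "top X%" cutoff: the threshold is the
    (100 - percentile)th percentile of the pooled case+control scores.
    Zero cells get the Haldane-Anscombe 0.5 correction before the odds
    ratio; the standard error is sqrt(sum of reciprocal cells)/ln 2 on the
    (possibly corrected) cells. ``seed`` is accepted for interface
    symmetry with the sampling-based evaluators; no sampling happens here.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    case = np.asarray(case_scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    pooled = np.concatenate([case, control])
    flagged = bool(np.all(pooled == pooled[0]))
    thr = np.quantile(pooled, 1.0 - percentile / 100.0)
    a = int((case >= thr).sum())
    b = case.size - a
    c = int((control >= thr).sum())
    d = control.size - c
    table = np.array([[a, b], [c, d]], dtype=float)
    cells = table + 0.5 if (table == 0).any() else table
    log2_or = float(
        (np.log(cells[0, 0]) - np.log(cells[0, 1]) - np.log(cells[1, 0]) + np.log(cells[1, 1]))
        / LN2
    )
    se = float(np.sqrt((1.0 / cells).sum()) / LN2)
    return EnrichmentResult(
        cutoff_percentile=float(percentile),
        table=table.astype(int),
        log2_or=log2_or,
        se_log2_or=se,
        flagged=flagged,
    )


def match_negatives_by_length(
    positives: pd.DataFrame,
    pool: pd.DataFrame,
    seed: int = 0,
    length_column: str = "length",
    id_column: str = "gene_id",
) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbour matching on log gene length.

    Positives are visited in a seeded random order; each takes the
    unclaimed pool gene closest in log length (lengths are right-skewed,
    so matching is on the log scale). Returns the matched negatives with a
    ``matched_to`` column, one per positive.
    """
    if len(pool) < len(positives):
        raise ValueError("pool must contain at least as many genes as positives")
    rng = np.random.default_rng(seed)
    pool_ids = pool[id_column].to_numpy()
    pool_log = np.log(pool[length_column].to_numpy(dtype=float))
    available = np.ones(len(pool), dtype=bool)
    order = rng.permutation(len(positives))
    rows = []
    for idx in order:
        prow = positives.iloc[idx]
        target = np.log(float(prow[length_column]))
        cand = np.flatnonzero(available)
        best = cand[np.argmin(np.abs(pool_log[cand] - target))]
        available[best] = False
        rows.append(
            {
                id_column: pool_ids[best],
                length_column: pool[length_column].iloc[best],
                "matched_to": prow[id_column],
            }
        )
    return pd.DataFrame(rows)


def median_split(gene_scores: dict[str, float]) -> tuple[list[str], list[str]]:
    """Split genes into an upper and lower half by score.

    Sorted by score descending with ties broken on the gene identifier;
    the upper set gets ceil(n/2) genes, so even n gives equal halves.
    """
    if len(gene_scores) < 2:
        raise ValueError("need at least two genes")
    ranked = sorted(gene_scores, key=lambda g: (-gene_scores[g], g))
    k = (len(ranked) + 1) // 2
    return ranked[:k], ranked[k:]


def roc_points(pos_scores, neg_scores, n_thresholds: int = 200) -> pd.DataFrame:
    """True-positive vs true-negative rates over a threshold sweep."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    thr = np.quantile(np.concatenate([pos, neg]), np.linspace(0, 1, n_thresholds))
    rows = [
        {"threshold": t, "tpr": float((pos >= t).mean()), "tnr": float((neg < t).mean())}
        for t in thr
    ]
    return pd.DataFrame(rows)
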