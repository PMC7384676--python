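"""Context-dependent neutral mutation model.

The probability that a given single-nucleotide mutation is observed as a
rare variant in a population sample, absent selection, is modelled in three
stages fitted to putatively neutral variation:

1. a genome-wide logistic regression of occurrence on log sequencing depth
   and the logit mutability F of the variant's 7-mer context / alternate
   allele class,
2. a per-exon local recalibration of the intercept using neutral variants
   within a window (default 60 kb) of the exon, with the depth and
   mutability coefficients frozen, which absorbs local mutation-rate
   variation, and
3. a single-intercept recalibration against synonymous variants from exome
   sequencing, which absorbs sample-size and platform differences between
   the whole-genome data the model is trained on and the exome data it is
   applied to.

The fitted model yields, for every candidate mutation, the neutral
occurrence probability mu = logistic(beta0 + q) used downstream as the
baseline against which missense depletion is measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .io import RegionMask, VariantRecord, bool_to_intervals

IRLS_TOL = 1e-10
IRLS_MAXITER = 100


class MutabilityLookupError(KeyError):
    """A (context, alt) class has no usable mutability entry."""


class FitError(RuntimeError):
    """A logistic regression failed to converge or separated."""


# ---------------------------------------------------------------------------
# Mutability table


@dataclass
class MutabilityEntry:
    count_total: int
    count_observed: int
    f: float
    F: float


@dataclass
class MutabilityTable:
    """Per (7-mer context, alternate allele) neutral mutability.

    ``f`` is the smoothed proportion of genomic instances of the context
    class carrying the given rare variant; ``F`` is its logit.
    """

    entries: dict[tuple[str, str], MutabilityEntry] = field(default_factory=dict)
    pseudocount: float = 0.5

    def lookup_F(self, context7: str, alt: str) -> float:
        try:
            e = self.entries[(context7, alt)]
        except KeyError:
            raise MutabilityLookupError(
                f"no mutability entry for context {context7!r} -> {alt!r}"
            ) from None
        if e.count_total == 0:
            raise MutabilityLookupError(
                f"mutability entry for {context7!r} -> {alt!r} has no observations"
            )
        return e.F

    def F_array(self, records: Sequence[VariantRecord]) -> np.ndarray:
        return np.array([self.lookup_F(r.context7, r.alt) for r in records])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "context7": k,
                "alt": l,
                "count_total": e.count_total,
                "count_observed": e.count_observed,
                "f": e.f,
                "F": e.F,
            }
            for (k, l), e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pseudocount: float = 0.5) -> "MutabilityTable":
        entries = {
            (row.context7, row.alt): MutabilityEntry(
                int(row.count_total), int(row.count_observed), float(row.f), float(row.F)
            )
            for row in df.itertuples(index=False)
        }
        return cls(entries=entries, pseudocount=pseudocount)


def compute_mutability(
    neutral_variants: Sequence[VariantRecord], pseudocount: float = 0.5
) -> MutabilityTable:
    """Empirical mutability per (context, alt) with Jeffreys-style smoothing.

    f = (n_observed + a) / (n_total + 2a). With a > 0 every class with at
    least one candidate site gets a finite logit; classes never seen at all
    stay absent and raise on lookup rather than silently contributing 0.
    """
    counts: dict[tuple[str, str], list[int]] = {}
    for r in neutral_variants:
        key = (r.context7, r.alt)
        c = counts.setdefault(key, [0, 0])
        c[0] += 1
        c[1] += r.observed
    a = pseudocount
    table = MutabilityTable(pseudocount=a)
    for key, (total, obs) in counts.items():
        f = (obs + a) / (total + 2 * a)
        if not 0.0 < f < 1.0:
            raise ValueError(f"mutability for {key} not in (0,1); use pseudocount > 0")
        table.entries[key] = MutabilityEntry(total, obs, f, float(logit(f)))
    return table


# ---------------------------------------------------------------------------
# Neutral region mask


def build_neutral_mask(
    coding_exons: RegionMask,
    conserved_elements: RegionMask,
    coverage: Mapping[str, np.ndarray],
    genome: Mapping[str, str],
    exon_buffer: int = 1000,
    conserved_buffer: int = 100,
    min_depth: float = 20.0,
) -> RegionMask:
    """Putatively neutral territory on each contig.

    Excludes coding exons padded by ``exon_buffer``, conserved elements
    padded by ``conserved_buffer``, sites with mean coverage below
    ``min_depth``, and both positions of every CG dinucleotide on the
    reference strand.
    """
    intervals: list[tuple[str, int, int]] = []
    removed = {"exons": 0, "conserved": 0, "coverage": 0, "cpg": 0}
    for chrom, seq in genome.items():
        n = len(seq)
        keep = np.ones(n, dtype=bool)
        ex = _padded_bool(coding_exons, chrom, n, exon_buffer)
        cons = _padded_bool(conserved_elements, chrom, n, conserved_buffer)
        depth = np.asarray(coverage[chrom], dtype=float)
        if depth.shape != (n,):
            raise ValueError(f"coverage track for {chrom} has wrong length")
        low = depth < min_depth
        cpg = _cpg_sites(seq)
        removed["exons"] += int(ex.sum())
        removed["conserved"] += int(cons.sum())
        removed["coverage"] += int(low.sum())
        removed["cpg"] += int(cpg.sum())
        keep &= ~(ex | cons | low | cpg)
        intervals.extend((chrom, s, e) for s, e in bool_to_intervals(keep))
    if not intervals:
        worst = max(removed, key=removed.get)
        raise ValueError(
            "neutral mask is empty; filter removing most territory: "
            f"{worst} ({removed})"
        )
    return RegionMask(label="neutral", intervals=intervals)


def _padded_bool(mask: RegionMask, chrom: str, length: int, pad: int) -> np.ndarray:
    arr = np.zeros(length, dtype=bool)
    for c, s, e in mask.intervals:
        if c == chrom:
            arr[max(0, s - pad) : min(length, e + pad)] = True
    return arr


def _cpg_sites(seq: str) -> np.ndarray:
    s = np.frombuffer(seq.upper().encode(), dtype="S1")
    cpg = np.zeros(len(s), dtype=bool)
    is_cg = (s[:-1] == b"C") & (s[1:] == b"G")
    cpg[:-1] |= is_cg
    cpg[1:] |= is_cg
    return cpg


# ---------------------------------------------------------------------------
# Logistic fits


def _glm_logistic(y: np.ndarray, X: np.ndarray, offset: np.ndarray | None = None):
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            model = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset)
            res = model.fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL)
        except Exception as e:  # separation, singular design, non-convergence
            raise FitError(f"logistic fit failed: {e}") from e
    if not res.converged:
        raise FitError(
            f"IRLS did not converge in {IRLS_MAXITER} iterations "
            f"(deviance {res.deviance:.6g})"
        )
    return res


def fit_global_wgs(
    neutral_variants: Sequence[VariantRecord], mutability: MutabilityTable
):
    """Genome-wide fit of occurrence ~ 1 + log(depth) + F.

    Returns ``(params, bse, glm_results)`` with params = (alpha0, alpha1,
    alpha2). Records with depth 0 are rejected (log undefined); exclude
    them upstream.
    """
    y = np.array([r.observed for r in neutral_variants], dtype=float)
    d = np.array([r.depth for r in neutral_variants], dtype=float)
    if np.any(d <= 0):
        raise ValueError("records with depth<=0 must be excluded before fitting")
    F = mutability.F_array(neutral_variants)
    X = np.column_stack([np.ones_like(d), np.log(d), F])
    res = _glm_logistic(y, X)
    return tuple(res.params), tuple(res.bse), res


def fit_local_exon(
    window_variants: Sequence[VariantRecord],
    alpha0_hat: float,
    alpha1_hat: float,
    alpha2_hat: float,
    mutability: MutabilityTable,
) -> tuple[float, float | None, bool]:
    """Exon-local intercept with the global slopes frozen as an offset.

    Returns ``(alpha3_m, se, fallback)``. An empty window, or one whose
    outcomes are all 0 or all 1 (the one-parameter MLE diverges), falls
    back to the global intercept with ``fallback=True``.
    """
    if not window_variants:
        return alpha0_hat, None, True
    y = np.array([r.observed for r in window_variants], dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        return alpha0_hat, None, True
    d = np.array([r.depth for r in window_variants], dtype=float)
    F = mutability.F_array(window_variants)
    offset = alpha1_hat * np.log(d) + alpha2_hat * F
    res = _glm_logistic(y, np.ones((len(y), 1)), offset=offset)
    return float(res.params[0]), float(res.bse[0]), False


def recalibrate_exome(
    synonymous_variants: Sequence[VariantRecord], q_values: np.ndarray
):
    """Single-intercept logistic recalibration with q as a fixed offset.

    At the optimum the score equation forces the sum of predicted
    occurrence probabilities to equal the observed count exactly.
    """
    y = np.array([r.observed for r in synonymous_variants], dtype=float)
    q = np.asarray(q_values, dtype=float)
    if len(y) != len(q):
        raise ValueError("q_values must align with synonymous_variants")
    res = _glm_logistic(y, np.ones((len(y), 1)), offset=q)
    return float(res.params[0]), float(res.bse[0]), res


# ---------------------------------------------------------------------------
# Parameters, point predictions


@dataclass
class MutationModelParams:
    alpha0: float
    alpha1: float
    alpha2: float
    alpha3: dict[str, float]
    beta0: float
    window_bp: int = 60000
    fitted_on: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "alpha0": self.alpha0,
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "alpha3": dict(self.alpha3),
            "beta0": self.beta0,
            "window_bp": self.window_bp,
            "fitted_on": self.fitted_on,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MutationModelParams":
        return cls(**d)


@dataclass(frozen=True)
class NeutralProb:
    variant_key: tuple[str, int, str, str]
    q: float
    mu: float


def compute_q(
    record: VariantRecord, params: MutationModelParams, mutability: MutabilityTable
) -> float:
    """Logit-scale neutral occurrence prediction for one record."""
    alpha3 = params.alpha3.get(record.exon_id, params.alpha0)
    F = mutability.lookup_F(record.context7, record.alt)
    return alpha3 + params.alpha1 * np.log(record.depth) + params.alpha2 * F


def compute_mu(
    record: VariantRecord, params: MutationModelParams, mutability: MutabilityTable
) -> NeutralProb:
    """Neutral occurrence probability mu = logistic(beta0 + q)."""
    q = compute_q(record, params, mutability)
    mu = float(expit(params.beta0 + q))
    return NeutralProb(
        variant_key=(record.chrom, record.pos, record.ref, record.alt), q=q, mu=mu
    )


# ---------------------------------------------------------------------------
# Model / Results


class NeutralMutationModel:
    """Hierarchical neutral occurrence model, statsmodels-style.

    Parameters
    ----------
    neutral_variants
        Putatively neutral records (whole-genome data restricted to the
        neutral mask, MAF-filtered upstream) used for the mutability table,
        the global fit, and the per-exon local fits.
    synonymous_variants
        Synonymous exome records used for the final recalibration. Their
        ``exon_id`` values select the local intercepts.
    exons
        Map exon_id -> (chrom, start, end), half-open 0-based, defining the
        local windows.
    mutability
        Optional precomputed table; by default recomputed from
        ``neutral_variants`` with ``pseudocount``.
    """

    def __init__(
        self,
        neutral_variants: Sequence[VariantRecord],
        synonymous_variants: Sequence[VariantRecord],
        exons: Mapping[str, tuple[str, int, int]],
        window_bp: int = 60000,
        pseudocount: float = 0.5,
        mutability: MutabilityTable | None = None,
    ):
        if not neutral_variants:
            raise ValueError("no neutral variants supplied")
        self.neutral_variants = list(neutral_variants)
        self.synonymous_variants = list(synonymous_variants)
        self.exons = dict(exons)
        self.window_bp = int(window_bp)
        self.pseudocount = float(pseudocount)
        self.mutability = mutability

    def window_variants(self, exon_id: str) -> list[VariantRecord]:
        chrom, start, end = self.exons[exon_id]
        lo, hi = start - self.window_bp, end + self.window_bp
        return [
            r
            for r in self.neutral_variants
            if r.chrom == chrom and lo <= r.pos - 1 < hi
        ]

    def fit(self) -> "MutationModelResults":
        mutability = self.mutability or compute_mutability(
            self.neutral_variants, self.pseudocount
        )
        (a0, a1, a2), (se0, se1, se2), global_res = fit_global_wgs(
            self.neutral_variants, mutability
        )
        cov12 = np.asarray(global_res.cov_params())[1:3, 1:3]
        alpha3: dict[str, float] = {}
        alpha3_se: dict[str, float | None] = {}
        alpha3_se_prop: dict[str, float | None] = {}
        fallbacks: list[str] = []
        for exon_id in self.exons:
            window = self.window_variants(exon_id)
            a3, se3, fb = fit_local_exon(window, a0, a1, a2, mutability)
            alpha3[exon_id] = a3
            alpha3_se[exon_id] = se3
            if fb:
                fallbacks.append(exon_id)
                alpha3_se_prop[exon_id] = None
            else:
                # the local intercept absorbs first-stage slope error:
                # alpha3_hat ~ alpha3 - wbar . (slopes_hat - slopes), with
                # wbar the local-likelihood-weighted means of (log d, F)
                d = np.array([r.depth for r in window])
                F = mutability.F_array(window)
                p = expit(a3 + a1 * np.log(d) + a2 * F)
                w = p * (1 - p)
                wbar = np.array(
                    [np.average(np.log(d), weights=w), np.average(F, weights=w)]
                )
                alpha3_se_prop[exon_id] = float(
                    np.sqrt(se3**2 + wbar @ cov12 @ wbar)
                )
        params = MutationModelParams(
            alpha0=a0,
            alpha1=a1,
            alpha2=a2,
            alpha3=alpha3,
            beta0=0.0,
            window_bp=self.window_bp,
            fitted_on={
                "n_neutral": len(self.neutral_variants),
                "n_synonymous": len(self.synonymous_variants),
                "fallback_exons": fallbacks,
            },
        )
        # at desk scale the exome set can carry 7-mer classes never seen in
        # the neutral training data; those records cannot be recalibrated
        # and are dropped explicitly (counted in provenance)
        usable = [
            r
            for r in self.synonymous_variants
            if (r.context7, r.alt) in mutability.entries
            and mutability.entries[(r.context7, r.alt)].count_total != 0
        ]
        params.fitted_on["n_synonymous_dropped_unseen_context"] = len(
            self.synonymous_variants
        ) - len(usable)
        if not usable:
            raise FitError("no synonymous record has a usable mutability entry")
        q_syn = np.array([compute_q(r, params, mutability) for r in usable])
        beta0, beta0_se, _ = recalibrate_exome(usable, q_syn)
        params.beta0 = beta0
        return MutationModelResults(
            synonymous_used=usable,
            model=self,
            params=params,
            mutability=mutability,
            standard_errors={
                "alpha0": se0,
                "alpha1": se1,
                "alpha2": se2,
                "alpha3": alpha3_se,
                "alpha3_propagated": alpha3_se_prop,
                "beta0": beta0_se,
            },
            q_synonymous=q_syn,
        )


class MutationModelResults:
    """Fitted neutral mutation model with point predictions and diagnostics."""

    def __init__(self, model, params, mutability, standard_errors, q_synonymous,
                 synonymous_used=None):
        self.model = model
        self.params = params
        self.mutability = mutability
        self.standard_errors = standard_errors
        self.q_synonymous = q_synonymous
        self.synonymous_used = (
            synonymous_used if synonymous_used is not None else model.synonymous_variants
        )

    def compute_q(self, record: VariantRecord) -> float:
        return compute_q(record, self.params, self.mutability)

    def compute_mu(self, record: VariantRecord) -> NeutralProb:
        return compute_mu(record, self.params, self.mutability)

    def mu_array(self, records: Sequence[VariantRecord]) -> np.ndarray:
        return np.array([self.compute_mu(r).mu for r in records])

    def predicted_synonymous_count(self) -> float:
        """Sum of predicted occurrence probabilities on the recalibration set.

        Equals the observed synonymous count at the optimum (intercept
        score equation); the calibration diagnostic mirrored from the
        model's genome-scale use.
        """
        return float(expit(self.params.beta0 + self.q_synonymous).sum())

    def observed_synonymous_count(self) -> int:
        return int(sum(r.observed for r in self.synonymous_used))

    def summary(self) -> str:
        p, se = self.params, self.standard_errors
        lines = [
            "Neutral mutation model",
            "======================",
            f"neutral records:    {p.fitted_on['n_neutral']}",
            f"synonymous records: {p.fitted_on['n_synonymous']}",
            f"alpha0 (intercept):    {p.alpha0:+.4f} (SE {se['alpha0']:.4f})",
            f"alpha1 (log depth):    {p.alpha1:+.4f} (SE {se['alpha1']:.4f})",
            f"alpha2 (mutability F): {p.alpha2:+.4f} (SE {se['alpha2']:.4f})",
            f"beta0  (exome recal.): {p.beta0:+.4f} (SE {se['beta0']:.4f})",
            f"local exon intercepts: {len(p.alpha3)} "
            f"({len(p.fitted_on['fallback_exons'])} fallback to alpha0)",
            f"predicted/observed synonymous count: "
            f"{self.predicted_synonymous_count():.2f}/{self.observed_synonymous_count()}",
        ]
        return "\n".join(lines)
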