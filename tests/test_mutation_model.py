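import numpy as np
import pytest
from scipy.special import expit, logit

from mixsel.io import RegionMask, VariantRecord
from mixsel.mutation_model import (
    MutabilityEntry,
    MutabilityLookupError,
    MutabilityTable,
    MutationModelParams,
    build_neutral_mask,
    compute_mu,
    compute_mutability,
    compute_q,
    fit_global_wgs,
    fit_local_exon,
    recalibrate_exome,
)

CONTEXTS = ["AAACAAA", "TTTCTTT", "GGGCGGG", "ACGCATG"]


def neutral_record(context7="AAACAAA", alt="T", observed=0, depth=30.0, exon_id="none"):
    return VariantRecord(
        chrom="chr1", pos=100, ref=context7[3], alt=alt, gene_id="neutral",
        exon_id=exon_id, context7=context7, depth=depth, observed=observed,
        consequence="noncoding",
    )


class TestMutability:
    def test_unsmoothed_proportion(self):
        recs = [neutral_record(observed=int(i < 3)) for i in range(10)]
        # pseudocount 0 is only valid when counts are interior
        table = compute_mutability(recs, pseudocount=0.0)
        e = table.entries[("AAACAAA", "T")]
        assert e.f == pytest.approx(0.3)
        assert e.F == pytest.approx(np.log(3 / 7), abs=1e-12)

    def test_jeffreys_smoothing_of_empty_class(self):
        recs = [neutral_record(observed=0) for _ in range(10)]
        table = compute_mutability(recs, pseudocount=0.5)
        assert table.entries[("AAACAAA", "T")].f == pytest.approx(0.5 / 11)

    def test_observed_counts_conserved(self):
        rng = np.random.default_rng(0)
        recs = [
            neutral_record(context7=rng.choice(CONTEXTS), alt="T",
                           observed=int(rng.random() < 0.3))
            for _ in range(500)
        ]
        table = compute_mutability(recs)
        total_obs = sum(e.count_observed for e in table.entries.values())
        assert total_obs == sum(r.observed for r in recs)
        assert sum(e.count_total for e in table.entries.values()) == 500

    def test_missing_class_raises(self):
        table = compute_mutability([neutral_record()])
        with pytest.raises(MutabilityLookupError):
            table.lookup_F("CCCCCCC", "A")

    def test_zero_count_entry_raises_not_zero(self):
        table = MutabilityTable()
        table.entries[("AAACAAA", "T")] = MutabilityEntry(0, 0, 0.5, 0.0)
        with pytest.raises(MutabilityLookupError):
            table.lookup_F("AAACAAA", "T")


class TestNeutralMask:
    def _genome(self, n=10_000, seed=0, no_cpg=True):
        rng = np.random.default_rng(seed)
        seq = rng.choice(list("ACGT"), size=n)
        if no_cpg:  # remove CG dinucleotides so only the tested filter acts
            for i in range(n - 1):
                if seq[i] == "C" and seq[i + 1] == "G":
                    seq[i + 1] = "A"
        return {"chr1": "".join(seq)}

    def test_exon_buffer_excluded(self):
        genome = self._genome()
        exons = RegionMask(label="coding_exon", intervals=[("chr1", 4000, 4100)])
        cons = RegionMask(label="conserved_element", intervals=[])
        coverage = {"chr1": np.full(10_000, 30.0)}
        mask = build_neutral_mask(exons, cons, coverage, genome)
        assert mask.intervals == [("chr1", 0, 3000), ("chr1", 5100, 10_000)]

    def test_uniform_low_coverage_fatal(self):
        genome = self._genome()
        empty = RegionMask(label="coding_exon", intervals=[])
        coverage = {"chr1": np.full(10_000, 19.0)}
        with pytest.raises(ValueError, match="coverage"):
            build_neutral_mask(empty, RegionMask(label="conserved_element", intervals=[]),
                               coverage, genome)

    def test_matches_per_base_oracle(self):
        n = 50_000
        rng = np.random.default_rng(7)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=n))}
        exon_iv = [("chr1", int(s), int(s) + 200) for s in rng.integers(0, n - 200, 3)]
        cons_iv = [("chr1", int(s), int(s) + 50) for s in rng.integers(0, n - 50, 5)]
        depth = rng.uniform(10, 40, size=n)
        mask = build_neutral_mask(
            RegionMask(label="coding_exon", intervals=exon_iv),
            RegionMask(label="conserved_element", intervals=cons_iv),
            {"chr1": depth},
            genome,
        )
        # independent per-base brute force
        keep = np.ones(n, dtype=bool)
        for _, s, e in RegionMask(label="x", intervals=exon_iv).intervals:
            keep[max(0, s - 1000) : e + 1000] = False
        for _, s, e in RegionMask(label="x", intervals=cons_iv).intervals:
            keep[max(0, s - 100) : e + 100] = False
        keep[depth < 20] = False
        seq = genome["chr1"]
        for i in range(n - 1):
            if seq[i] == "C" and seq[i + 1] == "G":
                keep[i] = keep[i + 1] = False
        assert np.array_equal(mask.to_bool("chr1", n), keep)


def _simulate_eq1(n, a0, a1, a2, seed=0, n_classes=64):
    """Direct draw from the genome-wide occurrence regression."""
    rng = np.random.default_rng(seed)
    table = MutabilityTable(pseudocount=0.0)
    ctxs = []
    bases = "ACGT"
    while len(ctxs) < n_classes:
        c = "".join(rng.choice(list(bases), size=7))
        if c not in ctxs:
            ctxs.append(c)
    F_true = rng.normal(-3.0, 1.0, size=n_classes)
    for c, F in zip(ctxs, F_true):
        table.entries[(c, "A" if c[3] != "A" else "T")] = MutabilityEntry(
            1, 0, float(expit(F)), float(F)
        )
    keys = list(table.entries)
    recs = []
    for i in range(n):
        ctx, alt = keys[int(rng.integers(n_classes))]
        d = float(np.exp(rng.normal(np.log(30.0), 0.3)))
        F = table.entries[(ctx, alt)].F
        y = int(rng.random() < expit(a0 + a1 * np.log(d) + a2 * F))
        recs.append(
            VariantRecord(chrom="chr1", pos=i + 4, ref=ctx[3], alt=alt,
                          gene_id="neutral", exon_id="none", context7=ctx,
                          depth=d, observed=y, consequence="noncoding")
        )
    return recs, table


class TestGlobalFit:
    def test_parameter_recovery_within_3se(self):
        recs, table = _simulate_eq1(200_000, -3.0, 0.5, 1.0, seed=3)
        (a0, a1, a2), (s0, s1, s2), _ = fit_global_wgs(recs, table)
        assert abs(a0 - (-3.0)) < 3 * s0
        assert abs(a1 - 0.5) < 3 * s1
        assert abs(a2 - 1.0) < 3 * s2

    def test_null_slope_not_detected(self):
        recs, table = _simulate_eq1(100_000, -3.0, 0.5, 0.0, seed=4)
        (_, _, a2), (_, _, s2), _ = fit_global_wgs(recs, table)
        assert abs(a2) < 3 * s2

    def test_score_equation_balances_counts(self):
        recs, table = _simulate_eq1(20_000, -2.5, 0.3, 0.8, seed=5)
        (a0, a1, a2), _, res = fit_global_wgs(recs, table)
        assert res.fittedvalues.sum() == pytest.approx(
            sum(r.observed for r in recs), abs=1e-6
        )

    def test_zero_depth_rejected(self):
        recs, table = _simulate_eq1(100, -3.0, 0.5, 1.0, seed=6)
        bad = recs[0]
        object.__setattr__(bad, "depth", 0.0)
        with pytest.raises(ValueError, match="depth"):
            fit_global_wgs(recs, table)


class TestLocalFit:
    def _window(self, a3, n=30_000, seed=0):
        recs, table = _simulate_eq1(n, a3, 0.5, 1.0, seed=seed)
        return recs, table

    def test_no_deviation_recovered(self):
        recs, table = self._window(-3.0, seed=8)
        a3, se, fb = fit_local_exon(recs, -3.0, 0.5, 1.0, table)
        assert not fb
        assert abs(a3 - (-3.0)) < 3 * se

    def test_doubled_rate_offset_recovered(self):
        recs, table = self._window(-3.0 + np.log(2), seed=9)
        a3, se, fb = fit_local_exon(recs, -3.0, 0.5, 1.0, table)
        assert abs(a3 - (-3.0 + np.log(2))) < 3 * se

    def test_all_zero_outcomes_fall_back(self):
        recs, table = self._window(-3.0, n=50, seed=10)
        for r in recs:
            object.__setattr__(r, "observed", 0)
        a3, se, fb = fit_local_exon(recs, -2.2, 0.5, 1.0, table)
        assert fb and a3 == -2.2 and se is None

    def test_empty_window_falls_back(self):
        a3, se, fb = fit_local_exon([], -2.2, 0.5, 1.0, MutabilityTable())
        assert fb and a3 == -2.2


class TestRecalibration:
    def _syn(self, n, frac, seed=0):
        rng = np.random.default_rng(seed)
        return [
            neutral_record(observed=int(rng.random() < frac)) for _ in range(n)
        ]

    def test_symmetric_half_observed(self):
        recs = [neutral_record(observed=i % 2) for i in range(1000)]
        b0, se, _ = recalibrate_exome(recs, np.zeros(1000))
        assert b0 == pytest.approx(0.0, abs=1e-10)

    def test_quarter_observed_closed_form(self):
        recs = [neutral_record(observed=int(i % 4 == 0)) for i in range(1000)]
        b0, _, _ = recalibrate_exome(recs, np.zeros(1000))
        assert b0 == pytest.approx(logit(0.25), abs=1e-8)

    def test_simulated_offset_recovery(self):
        rng = np.random.default_rng(12)
        n = 100_000
        q = rng.normal(-2.0, 1.0, size=n)
        y = rng.random(n) < expit(-1.5 + q)
        recs = [neutral_record(observed=int(v)) for v in y]
        b0, se, _ = recalibrate_exome(recs, q)
        assert abs(b0 - (-1.5)) < 3 * se


class TestPointPredictions:
    def _setup(self):
        table = MutabilityTable()
        table.entries[("AAACAAA", "T")] = MutabilityEntry(10, 3, 0.3, float(logit(0.3)))
        params = MutationModelParams(
            alpha0=-3.0, alpha1=0.0, alpha2=1.0, alpha3={"e1": -3.0}, beta0=0.0
        )
        return table, params

    def test_zero_terms(self):
        table, params = self._setup()
        table.entries[("AAACAAA", "T")] = MutabilityEntry(10, 5, 0.5, 0.0)
        rec = neutral_record(exon_id="e1")
        assert compute_q(rec, params, table) == pytest.approx(-3.0)

    def test_depth_one_removes_depth_term(self):
        table, params = self._setup()
        params.alpha1 = 7.0
        rec = neutral_record(exon_id="e1", depth=1.0)
        q = compute_q(rec, params, table)
        params2 = MutationModelParams(
            alpha0=-3.0, alpha1=0.0, alpha2=1.0, alpha3={"e1": -3.0}, beta0=0.0
        )
        assert q == pytest.approx(compute_q(rec, params2, table))

    def test_matches_manual_recomputation_and_is_pure(self):
        rng = np.random.default_rng(13)
        table, _ = self._setup()
        F = table.entries[("AAACAAA", "T")].F
        for _ in range(20):
            params = MutationModelParams(
                alpha0=rng.normal(), alpha1=rng.normal(), alpha2=rng.normal(),
                alpha3={"e1": rng.normal()}, beta0=rng.normal(),
            )
            d = float(rng.uniform(1, 60))
            rec = neutral_record(exon_id="e1", depth=d)
            expected = params.alpha3["e1"] + params.alpha1 * np.log(d) + params.alpha2 * F
            assert compute_q(rec, params, table) == expected
            np1 = compute_mu(rec, params, table)
            np2 = compute_mu(rec, params, table)
            assert np1.mu == np2.mu == expit(params.beta0 + expected)

    def test_mu_examples_and_monotonicity(self):
        table, params = self._setup()
        table.entries[("AAACAAA", "T")] = MutabilityEntry(10, 5, 0.5, 0.0)
        rec = neutral_record(exon_id="e1", depth=1.0)
        assert compute_mu(rec, params, table).mu == pytest.approx(expit(-3.0))
        params.beta0 = -2.0
        params.alpha3["e1"] = -2.0
        assert compute_mu(rec, params, table).mu == pytest.approx(expit(-4.0))
        # monotone in q at fixed beta0
        mus = []
        for a3 in (-4.0, -2.0, 0.0, 2.0):
            params.alpha3["e1"] = a3
            mus.append(compute_mu(rec, params, table).mu)
        assert all(a < b for a, b in zip(mus, mus[1:]))
        assert all(0 < m < 1 for m in mus)

    def test_missing_mutability_entry_raises(self):
        table, params = self._setup()
        rec = neutral_record(context7="AAAGAAA", alt="T", exon_id="e1")
        with pytest.raises(MutabilityLookupError):
            compute_q(rec, params, table)
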