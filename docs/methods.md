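# Methods

`mixsel` infers the strength of negative (purifying) selection on missense
mutations from their depletion in population sequencing data, jointly at the
variant level and the gene level. This note documents the models, the
estimation procedures, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Neutral occurrence model

The baseline for measuring depletion is the probability `mu_ij` that
candidate mutation `i` in gene `j` would be observed as a rare variant
(MAF < 0.1%) in the sample if only mutation, drift, and technical factors
acted. It is fitted in three stages on putatively neutral variation:

1. **Mutability.** For every combination of 7-mer reference context `k`
   (focal base ± 3) and alternate allele `l`, the mutability `f_{k->l}` is
   the proportion of genomic instances of `k` carrying the rare variant
   `l`, smoothed with a Jeffreys-style pseudocount `a` (default 0.5):
   `f = (n_obs + a) / (n_total + 2a)`. Its logit `F` enters the regressions
   below. Context classes never seen in the training data stay absent and
   raise an explicit lookup error downstream — a silent default of zero
   would masquerade as an extremely cold context.
2. **Genome-wide regression.** On neutral whole-genome records,
   `P(Y=1) = logistic(alpha0 + alpha1 * log d + alpha2 * F)`, with `d` the
   mean sequencing depth at the site. Natural log; records with `d <= 0`
   are excluded (the log is undefined and such sites are uncallable anyway).
3. **Local recalibration.** For each exon `m`, an exon-specific intercept
   `alpha3_m` is refitted on the neutral variants within `window_bp`
   (default 60 kb) of the exon, with `alpha1`, `alpha2` frozen — a
   multiplicative adjustment for local mutation-rate variation. Windows of
   nearby exons may share variants, so the `alpha3_m` are correlated
   across exons; this is intrinsic to the design. An empty window, or one
   whose outcomes are all 0 or all 1 (the one-parameter MLE diverges),
   falls back to `alpha0` and is flagged in provenance.
4. **Exome recalibration.** A single intercept `beta0` is refitted on
   synonymous exome records with the whole-genome prediction
   `q = alpha3_m + alpha1 log d + alpha2 F` as a fixed offset, absorbing
   sample-size and platform differences. Finally
   `mu = logistic(beta0 + q)`.

All logistic fits go through IRLS (statsmodels GLM, binomial family) with
relative tolerance 1e-10 and at most 100 iterations, so convergence is
exact and deterministic. A corollary used as a built-in diagnostic: at the
optimum of stage 4 the intercept score equation forces the **sum of
predicted synonymous occurrence probabilities to equal the observed
synonymous count exactly**.

Neutral territory is the complement of: coding exons padded by 1000 bp,
conserved elements padded by 100 bp, sites with mean coverage below 20,
and both positions of every CG dinucleotide on the reference strand (CpG
sites mutate too fast and too heterogeneously to serve as a baseline).
Thresholds are configurable; the defaults are the standard ones for this
kind of analysis. 7-mer contexts are read from the reference strand with
no strand collapsing; a pyrimidine-centered folding variant could be added
on top of the same machinery.

### Two-stage standard errors

`alpha3_m` is estimated with the first-stage slopes frozen, so its naive
SE understates the uncertainty: an error in `alpha1` or `alpha2` is
absorbed by the local intercept in proportion to the local
likelihood-weighted means of `log d` and `F`. The results object therefore
also reports a delta-method SE,

    SE^2 = SE_local^2 + wbar' Cov(alpha1_hat, alpha2_hat) wbar,

with `wbar` those weighted means. Recovery tests check `alpha3_m` against
this propagated SE; at genome scale the first-stage term is negligible,
at desk scale it dominates.

## Deep mixed-effects occurrence model

Selection is modelled through the relative occurrence probability
`eta_ij = logistic(z_ij + u_j)`: the full occurrence probability of a
candidate missense mutation is `eta_ij * mu_ij`, so `eta < 1` means
depletion relative to neutral expectation.

- The **fixed effect** `z_ij` is a feedforward network of the variant's
  feature vector: one ReLU hidden layer (`hidden_units` in {64, 128, 256,
  512}) followed by inverted dropout (rate 0.5, training mode only;
  inference is deterministic), then a linear output. `hidden_units = 0`
  selects the linear model, an ordinary generalized linear mixed model.
  Weights are Glorot-uniform initialised, biases zero.
- The **random effect** `u_j ~ N(0, sigma)` is a gene-level intercept
  capturing constraint not predictable from variant features.
- Continuous features are standardized to mean 0, sd 1 (population
  convention, denominator n) on the fitting set; binary features pass
  through. The standardization record is stored with the parameters and
  reapplied verbatim at scoring time.

The per-gene marginal likelihood integrates `u_j` out of the product of
Bernoulli terms `(eta mu)^Y (1 - eta mu)^(1-Y)` against its Gaussian prior
by Gauss–Hermite quadrature with the change of variables
`u = sqrt(2) sigma x` (order 20 by default — the natural fixed-node rule
for a Gaussian integral), accumulated in log space with log-sum-exp.
Against 20,001-point dense-grid integration, order 20 is accurate to
better than 1e-6 relative in the regime the model operates in (sigma up
to ~1.5, rare-variant `mu`); the dense-grid backend is kept as a
reference implementation for tests and diagnostics.

### Training

The summed negative log marginal likelihood is minimized by Adam
(betas 0.9/0.999, eps 1e-8) over minibatches of one gene each, with the
gene order reshuffled every epoch (seeded). `sigma` is optimized jointly
with the network weights on an unconstrained log scale, initialized at
0.5. Genes are split 80/10/10 into train/validation/test with the run
seed; training stops when the validation objective has not beaten its
running best by more than 1e-6 for `patience` consecutive epochs
(default 5), and the best-validation-epoch weights are restored. All
gradients are analytic (the quadrature nodes move with `sigma`, and that
dependence is differentiated through); the implementation is plain numpy
and is verified against finite differences in the test suite.

**Sigma profile refinement.** Adam's per-parameter step normalization
caps the drift of a parameter at roughly the learning rate times its
gradient signal-to-noise ratio. The per-gene gradient of `log sigma` has
low signal-to-noise when genes are small, so joint optimization can halt
(via early stopping on the weight-dominated validation objective) with
`sigma` far from its optimum while the weights are fully converged. Since
the fixed effects do not depend on `sigma`, training finishes with a
deterministic one-dimensional profile optimization of `sigma` on the
training objective at the fitted weights (bounded Brent on `log sigma`),
which computes its conditional MLE exactly. This is on by default
(`refine_sigma`) and accepted only if it improves the objective.

Hyperparameters (learning rate in {1e-2, 1e-3, 1e-4}; hidden units in
{64, 128, 256, 512, 0}) are chosen by grid search. Selection uses the
validation split by default; selecting on the test split (as is sometimes
done) conflates selection with evaluation, so it is available but not the
default (`selection_split`). Ties break toward fewer hidden units, then
smaller learning rate.

### Scores

After fitting, the posterior of each gene's random effect given its own
occurrence data is evaluated on the quadrature nodes and normalized in
log space. The **variant constraint score** is
`1 - E[eta_ij | data_j]` — the posterior-expected reduction in occurrence
probability — and the **gene constraint score** is the arithmetic mean of
the variant scores over the gene's candidate missense mutations (the
variant universe is caller-supplied, never inferred). Both lie in [0, 1];
higher means stronger inferred selection. A gene with no occurrence
evidence, or one deliberately scored with `use_posterior=False` (e.g. a
gene held out from training), uses the prior, i.e. the genome-wide
average random effect of zero. An empty gene yields an explicit missing
marker, never a default score.

For interpretation, the **linear surrogate**: a linear model trained on
the same data is read off directly — the contribution of a feature is the
negated regression weight, and the contribution of the gene random effect
is `-sigma`. Calling this on a nonlinear model is an error by design; the
surrogate, not the network, is the object to interpret.

## Synthetic data

The generator draws data from the model's own likelihood — sites and
contexts from a random genome, occurrence indicators from the logistic
occurrence models, gene effects from `N(0, sigma_true)` — with the full
ground truth recorded. Defaults: features standard normal, neutral
probability baseline `mu ~ Beta(2, 50)` (mean ≈ 0.04, the rare-variant
occurrence regime), depth log-normal around 30x, uncorrelated features
(a single-factor correlation and log-normal gene sizes are available).

This is deliberately **not** a population-genetic forward simulation:
there is no drift, no site-frequency spectrum, no linkage. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery — that the implementation recovers the parameters of its own
generative model — not robustness to model misspecification on real
cohorts (real feature distributions are non-Gaussian and correlated, real
mutability interacts with selection, and real depth varies systematically
with sequence context).

### Problem sizes and experiment designs

Desk-scale experiment sizes were chosen so each check has statistical
power under its stated threshold:

- **Quadrature validation**: 100 random genes, up to 20 variants,
  sigma in [0.2, 1.5].
- **Neutral-model recovery**: two 1 Mb contigs, four exons with disjoint
  60 kb windows and local offsets {0, log 2, -0.3, +0.3}, 1e5 neutral
  sites, 8e3 synonymous sites. The regression is refit using the
  generating mutability table as covariate, so the coefficients are
  exactly identified and the 3-SE check is sharp; re-estimating the
  table from the simulated data itself (the real-data route, also
  implemented) folds the table's own sampling noise into the covariate.
- **Mixed-effects recovery**: 200 genes × 300 variants, 5 features with
  weights (-1, -0.5, 0, 0.5, 1), sigma_true = 1. With ~6 expected
  occurrences per gene, sigma is weakly identified per gene; across 200
  genes its MLE concentrates within ~±0.1 of truth.
- **No-gene-effect control**: under sigma_true = 0 the sampling noise of
  `sigma_hat^2` scales as `1 / (I sqrt(J))` with `I` the per-gene Fisher
  information about `u`. For the control's `sigma_hat < 0.1` decision
  threshold to have power, the design uses 200 genes × 6000 variants with
  half-scale weights (keeping `eta` in its informative mid-range); at the
  sigma=1 recovery size the null estimate itself fluctuates to ~0.2-0.4
  and the check would be uninformative.
- **Recovery optimizer settings**: learning rate 1e-3 (from the standard
  grid), early-stopping patience 15 rather than the default 5 — the
  validation signal from `sigma` is small relative to minibatch noise at
  these sizes — and at most 300 epochs.

## Known limitations

- The 30 upstream variant features (conservation scores, protein
  structural features, splicing scores, ...) are consumed as a
  precomputed table; computing them is out of scope.
- Input formats are TSV/BED/FASTA; VCF ingestion would be a thin mapping
  onto the same variant schema and is not currently implemented.
- The sample odds ratio (with Haldane–Anscombe 0.5 correction for zero
  cells) is the enrichment estimator; the conditional-MLE odds ratio of
  an exact Fisher test differs slightly in small tables.
- Percentile enrichment thresholds are computed on the pooled
  case+control distribution (configurable).
- Gene-length matching is greedy 1:1 nearest-neighbour on log length
  without replacement — adequate for the matched-negative constructions
  used here, not an optimal-matching implementation.
- No GPU, no distributed training; the implementation targets
  desk-scale data (up to ~1e6 variants) on one CPU.
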