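# Methods

## Model and procedure

The pipeline identifies senescent cells (SnCs) in the oldest age group of a
single-cell cohort and derives a marker signature from them, under three
working assumptions: (a) cells from donors younger than 30 are healthy, so
the young group provides labeled positives; (b) the unlabeled groups are
mixtures p(x) = α·p₊(x) + (1−α)·p₋(x) of healthy and senescent cells with
mixture proportion α; and (c) the healthy-given-expression relation is the
same across ages while the input distribution drifts with age (covariate
shift): healthy aged cells carry aging programs — inflammation, epigenetic
drift — that have nothing to do with senescence.

Per cell type, cells of all three age groups are pooled and projected onto
the top principal components of the measured part of U, the union of the
prior senescence gene lists (centered, unscaled PCA; inputs are assumed
log-normalized). U restricts the feature space to genes with prior
senescence evidence, giving the learner a weak separation to amplify.

The classifier g minimizes the importance-weighted unbiased PU risk

    R(g) = α · E_{x~p+tr}[ ℓ̃(g(x)) · w(x) ] + E_{x~ptr}[ ℓ(−g(x)) · w(x) ]

with composite loss ℓ̃(z) = ℓ(z) − ℓ(−z) and importance weight
w(x) = p_te(x)/p_tr(x). Both the positive sample (group Y) and the unlabeled
training sample (group M) are reweighted by w, which transports the
empirical risk to the test distribution (group A); the risk on training data
is then an unbiased estimator of the test-distribution PU risk. For any loss
with ℓ(z) − ℓ(−z) = −z (squared loss, double hinge) the positive term is
linear in g. With the squared loss ℓ(z) = (1−z)²/4 and a
linear-in-parameter model g(x) = Σₗ θₗ K(x, cₗ) + b over Gaussian kernels,
the minimizer solves one ridge system; this closed form is the default.
Aged cells with g(x) < 0 are called senescent (ties go to healthy).

A note on identifiability: PU learning extracts the negative class by
contrasting the unlabeled mixture against the positive sample. If the
unlabeled *training* population contained no negatives at all, positives
and unlabeled would be identically distributed and the pointwise optimum
would be g ≡ 2α − 1 > 0 everywhere — no cell could ever be called
senescent. The mixture assumption (b) therefore applies to the middle
group as well, and the synthetic generator plants the senescent
subpopulation in both M and A by default.

Differential expression then compares called-senescent against healthy
cells *within the aged group only*, so donor-age programs shared by both
subpopulations cancel instead of confounding the contrast: a two-sided
Wilcoxon rank-sum test per gene of U, BH-adjusted within each cell type at
FDR 0.05, direction from the sign of the group-mean difference of
log-normalized expression (group medians are frequently both zero in
sparse data). Genes significant in at least k = 6 cell types — up- or
downregulated alike, directional consistency not required — form the
signature, with per-cell-type directions retained.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| age boundaries | 30, 50 years | Y = [0,30), M = [30,50), A = [50,∞); half-open, so a 50-year-old is aged |
| α | 0.9 | assumed healthy fraction of the unlabeled populations (~10% SnCs); calls are robust over α ∈ [0.7, 0.95] |
| PCA components | 10 | per-cell-type projection of the U-restricted matrix |
| min cells per group | 50 | cell types below this in any age group are skipped |
| min negatives to report | 10 | types with fewer senescent calls are flagged not reportable |
| min SnCs for DE | 20 | types with fewer negatives are excluded from DE |
| FDR | 0.05 | BH within each cell type (per-type gene family; the per-type DE tables are reported per type) |
| k | 6 | minimum number of significant cell types for selection |
| kernel centers (g) | ≤ 200 from unlabeled train | seed-controlled subsample |
| bandwidth (g) | median pairwise distance | computed on pooled positive + unlabeled-train points |
| ridge (g) | 1e-3 | fixed; held-out-risk CV over a grid is available but the risk surface is nearly flat in the ridge while recovery degrades with oversmoothing, so a fixed light penalty is the default |
| uLSIF | ≤ 100 centers from test, 5-fold CV | bandwidth × ridge grid selected by the uLSIF least-squares criterion J = ½E_tr[w²] − E_te[w]; weights clipped at 0 and self-normalized to mean 1 over the training sample |
| Pearson combination | lower χ²₂ₙ tail | P = −2Σlog(1−pᵢ); n = 1 recovers the input p; a single pᵢ = 1 makes P infinite (flagged, combined p = 1). The method emphasizes large p-values: evidence must be broad, not carried by one gene |
| rank-sum variant | exact / asymptotic | exact enumeration for tie-free pooled samples with n+m ≤ 20; tie- and continuity-corrected normal approximation otherwise |
| Wasserstein | per-gene 1-D, mean over genes | groups subsampled to 5000 cells without replacement, seed-controlled; a multivariate variant on PCA scores exists but is off by default |
| QC | 500 counts, 400 genes, 50 gene counts | cells failing either cell rule are removed first, then genes |

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
not lung biology. Negative-binomial counts (var = μ + 0.3·μ²) with
lognormal per-gene baselines (log-mean −1, log-sd 1) and per-cell-type
perturbations (log-sd 0.3); lognormal cell-depth factors (log-sd 0.3);
library-size normalization to the median depth followed by log1p. Default
cohort: 8 cell types × 3 age groups × 1000 cells, 2000 genes, sized to
the regime of a large atlas where each analyzed cell type has on the order
of a thousand cells per age group — with many fewer cells the ~10%
unlabeled minority is tens of cells and no method recovers it stably.

Planted structure: 50 marker genes (70% up, 30% down, log-scale shift 1.0)
expressed by the 10% senescent subpopulation of M and A; 100 disjoint
aging-program genes shifted by 0.5 in *every* aged cell, so the aging
program is a property of the aged donor and cancels within-A, exactly the
confounder the within-group DE design controls for. Markers and aging
genes are planted only on genes above the median baseline: a log-scale
effect on a gene at the detection floor would be no effect at all in the
measured data. Four prior lists of 120 genes each carry 60% marker recall
plus random decoys (which may include aging genes, so part of the
covariate shift is visible inside U, as with real prior lists). Effects
are additive on the log-mean scale, matching the rank-based tests. All
randomness derives from one seed through fixed-offset substreams;
identical seeds give bit-identical cohorts.

What the generator does not emulate — ambient RNA, doublets, batch
effects, donor-level pseudobulk correlation, realistic SASP co-regulation,
cell-type-specific marker programs in the cohort (markers shift uniformly
across types) — bounds what passing tests show: they demonstrate that the
estimator recovers the planted structure under the model's own
assumptions, not that those assumptions hold in any particular tissue.

The treatment experiment generator produces balanced control/bleomycin/
doxorubicin/irradiation arms with per-cell-type, per-gene planted
regulation (probability 0.8, random sign, recorded in the truth table),
for testing the pooled-treatment enrichment and p-value-combination path.

## Numerical choices and degenerate inputs

- Decision ties (g = 0) go to the positive (healthy) class.
- The ridge system falls back to progressively stronger regularization
  (×10 per step, with a warning) if singular.
- uLSIF coefficients are clipped at zero, so predicted weights are
  nonnegative by construction; a fit collapsing to all-zero weights raises.
- Rank-sum on two all-identical samples returns p = 1 (zero-variance flag).
- BH inputs outside [0, 1] raise; empty gene-set intersections raise.
- PCA requires at least n_components + 1 cells; cell types failing the
  50-cell rule are excluded before any fit.
- Density-ratio estimation on zero-variance input raises.

## Design choices where the design was open

- **Density-ratio estimator**: uLSIF (closed form, standard for covariate
  shift); centers from the test sample because the ratio must be resolved
  where test density is high.
- **Loss**: squared loss for the closed ridge form; double hinge available
  (convex, solved by L-BFGS) for robustness studies.
- **BH scope**: within each cell type, since DE is reported per cell type;
  a global-correction option exists.
- **Stability protocol**: stability is measured across *algorithm* seeds at
  a fixed cohort (kernel-center subsampling and CV splits re-randomized);
  across different cohorts the planted truth itself changes, so
  cross-cohort Jaccard would conflate data variation with algorithmic
  variation.
- **Smoker exclusion**: derivation uses never-smokers by default
  (metadata-driven filter), keeping exposure effects out of the signature;
  the validation utilities take arbitrary group masks.

## Problem sizes

The test suite and the acceptance script use the default cohort
(24,000 cells × 2,000 genes) for end-to-end checks, a 3-type × 400-gene
variant for unit tests, n = 2000 samples for density-ratio checks, 200
replicates × 1000 samples for the risk-unbiasedness check, and 1000 random
vectors for the BH oracle. A full acceptance run completes in about a
minute on one CPU.

## Known limitations

- α is supplied, not estimated; the same α is used for every cell type.
- The called negative class is *defined* as senescent; the method cannot
  distinguish senescence from any other deviation of aged cells that is
  concentrated in U and absent from the young group.
- Balanced accuracy of per-cell calls (~0.9 at default effect sizes)
  decays with weaker marker effects or smaller cell types; the 20-SnC DE
  floor then removes types from the signature tally.
- The per-gene-averaged Wasserstein distance ignores gene-gene
  correlation; the multivariate option is provided but unvalidated against
  a closed form.
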