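# Methods

## The measurement model

A synthetic genetic array (SGA) screen crosses a set of query strains — here
several mutant alleles of one gene plus a neutral control deletion — into a
genome-wide deletion library and reads out double-mutant fitness as colony
size on 1536-position agar plates.  Each double mutant is pinned as a 2×2
quadruplicate block, and the whole screen is repeated in independent batches
(default 3), giving 12 technical/biological replicate colonies per double
mutant.  Colony sizes are treated as log2-normal around an expected size

    log2(size) = base + delta(gene, query) + batch + row + col + spatial + block + eps

where `delta` is the genetic-interaction effect of interest (negative =
synthetic sick, positive = suppression), and the remaining terms are
nuisances: a per-batch offset, per-row and per-column offsets, a smooth
spatial field per plate, a block effect shared by the four colonies of a
quadruplicate, and colony-level noise.  A colony that fails to grow is
recorded as size 0 and treated as missing, not as a fitness of zero.

Two features of real colony data are modelled explicitly:

* **mean–variance trend** — smaller colonies are relatively noisier.  The
  generator uses `SD(eps) = sigma0 * (1 + trend_strength * max(0, base - m))`
  with `m` the expected log2 size, so sick double mutants get inflated
  residual SD.
* **intra-quadruplicate correlation** — the four colonies of a block share
  pinning source and micro-environment.  A fraction `rho` of the residual
  variance is drawn once per block.

Genes physically near a query locus cannot segregate away from the query
marker during meiosis, so their double mutants are systematically sick
regardless of any true interaction.  The generator plants this artifact as
an additive `-linkage_penalty * (1 - d/W)` log2 penalty for genes whose
midpoint lies within `W` of the query-locus midpoint (default W = 500 kb,
peak penalty 1.5), reproducing the characteristic fitness dip around each
query locus and giving the linkage filter something real to remove.

### Generator defaults and why

| parameter | default | rationale |
|---|---|---|
| `sigma0` | 0.3 log2 | a 20–25 % CV in colony area, typical of pinned colonies |
| `trend_strength` | 0.5 | SD roughly doubles two log2 units below the reference size |
| `rho` | 0.25 | moderate within-quadruplicate sharing |
| `batch_sd` | 0.3 log2 | visible day-to-day offsets, removed by plate medians |
| `rowcol_sd` | 0.1 log2 | mild edge/gradient striping |
| `spatial_amplitude` | 0.3 log2 | smooth within-plate gradients |
| `dropout_p` | 0.02 | occasional pinning failures |
| `base` | 10 | ~1000 px² colonies |
| gene spacing | 20 kb | a 500-kb window then spans ~50 genes, a meaningful exclusion |
| queries | 1 control + 3 mutants | the three-allele-versus-control design |

The generator emulates plate geometry, replicate structure, heteroscedastic
noise, dropout and linkage, but not colony-image artifacts (lawn effects,
agar defects), pinning-source carryover, or mating/sporulation efficiency
differences between library strains.  Passing tests therefore demonstrate
the statistical machinery is correct and calibrated under this model, not
that any particular biological screen satisfies the model.

## Normalization

Per plate (library positions only — empty control quadrants are never used
in reference statistics):

1. log2 transform; zero sizes become missing;
2. subtract the plate median;
3. two rounds of row/column median polish;
4. subtract a smooth spatial surface — a 9×9 NaN-aware moving median of the
   residuals (robust to true interactions, which occupy single blocks);
5. re-polish rows/columns/overall to convergence (tolerance 1e-12), so
   that plate, row and column medians are all exactly zero on complete
   plates.  Step 5 is needed because the spatial subtraction perturbs the
   medians zeroed in steps 2–3.

Everything is median-based, hence scale-invariant: multiplying all raw
sizes by a constant changes nothing downstream.  Plates where fewer than
half of the library positions grew are rejected.

Two exclusion rules run before modelling.  A library gene whose median
colony size on the control-query plates is below `min_fraction` (default
0.1) of the plate median is a failed mutant, excluded from that batch for
all queries; the threshold is a package choice since exclusion of small
control colonies is a qualitative step.  The linkage filter removes genes
within 500 kb (midpoint to midpoint, boundary inclusive — the window is
stated as "±500 kb" without an endpoint convention, and inclusive is the
conservative choice) of each query locus, for that query only.

## Differential fitness

Each gene is analysed with a weighted mixed linear model across all
(query, batch, replicate) observations:

* **Design** — fixed effects for query (control as baseline, so each query
  coefficient is directly the normalized colony-size difference versus
  control) and batch.
* **Mean–variance trend** — robust lowess of sqrt(residual SD) on mean
  fitted log2 size across genes from preliminary unweighted fits,
  discretized to ≥20 piecewise-linear knots with flat extrapolation.
  Observation weights are the inverse predicted variance
  (precision weighting in the voom style).
* **Consensus correlation** — quadruplicates are technical replicates, so
  their four colonies are not independent.  Per gene, a one-way ANOVA
  moment estimator on block means and within-block deviations gives a
  variance-ratio statistic; the consensus pools the bias-corrected mean of
  these scale-free ratios across genes before inverting to the correlation
  scale.  Pooling the ratios rather than averaging per-gene correlations
  avoids the downward Jensen bias of the nonlinear ratio→correlation map,
  which otherwise propagates into anticonservative contrast SEs.
* **Per-gene GLS** — generalized least squares with diagonal precision
  weights and block compound-symmetric correlation.  Because the design
  and the weights are constant within a block, the block means are
  sufficient statistics: the fit collapses each quadruplicate to its mean
  with effective weight `w·n/(1+(n-1)·rho)`, giving identical point
  estimates and contrast variances to the full GLS while estimating the
  residual variance from block-level residuals.  This matters for
  calibration: the contrast variance lives in the block-mean stratum, and
  estimating `s²_g` there (instead of diluting it with within-block
  degrees of freedom) lets the empirical-Bayes step see the true
  gene-to-gene variance heterogeneity (e.g. position-dependent residual
  spatial noise) and absorb it into finite prior degrees of freedom.
* **Moderation** — the prior (d0, s0²) is estimated by moment matching on
  log s²_g using digamma/trigamma identities, with the trigamma function
  inverted by Newton iteration; the posterior variance is the standard
  pooled form `(d0·s0² + d_g·s²_g)/(d0 + d_g)`.  If the excess variance
  estimate is ≤0 the prior is degenerate (d0 = ∞) and the common variance
  is the geometric mean of the s²_g.
* **Contrasts** — each mutant−control and each mutant−reference (the
  reference being the full deletion allele), moderated t = effect/(s̃·√v)
  on d0 + d_g degrees of freedom, two-sided p, Benjamini–Hochberg
  adjustment within each contrast across genes (each contrast is its own
  screen report).

Significance is `padj < 0.05`, with the sign of the effect splitting
positive from negative interactions and no effect-size floor.  The ±0.5
log2 thresholds that appear in cluster heatmaps are display colour classes
only, never calling thresholds.

## Allele-signature ("trifecta") classification

For an allele A compared against the reference deletion B (both versus the
control) and directly (D = allele − reference), each gene receives exactly
one category by priority (first match wins):

1. `unique_gain_{sign}` — D significant, B not: an interaction the allele
   has but the deletion lacks (gained function);
2. `residual_restored` — D and B significant with opposite signs: the
   allele reverses the deletion's interaction (retained/restored function);
3. `increased_sensitivity` — D and B significant with the same sign: the
   allele aggravates the deletion's interaction;
4. `shared_{sign}` — A and B significant, same sign, D not: interaction
   shared with the deletion (lost function);
5. `none`.

Unique gain takes top priority because it is the category defined by its
own explicit criteria (allele-vs-reference significant, reference-vs-control
not).  The priority order makes the categories mutually exclusive and
exhaustive for arbitrary inputs, which is property-tested.

The 2D-volcano tables score each gene by the more significant (minimum) of
the two adjusted p-values on a −log10 scale; "max adjusted p-value score"
is read as "the maximal significance of the pair".

## Enrichment and disease mapping

Over-representation uses the one-sided hypergeometric tail P(X ≥ k) with
the background defaulting to the post-filter screen library (the set of
genes actually testable), BH across the terms of a collection, enriched at
FDR < 0.1.  Collections (e.g. pathway vs process) are tested separately.
Disease mapping intersects a gene set with each disease of a slim disease
ontology; a gene may map to several diseases, and empty diseases are
omitted.

## Exploratory reports

PCA is computed on the gene × (query, batch) mean matrix after removing
per-gene additive batch effects (display only — inference always uses the
batch term in the model); components are sign-fixed by making the
largest-magnitude loading positive.  Hierarchical clustering uses
1 − uncentered correlation with average linkage (the classic colony-screen
clustering defaults); both are configurable, and a 6-leaf brute-force
agglomeration oracle pins the implementation.  Linkage profiles tabulate
signed genomic distance to the query locus against the effect, flagging the
excluded window.

## Validation experiments and problem sizes

`sgafit.validation` (exercised by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs:

* **null calibration** — 20 null screens of 1000 genes; the mean fraction
  of genes falsely called at padj < 0.05 in any mutant−control contrast
  must stay below 0.075 (it is typically ~1e-4: on a full-null screen BH
  rarely rejects anything at all);
* **parameter recovery** — |delta| = 1.0 planted in 5 % of 1000 genes:
  sensitivity ≥ 0.8, mean absolute effect error ≤ 0.2, consensus
  correlation within ±0.1 of the generator value (the estimate sits a few
  hundredths below the raw generator rho because row/column/spatial
  correction genuinely removes part of the shared block signal);
* **trifecta recovery** — six screens, one per category, 500 genes with
  5 % planted at magnitudes |N(1, 0.25)| and random sign for the
  sign-symmetric categories; ≥ 90 % of genes with magnitude ≥ 1.0 must be
  recovered.  Planting density matters: heavy planting (≫10 % of a plate)
  visibly attenuates effects through the robust surface estimators, which
  is also why screens with realistically sparse interactions are the right
  test condition;
* **oracle agreement** — BH vs brute-force step-up, hypergeometric tail vs
  exact enumeration (N ≤ 30), GLS vs OLS at rho = 0, clustering vs
  brute-force agglomeration;
* **normalization invariants** and **linkage-filter completeness** as
  described above.

Problem sizes (1000-gene screens, 20 nulls, 18 trifecta screens) keep each
experiment to a few minutes on one CPU while leaving the binomial noise of
the measured rates well inside the asserted margins.

## Numerical notes and degenerate inputs

* Median polish on even-length rows/columns uses midpoint medians; the
  convergence loop is capped at 200 iterations (it converges in a handful
  on continuous data).
* All-NaN rows/columns (plates with empty regions) contribute zero
  corrections rather than NaNs.
* A block whose replicates are numerically identical yields a clamped
  correlation of 0.99; per-gene correlations are clamped to the
  identifiable range (−1/(k−1), 1).
* Rank-deficient per-gene designs (after missingness) drop the gene with a
  log entry rather than aborting the screen.
* Ties in clustering and sorting are broken by input order
  (`kind="mergesort"`) so reruns are byte-identical.

## Known limitations

* The spatial estimator (9×9 moving median) is a documented stand-in for
  whatever surface correction an upstream protocol might use; any smooth
  robust estimator slots in behind `normalize_plate`.
* One consensus correlation is shared across genes; per-gene correlations
  are too noisy at 9–12 blocks.
* Effect estimates are mildly attenuated (a few percent) by the robust
  plate corrections; at realistic interaction densities this is within the
  recovery tolerances, but screens where a large fraction of the library
  truly interacts would need gentler surface estimation.
* The enrichment background is configurable but defaults to the
  post-filter library; annotation-version differences make external term
  lists only qualitatively comparable.
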