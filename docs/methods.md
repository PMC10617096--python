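# Methods

This note documents the models, parameter choices and numerical behaviour of
`cropmap`, and what its synthetic validation does and does not establish
about real screens.

## Scope and data model

The package analyses a low-MOI pooled CRISPR screen read out by scRNA-seq:
a sparse cell × gene UMI matrix (`ScreenMatrix`), per-cell sgRNA
assignments, a guide library with non-targeting (NT) controls, and a set of
TF-centred regulons supplied as GMT.  Regulon *inference* (co-expression
networks, motif pruning) is out of scope; regulons are inputs.  Analyses
flow: cell QC → unique-sgRNA selection → gene filtering → regulon activity →
perturbation effects → modules and module map → unperturbed-cell filtering →
marker scores, with a benchmarking layer for readout robustness.

## Cell and gene filters

* Cells are kept when genes detected > 200 and < 6000 and mitochondrial
  fraction < 10% — all strict inequalities.  Mitochondrial genes are
  identified by a configurable, case-insensitive symbol prefix (default
  `mt-`), since annotation conventions differ between references.
* Cells are kept only with exactly one distinct assigned sgRNA; cells with
  zero or multiple guides are removed at this step, not at QC.
* For activity scoring, genes need ≥ 6 total UMIs and detection in ≥ 1% of
  cells (inclusive bounds; the fraction is detected/n_cells, no ceiling).
* Per-sgRNA groups need ≥ 40 cells; a target survives if any of its guides
  does.

## Regulon activity (recovery-curve AUC)

Per cell, all G genes are ranked by decreasing raw count; raw counts are
used because the statistic is rank-based and therefore invariant to depth
normalization.  Ties take the average rank — deterministic, unlike random
shuffling; a seeded random-tie mode exists for cross-checking against
shuffle-based implementations.  With window T = ⌊top_frac · G⌋ (default
top_frac = 0.05, the conventional window for this class of scorer;
configurable), the activity is

    AUC = Σ_{x=1..T} rec(x)  /  Σ_{x=1..T} min(x, M)

where rec(x) counts the regulon's M scored members with (ceiled) rank ≤ x.
Members absent from the matrix are dropped at scoring with a logged count;
an empty intersection scores 0 with a warning.  The implementation is a
vectorized closed form of the step-curve sum; the test suite checks it
exactly against an explicit per-rank loop.

## Perturbation effects and regulations

Effect(t, r) = mean activity over target-t cells − mean over reference
cells.  The reference defaults to NT-control cells; an "all other cells"
mode exists because practice varies, but NT is the default so the reference
matches the unperturbed-cell usage of the marker score.  Significance is the
two-sided Wilcoxon rank-sum test: the exact null when both sides have ≤ 25
cells, otherwise the normal approximation with continuity and tie
correction.  Pairs with p < 0.05 (strict) become regulations, activating or
repressive by the effect sign; a zero-effect significant pair carries no
direction and is discarded with a warning.  When condition labels (e.g.
EM/DM) are present, effects are computed within one condition.

## Modules and the hypergeometric map

Spearman correlation matrices over effect profiles (targets × targets and
features × features) feed k-means, each label represented by its row of
correlations.  Defaults k = 4 for perturbations and k = 5 for regulons —
the module counts used in this class of organoid screens — with 50 seeded
restarts; cluster ids are renumbered in order of first appearance so a
partition always serializes identically.  Constant effect profiles have
undefined ranks; they get correlation 0 with a warning (diagonal stays 1).

Within each sign class the (Pi, Rj) cell is tested hypergeometrically (see
README for the formula), computed in log space via `gammaln` and exact to
~1e-14 for the N ≤ 10⁴ regimes of interest.  Two tails are exposed: `upper`
(P(X ≥ k), the default — the quantity that actually measures enrichment)
and `pmf` (P(X = k), kept for bit-compatibility with tools that report the
point mass as the significance).  BH adjustment pools all Pi × Rj × sign
tests jointly by default; per-class pooling is available since either
convention is defensible.  Edges need adjusted p < 0.05; the edge weight is
−log10(adjusted p).

## Perturbation probability and unperturbed-cell filtering

The model: standardized log-normalized expression of the top-variance genes
(default 2000) regressed on cell × guide indicators (optional covariates:
log total UMI, condition dummies) with an elastic net, l1_ratio = 0.5.  The
penalty is either fixed (pipeline default α = 0.05) or chosen by 5-fold CV
over a log-spaced grid.  α = 0.05 is strong enough to zero the spurious
small coefficients that NT guides would otherwise pick up from global-mean
standardization, which is what centres NT probabilities at 0.5 — the
model-consistency property the probability is defined by.

The probability itself is the equal-prior two-hypothesis Gaussian posterior
contrasting the cell's residual under the full model (r₁) against the model
with its own guide's coefficient row zeroed (r₀), with the pooled residual
variance as scale: p = σ((r₀ − r₁)/2σ̂²).  A guide with all-zero
coefficients gives exactly 0.5.  This contrast is this package's concrete
definition of the perturbation probability: it is the simplest posterior
consistent with the fitted linear model, and it reproduces the two
qualitative behaviours that matter — NT cells unimodal around 0.5, strong
targeting guides bimodal.

For filtering, cells are grouped per sgRNA (default; per-target-gene mode
exists because both granularities are sensible) and a two-component 1-D
Gaussian mixture is fitted by EM — 10 restarts with k-means++-style initial
means, tolerance 1e-6, up to 1000 iterations, components ordered by mean.
The mixture is fitted on the **logit** of the probabilities (clipped at
1e-12): posteriors saturate at 0/1 for strong signatures, which collapses a
raw-scale component to a near-delta and misallocates the middle of the
distribution, whereas both modes are approximately Gaussian on the logit
scale.  The EM log-likelihood is non-decreasing by construction and is
recorded per iteration.  Degenerate fits (identical values, variance
collapse, died component) or non-convergence flag the group, which then
passes through unfiltered with a warning rather than discarding cells on a
meaningless fit.  A cell is labelled unperturbed when its posterior for the
higher-mean component is strictly below 0.05, and NT cells are never
filtered — they define the reference distribution.

## Marker scores

Fold changes are computed on depth-normalized linear-scale (counts per 10⁴)
group means — matching the "normalized expression" convention — with a
pseudocount (default 0.01) added to both group and reference means to
stabilize zero-expression markers; the score is the mean log2 fold change
over the panel.  The default 9-gene hepatocyte panel (Alb, Ttr, Mup20,
Sult1a1, Cyp3a13, Abcc3, Tff3, Trf, Fga) is replaceable.  Both NT cells and
mixture-labelled unperturbed cells are accepted as the reference; the
pipeline uses NT.  Positive score = knockout raises marker expression =
candidate repressor of the differentiated fate.

## Synthetic screens and what they establish

The generator emulates: a guide library (default 3 guides/target + NT
controls, mirroring pilot-screen composition), one guide per cell (optional
zero-truncated Poisson multiplicity at MOI 0.3 to exercise unique-sgRNA
filtering), negative-binomial counts (dispersion 2) with per-gene lognormal
baseline means (σ = 1 around median 1), per-entry logistic dropout in the
log-mean (midpoint −2, ≈ 12% dropout at mean 1 — mild 10x-like sparsity),
disjoint regulons whose member genes shift by 2^effect in truly perturbed
cells, an editing-escape fraction (default 0.3) of guide-carrying cells
drawn from the unperturbed distribution entirely (matching the
two-component assumption of the mixture filter), and explicit TF
transcripts: the first n_tfs genes are the TF genes themselves, drawn from
a compressed low-abundance band (0.25× median, σ = 0.5) and co-shifted with
their regulon.  Modelling TF transcripts as sparse is what makes the
regulon-versus-TF-expression robustness comparison meaningful — it is the
sparsity that motivates regulon readouts.  The designated first regulon
carries the marker panel as its leading members.

Deliberately absent: ambient RNA, doublets, batch structure, partial
editing effects, lentiviral recombination.  Passing tests therefore
establish internal correctness (oracle agreement, calibration, recovery of
planted structure under the stated generative model), not performance on
real tissue data with those artefacts.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` seeded per run;
  simulator output, k-means, subsampling and the pipeline are
  byte-reproducible under a fixed seed, verified by artifact checksums.
* Ranking ties: average rank everywhere (scoring, Spearman, Wilcoxon via
  the standard tie-corrected statistics).
* Variable-feature selection for the benchmark cell-feature matrix uses
  the standard dispersion-based highly-variable-gene ranking (default top
  4000) and keeps TFs that are both regulon masters and variable genes;
  feature matrices are z-scored per feature before sign-based comparisons,
  since the compared readouts live on different scales.
* Benchmark sizes: downsampling uses 100 draws per setting by default; the
  cell-number sweep function defaults to 1000 draws per grid point, while
  the packaged analyses use 150–200 draws on grids of ~11 cell counts,
  which bounds the Monte-Carlo error of a median Spearman well below the
  0.9-threshold granularity at a fraction of the cost.
* The eligibility rule for robustness comparisons (targets with > 600
  perturbed cells) is a configurable inclusion filter.

## Known limitations

* The hypergeometric map treats regulations as exchangeable draws; strongly
  correlated regulons violate independence and make the test liberal —
  the BH step mitigates but does not remove this.
* The perturbation probability assumes a single shared residual variance;
  guide-specific noise scales would sharpen separation for weakly expressed
  signatures.
* The GMM filter needs ≥ 10 cells per group and a genuinely bimodal
  probability distribution; very weak knockouts degrade gracefully (fit
  flagged, group unfiltered) rather than being resolved.
* k is user-chosen for the module clustering; no model-selection criterion
  is applied.
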