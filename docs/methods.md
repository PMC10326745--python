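# Methods

This note documents the models and procedures implemented in coexnet,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter for
reproducibility.

## Preprocessing

Input is a proteins × samples matrix of log2 abundances (e.g. iBAQ)
with empty cells for missing values, plus a sample → group design. The
pipeline order is **quantile normalization → missingness filter → KNN
imputation**.

*Quantile normalization* replaces each sample's observed values
rank-wise by the mean of the per-sample sorted values at that rank.
Samples with unequal observed counts are aligned on quantile position
with linear interpolation of the reference; rank ties receive the
average of the tied ranks' reference values. Normalization is applied to
the log2 matrix (log-transform first, then normalize).

*Missingness filter*: proteins with missing fraction ≥ 40% across all
samples (jointly, not per group) are removed; complete proteins always
survive, including at a threshold of 0.

*KNN imputation* (k = 10, the default of the classical gene-expression
KNN imputer) treats proteins as neighbors: a missing entry becomes the
mean of that sample's values over the k nearest protein profiles by
Euclidean distance on co-observed samples. Observed entries are never
altered. Note that re-running the full preprocessing on its own output
is exactly the identity only when nothing was imputed; imputed entries
perturb the per-sample distributions, so a second normalization
redistributes values slightly (mean absolute change well under 10% of
the data SD at 15% missingness).

## Moderated differential expression

The two-group design is an intercept + group-indicator linear model,
i.e. a difference of means. Hyperparameters (d₀, s₀²) of the inverse
chi-square variance prior are estimated by the closed-form moment
equations on log s²_g: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2),
mean(e) = log s₀² + ψ(d₀/2) − log(d₀/2) and
var(e) − ψ′(d_g/2) = ψ′(d₀/2); the trigamma equation is solved by
Newton iteration on ψ′. If the excess variance is non-positive (no
evidence of variance heterogeneity), d₀ is set infinite and every
posterior variance equals s₀². Forcing d₀ = 0 recovers the ordinary
pooled-variance t exactly. p-values use d₀ + d_g df (standard normal
when infinite). Calls require BH FDR < 0.1 together with a case/control
ratio above 1.5, applied post hoc as |log2fc| > log2(1.5). Zero-variance
proteins are excluded from hyperparameter estimation but still shrunk.
The implementation was verified against an independent moment-estimator
oracle (and reproduces the d₀ → 0 and d₀ → ∞ limits in the tests).

## Differential co-expression

All ~p²/2 pairs are processed block-wise: per group, rows are
standardized and correlations computed as a matrix product one block of
rows at a time, so 4000 proteins (~8M pairs) fit in ordinary memory;
only flat per-pair vectors are kept, and only classified DCLs are
written to disk. Pairs are stored canonically (lexicographic), making
results invariant to input row order. Pairs with zero variance in
either group are dropped and excluded from all denominators.

Per-group correlation p-values use the exact t transform (n−2 df) — the
conventional default, exact under normality — and are BH-adjusted across
all tested pairs. The correlation-difference test is Fisher's Z. The
DCL criteria are (1) |r| > 0.5 with FDR < 0.1 in at least one group and
(2) |r_case − r_ctrl| > 0.5 with difference-test FDR < 0.1. **Scope of
the difference FDR**: by default the difference p-values are BH-adjusted
within the pairs already passing criterion (1), matching the reference
differential co-expression tooling; adjusting over all pairs instead is
available as `diff_fdr_scope="all"`. The choice matters: with millions
of tested pairs and a handful of truly co-expressed ones, the all-pairs
family roughly halves the power to flag genuinely differential links,
while the co-expressed family preserves it without inflating the null
rate (the global-null DCL rate stays ≪ 0.5% because criterion (1)
already requires a within-group FDR pass).

DCL classes: *gain* (significant co-expression only in cases), *loss*
(only in controls), *reversal* (both, opposite signs), *other*.

DCPs: per protein, p = P(Binom(n links tested, global DCL rate) ≥ n
DCLs), BH-adjusted, flagged at FDR < 0.1. Link-level pathway enrichment
tests, per gene set, the 2×2 table {DCL vs not} × {both-members-in-set
vs not} over all tested links, one-sided, BH across sets.

## Network integration

The PPI loader accepts HIPPIE-style six-column files (with optional
confidence filtering) or plain two-column edge lists; self-interactions
are dropped and duplicate edges collapse.

*Local enrichment scan*: each star (center + direct neighbors,
restricted to proteins carrying a DE p-value; unscored proteins carry no
evidence and are excluded rather than assigned p = 1) gets the
order-statistic score min_k P(Binom(m, p₍k₎) ≥ k) over its sorted member
p-values. Calibration is empirical: the score distribution of random
size-m member sets drawn with replacement from the global p-value pool
(default 10,000 draws, seeded; one shared null per distinct star size),
with the add-one rank estimate (r+1)/(n+1). Calibrated p-values are
BH-adjusted across centers; significance at FDR < 0.1. Under the global
null the calibrated p-values are uniform in the marginal sense; note
that a KS test on one dataset's centers fluctuates more than iid theory
suggests because stars share member p-values.

*DC-link filter*: among significant stars, a one-sided Fisher's exact
test compares DCL vs non-DCL counts of the star's tested edges against
all tested pairs outside the star (default background; the network's own
tested edges are available as `background="ppi"`). Holm adjustment is
computed across the significant stars — following the order of the
filtering steps — and stars with adjusted p < 0.1 are retained.

*Unified network*: within each retained star's induced edge set, non-DCL
edges are pruned; the maximum connected component (most nodes, ties by
most edges, then lexicographically smallest node set) is kept; all
components are unioned, which is idempotent on shared nodes/edges and
order-independent. Every unified edge is by construction a PPI edge and
a DCL and carries the link statistics; nodes are annotated with DE
status, DCP flag, and optional disease-gene/druggable-target flags.
Gene-set neighborhoods are extracted as the induced subgraph plus
shortest-path linkers (≤ 2 intermediates by default) — a deliberately
simple stand-in for prize-collecting subnetwork extraction, which is out
of scope.

## Enrichment

Over-representation uses the one-sided hypergeometric test per gene set
against a universe that defaults to all proteins surviving
preprocessing, BH across sets, significance at FDR < 0.1. GMT sets are
taken flat; no GO-graph propagation.

## Subtyping and survival

Consensus clustering: 1000 subsample repeats (80% of samples each),
base clusterer agglomerative average linkage on 1 − Pearson correlation
between samples, k = 2..6 — the base method, linkage and subsample
fraction are the defaults of the standard consensus-clustering tool.
Features are z-scored per protein first so high-abundance proteins do
not dominate the correlation distance. consensus(i,j) = co-clustered /
co-sampled; final labels cut a hierarchical tree of 1 − consensus. The
area under the consensus CDF and its relative gain per added k are
reported; the default chosen k is the largest k whose relative gain is
≥ 0.1, but the pipeline pins k = 2 by default (`k_override`), mirroring
inspection-based practice. Subtype markers are moderated-t hits between
the two subtypes at FDR < 0.001 with no fold-change cut. Signature
validation restricts an external cohort to the shared markers (≥ 10
required, matched by gene symbol; unmatched markers are dropped with a
logged count), z-scores per gene and consensus-clusters at fixed k = 2.
Kaplan–Meier estimation and the unweighted log-rank test are delegated
to lifelines behind validated wrappers.

## Synthetic data

The generator emulates a 30-tumor / 22-control log2-abundance study:

* per-protein baselines: mean ~ N(25, 3) (log2-iBAQ scale), SD
  log-normal with median 0.6;
* DE: 8% of proteins shifted by ±1.5 log2 units in cases (the magnitude
  a well-powered label-free study reliably detects at these n);
* co-expression modules: members share a latent factor,
  x = √ρ·f + √(1−ρ)·ε, giving exact expected pairwise correlation ρ
  per group (defaults ρ_case = 0.9, ρ_ctrl = 0); module members form
  cliques in the emitted network and are, by default, also DE
  (dysregulated modules, which is what the star scan looks for);
* the interaction network adds a preferential-attachment background
  (2 edges per node), whose heavy-tailed degrees stress the star scan
  the way curated PPI resources do;
* missingness: 10% overall, half uniform and half logistic in
  abundance (MNAR), mimicking low-intensity dropout;
* two tumor subtypes (60/40 split, as 18/12 of 30), 125 marker proteins
  shifted by ±1.5 in subtype 2; survival exponential with hazard ratio
  3 between subtypes (baseline 1/40 events/month, uniform censoring to
  60 months);
* an "mRNA mirror" cohort (113 samples, as 67+46) carries the marker
  genes with the same subtype structure plus N(0, 1) noise and
  subtype-linked survival, for cross-dataset signature validation.

What it does **not** emulate: peptide/spectrum-level effects, batch
structure, covariates, non-normal abundance distributions, or
biologically structured (pathway-correlated) noise — so passing tests
demonstrate correctness of the statistical machinery under the planted
model, not performance on real tissue data.

Two planted axes interact deliberately: subtype markers are genuinely
differentially expressed between cases and controls (the shift acts on
40% of cases) and genuinely differentially co-expressed (the subtype
indicator induces tumor-specific marker–marker correlation ≈ 0.6).
Tests that score DE or DCL recovery against the planted-DE/module truth
therefore switch the subtype axis off (`subtype_effect=0`), and the
module-recovery checks also disable dropout (`missing_fraction=0`),
because imputation attenuates a planted r = 0.9 to ≈ 0.82 and the
attenuation is a property of imputation, not of the co-expression test.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] before the atanh transform (|r| =
  1 maps just inside); the scalar API refuses |r| = 1 and n ≤ 3.
* BH/Holm cap at 1; ties broken by stable sort on input order.
* Quantile-normalization reference uses the (i+0.5)/n quantile grid.
* The consensus matrix is symmetrized and its diagonal fixed at 1;
  constant matrices and reps < 10 are rejected.
* All randomized stages (generator, LEAN calibration, consensus
  subsampling) consume explicit seeds; a run manifest (seed, parameter
  hash, record counts) fully determines reproduction, and repeated runs
  are byte-identical.
* Problem sizes in the test suite are scaled for quick runs (e.g. 2000
  proteins for the recovery checks, 250–1000 consensus repeats, 2000
  calibration permutations); the defaults in `PipelineConfig` are the
  full analysis settings.

## Known limitations

* The difference-FDR family choice (above) changes DCL counts;
  both scopes are exposed, only the default is tuned for power.
* LEAN calibration shares one null per star size; marginal calibration
  is exact up to Monte-Carlo error, but p-values of equal-size stars
  are correlated through the shared null.
* The unified network inherits any false-positive DCL inside a retained
  star; contamination is controlled by the double filter, not bounded.
* Consensus clustering's chosen-k heuristic (relative CDF-area gain) is
  a default, not an inference; k is meant to be inspected.
* Survival comparison of discovered subtypes reuses the samples that
  defined the subtypes; as in the emulated design, external validation
  (the mirror cohort) is the meaningful test.
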