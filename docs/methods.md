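# Methods

This note records the statistical model behind `breathlink`, the defaults
and why they were chosen, and what the synthetic cohorts do and do not
emulate. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

Both blocks are carried as samples × features tables of non-negative
values: GC–MS peak areas for breath VOCs, relative-abundance fractions for
taxa. Missing VOC cells are read as zero — untargeted GC–MS tables omit
peaks below the detection limit, so absence is censoring, not missingness.
"Present" means strictly positive, and the prevalence filter keeps features
with presence in at least the stated fraction of samples, boundary
inclusive (a feature seen in exactly 3 of 10 samples passes a 30% filter).
Defaults: 20% for VOCs, 30% for taxa.

Taxon profiles are parsed from the merged-table dialect (pipe-delimited
lineages, one column per sample). Only rows terminating exactly at the
requested rank are kept, percent tables are rescaled, and every sample is
renormalized to sum to one. Short names that collide after stripping the
lineage are disambiguated with the parent segment.

Before multivariate analysis, VOCs get log10 with a per-feature
pseudo-count of half the smallest positive value, then per-feature
z-scoring; taxa get multiplicative zero replacement followed by the
centered log-ratio. These are the standard choices for heavy-tailed peak
areas and compositions respectively; both are configurable, and the
rank-based univariate tests run on untransformed values (they are
invariant under monotone maps).

## Sparse PCA

Each component solves a penalized rank-one problem by alternating power
iterations: scores t = Xw, then loadings w ← soft-threshold(Xᵀt),
renormalized, until the direction stabilizes; the matrix is then deflated
by projection and the next component extracted. The threshold is
*relative* — entries are shrunk by `penalty` × (largest |entry|) and
values at or below the threshold become exact zeros — so `penalty = 0`
reproduces ordinary PCA exactly (this is tested against an SVD oracle at
1e-8) and `penalty ≥ 1` empties the loading vector, which is reported as
an error advising a smaller penalty. Initialization uses the residual's
leading right-singular vector, making fits deterministic; the sign
convention puts each column's largest-magnitude loading positive.

The number of components per block defaults to the sample-ratio policy
k = min(5, ⌊n/3⌋, p): with cohorts of 16–33 samples per group this keeps
the reduced dimension well below n, which both the Wilks approximation and
the permutation null require to be meaningful. A variance-threshold policy
and a fixed k are available.

The penalty is chosen per group by a small grid (default {0, 0.2, 0.4})
maximizing the mean held-out first canonical correlation under k-fold
sample splitting (folds capped at ⌊n/3⌋); the per-penalty grid scores are
written to the run log. Ties prefer the sparser model. A fixed penalty can
be passed instead, which the simulation studies do for determinism and
speed.

## Canonical correlation analysis

Both blocks of component scores are mean-centered and whitened by their
sample covariance; the SVD of the whitened cross-covariance gives the
canonical correlations (clipped to [0, 1]) and weights, with variates
scaled to unit sample variance. A ridge term `ridge × trace(S)/p` on each
covariance diagonal (default 1e-6) guards against near-collinear score
blocks; at ridge 0 the fit is exact CCA and is invariant under invertible
within-block linear maps (tested to 1e-8).

Significance is reported two ways:

- **Permutation test** (primary): one block's sample order is permuted B
  times (default 199) and p = (1 + #{r₁ᵖᵉʳᵐ ≥ r₁}) / (1 + B). The add-one
  convention avoids p = 0; B < 99 is rejected as too coarse. This test is
  distribution-free and is the gate used by the selection stage.
- **Wilks' Λ / Rao F** (secondary): sequential Λ_k = Π_{i≥k}(1 − rᵢ²) with
  the standard degrees of freedom. At p = q = 1 this reduces exactly to
  the two-sided Pearson correlation t-test (tested at 1e-10).

Structure coefficients — Pearson correlations of each transformed feature
with each canonical variate, own-block and cross-block — are the
interpretive output; constant features get coefficient 0 with a warning.

## Backward elimination

The selection stage operationalizes a sensitivity analysis by backward
elimination of the least-contributing features. At each step, candidates
are every remaining feature in either block above that block's floor
(`min_features`, default 5 per block). The default rule removes the
candidate with the smallest |structure coefficient| against its block's
first canonical variate whose removal — after refitting sparse PCA and CCA
without it — keeps the association significant at `alpha`. Elimination
stops when no removal stays significant or both blocks are at their
floors.

The alternative `max_r1` rule (remove the candidate whose removal yields
the highest refit r₁ among significant refits, ties broken by smaller
|structure coefficient| then feature id) is implemented and kept for
sensitivity analysis of the selection itself, but it is not the default:
when a signature is redundant — several features loading on one latent
factor — the marginal r₁ effect of removing any single signature feature
is near zero, so the max-r₁ ordering is dominated by refit jitter and
cannot distinguish signal from noise features. The structure coefficient
measures total, not marginal, contribution and separates the classes
sharply; simulation tests in the suite quantify the recovery difference.

Two engineering notes: (i) the initial and final significance gates use
the permutation test, while the per-candidate scan inside a step uses the
Wilks p — a step scans up to p + q candidates and a permutation gate per
candidate would multiply the cost by B; (ii) blocks are transformed once
per group and candidate removals drop columns of the transformed
matrices. For the CLR this is the standard subcomposition approximation;
sparse PCA and CCA are refit from scratch for every candidate.

Selection need not be monotone in alpha: the greedy path can differ, and
the suite treats observed monotonicity as an empirical property, not an
invariant.

## Association mapping

Retained VOCs (transformed) are correlated with retained taxa (relative
abundances) by Spearman's rank correlation — peak areas are heavy-tailed
and ranks are invariant to the upstream monotone transforms; Pearson is
available. The reporting threshold masks entries with |r| < 0.5 and drops
features with no surviving partner. The threshold is applied to absolute
feature–feature correlations; applying it instead to structure
coefficients against the canonical variates is available behind the same
interface (correlate against the variate columns).

## Community statistics

Bray–Curtis dissimilarity (Σ|x−y| / Σ(x+y)) feeds a non-metric MDS
minimizing Kruskal stress-1 (20 random restarts, 500 iterations,
convergence 1e-6) and a one-way PERMANOVA using Anderson's pseudo-F on
squared distances. PERMANOVA p-values use add-one permutation, except that
designs with at most 10,000 distinct relabelings are enumerated exactly.
On the perfectly separated 3-vs-3 toy the exact p is 2/20 = 0.1: the
complement relabeling induces the same partition and the same (infinite)
F as the observed one, so two of the C(6,3) = 20 relabelings attain the
maximum.

Per-feature group comparisons use the Wilcoxon rank-sum test — exact
enumeration when n ≤ 20 without ties, otherwise the normal approximation
with tie and continuity correction — followed by Benjamini–Hochberg. The
descriptive summary tables report group means ± sd, the pooled mean as
the sample-size-weighted mean of group means, and percentages to one
decimal rounding half away from zero.

## Synthetic cohorts

The generator emulates a two-group breath–stool study: unequal group
sizes (16/33 by default), log-normal VOC peak areas with baselines drawn
so typical areas span ~1e5–2e6, logistic-normal taxon compositions, and a
planted latent pair (u, v) with corr = ρ (default 0.9). u loads on a VOC
signature subset and v on a taxon signature subset (8 and 10 features by
default, disjoint between groups), with loading 2.0 on the natural-log
scale — about a 7-fold intensity change per latent standard deviation,
the strong-biomarker regime consistent with the order-of-magnitude group
differences seen in real peak-area tables. Signals are planted on the log
scale *before* censoring and closure, so the planted correlation survives
the default transforms approximately, not exactly: measurement noise,
censoring and the closure attenuate the recoverable first canonical
correlation below ρ (the acceptance run reports the attained mean).

Below-detection zeros are modeled as left-censoring at each feature's
empirical `zero_prob` quantile (per-feature probabilities drawn from
`zero_prob_range`, default (0, 0.4)): the lowest ⌊n·zero_prob⌋ values of a
feature are set to zero, so prevalence equals 1 − zero_prob while zeros
remain low-intensity cells — which is what a detection limit does.
Purely random (missing-completely-at-random) zeroing was rejected because
it turns censored cells into outliers uncorrelated with the latent
factor, which no analysis can undo; detection limits in GC–MS and
sequencing are intensity-dependent, not random. All-zero stool profiles
are prevented by restoring the sample's dominant taxon.

The generator does **not** emulate: phylogenetic correlation among taxa,
instrument drift or batch effects, ambient-air blank contamination,
longitudinal sampling, or covariate effects (age/sex are carried but
inert). Passing recovery tests therefore demonstrates that the pipeline
recovers planted low-rank cross-block structure under censoring and
compositionality — not that it is robust to those unmodeled artifacts.

A compositional identifiability limit is worth stating: if a large
fraction of the taxa carry the planted signal (e.g. 10 signature taxa in
a 20-taxon composition), CLR centering transfers part of the signal, with
opposite sign, onto the complement taxa, and no selection rule can fully
separate signature from background. Recovery studies therefore use
signature fractions well below half the composition (8/40 VOCs, 10/60
taxa), where the contamination is mild.

## Problem sizes and determinism

Simulation studies in the tests and the acceptance script use: 200
null-cohort replicates (16/33 design, 199 permutations each) for type-I
calibration; 50 replicates at n=150 for correlation recovery; 25
replicates at n=150 with 40 VOCs / 60 taxa for elimination recovery.
These sizes give Monte-Carlo standard errors comfortably inside the
tolerances asserted while keeping the whole suite within a few minutes on
one CPU.

Every stage derives its seed from the master seed and the stage name
(blake2 hash, < 2³¹), so stages re-run independently yet reproducibly and
an identical config yields byte-identical output files; the run manifest
records the config hash, package versions and all stage seeds.

## Known limitations

- The permutation CCA test at n=16 with 5+5 components has little power:
  the null distribution of the largest canonical correlation is
  concentrated near 1 at that dimension/sample ratio. A non-significant
  gate on small groups is expected behavior, and the pipeline then skips
  elimination rather than selecting from a non-significant fit.
- Wilks/Rao p-values treat the sparse-PCA scores as fixed covariates; the
  reduction is within-block only, so the null is preserved, but the
  asymptotic p is secondary to the permutation p throughout.
- The elimination scan's Wilks gate and the transform-once column-drop
  are approximations chosen for tractability; both are exact in the
  penalty-free, CLR-free limit.
- Group-stratified sparse PCA (fit per group, as done here) reflects the
  stratified analysis design; fitting on pooled samples before stratified
  CCA is a reasonable alternative the interface permits but does not
  default to.
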