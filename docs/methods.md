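# Methods

This note documents the models and procedures implemented in `splicerad`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not show.

## Quantification

Isoform counts are normalized to counts per million (CPM; column sums are
exactly 10^6).  Gene-level expression is defined as the sum of a gene's
isoform rows, which keeps it consistent with the PSI denominator by
construction.  PSI is computed on normalized values — the ratio is
invariant to any per-sample rescaling, so PSI inherits library-size
invariance — and is *missing* (NaN), never zero, in samples where the
gene's total abundance is zero.  Unexpressed and skipped are different
states: several downstream steps (pairwise-complete correlations, novelty
calls) depend on the distinction.

**Presence rule.** A feature is "present" in a group when more than
`presence_threshold` (default 1 CPM) is observed in at least
`presence_min_fraction` (default 40%) of the group's samples.  Both knobs
are config-exposed and logged; the rule is deliberately replicate-based so
that sampling zeros at low depth do not register as absence.  Presence is
monotone in the threshold.

**Constitutive isoforms.** One isoform per gene is flagged constitutive:
the annotation's primary isoform when provided, otherwise the isoform with
the highest mean abundance (ties broken toward the lexicographically
smaller id, logged).

**Clade sharing.** Features are classified from clade-level presence over
{NR, LV, LM, LT}: *ancestral* (present in the nonradiating clade and at
least one radiation), *unique:&lt;radiation&gt;*, *shared-radiations*,
*NR-only*, *absent*; percentages are reported over expressed features.

## Divergence profiling

Sample-by-sample Spearman ρ is computed with average ranks; PSI
correlations use pairwise-complete observations because PSI missingness is
structural, and listwise deletion would discard most multi-isoform genes.
The GE-vs-PSI comparison of ρ distributions is a Welch t-test on the
upper-triangle values; since sample pairs share samples, the test is
descriptive, and a label-permutation p-value can be requested alongside.

Hierarchical clustering uses average linkage on 1 − ρ (the linkage is
config-exposed; merge order is deterministic, ties broken by smallest
index pair).  Neighbor joining follows the Saitou–Nei Q-criterion via
scikit-bio; negative branch lengths, which NJ can produce on non-additive
input, are clamped to zero with a warning.  PCA drops zero-variance
features, reports variance explained over the full rank (sums to 1), and
fixes signs so each component's largest-magnitude loading is positive.
Cophenetic correlation between two dendrograms is provided as a
quantitative surrogate for a tanglegram.

## Phylogenetic models of expression evolution

Traits are species means of log2(CPM + 1), per tissue.  Means rather than
replicates are modeled: the phylogenetic models describe among-species
evolution, and the replicate level is deliberately collapsed (a
within-species variance component is out of scope).  The transform and
level are prominent choices, not defaults hidden in code.

Under **BM**, tip traits are multivariate normal with mean `root_mean` and
covariance σ²C, where C_ij is the root-to-MRCA path length.  Under **OU**
two root conventions are implemented:

* *stationary* (default for likelihood evaluation): the root is drawn from
  the stationary law, giving V_ij = σ²/(2α)·exp(−α d_ij) with d the
  patristic distance;
* *fixed*: the root is pinned at the optimum θ, giving
  V_ij = σ²/(2α)·exp(−α d_ij)·(1 − exp(−2α t_ij)) with t the shared time.

The fixed-root family converges to BM exactly as α → 0; the stationary
family does not (its α → 0 limit degenerates through a rank-one
component).  The fitter therefore maximizes over **both** conventions and
over α (log-scale grid on [1e−4, 1e3] per unit tree height, bounded
refinement), and treats the α → 0 limit point as a member of the family.
This makes the likelihood-ratio statistic 2(logL_OU − logL_BM)
nonnegative by construction and honestly so — the bound is attained by an
actual member of the fitted family, not by clamping an ill-fitting model.
Given α, θ and the scale are profiled analytically by GLS (ML denominator
n).  The LRT is referred to χ²(1); with α on the boundary this is
conservative, which is accepted and preferred to mixture corrections.
BH-FDR is applied across features; regime is *stabilizing* at q < 0.05,
*neutral* otherwise, and *unclassified* when the trait is constant, α pins
at the upper search bound, or fewer than four usable tips remain.

**Evolutionary variance** σ̂²/(2α̂) is the stationary spread expression
maintains around its optimum — small values mean tight constraint.  It is
reported only when the OU fit genuinely improves on BM, and distributions
between feature sets (e.g. isoform-level vs gene-level) are compared by
Mann–Whitney U.

**Ancestral states** are ML/GLS reconstructions under BM: the root
estimate is the GLS mean; internal nodes get the conditional expectation
given the tips, with variances conditional on the plugged-in parameters.
Near-singular covariances (zero-length cherries) receive a one-shot
diagonal jitter, logged.

*Power at desk scale.* On the default synthetic dataset (20 tips, 5
replicates, NB counting noise, stationary variances mostly 0.01–0.5), the
LRT correctly controls false positives under BM but classifies only
~20% of the 90% truly-OU genes as stabilizing — with 20 species the test
simply has limited power at realistic effect sizes.  The dedicated
calibration runs (strong OU: ≥ 80% stabilizing; BM: ≤ 10%) demonstrate
that the classifier itself is sound; the dataset-level percentage should
be read as a power statement, not a defect.

## Differential splicing and expression

**Differential PSI** uses a guild-label permutation test on the statistic
|mean PSI(herbivore) − mean PSI(carnivore)| per isoform (multi-isoform
genes only; isoforms need ≥ 2 non-missing values per guild).  All label
splits are enumerated exactly when C(n, n_herb) ≤ 10^4 — at the default
5-vs-5 replication that is 252 splits, and the 2-vs-2 case is verified
against brute-force enumeration in the tests — otherwise the observed
labeling plus ≥ 1000 seeded random permutations is used with the
add-one-p convention.  Gene-level DSG calls take the gene's minimum
isoform p with a Šidák correction for its isoform count, then BH across
genes; the direction comes from the most significant isoform.  This
replaces an external differential-transcript-usage tool with a fully
specified statistic that is exact at small n and testable against
enumeration.

**Differential GE** defaults to a Welch t-test on log2(CPM + 1) per gene
(effect = difference of guild means, a log2 fold change), with an optional
per-gene negative-binomial GLM Wald variant (log link, method-of-moments
dispersion), both labeled in the output.  Genes with zero variance in both
guilds get p = 1 and a flag.  The claims this package makes are about
pipeline structure and synthetic recovery, not about replicating any
specific DE tool's estimator.

Overlaps between gene sets use the one-sided hypergeometric tail;
convergence requires significance (q < 0.05) in at least `min_radiations`
radiations with the same direction.  Species with guild "other"
(nonradiating lineages) never enter guild contrasts.

## Trajectory classification

For each isoform and radiation, mean PSI over all NR samples and all
radiation samples is compared; with the presence calls this maps to one of
six classes (stable-ancestral, ancestral-gain, ancestral-loss, novel-low,
novel-gain, absent) at threshold `psi_delta_threshold` = 0.2 PSI units.
When the isoform is absent in NR its NR mean is taken as 0.
*Ancestral-loss* is an explicit class: highly used ancestral isoforms can
decrease as an alternative rises, and folding that into "stable" would
hide it.  The same presence rule serves both "not expressed" and "low
expressed" — no separate numeric floor is introduced.  The decision table
is total and mutually exclusive (property-tested over a presence × ΔPSI
grid), and raising the threshold can only move isoforms toward the stable
class, never away from it.

**Novel isoforms** are those absent in *every* nonradiating species
individually (species-level presence for NR, so one NR-positive species
disqualifies) and present in at least one radiation.

## Synthetic-data generator

The generator is first-class, tested code; its defaults *are* the study
conditions.  Per gene, species-level log2 expression evolves along a
20-tip ultrametric tree (height 1) with three 6-species radiations whose
stem ages are ordered LT (1.0) > LM (0.8) > LV (0.6) and an NR cherry, 90%
of genes under stationary-root OU (α ∈ [2, 8], σ² ∈ [0.2, 2], θ ∈ [4, 9]
log2 units) and 10% under BM.  Tissue effects (sd 1.5 log2 units, applied
to one tissue) dominate GE; clade effects (sd 0.5) are secondary —
yielding the tissue-first GE clustering.  Isoform proportions come from a
per-gene Dirichlet base (concentration 1.5 over 1–5 isoforms) perturbed on
the logit scale per clade (sd 1.0) and species (sd 0.25) — yielding
clade-first PSI clustering with no tissue dependence.  Guild effects are
planted as a logit shift sized to move the focal isoform's PSI by exactly
ΔPSI = 0.3 (differential splicing, 10% of multi-isoform genes) or a ±1
log2 offset per guild (differential expression, 10% of genes, a fifth of
them in all three radiations with a shared direction to exercise
convergence detection).  "Novel" isoforms are structural zeros outside
their radiation — not sampling zeros — with usage floored at 0.15 in their
home radiation, because the ancestry classifier must be able to
distinguish the two kinds of zero and the generator controls which occurs.
Counts are negative binomial (dispersion 0.05, Poisson in the
dispersion → 0 limit) around depth-scaled means (3×10^5 per sample),
split multinomially across isoforms, so isoform counts of a gene sum to
the gene count exactly.  Same seed and config give byte-identical output.

What the generator does *not* emulate: mapping/assembly artifacts, shared
3' ends and length biases, correlated expression across genes,
hybridization/introgression, within-species polymorphism, unequal
replicate numbers.  Passing the synthetic benchmarks therefore shows the
pipeline's statistics are correct and calibrated under the stated
generative model, not that any particular biological dataset will behave
as cleanly.

Free parameters the source design leaves open (effect-size distributions
of real DSGs/DEGs, the expression cutoff behind "expressed", the exact
herbivore/carnivore species assignments) are set once to field-plausible
values, documented here, and exposed in the config — they are choices, not
estimates.

## Numerical choices

* Likelihood evaluation by Cholesky; one-shot 1e−10-scale diagonal jitter
  on singular covariances, logged.
* Quadratic forms floored at 1e−300 before logs; profile scales use the ML
  (n) denominator.
* BH q-values computed by a direct step-up with enforced monotonicity and
  cross-checked against an independent implementation in the tests.
* Exact permutation p-values use a ≥ obs − 1e−12 comparison to make ties
  deterministic; random permutations use the add-one convention.
* Spearman matrices with no missing data take a rank-once fast path;
  missing data fall back to per-pair common-mask ranking.
* PSI values within 1e−9 of the simplex are accepted as conserved; larger
  deviations fail validation.

## Known limitations

* Single-optimum OU only; no branch-painted multi-optima models and no
  within-species variance component.
* The ρ-distribution t-test ignores dependence between sample pairs (by
  design, as a descriptive summary; the permutation option is provided).
* Gene-level DSG aggregation by Šidák/min-p is conservative when a gene's
  isoform p-values are strongly dependent (they are, since PSI sums to 1).
* The NB-GLM DE variant uses a crude per-gene moment dispersion; it is an
  option for robustness checks, not a shrinkage estimator.
* Regime classification at 20 species has limited power at small
  stationary variances (see above).
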