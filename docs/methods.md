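# Methods

This note documents the statistical procedures implemented in `danseq`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## Study design being modelled

The target design is a small purified-cell case/control RNA-seq cohort:
three mutation-carrier and three control donor-derived lines, one library
each, with donor sex and age as known covariates. Everything downstream —
the loose nominal-p signature, the convergence tests, the drug matching —
exists because at n = 3 + 3 single-gene inference is weak, and the
scientific signal lives in the joint behaviour of the gene set.

## Count simulation

`synthetic.simulate_counts` draws per-gene counts from a negative binomial
with variance μ + φμ². The (μ, φ) pairs are resampled **jointly** with
replacement from a fitted parameter table (a nonparametric bootstrap of
the empirical mean-dispersion law — never marginal resampling, which would
destroy it), after discarding the top `drop_extreme_dispersion = 0.1`
fraction of φ. Truly differential genes (fraction `p_diff`, default 0.1)
have their case-group mean multiplied or divided by `fold_diff = 3`,
split 50/50 by direction. With probability `p_outlier = 0.01` a gene gets
a single-count outlier: one randomly chosen sample's count multiplied by
a Uniform[2, 10] factor. The fold change, outlier rate, outlier mechanism
(single count) and dispersion-trimming fraction are the study conditions;
`p_diff` is a package default (0.1) chosen to give a signature of
realistic size (~100–200 genes at nominal p < 0.01 out of 2000).

The built-in template (`default_nb_params`, 500 genes, fixed seed) is
synthetic: log-normal means (median ≈ 60 counts, σ = 1.4) and dispersions
φ = (0.04 + 1.2/μ^0.7)·LogNormal(0, 0.35), i.e. a biological CV of
roughly 0.2–0.35 at moderate counts rising at low counts — the profile
NB fits on donor-derived cell lines typically show. An earlier draft with
a heavier dispersion tail produced quasi-separated null genes (one group
all zero at mean > 100), a regime real purified-line bulk data do not
occupy and in which Wald statistics are degenerate; the template was
tightened on realism grounds.

`simulate_matched_null` emits null case/control matrices whose per-gene
mean equals the template gene's observed mean. The template only pins the
mean, so φ is drawn conditionally: from the fitted pairs of the ~50 genes
nearest in log-mean (a k-nearest-neighbour conditional bootstrap). Counts
are then NB with no condition effect.

## Differential expression

* **Normalization.** Median-of-ratios size factors over genes positive in
  every sample, rescaled to geometric mean 1; a per-sample fallback (with
  a warning) covers matrices with no all-positive gene.
* **Model.** Per-gene NB GLM, log link, offset log s_j, design intercept +
  condition + sex + standardized age. Age is z-scored because donor ages
  span four decades and the raw scale degrades IRLS conditioning; sex
  enters as a factor. Rank-deficient designs are rejected with the
  collinear columns named. Fitting is IRLS, vectorized across genes
  (stacked 4×4 normal equations), 50 iterations max, tolerance 1e-8.
* **Dispersion.** Moments start on normalized counts, then 1-D
  maximization of the Cox–Reid adjusted profile likelihood
  (loglik − ½·logdet XᵀWX, W = μ/(1+φμ), means held at their fitted
  values) over a coarse-then-fine log grid in [1e-8, 25]. With only two
  residual degrees of freedom the per-gene optimum is noisy and often
  collapses toward zero, which would make the Wald tests anticonservative
  by an order of magnitude. Each gene's estimate is therefore **floored**
  at the 60th percentile of the profile estimates among genes of similar
  mean (20 mean-quantile bins; applied only when ≥ 100 genes are fitted).
  This is a conservative trended floor, not shrinkage: estimates above
  the floor are untouched, so genuinely high dispersions keep their
  value. The floor quantile was calibrated on independent null and power
  simulations: 0.5 left the null rejection rate at nominal 0.01 slightly
  above 0.02, 0.7 halved power for fold-3 genes; 0.6 gives ~0.012–0.016
  null rejection with fold-3 power ≈ 0.34 at μ = 100.
* **Inference.** Wald z = β_c/se from the observed information, two-sided
  normal p, BH step-up over the tested genes (all-zero genes excluded
  from the family). Signature selection is strict `p < 0.01` on raw
  nominal p (or `p_adj < 0.1`), partitioned by the sign of log₂FC.
* **Known behaviour.** p-values on discrete counts at n = 6 are not
  exactly uniform under the null (KS distance ≈ 0.06 against uniform);
  the tail calibration that selection relies on is accurate
  (rejection at p < 0.01 within [0.005, 0.02]). Count-likelihood fits are
  also not exactly invariant to scaling a single column's counts — the
  size factor absorbs the scale, and Wald statistics agree to ~1% — exact
  invariance would require modelling rescaled counts instead of counts.

## Functional convergence

The statistic is Σ w(u,v) over unordered within-set pairs with an edge
(plus the link count). Genes missing from the network stay in the set but
contribute nothing, so "m of k genes formed a cluster" is meaningful.

* **Matched null.** Each target gene is replaced by a random gene from
  the same joint quantile cell of (degree, CDS length, FPKM), 10 bins per
  attribute, drawn without within-set replacement and excluding all
  target genes. Cells with fewer than 20 donors are widened one quantile
  step at a time, loosening the last-listed attribute first so degree —
  the attribute that mechanically drives the statistic — keeps the
  tightest match. Degree is the incident-edge count (unweighted).
* **Empirical p.** Add-one estimator (r+1)/(n+1); it can never be zero,
  and n_null bounds the resolution (999 nulls → minimum p 1e-3). The
  default n_null = 10⁴ in the pipeline config is a runtime compromise;
  claims below ~1e-4 need proportionally more nulls.
* **Direction specificity.** Membership is shuffled between the up and
  down sets (sizes preserved) and each shuffled set re-tested. When the
  two directions occupy distinct network neighbourhoods, shuffling
  dilutes both weight sums well below the intact ones. A shuffled set can
  still beat *matched random* genes — both halves remain truly
  functional — so the informative comparison is against the intact sets'
  statistics, not the shuffled sets' own p-values.
* **Simulation null.** For each matched null count set, the full DE stage
  runs and the k most significant genes (ties broken by p, then |Wald|
  descending, then gene id — deterministic) are scored on the network.
  This asks whether *any* top-k selection from condition-free data of the
  same mean structure clusters as strongly as the observed signature.
* **Network integration** (`build_integrated_network`): each evidence
  source's pair scores are quantile-binned, each bin calibrated against a
  phenotype benchmark as LR = P(share | bin)/P(share); a pair's weight is
  Σ log LR over sources, floored at 0, top-m pairs kept. Bins with fewer
  than 100 benchmark pairs merge downward. This is a deliberately
  simplified stand-in for full multi-source network construction; the
  package's tests treat the network as an input, not a deliverable.

## Phenotype enrichment

The universe is every annotated gene; the signature is intersected with
it before matching. Null sets match on CDS length × FPKM bins only (no
degree — the background here is the annotated genome, not the network).
Per term: observed overlap, expected = mean null overlap, add-one
empirical p, BH q over the tested family only (mirroring an analysis
restricted to pre-chosen phenotype branches). Null replacements are
matched *per signature position*, so direction breakdowns reuse the same
cached null sets restricted to the up/down positions — no re-sampling,
and the up/down observed counts partition the total exactly. An optional
child → parent table propagates annotations up the term hierarchy.

## Drug-signature connectivity

For tag positions V(1)<…<V(t) in a ranked list of n probes,
a = max_j(j/t − V(j)/n), b = max_j(V(j)/n − (j−1)/t), ES = a if a > b
else −b ∈ [−1, 1]. The degenerate whole-list tag set evaluates to −1/n.
An instance's combined score is (ES_up − ES_down)/2 when the two scores
disagree in sign and 0 otherwise. Perturbagen significance: the mean
combined score over its instances versus random signatures of identical
up/down sizes drawn from the mapped-gene universe; two-sided add-one
permutation p (|null| ≥ |observed|), two-sided because both mimicking
and opposing compounds are of interest. Probes without a gene mapping
keep their rank positions but are never sampled. The consistent-gene
rule calls a gene up (down) only if **all** its probes rank ≤ k
(≥ n−k+1) in **all** instances of the perturbagen; k < n/2 makes the
calls disjoint, and the rule is monotone in k.

## Profile comparison

Genes absent or unexpressed (max ≤ threshold, default 0) in any source
are dropped; remaining genes are ranked within each sample (average ranks
on ties); samples are clustered by Ward linkage on Euclidean rank
distances (the squared-distance Lance–Williams update on Euclidean
input). Samples are pre-sorted by label so exact ties resolve
deterministically. Rank distances are exactly invariant to strictly
monotone per-sample transforms — the property that makes array, RPKM and
FPKM samples commensurable. Marker reporting flags each marker gene
against the 50th/75th percentile of the sample's genome-wide
distribution. PCA removes zero-variance genes, centres and scales, and
uses the SVD; variance fractions sum to 1.

## Seeds and determinism

Every stage seed derives from the master seed as
SHA-256(seed ":" stage-name) mod 2³¹, so adding a stage never perturbs
earlier stages' draws, and identical seeds give byte-identical output
bundles.

## Problem sizes

Default analyses and the acceptance script run at 2000 genes, 999 matched
nulls, 100 simulated-transcriptome nulls, 999 connectivity permutations —
sizes chosen so the full chain completes in minutes on one CPU while
every permutation p-value retains enough resolution (≥ 1e-3) for its
claim. All sizes are configurable upward.

## What the synthetic tests do and do not show

The generators reproduce the features the methods *assume*: NB marginals
with an empirical mean-dispersion law, a clean fold-change alternative,
modular network structure aligned with the perturbed genes, uniform rank
columns with block-planted signatures. They do not reproduce library-
preparation artifacts (3′ coverage bias, hexamer priming), correlated
genes within pathways in the *count* matrix, annotation incompleteness,
or probe-level noise structure in real perturbation compendia. Passing
tests therefore establish correctness and calibration of the statistics
under their stated models — not robustness of any one biological
conclusion to those real-data violations.

## Known limitations

* Wald inference at 2 residual df leans on the trended dispersion floor;
  a likelihood-ratio or quasi-likelihood route would be the natural
  extension.
* The matched sampler requires ≥ 20 donors per (possibly widened) cell;
  very small universes degrade match tightness before failing loudly.
* The integration scheme's LR binning assumes a benchmark dense enough
  for ≥ 100 pairs per bin.
* Empirical p-values are bounded below by 1/(n_null+1); headline claims
  of p < 1e-6 would need 10⁶ nulls, which is configuration, not code.
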