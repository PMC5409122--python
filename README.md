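# danseq

Case/control transcriptomics of purified dopaminergic neurons: a tested,
reusable re-implementation of an analysis chain for small iPSC-derived
cohort designs (three mutation-carrier lines vs three controls), where the
question is not "which single genes change?" but "do the changed genes
converge on shared biology, and which drugs move them?"

The pipeline runs five stages over a gene × sample count matrix:

1. **Differential expression** — per-gene negative-binomial GLM with log
   link, `log μ_ij = log s_j + β₀ + β_c·case_j + β_s·sex_j + β_a·age_j`,
   where `s_j` are median-of-ratios size factors and the dispersion φ_g
   (Var = μ + φμ²) is a moments estimate refined by Cox–Reid adjusted
   profile likelihood with a trended floor. Wald test on β_c, BH-adjusted;
   the disease signature is the genes with nominal p < 0.01, split by sign
   of the fold change.
2. **Functional convergence** — the signature's sum of edge weights inside
   a weighted gene functional network, against (a) random gene sets
   matched on network degree, CDS length and expression, and (b) a
   simulated-transcriptome null: count matrices matched to the observed
   per-gene means with no condition effect, pushed through the full DE
   stage, taking the top-k genes each time. Empirical p-values use the
   add-one estimator (r+1)/(n+1).
3. **Phenotype enrichment** — signature overlap with annotation terms
   (mouse knock-out phenotype style) vs CDS-length/FPKM-matched random
   sets from the annotated universe, with a per-direction breakdown.
4. **Drug-signature connectivity** — KS-statistic enrichment scores of the
   signature's up- and down-probes in drug-perturbation rank profiles,
   combined as (ES_up − ES_down)/2 when the signs disagree (positive =
   drug mimics the disease profile, negative = opposes it), with
   permutation p-values; plus the rank rule extracting genes a perturbagen
   moves consistently (all probes in the top/bottom-k of all instances).
5. **Cross-platform profile comparison** — genes ranked within each
   sample, Euclidean distances on ranks, Ward clustering; invariant to any
   monotone per-sample transform, so array, RPKM and FPKM sources are
   comparable.

Because the original raw sequencing data are not needed for any of this to
be testable, `danseq.synthetic` generates every input with the statistical
structure the methods assume: NB counts with jointly resampled (μ, φ)
pairs, a fold-change-3 case/control structure, single-count outliers,
networks with planted modules on the truly perturbed genes, annotation
terms overlapping those modules, and rank matrices with planted
concordant/anti-concordant perturbagens.

## Worked example

The numbered scripts under `analysis/` run the chain end to end on
synthetic data (everything under `results/`):

```sh
python analysis/01_simulate_inputs.py --seed 0
python analysis/02_differential_expression.py
python analysis/03_network_convergence.py --seed 0
python analysis/04_phenotype_enrichment.py --seed 0
python analysis/05_drug_matching.py --seed 0
python analysis/06_profile_clustering.py --seed 0
```

which prints (seed 0):

```
signature at nominal p<0.01: 84 up + 71 down = 155 genes; 147 genes at FDR<0.1
  132/155 selected genes are truly differential (of 200 planted); median |log2FC|
  among well-expressed planted genes: 1.592 (truth 1.585)
all  : 149/155 genes linked, weight sum 4548.7 vs null median 374.1, p = 0.001
up   : 80/84 genes linked, weight sum 2943.7 vs null median 298.4, p = 0.001
down : 63/71 genes linked, weight sum 1575.8 vs null median 176.2, p = 0.001
shuffled_up: weight sum 1326.0 (55% below the intact up set - mixing the
  directions dilutes their separate clusters)
simulated-transcriptome null (top-50 genes, 100 sets): observed 676.0 vs null
  median 10.6, p = 0.009901
TERM:0000: 69 observed vs 4.17 expected (q = 0.006; up/down split 69/0)
mimic: combined score +0.169 (p = 0.001) - mimics the signature
reverser: combined score -0.167 (p = 0.001) - opposes the signature
```

Reading this: the DE stage recovers the planted fold change almost exactly
(1.592 vs log₂3 = 1.585) and the selected signature is dominated by truly
perturbed genes; the signature clusters in the network far beyond both
matched random gene sets and simulated null transcriptomes; the planted
enrichment term and both planted drug signatures are recovered with the
correct direction at the smallest attainable permutation p.

The same stages are importable from Python (`danseq.de.fit_nb_glm_wald`,
`danseq.network.cluster_test`, `danseq.cmap.perturbagen_significance`, …)
and are exposed as a CLI (`danseq simulate | de | cluster-test | enrich |
cmap | compare | run`); `danseq run --config cfg.yaml --out run/` executes
the full chain from a YAML file and writes a result bundle with a
manifest.

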