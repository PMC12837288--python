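# Methods

`germcore` implements the computational core of core-collection
construction for clonally propagated, genetically structured germplasm
panels: genotype-matrix quality control, genetic-diversity indices,
accession distance metrics, seven subset-selection objectives under
stratified and unstratified sampling, and a two-step genetic + phenotypic
evaluation framework.  A synthetic-panel generator with known ground truth
makes every stage testable without external data.

## Genotype model

Genotypes are diploid biallelic SNP dosages g ∈ {0, 1, 2} (count of
alternate alleles), with an explicit missing sentinel.  All per-locus
statistics (alternate-allele frequency p, MAF, missing rate) are computed
over non-missing calls and refreshed after any subsetting.  Coordinates
are 1-based throughout, as in VCF.

### Variant filters

Matrix-level filters mirror standard resequencing practice: drop loci with
missing rate above 10%, minor-allele frequency below 5% (monomorphic loci
always fail any positive MAF threshold), and non-biallelic records.  The
MAF rule keeps loci at exactly the threshold (the PLINK convention).
Depth- and mapping-quality-based site filters require annotations absent
from a plain GT matrix and are assumed applied upstream by the caller.

### LD pruning

Sliding windows of 100 loci advanced by 10, threshold r² = 0.2 (the
`indep-pairwise 100 10 0.2` parameterization).  Within each window,
pairwise squared Pearson correlation of dosages is computed over
pairwise-complete accessions among loci still retained; while any pair
exceeds the threshold, the pair with the highest r² is resolved first and
its lower-MAF member removed (ties: the later locus).  This is a
deterministic approximation of PLINK's behaviour, not a bit-for-bit
reproduction; r² is composite (genotype-vector) LD since phase is
unavailable.

## Diversity indices

With alternate-allele frequency p and q = 1 − p at a biallelic locus:

- observed heterozygosity Ho: fraction of non-missing genotypes with
  dosage 1;
- expected heterozygosity He = 2pq.  No small-sample correction by
  default; `unbiased=True` applies Nei's 2n/(2n−1) factor;
- polymorphism information content PIC = 1 − (p² + q²) − 2p²q²;
- Shannon index I = −(p ln p + q ln q), with 0·ln 0 ≡ 0;
- evenness J′ = I / ln a, a = number of observed alleles.  Monomorphic
  loci (a = 1) have undefined J′ and are excluded from the J′ mean; the
  panel value is the mean of per-locus J′ over polymorphic loci.  Other
  aggregation rules (ratio of means, ln-2 normalization of the mean I)
  exist in the literature; the per-locus-mean rule used here is a
  documented choice.

Panel-level values are unweighted means over loci with defined values.

## Distances

Both metrics operate on within-individual allele fractions and use
pairwise-complete loci L_ij (an error is raised if a pair shares no
genotyped locus):

- Modified Rogers (MR): d(i,j) = sqrt( (1/L_ij) Σ_l ((g_il − g_jl)/2)² ),
  the Euclidean metric on dosage/2 scaled to [0, 1].  It satisfies the
  triangle inequality.
- Cavalli-Sforza & Edwards chord (CE): with per-allele fractions
  x ∈ {0, ½, 1}, d(i,j) = sqrt( (1/(2L_ij)) Σ_l Σ_a (√x_ila − √x_jla)² ).
  The 2L normalization bounds the distance by 1; some implementations use
  L instead (values √2 larger) — the bounded form is used here and
  flagged in the API docs.

## PCA

Genotype PCA mean-imputes missing calls to the locus mean, centers
columns, and takes the SVD; variance-explained fractions are relative to
the full covariance spectrum.  Phenotype PCA standardizes traits to unit
variance and eigen-decomposes the correlation matrix; contribution
percentages are eigenvalues over their sum (the trait count), so they
total 100 exactly, and each component reports its top-3 traits by absolute
loading.  Zero-variance traits are dropped with a warning.

## Selection objectives

Seven objectives over a candidate pool, all driven from the dosage matrix
or a precomputed distance matrix:

- EN-MR / EN-CE (entry-to-nearest-entry, maximized): mean over core
  members of the distance to their closest core neighbour; rewards
  intra-core spread and repels clone pairs (a duplicated accession
  contributes a zero nearest-neighbour term).
- AN-MR / AN-CE (accession-to-nearest-entry, minimized): mean over all
  candidates of the distance to their closest core entry; rewards
  coverage and is monotone non-increasing as the core grows.  Internally
  negated so the optimizer uniformly maximizes.
- HE (maximized): mean over loci of 2pq with p the core allele frequency.
- SH (maximized): Shannon index over all alleles pooled across loci
  (per-locus allele frequencies renormalized to one distribution over 2L
  alleles); rare alleles are weighted heavily, so losing the last copy of
  an allele strictly decreases the value.
- ENMR0.5_SH0.5: equally weighted sum of EN-MR and SH after min-max
  normalization.  Component bounds are estimated from 100 seeded random
  subsets of the target size; a degenerate component (max = min)
  contributes a constant 0.5 with a warning.

## Optimizer

A seeded random-descent over the single-swap neighbourhood (drop one
selected accession, add one unselected).  Proposals are uniform; strict
improvements reset a staleness counter, equal-value (sideways) moves are
accepted but do not reset it, and the best configuration seen is returned.
A run stops after 5,000 consecutive non-improving proposals or 200,000
evaluations; the best of 5 restarts is kept.  All constants are exposed in
`OptimizerConfig`.  Five restarts (rather than a smaller number) were
adopted after observing that tiny HE/SH instances have multiple
swap-neighbourhood local optima; with this budget the search reaches the
exhaustive-enumeration optimum on ≥97% of random instances at n = 8,
k = 3 and can never exceed it.  Frequency-based objectives (HE, SH) use
incremental per-locus dosage-sum updates, making one proposal O(L);
distance objectives recompute on the core submatrix, O(k²) or O(nk).

At a core size of 1 the entry-to-nearest-entry criterion is undefined;
the optimizer then returns the pool medoid (the k = 1 optimum of the AN
objective under the same metric).  This arises legitimately for small
strata at 10% sampling intensity.

## Stratified sampling

Quotas are proportional by largest-remainder apportionment of
intensity × group size over non-excluded groups, with every group
guaranteed at least one slot (an error if the total cannot honour that),
remainder ties resolved in favour of the first-listed group, and the total
equal to intensity × pool size rounded half away from zero.  Hybrid
(admixed) accessions are excluded from stratified runs — they do not form
a population cluster and their small number makes proportional allocation
infeasible — but remain eligible in unstratified runs.  Each stratum is
optimized independently and the union returned; a global optimization
under quota constraints is deliberately not implemented.

The default grid is 2 stratification schemes × 7 objectives × 5
intensities (10–30%), i.e. 70 candidate cores, each with a full
diversity report, run seeds derived hierarchically from one global seed.

## Evaluation framework

Phenotypic representativeness of a core against the full collection
(including the core's members) over n traits:

- MD = 100·St/n, St = traits whose means differ significantly (two-sample
  t-test; Welch by default, pooled-variance optional; α = 0.05);
- VD = 100·SF/n, SF counted from two-sided variance-ratio F-tests;
- CR = 100 · mean over traits of (core range / full range);
- VR = 100 · mean over traits of (core CV / full CV), CV = sd/|mean|.

A core passes when MD < 20% and CR > 80%.  Among passers, higher CR, VD
and VR and lower MD are preferred — VD and VR reward retained variance,
so higher is better by convention even though they are built from
difference counts/ratios.  The two-step framework first ranks all
candidates by genetic diversity (He, then PIC, then I, descending — an
editorial tie-break, since no explicit rule is standard), retains a top
set (default 5), then applies the phenotypic filters and preference
order.  Traits with too few observations, zero variance, zero range or
zero mean are skipped per metric with a warning, reducing n.

Validation of a chosen core compares per-locus index vectors (core vs
full) by unpaired Welch t-tests with two-group significance letters
(shared letter ⇔ p ≥ 0.05), compares trait maxima/minima/means/CVs, and
reports genotype and phenotype PCA summaries for both sets.

## Synthetic panels

The generator emulates a clonal, structured germplasm panel:

- Cluster allele frequencies follow the Balding-Nichols model: ancestral
  frequency p ~ Uniform(ancestral_maf_range), cluster frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so each cluster sits at Fst ≈ F from
  the ancestral pool.  Defaults use K = 3 with asymmetric divergence
  (0.3, 0.3, 0.12): the dominant cluster is the most internally diverse,
  the small clusters tighter — the configuration typical of clonal forest
  germplasm where the widespread lineage carries most variation.  Under
  symmetric divergence the Wahlund effect of balanced cluster pooling
  masks the diversity contrast between stratified and unstratified
  selection; the asymmetric default restores the structure the generator
  is meant to emulate.
- Genotype classes follow the inbreeding parameterization
  P(het) = 2pq(1−f), P(hom) = p² + f·pq (resp. q² + f·pq), which
  preserves allele frequencies exactly for any f.  `het_excess` (default
  −0.3) is the mean founder-level f; `het_excess_sd` (default 0.3) spreads
  founder coefficients, mixing strongly heterozygous clonal lineages with
  more homozygous recruits.  Negative f is clamped per locus to the
  largest magnitude keeping all class probabilities non-negative
  (f_eff = max(f, −p/q, −q/p)); without the clamp any realistic
  frequency distribution would make a global f = −0.3 infeasible at loci
  near fixation.
- Clonal copies duplicate randomly chosen founders within a cluster;
  `clone_fraction` is per-cluster (default 0.1/0.1/0.7 — heavy
  duplication concentrated in the dominant cluster) and each copied locus
  mutates to a different dosage class with probability
  `somatic_mutation_rate` (default 10⁻³).  Clone groups are recorded in
  the truth table.  Hybrids (default 7) draw ancestry weights from a
  symmetric Dirichlet over clusters and genotypes from the mixed
  frequencies; they are never cloned.
- Phenotypes: each of the 15 named traits is
  10 + √h²·z + √(1−h²)·ε with z a standardized random linear combination
  of the top-5 genotype principal components and ε standard normal, so
  genotype structure explains `trait_h2` (default 0.5) of trait variance.
  The offset keeps means away from zero so coefficients of variation are
  defined.

One global seed drives a hierarchical stream (one substream per stage:
frequencies, genotypes, clones, hybrids, phenotypes), so identical
configurations are byte-identical on disk and stages are independently
reproducible.

### What the generator does not model

No linkage or recombination (loci are exchangeable and independent given
cluster frequencies), no coalescent history, no genotyping error beyond
missingness patterns the caller introduces, no geographic coordinates,
and no read-level data.  Passing tests therefore demonstrate correctness
of the selection and evaluation machinery under a clean population-genetic
model, not robustness to LD structure or call-error artifacts of real
resequencing panels.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale panels — typically 120
accessions × 1,000 loci for the full 70-run grid, 200 × 2,000 for
divergence-recovery checks, and n = 8, k = 3 for exhaustive-enumeration
comparisons — sizes at which every result is reproducible in minutes on
one CPU.  Distance matrices are symmetrized and their diagonals zeroed
exactly; objective comparisons use a 10⁻¹² tolerance; stratified quota
assertions are exact integers.  Empirical claims in this document (oracle
agreement rates, direction frequencies) are exactly the quantities the
test suite and `scripts/acceptance.py` recompute.

## Known limitations

- PLINK's exact pruning order is not reproduced; pruned sets can differ
  at boundary r² values.
- The CE distance normalization (2L) is one of two conventions in use.
- J′ aggregation over loci is a documented choice among several.
- The optimizer is a local search: on larger panels it returns
  high-quality but not certified-optimal cores; certified optimality is
  only asserted (and tested) at enumeration scale.
- Significance letters cover the two-group case (core vs full) only.
- MD/VD counts apply no multiple-testing correction across traits, by
  design of the evaluation convention.
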