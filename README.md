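# germcore

Core-collection construction and evaluation for clonal, structured
germplasm panels.

A core collection is a minimal-redundancy subset of a germplasm bank that
retains as much of the bank's genetic and phenotypic diversity as
possible.  Building one for a clonally propagated species is harder than
it sounds: vegetative reproduction fills collections with near-identical
ramets, inflates observed heterozygosity above Hardy-Weinberg expectation
(Ho > He), and concentrates most accessions in one dominant genetic
cluster — so naive sampling keeps clones and drops rare lineages.
`germcore` provides the full computational pipeline for this setting:

- **Genotype QC** — VCF → dosage matrix, missing-rate / MAF / biallelic
  filters, sliding-window LD pruning (`indep-pairwise`-style, r² on
  dosages).
- **Diversity and distance** — observed/expected heterozygosity,
  polymorphism information content, Shannon index I, evenness
  J′ = I/ln a; Modified Rogers (MR) and Cavalli-Sforza–Edwards chord (CE)
  accession distances; genotype and phenotype PCA.
- **Core selection** — seven objectives (entry-to-nearest-entry E-NE and
  accession-to-nearest-entry A-NE under MR or CE, Shannon allelic
  richness SH, expected heterozygosity HE, and an equally weighted
  EN-MR + SH composite), optimized by a seeded swap local search, under
  stratified (proportional per-cluster quotas, largest-remainder
  apportionment) or unstratified sampling at 10–30% intensity — a
  2 × 7 × 5 factorial of 70 candidate cores.
- **Two-step evaluation** — genetic screening (He, PIC, I), then
  phenotypic representativeness over 15 traits: mean-difference
  percentage MD = 100·St/n, variance-difference percentage VD = 100·SF/n,
  coincidence rate of trait ranges CR, and coefficient-of-variation ratio
  VR, with the conventional pass rule MD < 20% and CR > 80%; plus
  core-vs-collection validation (index t-tests with significance letters,
  trait summaries, PCA comparison).
- **Synthetic panels** — a Balding-Nichols generator of structured, clonal,
  phenotyped panels with known truth (cluster labels, ancestry
  proportions, clone groups), used throughout the test suite.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Select a stratified expected-heterozygosity core at 20% intensity
(S-HE20) from a simulated 427-accession panel with one dominant, heavily
clonal cluster, then check its phenotypic representativeness:

```python
from germcore import (SimulationConfig, simulate_panel, select_core,
                      SelectionStrategy, evaluate_core, diversity_report,
                      reduction_pct)

cfg = SimulationConfig(cluster_sizes=(65, 10, 345), seed=1)   # + 7 hybrids
g, phen, truth = simulate_panel(cfg)
groups = truth.table["cluster_label"]

strategy = SelectionStrategy("stratified", "HE", 0.20, seed=1)
core = select_core(g, strategy, groups=groups)      # hybrids excluded
print(f"{strategy.label}: {len(core.selected)} of {g.n_accessions} accessions "
      f"({reduction_pct(g.n_accessions, len(core.selected)):.1f}% reduction)")
print(f"per-group allocation: {core.allocation}")

rep = evaluate_core(core.selected, phen)
print(f"MD {rep.md_pct:.2f}%  VD {rep.vd_pct:.2f}%  CR {rep.cr_pct:.2f}%  "
      f"VR {rep.vr_pct:.2f}%  pass={rep.passes}")
full, sub = diversity_report(g), diversity_report(g, core.selected)
print(f"He {full.he:.4f} -> {sub.he:.4f}   Ho {full.ho:.4f} -> {sub.ho:.4f}")
```

Output:

```
S-HE20: 84 of 427 accessions (80.3% reduction)
per-group allocation: {'G1': 13, 'G2': 2, 'G3': 69}
MD 0.00%  VD 6.67%  CR 80.53%  VR 99.30%  pass=True
He 0.3580 -> 0.3636   Ho 0.4086 -> 0.4176
```

The 84-accession core draws 13, 2 and 69 accessions from the three
clusters in proportion to their sizes.  MD = 0 means no trait mean differs
significantly from the full collection; CR > 80 means the core covers over
80% of every trait's range on average, so the pass rule (MD < 20, CR > 80)
is met.  Expected and observed heterozygosity both rise slightly — the
core sheds clonal redundancy without losing allelic variation.

The full factorial and two-step screening are one call each:

```python
from germcore import run_strategy_grid, two_step_select

cores, table = run_strategy_grid(g, groups, seed=1)   # 70 candidate cores
result = two_step_select(cores, g, phen)              # ranked report + winner
```

A `germcore` console script exposes the same steps
(`simulate`, `filter`, `prune`, `diversity`, `distance`, `pca`, `select`,
`grid`, `evaluate`, `validate`); `germcore --help` lists them.

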