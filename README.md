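# egfr-groups

Structure–function classification of *EGFR* kinase-domain mutations and
drug-selectivity analysis for non-small-cell lung cancer (NSCLC).

## The problem

Most clinical decision-making for *EGFR*-mutant NSCLC groups mutations by
exon (18–21). But mutations within one exon can behave very differently
under tyrosine-kinase inhibitors (TKIs), while mutations in different
exons can share a structural mechanism and a drug-sensitivity profile.
This package implements a structure-based alternative: atypical (i.e.
non-classical) kinase-domain mutations are assigned to four
structure–function groups,

| group | structural rationale | most selective drug class |
|---|---|---|
| **classical-like** | distant from the ATP-binding pocket | 3rd-generation TKIs |
| **T790M-like** (3S / 3R) | hydrophobic-core mutations | 3rd-gen (3S); ALK/PKC inhibitors (3R) |
| **Ex20ins-L** (NL / FL) | insertions in the loop C-terminal to the αC-helix (A767–V774) | Ex20ins-active TKIs |
| **PACC** | P-loop and αC-helix compressing | 2nd-generation (covalent) TKIs |

alongside the *classical* category (L858R, T790M, and exon-19 deletions
starting at E746/L747 and ending at ≤A755). T790M-like alleles split into
third-generation-sensitive (3S) and -resistant (3R, carrying a
co-occurring C797X/L718X/L792X lesion); Ex20ins-L splits into near-loop
(anchors 767–770) and far-loop (771–774) insertions.

## What the package does

- **`variants`** — parse protein-level mutation strings (`L858R`,
  `E746_A750del`, `A763insFQEA`, `L747_K754delinsATSPE`, compound
  alleles like `E709K/G719S`), map residues to exons, and annotate the
  structural regions of the kinase domain (P-loop L718–V726, αC-helix,
  its C-terminal loop A767–G779, hinge, hydrophobic core).
- **`classify`** — ordered first-match-wins rules (curated exceptions,
  then positional rules) assigning variants and alleles to groups,
  subgroups, patient-level cohort buckets, with a full rule trace; cohort
  frequency tabulation.
- **`screen`** — DMSO normalisation, variable-slope logistic IC50 fits
  (absolute 50%-inhibition interpolation), mutant/WT selectivity ratios
  log10(IC50_mut / mean IC50_WT), the median-over-replicates selectivity
  matrix, Euclidean-distance hierarchical clustering, and Welch ANOVA
  with Holm–Šidák pairwise comparisons between drug classes or groups.
- **`predictive`** — does the structure grouping predict drug
  selectivity better than the exon grouping? Leave-one-out Spearman
  correlation of each mutation against its group's mean profile
  (paired two-sided t-test across schemes) and CART regression trees
  per drug with rpart-style goodness-of-split variable importance
  (scaled to 100 per tree).
- **`survival`** — Kaplan–Meier estimates and medians, two-sided
  Mantel–Cox log-rank tests with O/E hazard ratios
  (O_A/E_A)/(O_B/E_B), stratified outcome layouts, and Fisher-exact
  overall-response-rate (ORR) contrasts.
- **`simulate`** — synthetic screens (7-concentration triplicate curves
  with lognormal IC50 noise around group×drug-class selectivity
  templates), survival cohorts (exponential event times matched to
  target medians, calibrated uniform censoring), and curated mutation
  panels — all with ground truth returned for recovery testing.

## Worked example

```python
import egfr_groups as eg

ga = eg.classify_allele(eg.parse_allele("L858R+T790M+C797S"))
print(ga.label)
print(ga.rule_trace)
```

```
T790M-like-3R
('classical:L858R', 'classical:T790M', 'positional:hydrophobic-core',
 'curated:C797S->PACC', 'allele:T790M-like+resistance-partner->3R')
```

The allele carries T790M, so the composite label is T790M-like; the
co-occurring C797S resistance lesion pushes it into the 3R subgroup
(resistant to third-generation TKIs, candidate for ALK/PKC-inhibitor
repurposing).

Comparing grouping schemes on a synthetic screen (24 mutations across
the four atypical groups, 18 drugs, replicate noise σ = 0.3 log10
units):

```python
panel = eg.generate_mutation_panel(
    {"classical-like": 6, "T790M-like-3S": 6, "Ex20ins-L": 6, "PACC": 6}, seed=1)
screen = eg.generate_screen(panel, eg.default_screen_template(sigma=0.3), seed=1)
matrix = eg.build_selectivity_matrix(screen.replicate_logratios)
names = list(matrix.mutations)
gas = {n: eg.classify_allele(eg.parse_allele(n)) for n in names}
structure = eg.GroupingScheme("structure", {n: gas[n].allele_group for n in names})
exon = eg.GroupingScheme("exon", {n: gas[n].exon_group for n in names})
print(eg.compare_groupings(matrix, structure, exon).summary())
```

```
LOO Spearman rho over 24 mutations (0 dropped as not evaluable)
  structure: mean rho = 0.8861, median = 0.8875
  exon: mean rho = 0.5692, median = 0.6295
  paired two-sided t(23) = 5.5049, p = 1.35e-05
```

Each mutation's per-drug selectivity profile correlates much better
with the mean profile of its structure–function group than with the
mean profile of its exon — the grouping carries real predictive
information about drug response.

## Command line

```bash
egfr-groups classify mutations.txt --out assignments.csv
egfr-groups screen wells.csv --out matrix.csv
egfr-groups compare-groupings matrix.csv assignments.csv --out-prefix report
egfr-groups survival cohort.csv --stratifier tki_generation --out medians.csv
egfr-groups orr responses.csv --out orr.csv
egfr-groups simulate --seed 1 --out-dir sim/
egfr-groups run --seed 1 --out-dir pipeline_out/   # full pipeline
```

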