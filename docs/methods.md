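# Methods

This note documents the models and procedures the package implements,
the parameter choices that matter, what the synthetic-data generators
do and do not emulate, and the numerical conventions.

## Mutation representation and regions

Mutations are protein-level changes in UniProt P00533 coordinates, in
the compact literature notation (`L858R`, `E746_A750del`,
`A763insFQEA`, `L747_K754delinsATSPE`; compound alleles joined by `+`,
`/` or `;`). Five kinds are represented: substitution, deletion,
insertion, duplication and delins. Insertions are anchored to the
residue they follow (1-based, inclusive intervals everywhere); a
duplication is treated as the insertion of the duplicated sequence
after its last residue (`A767_V769dupASV` ≡ `V769insASV`).

The kinase domain spans residues 688–875. Exon boundaries are not part
of the protein annotation itself, so the canonical EGFR transcript
convention is used and kept configurable in `RegionMap`: exon 18 =
688–728, 19 = 729–761, 20 = 762–823, 21 = 824–875. Two structural
intervals are fixed by the hotspot definitions: the P-loop L718–V726
and the αC-helix C-terminal loop A767–G779. The remaining regions are
package defaults, chosen to sit consistently with those two and
configurable because only those two are externally pinned: αC-helix
756–766 (immediately N-terminal of the loop), hinge 792–797,
hydrophobic core {790}. The exon-20 insertion span is A767–V774; its
near-/far-loop split defaults to the D770/N771 boundary (near = anchors
767–770, far = 771–774). That boundary is a documented default rather
than an externally fixed one, and is configurable.

Validation of stated reference residues against the canonical sequence
is off by default (synthetic or toy mutation names need not match
P00533); when enabled it uses a partial table of the residues named in
the TKI-resistance literature, or any user-supplied position→residue
mapping.

## Classification rules

The classifier is an ordered, first-match-wins rule table; every
assignment carries a `rule_trace`, so no label is ever produced
silently, and an unmatched variant is `unclassified`, never silently
classical-like.

Variant-level order:

1. curated whole-name exceptions (`L747_K754delinsATSPE` → T790M-like);
2. the classical definition: L858R, T790M, or an exon-19
   deletion/delins starting at E746/L747 and ending at ≤A755
   (deletions that include insertions count);
3. curated residue patterns for PACC: any substitution at E709, L718,
   G719, L747 (non-classical), L792; and the named substitutions
   V765L, S768I, G796S, C797S, T854I;
4. positional rules: hydrophobic-core substitutions → T790M-like;
   insertions anchored in the αC-helix → classical-like; insertions
   anchored in A767–V774 → Ex20ins-L (NL/FL by anchor); point
   mutations in the P-loop, hinge, or αC C-terminal loop → PACC;
   any other kinase-domain change → classical-like by the
   distant-from-pocket rule (flagged `positional:` in the trace);
   changes outside 688–875 → unclassified.

C797S *without* T790M is PACC (it compresses the pocket and remains
second-generation sensitive); L792X alone is likewise PACC. With T790M
present, the allele-level rule resolves both to T790M-like-3R.

Allele-level precedence is resistance-first: a fully classical allele
is classical (T790M may co-occur); otherwise any T790M (or curated
T790M-like variant) makes the allele T790M-like — subgroup 3R iff a
C797X/L718X/L792X partner co-occurs, else 3S; then Ex20ins-L; then
PACC; then classical-like. The rationale is that resistance-driving
lesions dominate the drug response of compound alleles. Composite
alleles keep their per-variant labels so analyses can re-group by
"PACC-containing" (e.g. classical + acquired PACC).

One label is deliberately positional rather than curated: L861Q is
classical-like via the distant-from-pocket rule; its trace marks it as
positional so downstream users can audit it.

Patient-level buckets: classical (classical variants only, ± T790M);
Ex20ins (single loop-insertion allele); atypical (single non-classical
variant); classical+T790M+atypical; complex-with-atypical (any other
multi-variant allele with an atypical component).

## Screen analysis

Raw bioluminescence is normalised to the mean DMSO control per curve.
A variable-slope (4-parameter) logistic is fitted by least squares in
log10-dose space, with asymptote bounds bottom ∈ [0, 0.5] and top ∈
[0.5, 1.2] to stabilise 7-point fits; the hill slope is effectively
free ([0.01, 20]). The IC50 is the *absolute* concentration where the
fitted curve crosses 0.5 of the DMSO level (not the curve's own
midpoint); if the curve never reaches 0.5 inside the tested range the
IC50 is censored at the nearest tested dose and flagged (direction
"high" for resistant curves, "low" for curves already below 50% at the
lowest dose). Censored values are kept at their bound rather than
dropped so the selectivity matrix stays finite for clustering; the
censor mask travels with the matrix.

Selectivity is log10(IC50_mut / mean IC50_WT) per drug; matrix cells
are the median over replicates (even counts: mean of the middle pair;
a cell is flagged censored when the median replicate is). Missing
(mutation, drug) cells are reported, never imputed. The log base is
10 by convention and configurable. Hierarchical clustering uses
Euclidean distance with complete linkage (configurable); scipy's
deterministic merge ordering provides the tie-break.

Group contrasts use Welch's heteroscedastic one-way ANOVA (implemented
from the Welch formula, cross-checked against an independent
implementation in the test suite) followed by pairwise Welch t-tests
with Holm–Šidák adjustment.

## Predictiveness of grouping schemes

For each mutation, the leave-one-out group profile is the per-drug
mean of the median log-ratios over the mutation's category *excluding
the mutation itself*; the mutation's own profile is Spearman-correlated
(average-rank ties) with that profile. Mutations in singleton
categories, or with zero-variance profiles, are not evaluable: they
are dropped from the pairing and listed, never silently ignored. The
per-mutation rho vectors under two schemes are compared with a paired
two-sided t-test; both mean and median rho are reported, since both
summaries are in common use for this comparison.

CART regression trees are fitted per drug by greedy recursive binary
partitioning minimising within-node sum of squares. Categorical
predictors are split by ordering categories by mean response and
scanning prefix splits (optimal for a single SS-minimising split);
the goodness of a split is SS(parent) − SS(left) − SS(right).
Splitting stops below `min_split` observations or when the best
split's goodness falls below `cp × SS(root)`; children must contain at
least `min_bucket` (= `min_split // 3`) observations. Ties go to the
earlier-listed predictor and the lower split value, so fits are
deterministic. Library defaults follow the reference
recursive-partitioning conventions (`min_split` 20, `cp` 0.01); the
pipeline configuration defaults to `min_split` 8 because its screen
panels have ~24 cell lines, and a 20-observation minimum would allow
at most one split. Variable importance is the per-predictor sum of
split goodness rescaled to total 100 per tree; surrogate splits do not
contribute. Predictors are one unordered categorical
structure-group variable plus four 0/1 exon indicators (a variant
spanning an exon boundary may set two).

## Survival and response analysis

Kaplan–Meier estimation uses the product-limit estimator with
simultaneous decrements at ties (via lifelines); the median is the
smallest time with S(t) ≤ 0.5 — the earliest such time when S sits
exactly at 0.5 over an interval — and undefined when S never reaches
0.5. The log-rank test is the two-sided Mantel–Cox form: at each
pooled event time a 2×2 (group × event) table contributes
observed-minus-expected with hypergeometric variance. The hazard ratio
is the O/E form (O_A/E_A)/(O_B/E_B) with CI
exp(log HR ± 1.96·√(1/E_A + 1/E_B)); Cox regression is deliberately
not used, because the retrospective comparisons this mirrors report
log-rank HRs. The numerator arm is stated explicitly in every pairwise
report, since HR direction conventions vary between figures in the
literature. ORR is (CR+PR)/evaluable per group, with NE records
excluded from the denominator and two-sided Fisher exact tests on all
pairwise 2×2 responder tables.

## Synthetic data

The screen generator encodes a ground-truth selectivity template per
(structure group, drug class), qualitatively matching the
structure–function ordering: classical and classical-like most
selective for third-generation TKIs; PACC most selective for
second-generation TKIs; Ex20ins-L selective only for Ex20ins-active
agents (and mildly for second-generation); T790M-like-3S selective for
third-generation; T790M-like-3R selective only for ALK/PKC inhibitors.
The default drug panel has 18 drugs across the six classes
(3/4/3/4/2/2). Each cell's true IC50 is WT_IC50 × 10^(template +
mutation offset), with a per-mutation offset (σ_m = 0.1 log10 units)
shared across drugs and per-replicate lognormal noise (σ = 0.2 by
default; specific analyses use the σ stated with them). Replicate
noise magnitudes in real screens of this kind are not published, so
these defaults are calibration choices of the generator, not estimates.

In raw mode the generator emits per-well signals from an exact unit
logistic (top 1, bottom 0, hill 1) at 7 half-log doses plus DMSO
control wells with multiplicative well noise. The dose grid is centred
per cell line on its noise-free IC50 so the 50% crossing is always
bracketed — this makes noiseless closure through the fitting pipeline
exact and well-defined under the wide (±2 log10) selectivity template;
a fixed per-drug grid, which produces censored curves exactly as real
screens do, is available via `fixed_doses`.

Survival cohorts draw exponential event times with rate ln2/median per
(group, TKI-generation) arm — a single-parameter family matched to a
target median; memorylessness is an accepted simplification (no
Weibull shape by default). Right-censoring is independent uniform
U(0, u), with u solved numerically so the expected censored fraction
equals the requested value (default 20%, a realistic figure for
retrospective time-to-treatment-failure cohorts; the true value for
any given cohort is unknown). Response cohorts are Bernoulli draws at
the requested per-group response rate.

What the generators do *not* emulate: plate/edge effects, drug
synergy, biological-replicate batch structure, clonal evolution or
time-varying hazards, and covariate-driven censoring. Passing recovery
tests therefore demonstrates the correctness and statistical behaviour
of the analysis code under the stated model, not the biological
fidelity of any particular real screen or cohort.

## Problem sizes used in the shipped analyses

The acceptance script and test suite run the comparison at 4 groups ×
6 mutations × 18 drugs with σ = 0.3 over 100 seeds, and the survival
scenario at medians 21.7/10.0/4.1 months (2nd/1st/3rd-generation TKIs
within the PACC group) with 50 patients per arm over 100 seeds —
deliberately compact designs that still give the directional results
high power. Oracle-equivalence checks enumerate all rank permutations
up to length 5 (Spearman), all 2×2 tables with total n ≤ 10–12
(Fisher), and dozens of random small CART instances against exhaustive
split search.

## Known limitations

- The curated rule table covers mutations named in the primary
  structure–function literature; the full curated mutation→group
  catalogue behind that work is not public, so rare names fall through
  to positional rules (and say so in their trace).
- Classification is protein-level only: no cDNA/genomic HGVS, no
  non-EGFR genes, no mutations outside exons 18–21.
- Exon-only records ("exon 19 mutation") cannot be structure-classified
  and should be excluded upstream from structure-based analyses while
  remaining usable for exon-based ones.
- The O/E hazard-ratio estimator is mildly conservative for large
  effects compared with a Cox fit; that is a property of the estimator
  family chosen deliberately for comparability.
- Censored IC50s are capped at the tested-range bound, which biases
  extreme selectivity values toward zero; the censor mask lets
  downstream analyses treat them differently if desired.
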