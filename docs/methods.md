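# Methods

This note documents the models, rules and numerical choices implemented in
`promoter_turnover`, in the order the pipeline applies them.

## Coordinates and formats

All coordinates are 0-based half-open everywhere; `from_one_based` is the
single conversion point for 1-based external sources (e.g. VCF positions).
Promoters travel as BED6 (name column = promoter id) with a side-car TSV for
class and gene assignment, so the BED stays standard. Alignment projections
use a 9-column TSV dialect (promoter_id, target_species, source, status,
target coordinates, aligned_fraction) with one row per (promoter, target
species, alignment source); this decouples the classifier from parsing
EPO/MAF or chain alignments, which is out of scope. All readers accept
gzip transparently; all writers emit a dialect-version comment line.

## Expression profiling

Samples are normalized by **median-of-ratios (RLE)**: the size factor of a
sample is the median, over features whose geometric mean across samples is
positive, of value / geometric mean, and values are divided by it. The
median is taken on linear ratios (not log ratios: for even reference-set
sizes the exponentiated median of logs is the geometric mean of the two
middle ratios, not their arithmetic mean). Replicates are then averaged per
replicate group, and groups per tissue type.

Architecture and bias follow the CAGE conventions:

- **tissue-restricted** ⇔ median TPM across tissue types = 0 (tolerance
  1e-9); biased to tissue T when mean TPM in T > 1 (absolute rule, so not
  scale-invariant);
- **broad** otherwise; biased to T when mean TPM in T ≥ 5× the cross-tissue
  median, boundary inclusive ("at least five times"), which makes the call
  scale-invariant. The median includes all tissue types (the focal tissue
  is not excluded).
- a separate **housekeeping** flag marks promoters expressed (> 0) in every
  tissue type.

Tissue categories (testis / immunity / brain / other) are carried on the
sample sheet; a biased category requires a biased tissue of that category.

**TATA scan.** A 6-nt TBP-like position weight matrix is scanned over the
20–30 nt window upstream of the promoter 5' boundary (both DNA strands;
minus-strand promoters are handled by reverse-complementing so "upstream" is
always leftward). A hit requires match P ≤ 1e-3, where the P-value is the
exact probability of an equal-or-better log-likelihood-ratio score under an
i.i.d. background (0.25 each by default, configurable). The exact score
distribution is built by dynamic programming over positions with scores
keyed on 9-decimal rounding; score comparisons use a 1e-6 tolerance, far
below the spacing of distinct PWM scores but above the rounding drift.
CpG-island promoters are those with ≥ 1 bp of island overlap (half-open
adjacency is not overlap).

## Sequence-fate classification

Per target species the two alignment sources combine into one presence
call: `ALIGNED` with aligned_fraction ≥ 0.5 counts as present;
`GAPPED`/`UNMAPPED` (or a lower fraction, or a missing source row) as
absent; `MULTI` dominates as multi-mapping; a present/absent disagreement is
`CONFLICT`. The 0.5 presence threshold is this package's operational choice
(the combination of the two sources at per-base level is not reproducible
here) and is exposed in `ClassifierConfig`.

Fate resolution consults outgroups only when the opposing projection is
absent — an aligned opposing projection settles the fate by itself, so
outgroup conflicts do not unclassify aligned promoters:

| opposing call    | outgroup evidence                | fate                  |
|------------------|----------------------------------|-----------------------|
| present (unique) | —                                | ALIGNED               |
| multi / conflict | —                                | UNCLASSIFIED          |
| absent           | any conflict                     | UNCLASSIFIED          |
| absent           | all four absent                  | INSERTED (focal)      |
| absent           | ≥ 1 uniquely present             | DELETED_IN_OPPOSING   |
| absent           | only multi-mapping support       | UNCLASSIFIED          |

Expression outcomes at aligned loci use three thresholds, all package
choices exposed in config: activity floor 0 TPM (`NO_ACTIVITY` when the
opposing locus never exceeds it), diminished ratio 0.1 (opposing maximum
below a tenth of the focal maximum), and matched minimum Jaccard 0.5 on
biased-tissue sets (two empty bias sets count as matched). Expression
turnover is reported without a lineage assignment — matched expression data
from an outgroup would be needed to polarize it.

The lineage count table attributes insertions to the focal species' own
outcomes and deletions to the opposing species' outcomes; the deletion-bias
fold is (del_B/ins_B)/(del_A/ins_A) with a χ² test on the 2×2 without
continuity correction (counts in the thousands make Yates' correction
pointless; Fisher's exact test is available for small tables).

## Gene-level compensatory turnover

Per gene, promoters with unclassified fates are ignored. The event count t
sums insertions, deletions, and complete expression turnover
(`NO_ACTIVITY`), but not diminished expression. Each event is witnessed by
exactly one species' promoter (the expressing one), so nothing is double
counted. P_h and P_m count expressed promoters (max TPM > 0 in the matched
panel) per species, and

    T_c = t − |P_h − P_m|,  compensatory ⇔ T_c > 0.

T_c ≥ 0 for any self-consistent configuration because each event moves the
between-species count difference by at most one. Categories: no events →
conserved architecture; only expression events → expression turnover only;
otherwise births vs deaths compared (exceeding, exceeded, balanced). A
promoter assigned to a gene in only one species counts toward t and that
species' P only. The 2×2 enrichment engine (fold of hit proportions, χ²
switching automatically to Fisher when any expected cell < 5, with
Benjamini–Hochberg available across many tests) serves all gene-set
contrasts: tissue bias, positive-selection overlap, paralog status.

## Derived allele frequency tests

Variants are reduced to bi-allelic SNPs at parse time (indels and
multi-allelic records dropped and counted). Polarization: ancestral = ref →
derived is alt at DAF = AF; ancestral = alt → derived is ref at 1 − AF;
unresolved or mismatching ancestral states are discarded with counters.
Bins: rare DAF < 0.015, nonrare DAF > 0.05, both bounds **exclusive**
(values exactly at a bound are ambiguous in the published "<1.5%/>5%"
notation and are excluded); the intermediate band is always excluded. The
test set is flattened before overlap so a variant under two intervals
counts once. The genome-wide reference enters as two fixed counts rather
than a whole-genome VCF scan, keeping runs desk-scale.

The two-sided P-value is Fisher's exact (hypergeometric) test. The odds
ratio is the sample ratio (test rare:nonrare over reference rare:nonrare).
The 95% CI uses the exact conditional method for tables with all cells
≤ 10⁴, the logit-normal (Woolf) approximation above that, and a
Haldane-corrected Woolf interval (one-sided where appropriate) when a cell
is zero; the method used is recorded in the result.

**Threshold calibration.** For a grid of candidate rare bounds, a
constrained set is tested against a neutral proxy set and the chosen bound
maximizes the **lower bound of the odds-ratio CI**. This operationalizes
"maximize the odds ratio while minimizing the confidence interval": a naive
odds-ratio/CI-width score degenerates because the width of an odds-ratio CI
scales with the odds ratio itself (width ≈ OR·2z·se(log OR)), reducing that
score to a pure precision measure that always selects the widest bin. The
CI lower bound rewards both effect size and precision, and recovers a
planted 1.5% rare-excess boundary in simulation. The full table is emitted
so users can apply their own criterion. When constrained and neutral sets
are indistinguishable (all |log OR| < 0.05) the lowest candidate is
returned with a degeneracy flag.

## Permutation nulls, profiles, bootstraps

Permuted intervals preserve their lengths and are placed uniformly over all
valid start positions inside the allowed regions (mappable minus
blacklist): a region is drawn with probability proportional to its number
of valid starts for that length, then a start uniformly within it. Permuted
intervals may overlap each other — rejection-free placement keeps the
sampler unbiased. A per-chromosome mode restricts placement to the source
chromosome; the default is genome-wide, as no G+C or chromosome matching is
modelled.

Window profiles use 50-bp windows over ±1 kb around the promoter 5'
boundary in transcription orientation (flipped for minus strands). The
profile is the mean over anchors of each anchor's within-window mean;
missing bases (off-chromosome or uncovered track) are excluded from means
and a window with no usable base anywhere is reported missing. Repeat
density is operationalized as the repeat base-coverage fraction per window
(the body-coverage fraction for the scalar summary), with per-family
frequencies (fraction of promoters with ≥ 1 bp overlap per family)
reported alongside. Proportions carry percentile bootstrap 95% CIs from
1000 resamples with replacement.

## The synthetic evolution simulator

The simulator emulates the data regime the real analysis consumes, never
nucleotide sequence. An ancestral genome (default one 1-Mb pseudo-
chromosome) carries non-overlapping promoters (60–300 bp, placed outside a
~2% blacklist; a ~5% unmappable mask defines the mappable regions). Two
focal lineages then diverge:

- **insertions**: Poisson(60) novel promoter-containing segments per
  lineage, each 60% repeat-derived (family drawn LTR 0.45 / SINE 0.25 /
  LINE 0.20 / low-complexity 0.10, echoing the LTR dominance among novel
  tissue-restricted promoters);
- **deletions**: Poisson(40) whole-promoter losses in lineage A and
  Poisson(40 × 4) in lineage B — the 4× multiplier reflects the rodent
  deletion excess implied by the published lineage counts
  (11249/2790 vs 2818/2472 ≈ 3.5-fold);
- **expression turnover** on sequence-conserved promoters: complete loss in
  one lineage with probability 0.10 and strong diminution (×0.02) with
  probability 0.05, lineage chosen at random.

Whole segments are inserted/deleted so truth labels stay unambiguous;
partial overlaps are not modelled. Both lineages share the ancestral
coordinate frame, so conserved promoters project onto themselves —
adequate because only statuses, not alignments, are consumed downstream.

Outgroup retention of ancestral sequence is drawn independently per
outgroup at loss probability 0.3; for deleted promoters the draws are
conditioned on at least one outgroup retaining the sequence, since an
ancestral segment invisible in every outgroup is generatively
indistinguishable from an insertion and would make the truth label
unverifiable. Source-disagreement (CONFLICT) noise is injected on the
opposing-species projection with probability 0.20, emulating the ~19–23%
unclassified fractions of the real data; `noise_free()` switches both
noise channels off for ground-truth recovery checks.

Expression is log-normal: restricted promoters (35%) are active in 1–3
tissue types (median across the 52-tissue panel is then zero); broad
promoters draw per-tissue means around 5 TPM with occasional 8× biased
tissues; replicate noise is i.i.d. log-normal with σ = 0.25. The 52 matched
tissue types split into 1 testis, 8 immunity, 10 brain and 33 other.
Conserved promoter pairs share their architecture across species, so a
noise-free classifier sees matched bias sets.

The conservation track mimics GERP semantics without computing GERP:
i.i.d. Normal(0, 0.5) background in 25-bp tiles, +2 over constrained
(conserved) promoter bases, +0.5 over expression-lost loci (reduced but
residual constraint). Allele frequencies come from a discrete
site-frequency spectrum on 5272 chromosomes (the 2 × 2636 cohort scale):
neutral weight 1/k; purifying multiplies weights below 1.5% frequency by
10 (a rare-derived-allele excess concentrated under the rare bound);
positive multiplies weights above 5% by 5. The genome-wide reference counts
are the analytic expectations of the neutral spectrum scaled to 10⁶ sites.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: nucleotide-level alignment artifacts, correlated
outgroup losses along the phylogeny, per-lineage event timing (each lineage
is one branch with aggregate rates), expression correlation structure
between tissues, linkage between variants, and genome-scale input sizes.
It validates the machinery, not the biology of any particular genome.

## Problem sizes and determinism

Everything is driven by `numpy.random.default_rng` from explicit seeds; a
fixed seed makes simulator output byte-identical and pipeline reports
checksum-identical. Default verification sizes — 500 ancestral promoters
for recovery checks, 50 000 sites × 100 replicates for DAF calibration,
10⁴ random gene configurations for the compensatory-statistic property,
200-permutation nulls over 50 seeded runs — were chosen as the smallest
sizes at which the stochastic criteria are statistically comfortable, and
run in seconds to a few minutes on one CPU.

## Known limitations

- The presence threshold on aligned_fraction (0.5) and the expression-
  outcome thresholds (0.1 diminished ratio, 0.5 Jaccard, 0 TPM floor) are
  conventions, not fitted values; conclusions sensitive to them should
  sweep the config.
- Expression turnover cannot be assigned to a lineage without outgroup
  expression data; gene categories treat it symmetrically.
- The exact conditional CI and the sample odds ratio come from different
  estimators; for tiny, highly unbalanced tables the reported point
  estimate can sit near a CI edge.
- The pipeline's file-input mode covers classification, gene summaries and
  DAF; enrichment stages need the mask/track bundle that currently only the
  simulator provides.
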