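# promoter-turnover

Tools for studying the evolutionary **birth and death of functional
promoters** between two mammalian lineages. Given promoter (TSS-cluster)
intervals, dual-source whole-genome alignment projections, matched-tissue
CAGE expression, and outgroup genomes, the package resolves each promoter's
fate — inserted in one lineage, deleted in the other, or aligned with
matched / divergent / diminished / lost expression — and quantifies the
downstream consequences: lineage deletion biases, gene-level compensatory
turnover, selective constraint from derived allele frequencies, and repeat /
conservation enrichments against permutation nulls.

It is written for regulatory-genomics researchers who want the full
analysis chain as a tested, seedable library. Because the real inputs
(CAGE promoter atlases, EPO multiple alignments, population variant
archives) are large external resources, the package ships a **synthetic
two-lineage evolution simulator** that emulates every input format with
ground-truth labels, so the whole pipeline is testable end to end at desk
scale.

## The model

**Sequence fate.** A promoter of the focal species is projected into the
opposing species and four outgroups (dog, horse, cow, pig) by two
independent alignment sources (multiple alignment and pairwise). Per
species the two sources combine into one presence call; disagreement is a
`CONFLICT` and leaves the promoter `UNCLASSIFIED`. With an absent opposing
projection:

- absent in **all four outgroups** → `INSERTED` in the focal lineage
  (the sequence never existed ancestrally);
- uniquely aligned in **≥ 1 outgroup** → `DELETED_IN_OPPOSING`
  (the sequence is ancestral and was lost in the other lineage).

**Expression outcome.** An aligned promoter is compared with the promoter
at its projected locus: no activity there → `NO_ACTIVITY` (expression
turnover); maximum expression below one tenth of the focal promoter's →
`DIMINISHED`; otherwise the Jaccard similarity of the two biased-tissue
sets decides `MATCHED` vs `DIVERGENT`. Tissue bias follows the CAGE
conventions: a broadly expressed promoter (median TPM across tissue types
> 0) is biased to a tissue at ≥ 5× its cross-tissue median; a
tissue-restricted promoter (median TPM = 0) is biased where its mean TPM
exceeds 1.

**Compensatory turnover.** Per 1:1 orthologous gene with promoter counts
P_h and P_m and t gain/loss events (insertions, deletions, and complete
expression loss, but not diminution),

    T_c = t − |P_h − P_m|

with T_c > 0 indicating compensatory turnover — gains offset by losses at
the same gene.

**Constraint.** Variants are polarized into derived alleles via an
ancestral-allele annotation and split into rare (DAF < 1.5%) and nonrare
(> 5%) classes; a test interval set's rare:nonrare ratio is compared to the
genome-wide ratio by Fisher's exact test. Odds ratio > 1 means an excess of
rare derived alleles: purifying selection.

**Nulls.** Genome-wide expectations come from permuting interval positions
uniformly within uniquely mappable, non-blacklisted regions (lengths
preserved), and observed proportions carry 1000-resample bootstrap CIs.

## Worked example

```python
from promoter_turnover import deletion_bias_ratio

# lineage-resolved event counts: (human ins, human del, mouse ins, mouse del)
fold, chi2, p = deletion_bias_ratio((2472, 2818, 2790, 11249))
print(f"{fold:.1f}-fold, p={p:.1e}")
```

```
3.5-fold, p=0.0e+00
```

The mouse lineage shows a 3.5-fold excess of promoter deletions relative to
insertions compared with the human lineage (χ² p below double precision) —
promoters in rodents are predominantly lost by deleting the sequence
outright.

The `examples/` directory walks through each capability with a small
simulated dataset; `examples/02_classify_turnover.py` for instance prints

```
human: {'ALIGNED': 172, 'DELETED_IN_OPPOSING': 109, 'INSERTED': 38, 'UNCLASSIFIED': 97}
mouse: {'ALIGNED': 178, 'DELETED_IN_OPPOSING': 20, 'INSERTED': 37, 'UNCLASSIFIED': 59}
mouse deletion bias: 5.60-fold (chi2=28.8, p=7.95e-08)
```

— the classifier seeing only alignment statuses and expression recovers the
simulated 4× mouse deletion asymmetry (single runs scatter around 4 at
these counts).

An end-to-end run (simulate → profiles → classify → genes → DAF →
enrichment → report) is one call, or one shell command:

```bash
ptk run --config run.yaml --outdir out/    # thin CLI over run_pipeline()
```

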