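"""Gene-level promoter turnover: the compensatory statistic and enrichments.

For each 1:1 orthologous gene the promoters of both species are collated
(promoters with unclassified alignments are ignored) and the compensatory
turnover statistic is

    T_c = t - |P_h - P_m|

where t is the number of promoter gain/loss events at the gene (sequence
insertions and deletions, plus complete expression turnover — zero expression
in one species — but not diminished expression), and P_h / P_m are the counts
of expressed promoters in each species. A gene with T_c > 0 shows compensatory
turnover: gains offset by losses, leaving the promoter count more balanced
than the event count alone would suggest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import (
    ALIGNED,
    DELETED_IN_OPPOSING,
    INSERTED,
    NO_ACTIVITY,
    UNCLASSIFIED,
    EvolutionaryOutcome,
)
from .genomic_io import ValidationError

CATEGORIES = (
    "conserved_architecture",
    "births_exceed_deaths",
    "deaths_exceed_births",
    "balanced",
    "expression_turnover_only",
)


@dataclass
class GeneTurnoverSummary:
    gene_id: str
    P_h: int  # expressed promoters, species A ("human"-like)
    P_m: int  # expressed promoters, species B ("mouse"-like)
    t: int    # gain/loss events at this gene
    T_c: int
    category: str
    compensatory: bool


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    fold: float
    odds_ratio: float
    p_value: float
    test_used: str  # chisq | fisher


@dataclass(frozen=True)
class GenePromoter:
    """One classified promoter attached to a gene, as seen from its species."""

    promoter_id: str
    species: str  # "A" (human-like) or "B" (mouse-like)
    sequence_fate: str
    expression_outcome: str | None
    expressed: bool  # max TPM > 0 in the matched panel


def gene_promoter(outcome: EvolutionaryOutcome, species_label: str,
                  expressed: bool) -> GenePromoter:
    return GenePromoter(
        promoter_id=outcome.promoter_id,
        species=species_label,
        sequence_fate=outcome.sequence_fate,
        expression_outcome=outcome.expression_outcome,
        expressed=expressed,
    )


def compute_gene_summary(gene_id: str, promoters: list[GenePromoter]) -> GeneTurnoverSummary:
    """Summarize one gene's promoter complement across the two species.

    Events (t): INSERTED or DELETED_IN_OPPOSING sequence fates, and aligned
    promoters with a NO_ACTIVITY expression outcome. Each event is seen from
    exactly one species' promoter (the expressing one), so no double
    counting arises. Unclassified promoters are excluded entirely.
    """
    classified = [p for p in promoters if p.sequence_fate != UNCLASSIFIED]
    births = sum(1 for p in classified if p.sequence_fate == INSERTED)
    deaths = sum(1 for p in classified if p.sequence_fate == DELETED_IN_OPPOSING)
    expr_events = sum(
        1 for p in classified
        if p.sequence_fate == ALIGNED and p.expression_outcome == NO_ACTIVITY
    )
    t = births + deaths + expr_events
    p_h = sum(1 for p in classified if p.species == "A" and p.expressed)
    p_m = sum(1 for p in classified if p.species == "B" and p.expressed)
    t_c = t - abs(p_h - p_m)
    if t == 0:
        category = "conserved_architecture"
    elif births == 0 and deaths == 0:
        category = "expression_turnover_only"
    elif births > deaths:
        category = "births_exceed_deaths"
    elif deaths > births:
        category = "deaths_exceed_births"
    else:
        category = "balanced"
    return GeneTurnoverSummary(
        gene_id=gene_id, P_h=p_h, P_m=p_m, t=t, T_c=t_c,
        category=category, compensatory=t_c > 0,
    )


def summarize_genes(
    outcomes_a: list[EvolutionaryOutcome],
    outcomes_b: list[EvolutionaryOutcome],
    gene_of_a: dict[str, str | None],
    gene_of_b: dict[str, str | None],
    expressed_a: dict[str, bool],
    expressed_b: dict[str, bool],
    ortholog_genes: set[str] | None = None,
) -> dict[str, GeneTurnoverSummary]:
    """Per-gene summaries over both species' classified promoters.

    ``gene_of_*`` map promoter ids to gene ids (None = unassigned, skipped);
    ``ortholog_genes`` restricts to a 1:1 ortholog set when given.
    """
    buckets: dict[str, list[GenePromoter]] = {}
    for outcomes, gene_of, expressed, label in (
        (outcomes_a, gene_of_a, expressed_a, "A"),
        (outcomes_b, gene_of_b, expressed_b, "B"),
    ):
        for o in outcomes:
            gid = gene_of.get(o.promoter_id)
            if gid is None:
                continue
            if ortholog_genes is not None and gid not in ortholog_genes:
                continue
            buckets.setdefault(gid, []).append(
                gene_promoter(o, label, expressed.get(o.promoter_id, False))
            )
    return {
        gid: compute_gene_summary(gid, promoters)
        for gid, promoters in sorted(buckets.items())
    }


def gene_category_census(
    summaries: dict[str, GeneTurnoverSummary] | list[GeneTurnoverSummary],
) -> dict[str, dict[str, int]]:
    """Counts per category, split by compensatory status.

    Returns {category: {"total": n, "compensatory": k}}; totals over
    categories sum to the number of summarized genes.
    """
    if isinstance(summaries, dict):
        summaries = list(summaries.values())
    census = {cat: {"total": 0, "compensatory": 0} for cat in CATEGORIES}
    for s in summaries:
        census[s.category]["total"] += 1
        if s.compensatory:
            census[s.category]["compensatory"] += 1
    return census


def enrichment_2x2(
    group_a: tuple[int, int],
    group_b: tuple[int, int],
    test: str = "auto",
) -> ContingencyResult:
    """Generic 2x2 enrichment of hit proportions between two groups.

    ``group_a`` and ``group_b`` are (hits, total). fold is the ratio of hit
    proportions; the chi-square test is used unless any expected cell is
    below 5 (or Fisher is requested), in which case Fisher's exact test is
    used and recorded.
    """
    (hits_a, total_a), (hits_b, total_b) = group_a, group_b
    for hits, total in (group_a, group_b):
        if not (0 <= hits <= total):
            raise ValidationError("need totals >= hits >= 0")
    table = np.array(
        [[hits_a, total_a - hits_a], [hits_b, total_b - hits_b]], dtype=float
    )
    if total_a == 0 or total_b == 0:
        raise ValidationError("empty group in 2x2 enrichment")
    prop_a = hits_a / total_a
    prop_b = hits_b / total_b
    fold = float("inf") if prop_b == 0 else prop_a / prop_b
    # sample odds ratio (inf/0 at zero margins)
    if hits_b == 0 or total_a == hits_a:
        odds = float("inf") if hits_a > 0 else float("nan")
    else:
        odds = (hits_a * (total_b - hits_b)) / (hits_b * (total_a - hits_a))
    expected = stats.contingency.expected_freq(table) if table.sum() else table
    use_fisher = test == "fisher" or (test == "auto" and (expected < 5).any())
    if test not in ("auto", "chisq", "fisher"):
        raise ValidationError(f"unknown test {test!r}")
    if use_fisher:
        _, p = stats.fisher_exact(table.astype(int))
        used = "fisher"
    else:
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
        used = "chisq"
    return ContingencyResult(
        table=((hits_a, total_a - hits_a), (hits_b, total_b - hits_b)),
        fold=fold,
        odds_ratio=float(odds),
        p_value=float(p),
        test_used=used,
    )


def ortholog_expression_coverage(n_expressed: int, n_orthologs: int) -> float:
    """Percentage of 1:1 ortholog genes with at least one expressed promoter."""
    if n_orthologs <= 0:
        raise ValidationError("need a positive ortholog count")
    return round(100.0 * n_expressed / n_orthologs, 1)
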