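"""Resolve each promoter's evolutionary fate from dual-source alignment evidence.

A promoter projected into the opposing species may land in aligned sequence or
in gapped/unaligned/unmapped sequence. Absence in the opposing species and in
all four outgroups (dog, horse, cow, pig by default) marks a lineage-specific
insertion; absence in the opposing species with uniquely aligned sequence in
at least one outgroup marks a deletion in the opposing lineage. Disagreement
between the two alignment sources (whole-genome multiple alignment vs pairwise
alignment) leaves the promoter unclassified.

Aligned promoters receive an expression outcome at the projected locus:
no activity, diminished, matched, or divergent tissue-bias patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .expression import ExpressionProfile
from .genomic_io import AlignmentStatus, PromoterRecord, ValidationError

PRESENT_UNIQUE = "PRESENT_UNIQUE"
PRESENT_MULTI = "PRESENT_MULTI"
ABSENT = "ABSENT"
CONFLICT = "CONFLICT"

INSERTED = "INSERTED"
DELETED_IN_OPPOSING = "DELETED_IN_OPPOSING"
ALIGNED = "ALIGNED"
UNCLASSIFIED = "UNCLASSIFIED"

MATCHED = "MATCHED"
DIVERGENT = "DIVERGENT"
DIMINISHED = "DIMINISHED"
NO_ACTIVITY = "NO_ACTIVITY"

SEQUENCE_FATES = (INSERTED, DELETED_IN_OPPOSING, ALIGNED, UNCLASSIFIED)
EXPRESSION_OUTCOMES = (MATCHED, DIVERGENT, DIMINISHED, NO_ACTIVITY)


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds for sequence and expression outcome calls.

    The category names come from the outcome taxonomy (inserted / deleted /
    aligned with matched, divergent, diminished or no activity); the numeric
    cutoffs are this package's operational choices and are all exposed here.
    """

    outgroup_species: tuple[str, ...] = ("dog", "horse", "cow", "pig")
    absence_max_aligned_fraction: float = 0.5
    diminished_ratio: float = 0.1
    matched_min_jaccard: float = 0.5
    activity_floor_tpm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("absence_max_aligned_fraction", "diminished_ratio",
                     "matched_min_jaccard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class EvolutionaryOutcome:
    promoter_id: str
    species: str
    sequence_fate: str
    lineage_of_event: str  # focal | opposing | none
    expression_outcome: str | None = None
    evidence: dict[str, str] = field(default_factory=dict)  # species -> presence call

    def __post_init__(self) -> None:
        if (self.sequence_fate == ALIGNED) != (self.expression_outcome is not None):
            raise ValidationError(
                f"{self.promoter_id}: expression outcome present iff fate is ALIGNED"
            )


# ---------------------------------------------------------------------------
# Presence calls


def presence_call(
    statuses: list[AlignmentStatus], config: ClassifierConfig | None = None
) -> str:
    """Combine the two alignment sources into one presence call for a species.

    Per source: ALIGNED with enough aligned bases -> present; GAPPED/UNMAPPED
    or a low aligned fraction -> absent; MULTI -> multi-mapping. A missing
    source row counts as UNMAPPED. Any multi-mapping source dominates; the two
    sources otherwise must agree, else the call is CONFLICT.
    """
    config = config or ClassifierConfig()
    per_source: dict[str, str] = {"msa": "absent", "pairwise": "absent"}
    for row in statuses:
        if row.status == "MULTI":
            call = "multi"
        elif (
            row.status == "ALIGNED"
            and row.aligned_fraction >= config.absence_max_aligned_fraction
        ):
            call = "present"
        else:
            call = "absent"
        per_source[row.source] = call
    calls = set(per_source.values())
    if "multi" in calls:
        return PRESENT_MULTI
    if calls == {"present"}:
        return PRESENT_UNIQUE
    if calls == {"absent"}:
        return ABSENT
    return CONFLICT


def presence_calls_by_species(
    statuses: list[AlignmentStatus], config: ClassifierConfig | None = None
) -> dict[str, str]:
    """Presence call per target species from a promoter's status rows."""
    by_species: dict[str, list[AlignmentStatus]] = {}
    for row in statuses:
        by_species.setdefault(row.target_species, []).append(row)
    return {sp: presence_call(rows, config) for sp, rows in by_species.items()}


# ---------------------------------------------------------------------------
# Sequence fate


def classify_sequence_fate(
    promoter_id: str,
    species: str,
    opposing_call: str,
    outgroup_calls: dict[str, str],
    config: ClassifierConfig | None = None,
) -> EvolutionaryOutcome:
    """Resolve insertion vs deletion vs aligned from presence calls.

    Outgroup evidence is consulted only when the opposing projection is
    absent: absence everywhere means a lineage-specific insertion, while a
    unique alignment in at least one outgroup means the sequence was present
    ancestrally and was deleted in the opposing lineage.
    """
    config = config or ClassifierConfig()
    missing = [sp for sp in config.outgroup_species if sp not in outgroup_calls]
    if missing:
        raise ValidationError(
            f"{promoter_id}: missing outgroup presence calls for {missing}"
        )
    evidence = {"opposing": opposing_call}
    evidence.update({sp: outgroup_calls[sp] for sp in config.outgroup_species})

    def outcome(fate: str, lineage: str) -> EvolutionaryOutcome:
        return EvolutionaryOutcome(
            promoter_id=promoter_id,
            species=species,
            sequence_fate=fate,
            lineage_of_event=lineage,
            # provisional outcome for aligned fates; refined by the expression step
            expression_outcome=MATCHED if fate == ALIGNED else None,
            evidence=evidence,
        )

    if opposing_call == PRESENT_UNIQUE:
        return outcome(ALIGNED, "none")
    if opposing_call in (CONFLICT, PRESENT_MULTI):
        return outcome(UNCLASSIFIED, "none")
    # opposing ABSENT: resolve with outgroups
    og = [outgroup_calls[sp] for sp in config.outgroup_species]
    if any(c == CONFLICT for c in og):
        return outcome(UNCLASSIFIED, "none")
    if all(c == ABSENT for c in og):
        return outcome(INSERTED, "focal")
    if any(c == PRESENT_UNIQUE for c in og):
        return outcome(DELETED_IN_OPPOSING, "opposing")
    # only multi-mapping support for the ancestral state
    return outcome(UNCLASSIFIED, "none")


# ---------------------------------------------------------------------------
# Expression outcome at aligned loci


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def classify_expression_outcome(
    focal_profile: ExpressionProfile,
    opposing_profile: ExpressionProfile | None,
    config: ClassifierConfig | None = None,
) -> str:
    """Expression outcome of an aligned promoter at its projected locus.

    ``opposing_profile`` of None means the projected locus falls in silent
    sequence (no promoter called there in the opposing species).
    """
    config = config or ClassifierConfig()
    if opposing_profile is None or opposing_profile.max_tpm <= config.activity_floor_tpm:
        return NO_ACTIVITY
    if opposing_profile.max_tpm < config.diminished_ratio * focal_profile.max_tpm:
        return DIMINISHED
    j = jaccard(focal_profile.biased_tissues, opposing_profile.biased_tissues)
    if j >= config.matched_min_jaccard:
        return MATCHED
    return DIVERGENT


# ---------------------------------------------------------------------------
# Whole-species classification


def _promoter_tree(promoters: list[PromoterRecord]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in promoters:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, p.promoter_id
        )
    return trees


def classify_promoters(
    promoters: list[PromoterRecord],
    statuses: list[AlignmentStatus],
    opposing_species: str,
    opposing_promoters: list[PromoterRecord],
    focal_profiles: dict[str, ExpressionProfile],
    opposing_profiles: dict[str, ExpressionProfile],
    config: ClassifierConfig | None = None,
) -> list[EvolutionaryOutcome]:
    """Classify every promoter of one focal species.

    For aligned promoters the projected interval (from the msa source when
    available, else pairwise) is intersected with the opposing species'
    promoters; the best-overlapping promoter's profile supplies the
    expression evidence, absence of any overlap counts as silent sequence.
    """
    config = config or ClassifierConfig()
    status_by_pid: dict[str, list[AlignmentStatus]] = {}
    for row in statuses:
        status_by_pid.setdefault(row.promoter_id, []).append(row)
    opposing_trees = _promoter_tree(opposing_promoters)

    outcomes: list[EvolutionaryOutcome] = []
    for promoter in promoters:
        rows = status_by_pid.get(promoter.promoter_id, [])
        calls = presence_calls_by_species(rows, config)
        opposing_call = calls.get(opposing_species, ABSENT)
        outgroup_calls = {
            sp: calls.get(sp, ABSENT) for sp in config.outgroup_species
        }
        outcome = classify_sequence_fate(
            promoter.promoter_id, promoter.species, opposing_call,
            outgroup_calls, config,
        )
        if outcome.sequence_fate == ALIGNED:
            target = None
            for source in ("msa", "pairwise"):
                for row in rows:
                    if (
                        row.target_species == opposing_species
                        and row.source == source
                        and row.target_interval is not None
                    ):
                        target = row.target_interval
                        break
                if target is not None:
                    break
            opposing_profile = None
            if target is not None:
                tree = opposing_trees.get(target.chrom)
                if tree is not None:
                    hits = tree.overlap(target.start, target.end)
                    if hits:
                        best = max(
                            hits,
                            key=lambda h: (
                                min(h.end, target.end) - max(h.begin, target.start),
                                h.data,
                            ),
                        )
                        opposing_profile = opposing_profiles.get(best.data)
            focal_profile = focal_profiles.get(promoter.promoter_id)
            if focal_profile is None:
                raise ValidationError(
                    f"{promoter.promoter_id}: no expression profile for focal promoter"
                )
            outcome.expression_outcome = classify_expression_outcome(
                focal_profile, opposing_profile, config
            )
        outcomes.append(outcome)
    return outcomes


# ---------------------------------------------------------------------------
# Summaries


def lineage_count_table(
    outcomes_a: list[EvolutionaryOutcome],
    outcomes_b: list[EvolutionaryOutcome],
) -> dict[str, tuple[int, int]]:
    """Per-lineage (insertions, deletions) counts.

    Lineage-A insertions are species-A promoters called INSERTED; lineage-A
    deletions are species-B promoters whose opposing-lineage copy was deleted.
    """
    ins_a = sum(1 for o in outcomes_a if o.sequence_fate == INSERTED)
    ins_b = sum(1 for o in outcomes_b if o.sequence_fate == INSERTED)
    del_a = sum(1 for o in outcomes_b if o.sequence_fate == DELETED_IN_OPPOSING)
    del_b = sum(1 for o in outcomes_a if o.sequence_fate == DELETED_IN_OPPOSING)
    return {"A": (ins_a, del_a), "B": (ins_b, del_b)}


def deletion_bias_ratio(
    table: dict[str, tuple[int, int]] | tuple[int, int, int, int],
) -> tuple[float, float, float]:
    """Fold excess of deletions over insertions in lineage B relative to A.

    Accepts the output of :func:`lineage_count_table` or a flat
    (ins_A, del_A, ins_B, del_B) tuple. Returns (fold, chi2, p) where the
    chi-square test (no continuity correction) is on the 2x2 counts.
    """
    if isinstance(table, dict):
        ins_a, del_a = table["A"]
        ins_b, del_b = table["B"]
    else:
        ins_a, del_a, ins_b, del_b = table
    if ins_a == 0 or ins_b == 0:
        raise ValidationError("deletion bias undefined with zero insertions")
    fold = (del_b / ins_b) / (del_a / ins_a)
    chi2, p, _, _ = stats.chi2_contingency(
        np.array([[ins_a, del_a], [ins_b, del_b]]), correction=False
    )
    return fold, float(chi2), float(p)


def fraction_percent(numerator: int, denominator: int, digits: int = 1) -> float:
    """A count expressed as a percentage of a total (rounded for reporting)."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    return round(100.0 * numerator / denominator, digits)


def tissue_outcome_summary(
    outcomes_a: list[EvolutionaryOutcome],
    profiles_a: dict[str, ExpressionProfile],
    outcomes_b: list[EvolutionaryOutcome],
    profiles_b: dict[str, ExpressionProfile],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-tissue outcome proportions and the cross-species rank correlations.

    For each tissue type and species: the number of promoters biased to it
    and the proportion showing each fate / expression outcome (NaN when no
    promoter is biased to the tissue). Also returns Spearman correlations
    between species of per-tissue biased-promoter counts and of matched
    proportions (NaN when degenerate).
    """
    def per_species(outcomes, profiles, label):
        rows = []
        tissues = sorted({t for p in profiles.values() for t in p.tissue_means})
        outcome_by_pid = {o.promoter_id: o for o in outcomes}
        for tissue in tissues:
            pids = [
                pid for pid, prof in profiles.items()
                if tissue in prof.biased_tissues and pid in outcome_by_pid
            ]
            n = len(pids)
            counts = {k: 0 for k in ("inserted", "deleted", "matched",
                                     "divergent", "diminished", "no_activity",
                                     "unclassified")}
            for pid in pids:
                o = outcome_by_pid[pid]
                if o.sequence_fate == INSERTED:
                    counts["inserted"] += 1
                elif o.sequence_fate == DELETED_IN_OPPOSING:
                    counts["deleted"] += 1
                elif o.sequence_fate == UNCLASSIFIED:
                    counts["unclassified"] += 1
                else:
                    counts[o.expression_outcome.lower()] += 1
            row = {"species": label, "tissue": tissue, "n_biased": n}
            for k, v in counts.items():
                row[f"prop_{k}"] = v / n if n else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    df = pd.concat(
        [per_species(outcomes_a, profiles_a, "A"),
         per_species(outcomes_b, profiles_b, "B")],
        ignore_index=True,
    )
    pivot_n = df.pivot(index="tissue", columns="species", values="n_biased")
    pivot_m = df.pivot(index="tissue", columns="species", values="prop_matched")
    correlations: dict[str, float] = {}
    for name, pivot in (("counts", pivot_n), ("matched_proportion", pivot_m)):
        sub = pivot.dropna()
        if len(sub) < 2 or sub["A"].nunique() < 2 or sub["B"].nunique() < 2:
            correlations[f"spearman_{name}"] = float("nan")
        else:
            rho, _ = stats.spearmanr(sub["A"], sub["B"])
            correlations[f"spearman_{name}"] = float(rho)
    return df, correlations
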