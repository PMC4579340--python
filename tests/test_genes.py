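"""Compensatory turnover statistic, gene census, contingency enrichments."""

from itertools import product
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from promoter_turnover import genes as gn
from promoter_turnover.classify import (
    ALIGNED,
    DELETED_IN_OPPOSING,
    INSERTED,
    MATCHED,
    NO_ACTIVITY,
    UNCLASSIFIED,
)
from promoter_turnover.genomic_io import ValidationError


def _gp(pid, species, fate, expr_outcome=None, expressed=True):
    return gn.GenePromoter(pid, species, fate, expr_outcome, expressed)


def conserved_pair(i):
    return [_gp(f"a{i}", "A", ALIGNED, MATCHED), _gp(f"b{i}", "B", ALIGNED, MATCHED)]


def random_gene_configuration(rng) -> list[gn.GenePromoter]:
    """A self-consistent random gene: conserved pairs plus turnover events."""
    promoters: list[gn.GenePromoter] = []
    for i in range(rng.integers(0, 5)):
        promoters += conserved_pair(i)
    for i in range(rng.integers(0, 4)):  # insertions, either lineage
        sp = "A" if rng.random() < 0.5 else "B"
        promoters.append(_gp(f"ins{i}", sp, INSERTED))
    for i in range(rng.integers(0, 4)):  # deletions: survivor carries the call
        sp = "A" if rng.random() < 0.5 else "B"
        promoters.append(_gp(f"del{i}", sp, DELETED_IN_OPPOSING))
    for i in range(rng.integers(0, 3)):  # complete expression turnover
        sp = "A" if rng.random() < 0.5 else "B"
        promoters.append(_gp(f"lost{i}", sp, ALIGNED, NO_ACTIVITY))
    for i in range(rng.integers(0, 3)):  # ambiguous promoters are ignored
        promoters.append(_gp(f"u{i}", "A", UNCLASSIFIED, expressed=bool(rng.integers(2))))
    return promoters


def test_four_promoter_compensatory_configuration():
    """Two conserved promoters plus one deletion in each lineage: T_c = 2.

    Species A keeps promoters 1, 3, 4 (promoter 2 was deleted from A, so the
    B copy carries that call); species B keeps 1, 3, 2. Both species have
    three expressed promoters, two events occurred, so T_c = 2 - |3 - 3| = 2
    and the gene shows compensatory turnover.
    """
    promoters = (
        conserved_pair(1) + conserved_pair(3)
        + [_gp("a4", "A", DELETED_IN_OPPOSING)]   # deleted in lineage B
        + [_gp("b2", "B", DELETED_IN_OPPOSING)]   # deleted in lineage A
    )
    s = gn.compute_gene_summary("PDE4C-like", promoters)
    assert (s.P_h, s.P_m, s.t, s.T_c) == (3, 3, 2, 2)
    assert s.compensatory
    # both events are deletions (one per lineage), so deaths dominate births
    assert s.category == "deaths_exceed_births"


def test_single_insertion_not_compensatory():
    promoters = conserved_pair(1) + [_gp("ins", "A", INSERTED)]
    s = gn.compute_gene_summary("g", promoters)
    assert (s.P_h, s.P_m, s.t, s.T_c) == (2, 1, 1, 0)
    assert not s.compensatory
    assert s.category == "births_exceed_deaths"


def test_no_events_is_conserved_architecture():
    s = gn.compute_gene_summary("g", conserved_pair(1) + conserved_pair(2))
    assert s.t == 0 and s.T_c == 0
    assert s.category == "conserved_architecture"


def test_expression_turnover_only_category():
    promoters = conserved_pair(1) + [_gp("lost", "A", ALIGNED, NO_ACTIVITY)]
    s = gn.compute_gene_summary("g", promoters)
    assert s.category == "expression_turnover_only"
    assert s.t == 1


def test_unclassified_promoters_excluded():
    promoters = conserved_pair(1) + [_gp("u", "A", UNCLASSIFIED)]
    s = gn.compute_gene_summary("g", promoters)
    assert (s.P_h, s.P_m, s.t) == (1, 1, 0)


@given(seed=st.integers(min_value=0, max_value=10_000))
def test_tc_identity_and_nonnegativity(seed):
    rng = np.random.default_rng(seed)
    s = gn.compute_gene_summary("g", random_gene_configuration(rng))
    assert s.T_c == s.t - abs(s.P_h - s.P_m)
    assert s.T_c >= 0
    assert s.compensatory == (s.T_c > 0)


def test_adding_conserved_pair_changes_only_p_counts(rng):
    base = random_gene_configuration(rng)
    before = gn.compute_gene_summary("g", base)
    after = gn.compute_gene_summary("g", base + conserved_pair(99))
    assert (after.t, after.T_c) == (before.t, before.T_c)
    assert (after.P_h, after.P_m) == (before.P_h + 1, before.P_m + 1)


def test_gene_category_census_partitions(rng):
    summaries = [
        gn.compute_gene_summary(f"g{i}", random_gene_configuration(rng))
        for i in range(50)
    ]
    census = gn.gene_category_census(summaries)
    assert sum(v["total"] for v in census.values()) == 50
    assert all(v["compensatory"] <= v["total"] for v in census.values())
    assert gn.gene_category_census([]) == {
        cat: {"total": 0, "compensatory": 0} for cat in gn.CATEGORIES
    }


# ---------------------------------------------------------------------------
# Contingency enrichments


def test_enrichment_fold_arithmetic():
    result = gn.enrichment_2x2((170, 1000), (100, 1000))
    assert result.fold == pytest.approx(1.7)
    flat = gn.enrichment_2x2((50, 500), (100, 1000))
    assert flat.fold == pytest.approx(1.0)
    assert flat.p_value > 0.9


def test_enrichment_antisymmetry():
    ab = gn.enrichment_2x2((30, 200), (70, 400))
    ba = gn.enrichment_2x2((70, 400), (30, 200))
    assert ab.fold * ba.fold == pytest.approx(1.0)


def fisher_two_sided_oracle(a, b, c, d) -> float:
    """Exhaustive hypergeometric enumeration with exact binomial coefficients."""
    n1, m1, total = a + b, a + c, a + b + c + d
    denom = comb(total, m1)
    pobs = comb(n1, a) * comb(total - n1, m1 - a) / denom
    p = 0.0
    for k in range(max(0, m1 - (total - n1)), min(m1, n1) + 1):
        pk = comb(n1, k) * comb(total - n1, m1 - k) / denom
        if pk <= pobs * (1 + 1e-7):
            p += pk
    return min(1.0, p)


def test_fisher_matches_enumeration_oracle():
    result = gn.enrichment_2x2((3, 13), (9, 21), test="fisher")
    assert result.test_used == "fisher"
    assert abs(result.p_value - fisher_two_sided_oracle(3, 10, 9, 12)) < 1e-12


def test_automatic_fisher_switch_on_small_expectation():
    small = gn.enrichment_2x2((1, 8), (2, 9))
    assert small.test_used == "fisher"
    large = gn.enrichment_2x2((170, 1000), (100, 1000))
    assert large.test_used == "chisq"


def test_enrichment_input_validation():
    with pytest.raises(ValidationError):
        gn.enrichment_2x2((5, 3), (1, 10))
    result = gn.enrichment_2x2((3, 10), (0, 10))
    assert result.fold == float("inf")


def test_ortholog_expression_coverage_from_reported_counts():
    assert gn.ortholog_expression_coverage(13881, 15768) == 88.0


# ---------------------------------------------------------------------------
# Census against truth on the noise-free simulation


def test_census_equals_truth_census(noise_free_dataset, noise_free_outcomes,
                                    noise_free_profiles):
    from promoter_turnover.sim import expected_sequence_fate

    ds = noise_free_dataset
    sp_a, sp_b = ds.config.species
    gene_of = {sp: {p.promoter_id: p.gene_id for p in ds.promoters[sp]}
               for sp in (sp_a, sp_b)}
    expressed = {sp: {pid: prof.max_tpm > 0
                      for pid, prof in noise_free_profiles[sp].items()}
                 for sp in (sp_a, sp_b)}
    observed = gn.summarize_genes(
        noise_free_outcomes[sp_a], noise_free_outcomes[sp_b],
        gene_of[sp_a], gene_of[sp_b], expressed[sp_a], expressed[sp_b],
    )
    # truth-side reconstruction: fates derived from the generative labels
    buckets: dict[str, list[gn.GenePromoter]] = {}
    for sp, label, other in ((sp_a, "A", sp_b), (sp_b, "B", sp_a)):
        for p in ds.promoters[sp]:
            if p.gene_id is None:
                continue
            event = ds.truth[sp][p.promoter_id].event
            fate = expected_sequence_fate(event)
            expr = None
            if fate == ALIGNED:
                expr = (NO_ACTIVITY if event == f"expression_lost_in_{other}"
                        else MATCHED)
            buckets.setdefault(p.gene_id, []).append(
                gn.GenePromoter(p.promoter_id, label, fate, expr, True)
            )
    truth_summaries = {
        gid: gn.compute_gene_summary(gid, promoters)
        for gid, promoters in buckets.items()
    }
    assert gn.gene_category_census(observed) == gn.gene_category_census(truth_summaries)
    for gid, s in observed.items():
        t = truth_summaries[gid]
        assert (s.t, s.T_c, s.P_h, s.P_m) == (t.t, t.T_c, t.P_h, t.P_m)
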