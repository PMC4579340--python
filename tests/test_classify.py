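"""Presence calls, sequence-fate resolution, expression outcomes, summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from promoter_turnover import classify as cl
from promoter_turnover.expression import ExpressionProfile
from promoter_turnover.genomic_io import AlignmentStatus, GenomeInterval, ValidationError
from promoter_turnover.sim import expected_sequence_fate

IV = GenomeInterval("chr1", 100, 200, "+")


def _status(source, status, fraction=0.9):
    interval = IV if status == "ALIGNED" else None
    return AlignmentStatus("p", "mouse", source, status, interval, fraction)


@pytest.mark.parametrize(
    "rows, expected",
    [
        ([_status("msa", "GAPPED", 0.02), _status("pairwise", "UNMAPPED", 0.0)],
         cl.ABSENT),
        ([_status("msa", "ALIGNED", 0.9), _status("pairwise", "GAPPED", 0.1)],
         cl.CONFLICT),
        ([_status("msa", "ALIGNED", 0.9), _status("pairwise", "MULTI", 0.0)],
         cl.PRESENT_MULTI),
        ([_status("msa", "ALIGNED", 0.9), _status("pairwise", "ALIGNED", 0.8)],
         cl.PRESENT_UNIQUE),
        # aligned fraction below the absence threshold counts as absent
        ([_status("msa", "ALIGNED", 0.3), _status("pairwise", "ALIGNED", 0.2)],
         cl.ABSENT),
        # missing source row behaves as unmapped
        ([_status("msa", "ALIGNED", 0.9)], cl.CONFLICT),
        ([_status("msa", "GAPPED", 0.0)], cl.ABSENT),
    ],
)
def test_presence_call_combinations(rows, expected):
    assert cl.presence_call(rows) == expected


@given(fraction=st.floats(min_value=0.0, max_value=1.0),
       threshold_lo=st.floats(min_value=0.0, max_value=1.0),
       threshold_hi=st.floats(min_value=0.0, max_value=1.0))
def test_presence_threshold_monotonicity(fraction, threshold_lo, threshold_hi):
    """Raising the absence threshold never converts an ABSENT call to PRESENT."""
    lo, hi = sorted((threshold_lo, threshold_hi))
    rows = [_status("msa", "ALIGNED", fraction),
            _status("pairwise", "ALIGNED", fraction)]
    call_lo = cl.presence_call(rows, cl.ClassifierConfig(absence_max_aligned_fraction=lo))
    call_hi = cl.presence_call(rows, cl.ClassifierConfig(absence_max_aligned_fraction=hi))
    if call_lo == cl.ABSENT:
        assert call_hi == cl.ABSENT


OG = ("dog", "horse", "cow", "pig")


def _fate(opposing, outgroups):
    calls = dict(zip(OG, outgroups))
    return cl.classify_sequence_fate("p", "human", opposing, calls).sequence_fate


def test_sequence_fate_rules():
    A, P, M, C = cl.ABSENT, cl.PRESENT_UNIQUE, cl.PRESENT_MULTI, cl.CONFLICT
    assert _fate(A, [A, A, A, A]) == cl.INSERTED
    assert _fate(A, [A, P, A, A]) == cl.DELETED_IN_OPPOSING
    assert _fate(P, [A, A, A, A]) == cl.ALIGNED
    assert _fate(C, [P, P, P, P]) == cl.UNCLASSIFIED
    assert _fate(M, [P, P, P, P]) == cl.UNCLASSIFIED
    # deletion supported only by multi-mapping sequence stays unresolved
    assert _fate(A, [M, A, A, A]) == cl.UNCLASSIFIED
    assert _fate(A, [C, A, A, A]) == cl.UNCLASSIFIED


def test_sequence_fate_requires_all_outgroups():
    with pytest.raises(ValidationError):
        cl.classify_sequence_fate("p", "human", cl.ABSENT, {"dog": cl.ABSENT})


def _profile(pid, means, cats=None):
    from promoter_turnover.expression import classify_breadth_and_bias

    return classify_breadth_and_bias(pid, means, cats or {})


def test_expression_outcomes():
    focal = _profile("f", {"a": 100.0, "b": 20.0, "c": 20.0})
    silent = _profile("o", {"a": 0.0, "b": 0.0, "c": 0.0})
    assert cl.classify_expression_outcome(focal, None) == cl.NO_ACTIVITY
    assert cl.classify_expression_outcome(focal, silent) == cl.NO_ACTIVITY
    weak = _profile("o", {"a": 5.0, "b": 1.0, "c": 1.0})
    assert cl.classify_expression_outcome(focal, weak) == cl.DIMINISHED  # 5/100 < 0.1
    same = _profile("o", {"a": 90.0, "b": 18.0, "c": 18.0})
    assert cl.classify_expression_outcome(focal, same) == cl.MATCHED
    other_bias = _profile("o", {"a": 20.0, "b": 100.0, "c": 20.0})
    assert cl.classify_expression_outcome(focal, other_bias) == cl.DIVERGENT


def test_expression_outcome_empty_bias_sets_match():
    flat_a = _profile("f", {"a": 2.0, "b": 2.0, "c": 2.0})
    flat_b = _profile("o", {"a": 2.1, "b": 1.9, "c": 2.0})
    assert cl.classify_expression_outcome(flat_a, flat_b) == cl.MATCHED


def _outcome(pid, species, fate):
    return cl.EvolutionaryOutcome(
        promoter_id=pid, species=species, sequence_fate=fate,
        lineage_of_event="focal" if fate == cl.INSERTED else
        ("opposing" if fate == cl.DELETED_IN_OPPOSING else "none"),
        expression_outcome=cl.MATCHED if fate == cl.ALIGNED else None,
    )


def test_lineage_count_table_and_symmetry():
    a = [_outcome("a1", "human", cl.INSERTED),
         _outcome("a2", "human", cl.DELETED_IN_OPPOSING),
         _outcome("a3", "human", cl.ALIGNED)]
    b = [_outcome("b1", "mouse", cl.INSERTED),
         _outcome("b2", "mouse", cl.DELETED_IN_OPPOSING),
         _outcome("b3", "mouse", cl.DELETED_IN_OPPOSING)]
    table = cl.lineage_count_table(a, b)
    assert table == {"A": (1, 2), "B": (1, 1)}
    swapped = cl.lineage_count_table(b, a)
    assert swapped == {"A": (1, 1), "B": (1, 2)}
    assert cl.lineage_count_table([], []) == {"A": (0, 0), "B": (0, 0)}


def test_deletion_bias_matches_reported_lineage_counts():
    """Human 2472 ins / 2818 del vs mouse 2790 ins / 11249 del -> 3.5-fold."""
    fold, chi2, p = cl.deletion_bias_ratio((2472, 2818, 2790, 11249))
    assert round(fold, 1) == 3.5
    assert p < 2.2e-16


def test_deletion_bias_equal_ratios_and_errors():
    fold, _, _ = cl.deletion_bias_ratio((100, 50, 200, 100))
    assert fold == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        cl.deletion_bias_ratio((0, 5, 10, 5))


def test_chi2_statistic_matches_textbook_formula(rng):
    counts = rng.integers(5, 80, size=4)
    _, chi2, _ = cl.deletion_bias_ratio(tuple(int(c) for c in counts))
    observed = np.array([[counts[0], counts[1]], [counts[2], counts[3]]], dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row * col / observed.sum()
    assert chi2 == pytest.approx(((observed - expected) ** 2 / expected).sum(),
                                 rel=1e-12)


def test_fraction_percent():
    assert cl.fraction_percent(14400, 76445) == 18.8
    with pytest.raises(ValidationError):
        cl.fraction_percent(1, 0)


# ---------------------------------------------------------------------------
# Whole-dataset behaviour on the noise-free simulation


def test_noise_free_recovery_is_exact(noise_free_dataset, noise_free_outcomes):
    ds = noise_free_dataset
    for sp in ds.config.species:
        for outcome in noise_free_outcomes[sp]:
            truth = ds.truth[sp][outcome.promoter_id]
            assert outcome.sequence_fate == expected_sequence_fate(truth.event)


def test_every_promoter_gets_exactly_one_fate(noise_free_dataset, noise_free_outcomes):
    ds = noise_free_dataset
    for sp in ds.config.species:
        assert len(noise_free_outcomes[sp]) == len(ds.promoters[sp])
        for o in noise_free_outcomes[sp]:
            assert o.sequence_fate in cl.SEQUENCE_FATES


def test_expression_turnover_recovered(noise_free_dataset, noise_free_outcomes):
    """Complete loss and strong reduction of activity are recovered at aligned loci."""
    ds = noise_free_dataset
    sp_a, sp_b = ds.config.species
    for sp, other in ((sp_a, sp_b), (sp_b, sp_a)):
        for o in noise_free_outcomes[sp]:
            event = ds.truth[sp][o.promoter_id].event
            if event == f"expression_lost_in_{other}":
                assert o.expression_outcome == cl.NO_ACTIVITY
            elif event == f"diminished_in_{other}":
                assert o.expression_outcome == cl.DIMINISHED


def test_lineage_table_matches_truth_counts(noise_free_dataset, noise_free_outcomes):
    ds = noise_free_dataset
    sp_a, sp_b = ds.config.species
    table = cl.lineage_count_table(noise_free_outcomes[sp_a], noise_free_outcomes[sp_b])
    truth_ins_a = sum(1 for h in ds.truth[sp_a].values()
                      if h.event == f"inserted_in_lineage_{sp_a}")
    truth_del_a = sum(1 for h in ds.truth[sp_b].values()
                      if h.event == f"deleted_from_lineage_{sp_a}")
    assert table["A"] == (truth_ins_a, truth_del_a)


def test_tissue_outcome_summary_correlation(noise_free_dataset, noise_free_profiles,
                                            noise_free_outcomes):
    ds = noise_free_dataset
    sp_a, sp_b = ds.config.species
    df, correlations = cl.tissue_outcome_summary(
        noise_free_outcomes[sp_a], noise_free_profiles[sp_a],
        noise_free_outcomes[sp_b], noise_free_profiles[sp_b],
    )
    assert set(df["species"]) == {"A", "B"}
    # conserved architecture is shared, so biased-promoter counts correlate
    # (positively, though lineage-specific deletions and replicate noise in the
    # bias calls keep the correlation well below 1)
    assert correlations["spearman_counts"] > 0.2
    # tissues with no biased promoter are reported missing, not zero
    empties = df[df["n_biased"] == 0]
    if len(empties):
        assert empties["prop_matched"].isna().all()


def test_tissue_summary_identical_counts_rho_one():
    profiles = {
        f"p{i}": ExpressionProfile(
            promoter_id=f"p{i}",
            tissue_means={"t1": 1.0, "t2": 2.0},
            median_tpm=1.5, max_tpm=float(i + 1), breadth="broad",
            biased_tissues=frozenset(["t1"] if i % 3 else ["t2"]),
            biased_categories=frozenset(["other"]),
        )
        for i in range(6)
    }
    outcomes = [_outcome(f"p{i}", "human", cl.ALIGNED) for i in range(6)]
    _, correlations = cl.tissue_outcome_summary(outcomes, profiles, outcomes, profiles)
    assert correlations["spearman_counts"] == pytest.approx(1.0)
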