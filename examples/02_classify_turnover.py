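"""Classify every promoter's evolutionary fate and measure the deletion bias.

The classifier sees only what a real analysis would see — dual-source
alignment statuses, outgroup projections, and expression at the projected
locus — and resolves each promoter to inserted, deleted-in-the-other-lineage,
aligned (with an expression outcome), or unclassified.
"""

from collections import Counter

from promoter_turnover import (
    ClassifierConfig,
    SimulationConfig,
    build_profiles,
    classify_promoters,
    deletion_bias_ratio,
    lineage_count_table,
    simulate_dataset,
)

config = SimulationConfig(seed=7, n_ancestral_promoters=400,
                          insertion_rate_per_lineage=50.0,
                          deletion_rate_per_lineage=30.0)
dataset = simulate_dataset(config)
profiles = {sp: build_profiles(*dataset.expression[sp]) for sp in config.species}

outcomes = {}
for focal, opposing in (("human", "mouse"), ("mouse", "human")):
    outcomes[focal] = classify_promoters(
        dataset.promoters[focal], dataset.alignment_statuses[focal],
        opposing, dataset.promoters[opposing],
        profiles[focal], profiles[opposing], ClassifierConfig(),
    )
    tally = Counter(o.sequence_fate for o in outcomes[focal])
    print(f"{focal}: {dict(sorted(tally.items()))}")

table = lineage_count_table(outcomes["human"], outcomes["mouse"])
print(f"\nlineage counts (insertions, deletions): {table}")
fold, chi2, p = deletion_bias_ratio(table)
print(f"mouse deletion bias: {fold:.2f}-fold (chi2={chi2:.1f}, p={p:.2e})")
# A fold > 1 means the mouse lineage loses promoters by deletion relatively
# more often than the human lineage — the simulated 4x rate asymmetry seen
# through the full classification chain (one Poisson draw at these counts is
# noisy, so individual runs scatter around 4). Unclassified promoters
# (conflicting alignment sources, ~20% here) are excluded from the counts.
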