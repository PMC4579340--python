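"""Repeat enrichment at inserted promoters and conservation-score profiles.

Newly inserted promoters are expected to be repeat-derived far more often
than conserved ones (retrotransposition as a source of new promoters), and
conserved promoters should sit on elevated per-base conservation scores
relative to a mappability-aware permutation null.
"""

import numpy as np

from promoter_turnover import (
    PermutationConfig,
    ProfileConfig,
    SimulationConfig,
    permute_intervals,
    repeat_enrichment,
    score_profile,
    simulate_dataset,
    subtract_intervals,
)
from promoter_turnover.sim import noise_free

config = noise_free(SimulationConfig(seed=3, n_ancestral_promoters=400,
                                     insertion_rate_per_lineage=60.0))
dataset = simulate_dataset(config)
species = config.species[0]

interval_of = {p.promoter_id: p.interval for p in dataset.promoters[species]}
inserted = [interval_of[pid] for pid, h in dataset.truth[species].items()
            if h.event.startswith("inserted")]
conserved = [interval_of[pid] for pid, h in dataset.truth[species].items()
             if h.event == "ancestral_conserved"]

repeats, families = dataset.repeats[species]
enr = repeat_enrichment(
    inserted, repeats, families, conserved, dataset.chrom_lengths,
    ProfileConfig(flank=500, window=50), n_boot=1000, seed=1,
)
print(f"repeat coverage at inserted promoters: {enr.overall.observed:.3f} "
      f"(bootstrap 95% CI {enr.overall.bootstrap_ci[0]:.3f}-"
      f"{enr.overall.bootstrap_ci[1]:.3f})")
print(f"conserved-promoter background:         {enr.overall.null_mean:.3f}")
print(f"fold enrichment:                       {enr.overall.fold:.2f}")
print("per-family overlap frequency:",
      {f: round(v, 3) for f, v in enr.family_frequency.items()})
# With 60% of insertions repeat-derived over a 20% genomic background the
# fold lands around 3; LTR dominates because it has the largest family weight.

allowed = subtract_intervals(dataset.mappable, dataset.blacklist)
nulls = permute_intervals(conserved, allowed,
                          PermutationConfig(n_permutations=200, seed=2))
profile = score_profile(conserved, dataset.conservation[species],
                        ProfileConfig(flank=1000, window=50), nulls)
centre = slice(18, 22)  # the 100 bp straddling the promoter 5' boundary
print(f"\nconservation score over promoters: "
      f"{np.nanmean(profile['observed'][centre]):.2f}")
print(f"permutation null (mean, 95% band): "
      f"{np.nanmean(profile['null_mean'][centre]):.2f} "
      f"[{np.nanmean(profile['null_lo'][centre]):.2f}, "
      f"{np.nanmean(profile['null_hi'][centre]):.2f}]")
# Conserved promoters sit well above the null band: the simulated track adds
# +2 over constrained promoter bases, mimicking GERP-style constraint.
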