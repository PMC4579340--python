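"""Permutation nulls, oriented window profiles, repeat density, bootstraps."""

import numpy as np
import pytest
from scipy import stats

from promoter_turnover import enrichment as en
from promoter_turnover.genomic_io import GenomeInterval, ValidationError

CHR = "chr1"


def test_subtract_intervals():
    regions = [GenomeInterval(CHR, 0, 100), GenomeInterval(CHR, 200, 300)]
    masks = [GenomeInterval(CHR, 50, 250), GenomeInterval("chr2", 0, 10)]
    out = en.subtract_intervals(regions, masks)
    assert out == [GenomeInterval(CHR, 0, 50), GenomeInterval(CHR, 250, 300)]


def test_permute_start_positions_uniform():
    allowed = [GenomeInterval(CHR, 0, 1000)]
    interval = [GenomeInterval(CHR, 40, 140)]  # 100 bp, 901 valid starts
    config = en.PermutationConfig(n_permutations=10_000, seed=3)
    perms = en.permute_intervals(interval, allowed, config)
    starts = np.array([p[0].start for p in perms])
    assert starts.min() >= 0 and starts.max() <= 900
    edges = np.linspace(0, 901, 11)
    observed, _ = np.histogram(starts, bins=edges)
    expected = np.diff(edges) / 901 * len(starts)
    _, p = stats.chisquare(observed, expected)
    assert p > 0.001


def test_permuted_lengths_preserved_and_inside_allowed(rng):
    allowed = [GenomeInterval(CHR, 100, 5000), GenomeInterval("chr2", 0, 3000)]
    intervals = [
        GenomeInterval(CHR, 200, 200 + int(n), "+")
        for n in rng.integers(50, 400, size=12)
    ]
    perms = en.permute_intervals(
        intervals, allowed, en.PermutationConfig(n_permutations=50, seed=1)
    )
    want = sorted(len(iv) for iv in intervals)
    for placed in perms:
        assert sorted(len(iv) for iv in placed) == want
        for iv in placed:
            assert any(
                iv.chrom == r.chrom and r.start <= iv.start and iv.end <= r.end
                for r in allowed
            )


def test_permutation_respects_blacklist():
    mappable = [GenomeInterval(CHR, 0, 10_000)]
    blacklist = [GenomeInterval(CHR, 4000, 6000)]
    allowed = en.subtract_intervals(mappable, blacklist)
    perms = en.permute_intervals(
        [GenomeInterval(CHR, 0, 500)], allowed,
        en.PermutationConfig(n_permutations=500, seed=2),
    )
    for placed in perms:
        for iv in placed:
            assert iv.end <= 4000 or iv.start >= 6000


def test_permute_per_chromosome_and_oversize_error():
    allowed = [GenomeInterval(CHR, 0, 1000), GenomeInterval("chr2", 0, 1000)]
    intervals = [GenomeInterval("chr2", 0, 200)]
    config = en.PermutationConfig(n_permutations=50, seed=0, per_chromosome=True)
    for placed in en.permute_intervals(intervals, allowed, config):
        assert placed[0].chrom == "chr2"
    with pytest.raises(ValidationError, match="length 2000"):
        en.permute_intervals([GenomeInterval(CHR, 0, 2000)], allowed)


# ---------------------------------------------------------------------------
# Window profiles


def test_constant_track_profile():
    track = {CHR: np.full(10_000, 3.25)}
    anchors = [GenomeInterval(CHR, 4000, 4200, "+"),
               GenomeInterval(CHR, 6000, 6100, "-")]
    cfg = en.ProfileConfig(flank=500, window=50)
    _, profile = en.window_profile(anchors, track, cfg)
    assert np.allclose(profile, 3.25)


def test_minus_strand_profile_is_reversed():
    rng = np.random.default_rng(5)
    track = {CHR: rng.normal(size=10_000)}
    cfg = en.ProfileConfig(flank=400, window=50)
    plus_anchor = GenomeInterval(CHR, 5000, 5100, "+")
    # a minus-strand promoter anchored (5' end) at the same base
    minus_anchor = GenomeInterval(CHR, 4900, 5000, "-")
    _, forward = en.window_profile([plus_anchor], track, cfg)
    _, reverse = en.window_profile([minus_anchor], track, cfg)
    assert np.allclose(forward, reverse[::-1])


def test_profile_matches_bruteforce_oracle():
    rng = np.random.default_rng(9)
    track = {CHR: rng.normal(size=50_000)}
    anchors = [
        GenomeInterval(CHR, int(s), int(s) + 80, "+" if rng.random() < 0.5 else "-")
        for s in rng.integers(2000, 45_000, size=20)
    ]
    cfg = en.ProfileConfig(flank=1000, window=50)
    _, profile = en.window_profile(anchors, track, cfg)
    # independent per-base double loop
    n_win = cfg.n_windows
    expect = np.zeros(n_win)
    for w in range(n_win):
        per_anchor = []
        for iv in anchors:
            anchor = iv.end if iv.strand == "-" else iv.start
            vals = []
            for k in range(cfg.window):
                offset = -cfg.flank + w * cfg.window + k
                pos = anchor + (-offset - 1 if iv.strand == "-" else offset)
                vals.append(track[CHR][pos])
            per_anchor.append(np.mean(vals))
        expect[w] = np.mean(per_anchor)
    assert np.max(np.abs(profile - expect)) < 1e-12


def test_profile_invariant_to_anchor_order(rng):
    track = {CHR: rng.normal(size=20_000)}
    anchors = [GenomeInterval(CHR, int(s), int(s) + 100, "+")
               for s in rng.integers(3000, 15_000, size=10)]
    cfg = en.ProfileConfig(flank=500, window=50)
    _, a = en.window_profile(anchors, track, cfg)
    _, b = en.window_profile(anchors[::-1], track, cfg)
    assert np.allclose(a, b)


def test_score_profile_constant_null():
    track = {CHR: np.full(20_000, 1.5)}
    anchors = [GenomeInterval(CHR, 5000, 5100, "+")]
    nulls = en.permute_intervals(
        anchors, [GenomeInterval(CHR, 2000, 18_000)],
        en.PermutationConfig(n_permutations=20, seed=4),
    )
    out = en.score_profile(anchors, track, en.ProfileConfig(flank=500, window=50),
                           nulls)
    assert np.allclose(out["observed"], 1.5)
    assert np.allclose(out["null_mean"], 1.5)


# ---------------------------------------------------------------------------
# Repeat enrichment


def test_repeat_enrichment_fold_arithmetic():
    """Fully repeat-covered promoters over a 20%-covered background give fold 5."""
    chrom_lengths = {CHR: 100_000}
    # left half: solid repeat; right half: exactly 10 bp of every 50 bp window
    repeats = [GenomeInterval(CHR, 0, 50_000)]
    repeats += [GenomeInterval(CHR, s, s + 10) for s in range(50_000, 100_000, 50)]
    families = ["LTR"] * len(repeats)
    promoters = [GenomeInterval(CHR, 10_000, 10_100, "+"),
                 GenomeInterval(CHR, 20_000, 20_200, "+")]
    background = [GenomeInterval(CHR, 60_000, 60_100, "+"),
                  GenomeInterval(CHR, 80_000, 80_150, "+")]
    result = en.repeat_enrichment(
        promoters, repeats, families, background, chrom_lengths,
        en.ProfileConfig(flank=500, window=50), n_boot=100, seed=0,
    )
    assert np.allclose(result.fold, 5.0)
    assert result.overall.fold == pytest.approx(5.0)
    assert result.family_frequency == {"LTR": 1.0}


def test_repeat_enrichment_no_repeats():
    chrom_lengths = {CHR: 10_000}
    promoters = [GenomeInterval(CHR, 4000, 4100, "+")]
    result = en.repeat_enrichment(
        promoters, [], [], [GenomeInterval(CHR, 6000, 6100, "+")], chrom_lengths,
        en.ProfileConfig(flank=500, window=50), n_boot=50, seed=0,
    )
    assert np.all(result.fold == 0.0)
    assert result.family_frequency == {}
    with pytest.raises(ValidationError):
        en.repeat_enrichment([], [], [], [], chrom_lengths)


def test_simulated_repeat_fold_recovered(noise_free_dataset, noise_free_outcomes):
    """Inserted promoters are repeat-enriched over conserved ones (~3-fold)."""
    ds = noise_free_dataset
    sp = ds.config.species[0]
    iv_of = {p.promoter_id: p.interval for p in ds.promoters[sp]}
    inserted = [iv_of[o.promoter_id] for o in noise_free_outcomes[sp]
                if o.sequence_fate == "INSERTED"]
    conserved = [iv_of[o.promoter_id] for o in noise_free_outcomes[sp]
                 if o.sequence_fate == "ALIGNED"]
    repeats, families = ds.repeats[sp]
    result = en.repeat_enrichment(
        inserted, repeats, families, conserved, ds.chrom_lengths,
        en.ProfileConfig(flank=500, window=50), n_boot=200, seed=1,
    )
    assert 2.0 <= result.overall.fold <= 5.0


# ---------------------------------------------------------------------------
# Bootstrap


def test_bootstrap_degenerate_cases():
    prop, lo, hi = en.bootstrap_proportion([True] * 20, n_boot=200, seed=0)
    assert (prop, lo, hi) == (1.0, 1.0, 1.0)
    prop, lo, hi = en.bootstrap_proportion([True], n_boot=50, seed=0)
    assert (prop, lo, hi) == (1.0, 1.0, 1.0)
    with pytest.raises(ValidationError):
        en.bootstrap_proportion([])


def test_bootstrap_ci_coverage():
    covered = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        flags = rng.random(1000) < 0.3
        _, lo, hi = en.bootstrap_proportion(flags, n_boot=300, seed=seed)
        if lo <= 0.3 <= hi:
            covered += 1
    assert covered >= 90


def test_uniform_features_inside_permutation_band():
    """Features scattered uniformly over allowed regions are not 'enriched'."""
    chrom_lengths = {CHR: 60_000}
    allowed = [GenomeInterval(CHR, 0, 60_000)]
    rng0 = np.random.default_rng(123)
    annotation = [GenomeInterval(CHR, int(s), int(s) + 40)
                  for s in rng0.integers(0, 59_900, size=300)]
    masks = en.coverage_mask(annotation, chrom_lengths)
    inside = 0
    n_runs = 50
    for seed in range(n_runs):
        rng = np.random.default_rng(1000 + seed)
        features = [GenomeInterval(CHR, int(s), int(s) + 100)
                    for s in rng.integers(0, 59_800, size=60)]
        observed = np.mean([
            masks[CHR][iv.start:iv.end].mean() for iv in features
        ])
        perms = en.permute_intervals(
            features, allowed, en.PermutationConfig(n_permutations=200, seed=seed)
        )
        null = np.array([
            np.mean([masks[CHR][iv.start:iv.end].mean() for iv in placed])
            for placed in perms
        ])
        lo, hi = np.percentile(null, [2.5, 97.5])
        if lo <= observed <= hi:
            inside += 1
    assert inside >= int(0.9 * n_runs)
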