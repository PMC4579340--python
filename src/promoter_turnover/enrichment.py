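"""Permutation nulls, bootstrap CIs, and strand-oriented window profiles.

The genome-wide null for interval statistics is built by randomly permuting
interval positions within the allowed regions (uniquely mappable sequence
minus blacklisted regions), preserving interval lengths; placement is uniform
over all valid start positions and permuted intervals may overlap each other.

Window profiles (repeat coverage, conservation-score means) are computed in
fixed-width windows (50 bp by default) around the promoter's 5' boundary in
transcription orientation, flipped for minus-strand promoters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomic_io import GenomeInterval, ValidationError


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 1000
    seed: int = 0
    preserve_length: bool = True
    per_chromosome: bool = False


@dataclass(frozen=True)
class ProfileConfig:
    flank: int = 1000
    window: int = 50
    orient_by_strand: bool = True

    def __post_init__(self) -> None:
        if self.flank % self.window != 0:
            raise ValidationError("flank must be divisible by window")

    @property
    def n_windows(self) -> int:
        return 2 * self.flank // self.window

    def window_offsets(self) -> np.ndarray:
        """Left edge of each window relative to the anchor."""
        return np.arange(-self.flank, self.flank, self.window)


@dataclass
class EnrichmentResult:
    observed: float
    null_mean: float
    null_ci: tuple[float, float]
    fold: float
    bootstrap_ci: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# Interval algebra


def subtract_intervals(
    regions: list[GenomeInterval], masks: list[GenomeInterval]
) -> list[GenomeInterval]:
    """Regions minus masks (e.g. mappable minus blacklist), strand dropped."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in masks:
        by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
    out: list[GenomeInterval] = []
    for region in regions:
        cuts = sorted(by_chrom.get(region.chrom, []))
        cursor = region.start
        for start, end in cuts:
            if end <= cursor or start >= region.end:
                continue
            if start > cursor:
                out.append(GenomeInterval(region.chrom, cursor, start))
            cursor = max(cursor, end)
        if cursor < region.end:
            out.append(GenomeInterval(region.chrom, cursor, region.end))
    return out


# ---------------------------------------------------------------------------
# Permutation null


def permute_intervals(
    intervals: list[GenomeInterval],
    allowed_regions: list[GenomeInterval],
    config: PermutationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[list[GenomeInterval]]:
    """Length-preserving uniform placement of intervals inside allowed regions.

    For each interval, a region is drawn with probability proportional to its
    number of valid start positions for that interval's length, then a start
    uniform within the region; every valid (region, start) pair is therefore
    equally likely. With ``per_chromosome`` intervals stay on their source
    chromosome.
    """
    config = config or PermutationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not allowed_regions:
        raise ValidationError("no allowed regions to permute into")
    lengths = np.array([len(iv) for iv in intervals])
    region_lens = np.array([len(r) for r in allowed_regions])
    region_chroms = np.array([r.chrom for r in allowed_regions])
    region_starts = np.array([r.start for r in allowed_regions])
    for iv in intervals:
        candidates = region_lens - len(iv) + 1
        if config.per_chromosome:
            candidates = np.where(region_chroms == iv.chrom, candidates, 0)
        if (candidates <= 0).all():
            raise ValidationError(
                f"interval of length {len(iv)} ({iv.chrom}:{iv.start}-{iv.end}) "
                "does not fit inside any allowed region"
            )
    permutations: list[list[GenomeInterval]] = []
    for _ in range(config.n_permutations):
        placed: list[GenomeInterval] = []
        for iv, length in zip(intervals, lengths):
            slots = np.maximum(region_lens - length + 1, 0)
            if config.per_chromosome:
                slots = np.where(region_chroms == iv.chrom, slots, 0)
            probs = slots / slots.sum()
            ridx = rng.choice(len(allowed_regions), p=probs)
            start = region_starts[ridx] + rng.integers(0, slots[ridx])
            placed.append(
                GenomeInterval(
                    str(region_chroms[ridx]), int(start), int(start + length),
                    iv.strand,
                )
            )
        permutations.append(placed)
    return permutations


# ---------------------------------------------------------------------------
# Mask / track helpers


def coverage_mask(
    intervals: list[GenomeInterval], chrom_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Boolean per-base coverage arrays for an interval set."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    for iv in intervals:
        if iv.chrom in masks:
            masks[iv.chrom][iv.start:min(iv.end, len(masks[iv.chrom]))] = True
    return masks


def anchor_point(iv: GenomeInterval) -> int:
    """The promoter's 5' boundary in transcription orientation."""
    return iv.end if iv.strand == "-" else iv.start


def _oriented_values(
    iv: GenomeInterval,
    arrays: dict[str, np.ndarray],
    flank: int,
    orient: bool,
) -> np.ndarray:
    """Per-base values over anchor +/- flank, NaN outside the chromosome."""
    arr = arrays.get(iv.chrom)
    anchor = anchor_point(iv)
    out = np.full(2 * flank, np.nan)
    if arr is not None:
        lo, hi = anchor - flank, anchor + flank
        src_lo, src_hi = max(lo, 0), min(hi, len(arr))
        if src_hi > src_lo:
            out[src_lo - lo:src_hi - lo] = arr[src_lo:src_hi]
    if orient and iv.strand == "-":
        out = out[::-1]
    return out


def window_profile(
    anchors: list[GenomeInterval],
    arrays: dict[str, np.ndarray],
    config: ProfileConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window mean of a per-base array around oriented anchors.

    Returns (offsets, means) where the mean is taken over anchors of each
    anchor's within-window mean (windows with no usable base are skipped for
    that anchor; NaN when no anchor contributes at all).
    """
    config = config or ProfileConfig()
    if not anchors:
        raise ValidationError("empty anchor set")
    n_win = config.n_windows
    sums = np.zeros(n_win)
    counts = np.zeros(n_win)
    for iv in anchors:
        values = _oriented_values(iv, arrays, config.flank, config.orient_by_strand)
        per_window = values.reshape(n_win, config.window)
        finite = np.isfinite(per_window)
        n_usable = finite.sum(axis=1)
        sums_w = np.where(finite, per_window, 0.0).sum(axis=1)
        means = np.divide(sums_w, n_usable, out=np.full(n_win, np.nan),
                          where=n_usable > 0)
        usable = np.isfinite(means)
        sums[usable] += means[usable]
        counts[usable] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return config.window_offsets(), profile


def score_profile(
    anchors: list[GenomeInterval],
    track: dict[str, np.ndarray],
    config: ProfileConfig | None = None,
    null_intervals: list[list[GenomeInterval]] | None = None,
) -> dict[str, np.ndarray]:
    """Conservation-score (or any per-base track) profile with optional null.

    ``null_intervals`` — e.g. from :func:`permute_intervals` — yields a
    permutation-null curve: the same profile computed over each permuted set,
    summarized by its mean and 2.5/97.5 percentiles per window.
    """
    config = config or ProfileConfig()
    offsets, observed = window_profile(anchors, track, config)
    out = {"offsets": offsets, "observed": observed}
    if null_intervals:
        null_curves = np.array(
            [window_profile(perm, track, config)[1] for perm in null_intervals]
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out["null_mean"] = np.nanmean(null_curves, axis=0)
            out["null_lo"] = np.nanpercentile(null_curves, 2.5, axis=0)
            out["null_hi"] = np.nanpercentile(null_curves, 97.5, axis=0)
    return out


# ---------------------------------------------------------------------------
# Repeat enrichment


@dataclass
class RepeatEnrichment:
    offsets: np.ndarray
    observed_coverage: np.ndarray      # per-window repeat base coverage fraction
    background_coverage: np.ndarray
    fold: np.ndarray
    overall: EnrichmentResult
    family_frequency: dict[str, float] = field(default_factory=dict)


def repeat_overlap_flags(
    promoters: list[GenomeInterval],
    repeat_masks: dict[str, np.ndarray],
) -> np.ndarray:
    """True where a promoter has >= 1 bp of repeat overlap."""
    flags = np.zeros(len(promoters), dtype=bool)
    for i, iv in enumerate(promoters):
        mask = repeat_masks.get(iv.chrom)
        if mask is not None:
            flags[i] = bool(mask[iv.start:iv.end].any())
    return flags


def repeat_enrichment(
    promoters: list[GenomeInterval],
    repeats: list[GenomeInterval],
    repeat_families: list[str],
    background: list[GenomeInterval],
    chrom_lengths: dict[str, int],
    profile_config: ProfileConfig | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> RepeatEnrichment:
    """Repeat density around promoters versus a background interval set.

    The statistic is the repeat base-coverage fraction per oriented window;
    the scalar summary is the coverage over the promoter intervals themselves,
    with a bootstrap CI over promoters and fold versus the same statistic on
    the background set (conserved promoters, or permuted insertion-sized
    intervals). Per-family frequencies are the fraction of promoters with any
    overlap by each repeat family.
    """
    if not promoters:
        raise ValidationError("empty promoter set")
    profile_config = profile_config or ProfileConfig()
    masks = coverage_mask(repeats, chrom_lengths)
    float_masks = {c: m.astype(float) for c, m in masks.items()}
    offsets, observed = window_profile(promoters, float_masks, profile_config)
    if background:
        _, bg = window_profile(background, float_masks, profile_config)
    else:
        bg = np.zeros_like(observed)
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where(bg > 0, observed / bg, np.where(observed > 0, np.inf, 0.0))

    def body_coverage(ivs: list[GenomeInterval]) -> np.ndarray:
        cov = np.zeros(len(ivs))
        for i, iv in enumerate(ivs):
            mask = masks.get(iv.chrom)
            cov[i] = mask[iv.start:iv.end].mean() if mask is not None else 0.0
        return cov

    obs_cov = body_coverage(promoters)
    bg_cov = body_coverage(background) if background else np.zeros(1)
    rng = np.random.default_rng(seed)
    boot = np.array([
        obs_cov[rng.integers(0, len(obs_cov), len(obs_cov))].mean()
        for _ in range(n_boot)
    ])
    null_mean = float(bg_cov.mean())
    overall = EnrichmentResult(
        observed=float(obs_cov.mean()),
        null_mean=null_mean,
        null_ci=(float(np.percentile(bg_cov, 2.5)), float(np.percentile(bg_cov, 97.5))),
        fold=float(obs_cov.mean() / null_mean) if null_mean > 0 else float("inf"),
        bootstrap_ci=(float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5))),
    )
    families = sorted(set(repeat_families))
    family_freq: dict[str, float] = {}
    for family in families:
        fam_ivs = [r for r, f in zip(repeats, repeat_families) if f == family]
        fam_masks = coverage_mask(fam_ivs, chrom_lengths)
        family_freq[family] = float(repeat_overlap_flags(promoters, fam_masks).mean())
    return RepeatEnrichment(
        offsets=offsets,
        observed_coverage=observed,
        background_coverage=bg,
        fold=fold,
        overall=overall,
        family_frequency=family_freq,
    )


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_proportion(
    flags: np.ndarray | list[bool],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Proportion of true flags with a percentile bootstrap 95% CI."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValidationError("need at least one observation")
    rng = np.random.default_rng(seed)
    n = flags.size
    resamples = rng.integers(0, n, size=(n_boot, n))
    props = flags[resamples].mean(axis=1)
    return (
        float(flags.mean()),
        float(np.percentile(props, 2.5)),
        float(np.percentile(props, 97.5)),
    )
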