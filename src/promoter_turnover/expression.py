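"""Expression normalization, promoter architecture and sequence-feature labels.

Promoter expression is consumed as a TPM matrix (promoters x CAGE samples).
Samples are RLE-normalized (median-of-ratios), replicates averaged, and each
promoter is classified as broadly expressed or tissue-restricted with a set
of biased tissue types:

* broad (median TPM across tissue types > 0): biased to tissue T when the
  mean TPM in T is at least 5x the cross-tissue median (inclusive);
* tissue-restricted (median TPM of 0): biased to T when mean TPM in T > 1.

Core-promoter sequence features: TATA-box presence by PWM scan of the
20-30 nt window upstream of the promoter start on either strand with an
exact match P-value threshold of 1e-3, and CpG-island overlap (any overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genomic_io import GenomeInterval, PromoterRecord, SampleSheet, ValidationError

ZERO_TOL = 1e-9  # a median below this counts as zero (tissue-restricted)


@dataclass
class ExpressionProfile:
    promoter_id: str
    tissue_means: dict[str, float]
    median_tpm: float
    max_tpm: float
    breadth: str  # broad | tissue_restricted
    biased_tissues: frozenset[str]
    biased_categories: frozenset[str]
    housekeeping: bool = False  # expressed > 0 in every tissue type


@dataclass(frozen=True)
class MotifConfig:
    """Upstream scan window and significance threshold for the TATA search."""

    window_start_offset: int = 20  # nt upstream of the promoter start
    window_end_offset: int = 30
    p_threshold: float = 1e-3
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.window_start_offset < self.window_end_offset:
            raise ValidationError("window_start_offset must be < window_end_offset")
        if not 0 < self.p_threshold < 1:
            raise ValidationError("p_threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Normalization


def rle_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios (RLE) normalization.

    The size factor of a sample is the median, over features with a positive
    geometric mean across samples, of value / geometric mean. Returns the
    normalized matrix and the per-sample size factors.
    """
    values = matrix.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValidationError("RLE normalization needs at least two samples")
    if (values < 0).any():
        raise ValidationError("negative values in expression matrix")
    with np.errstate(divide="ignore"):
        log_values = np.log(values)
    log_geomean = log_values.mean(axis=1)
    reference = np.isfinite(log_geomean)
    if not reference.any():
        raise ValidationError(
            "no feature has a positive geometric mean across samples; "
            "cannot compute RLE size factors"
        )
    ratios = values[reference] / np.exp(log_geomean[reference, None])
    factors = np.median(ratios, axis=0)
    size_factors = pd.Series(factors, index=matrix.columns, name="size_factor")
    return matrix / size_factors, size_factors


def average_replicates(matrix: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Mean normalized TPM per replicate group (one column per group)."""
    groups = sheet.replicate_groups()
    cols = {}
    for group, samples in groups.items():
        present = [s for s in samples if s in matrix.columns]
        if not present:
            continue
        cols[group] = matrix[present].mean(axis=1)
    return pd.DataFrame(cols)


def tissue_mean_matrix(matrix: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Mean normalized TPM per tissue type (replicates averaged first)."""
    group_means = average_replicates(matrix, sheet)
    group_tissue: dict[str, str] = {}
    tissues = sheet.tissue_of()
    for group, samples in sheet.replicate_groups().items():
        tts = {tissues[s] for s in samples}
        if len(tts) != 1:
            raise ValidationError(f"replicate group {group} spans multiple tissues")
        group_tissue[group] = tts.pop()
    by_tissue: dict[str, list[str]] = {}
    for group, tt in group_tissue.items():
        if group in group_means.columns:
            by_tissue.setdefault(tt, []).append(group)
    return pd.DataFrame(
        {tt: group_means[gs].mean(axis=1) for tt, gs in sorted(by_tissue.items())}
    )


# ---------------------------------------------------------------------------
# Breadth and tissue bias


def classify_breadth_and_bias(
    promoter_id: str,
    tissue_means: dict[str, float],
    tissue_categories: dict[str, str],
    broad_bias_factor: float = 5.0,
    restricted_bias_tpm: float = 1.0,
) -> ExpressionProfile:
    """Classify one promoter's expression architecture and per-tissue bias."""
    if not tissue_means:
        raise ValidationError(f"{promoter_id}: empty tissue means")
    means = np.array(list(tissue_means.values()), dtype=float)
    median = float(np.median(means))
    maximum = float(means.max())
    restricted = median <= ZERO_TOL
    if restricted:
        biased = {t for t, m in tissue_means.items() if m > restricted_bias_tpm}
        breadth = "tissue_restricted"
    else:
        # inclusive boundary: "at least five times the median"
        biased = {
            t for t, m in tissue_means.items() if m >= broad_bias_factor * median
        }
        breadth = "broad"
    categories = frozenset(
        tissue_categories.get(t, "other") for t in biased
    )
    return ExpressionProfile(
        promoter_id=promoter_id,
        tissue_means=dict(tissue_means),
        median_tpm=median,
        max_tpm=maximum,
        breadth=breadth,
        biased_tissues=frozenset(biased),
        biased_categories=categories,
        housekeeping=bool((means > 0).all()),
    )


def build_profiles(
    matrix: pd.DataFrame,
    sheet: SampleSheet,
    normalize: bool = True,
) -> dict[str, ExpressionProfile]:
    """Full path from a raw TPM matrix to per-promoter expression profiles."""
    if normalize:
        matrix, _ = rle_normalize(matrix)
    tmeans = tissue_mean_matrix(matrix, sheet)
    categories = sheet.tissue_categories()
    return {
        pid: classify_breadth_and_bias(pid, row.to_dict(), categories)
        for pid, row in tmeans.iterrows()
    }


# ---------------------------------------------------------------------------
# TATA-box scan

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# TBP-binding consensus (TATAWAWR-like 6-mer core) expressed as base
# probabilities per position; pseudo-counted so every base scores finitely.
DEFAULT_TATA_PWM = np.array(
    [
        # A     C     G     T
        [0.04, 0.04, 0.04, 0.88],  # T
        [0.88, 0.04, 0.04, 0.04],  # A
        [0.04, 0.04, 0.04, 0.88],  # T
        [0.88, 0.04, 0.04, 0.04],  # A
        [0.58, 0.04, 0.04, 0.34],  # A/T
        [0.88, 0.04, 0.04, 0.04],  # A
    ]
)


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def pwm_score(kmer: str, pwm: np.ndarray, background: np.ndarray) -> float:
    """Log2 likelihood-ratio score of a k-mer under the PWM vs background."""
    score = 0.0
    for i, base in enumerate(kmer.upper()):
        j = _BASE_INDEX.get(base)
        if j is None:
            return -np.inf
        score += np.log2(pwm[i, j] / background[j])
    return score


def pwm_score_distribution(
    pwm: np.ndarray, background: np.ndarray, decimals: int = 9
) -> dict[float, float]:
    """Exact distribution of PWM scores under an i.i.d. background.

    Dynamic programming over positions: at each step the score distribution is
    convolved with the four per-base score increments. Scores are keyed on a
    rounded value so numerically identical paths merge.
    """
    dist: dict[float, float] = {0.0: 1.0}
    for row in pwm:
        increments = np.log2(row / background)
        new: dict[float, float] = {}
        for score, prob in dist.items():
            for j in range(4):
                key = round(score + increments[j], decimals)
                new[key] = new.get(key, 0.0) + prob * background[j]
        dist = new
    return dist


SCORE_TOL = 1e-6  # distinct PWM scores are separated by far more than this


def pwm_match_pvalue(
    score: float, pwm: np.ndarray, background: np.ndarray
) -> float:
    """P(score' >= score) for a random background k-mer (exact)."""
    dist = pwm_score_distribution(pwm, background)
    return float(sum(p for s, p in dist.items() if s >= score - SCORE_TOL))


@dataclass
class TataScanResult:
    has_tata: bool
    hits: list[tuple[int, str, float]] = field(default_factory=list)  # (pos, strand, p)


def scan_tata(
    sequence: str,
    promoter_start: int,
    promoter_strand: str,
    config: MotifConfig | None = None,
    pwm: np.ndarray | None = None,
    background: np.ndarray | None = None,
) -> TataScanResult:
    """Scan for a TATA box in the 20-30 nt window upstream of the promoter.

    ``sequence`` is genomic (plus-strand) sequence containing the promoter and
    its upstream flank; ``promoter_start`` is the index in ``sequence`` of the
    promoter's 5' boundary in transcription orientation. Matches are accepted
    on either DNA strand when their exact background P-value is at or below
    the configured threshold and their start lies within the upstream window.
    """
    config = config or MotifConfig()
    pwm = DEFAULT_TATA_PWM if pwm is None else np.asarray(pwm, dtype=float)
    background = (
        np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    )
    width = pwm.shape[0]
    if promoter_strand == "-":
        # orient: work on the reverse complement so upstream is to the left
        sequence = revcomp(sequence)
        promoter_start = len(sequence) - promoter_start
    lo = promoter_start - config.window_end_offset
    hi = promoter_start - config.window_start_offset
    if lo < 0 or hi + width > len(sequence):
        raise ValidationError(
            "upstream scan window extends past the provided sequence"
        )
    dist = pwm_score_distribution(pwm, background)
    scores = sorted(dist)
    tail = np.cumsum([dist[s] for s in reversed(scores)])[::-1]  # P(>= scores[i])

    def pvalue(score: float) -> float:
        idx = np.searchsorted(scores, score - SCORE_TOL)
        return float(tail[idx]) if idx < len(scores) else 0.0

    hits: list[tuple[int, str, float]] = []
    for pos in range(lo, hi + 1):
        kmer = sequence[pos:pos + width]
        for strand, candidate in (("+", kmer), ("-", revcomp(kmer))):
            if strand == "-" and not config.both_strands:
                continue
            p = pvalue(pwm_score(candidate, pwm, background))
            if p <= config.p_threshold:
                hits.append((pos, strand, p))
    return TataScanResult(has_tata=bool(hits), hits=hits)


# ---------------------------------------------------------------------------
# CpG overlap


def label_cpg_overlap(
    promoters: list[PromoterRecord], cpg_islands: list[GenomeInterval]
) -> dict[str, bool]:
    """Flag promoters with any (>= 1 bp) CpG-island overlap."""
    trees: dict[str, IntervalTree] = {}
    for island in cpg_islands:
        trees.setdefault(island.chrom, IntervalTree()).addi(island.start, island.end)
    out: dict[str, bool] = {}
    for p in promoters:
        tree = trees.get(p.interval.chrom)
        out[p.promoter_id] = bool(tree and tree.overlap(p.interval.start, p.interval.end))
    return out
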