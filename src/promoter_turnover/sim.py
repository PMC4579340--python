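"""Two-lineage promoter evolution simulator with ground-truth labels.

An ancestral genome carries a set of promoters; two focal lineages (default
"human" and "mouse") then diverge by whole-segment insertions of novel
promoter-containing sequence (with repeat-family provenance), whole-promoter
deletions (with a configurable deletion excess in the second lineage), and
expression divergence at sequence-conserved promoters (complete loss of
activity in one lineage, or strongly diminished output). Four outgroup
species retain the ancestral sequence per-outgroup with an independent loss
probability, so outgroup-based insertion/deletion resolution is non-trivially
exercised.

Only intervals, alignment statuses, expression levels, per-base scores and
allele frequencies are simulated — never nucleotide sequence. Every emitted
promoter carries exactly one :class:`TrueHistory`, and all emitted tables are
mutually consistent: a truth-inserted promoter projects into gapped/unmapped
sequence in the opposing species and all outgroups in both alignment sources,
a deletion retains uniquely aligned sequence in at least one outgroup, and so
on. A fixed seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import (
    AlignmentStatus,
    GenomeInterval,
    PromoterRecord,
    SampleSheet,
    ValidationError,
    VariantRecord,
    write_alignment_status,
    write_bed,
    write_bedgraph,
    write_expression,
    write_promoter_bed,
    write_variants,
)

# Events a promoter's history may record
ANCESTRAL_CONSERVED = "ancestral_conserved"
REPEAT_FAMILIES = ("LTR", "SINE", "LINE", "low_complexity")

# Size of the population the allele-frequency spectra are expressed in
# (2 x 2636 diploid genomes, the cohort scale of the constraint analysis).
COHORT_CHROMOSOMES = 5272


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    n_ancestral_promoters: int = 500
    insertion_rate_per_lineage: float = 60.0
    deletion_rate_per_lineage: float = 40.0
    mouse_deletion_multiplier: float = 4.0
    repeat_insertion_fraction: float = 0.6
    repeat_family_weights: tuple[tuple[str, float], ...] = (
        ("LTR", 0.45), ("SINE", 0.25), ("LINE", 0.20), ("low_complexity", 0.10),
    )
    genome_repeat_fraction: float = 0.2
    n_tissue_types: int = 52
    n_replicates_per_sample: int = 3
    expression_noise_sd: float = 0.25
    frac_tissue_restricted: float = 0.35
    expr_turnover_prob: float = 0.10
    diminish_prob: float = 0.05
    conflict_prob: float = 0.20
    outgroup_loss_prob: float = 0.30
    selection_regimes: tuple[tuple[str, str], ...] = (
        ("promoter", "purifying"), ("background", "neutral"),
    )
    n_variants: int = 20_000
    blacklist_fraction: float = 0.02
    unmappable_fraction: float = 0.05
    species: tuple[str, str] = ("human", "mouse")
    outgroups: tuple[str, ...] = ("dog", "horse", "cow", "pig")
    promoter_length_range: tuple[int, int] = (60, 300)

    def __post_init__(self) -> None:
        probs = {
            "repeat_insertion_fraction": self.repeat_insertion_fraction,
            "frac_tissue_restricted": self.frac_tissue_restricted,
            "expr_turnover_prob": self.expr_turnover_prob,
            "diminish_prob": self.diminish_prob,
            "conflict_prob": self.conflict_prob,
            "outgroup_loss_prob": self.outgroup_loss_prob,
            "blacklist_fraction": self.blacklist_fraction,
            "unmappable_fraction": self.unmappable_fraction,
            "genome_repeat_fraction": self.genome_repeat_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {p}")
        for name in ("insertion_rate_per_lineage", "deletion_rate_per_lineage",
                     "mouse_deletion_multiplier"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        total = sum(w for _, w in self.repeat_family_weights)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("repeat_family_weights must sum to 1")
        regimes = dict(self.selection_regimes)
        for key, regime in regimes.items():
            if regime not in ("neutral", "purifying", "positive"):
                raise ValidationError(f"unknown selection regime {regime!r} for {key}")


@dataclass(frozen=True)
class TrueHistory:
    """Ground-truth evolutionary history of one emitted promoter."""

    event: str  # ancestral_conserved | inserted_in_lineage_X | deleted_from_lineage_X
    #            | expression_lost_in_X | diminished_in_X  (X = species name)
    repeat_provenance: str = "none"


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    chrom_lengths: dict[str, int]
    promoters: dict[str, list[PromoterRecord]]
    alignment_statuses: dict[str, list[AlignmentStatus]]
    expression: dict[str, tuple[pd.DataFrame, SampleSheet]]
    repeats: dict[str, tuple[list[GenomeInterval], list[str]]]
    conservation: dict[str, dict[str, np.ndarray]]
    variants: dict[str, list[VariantRecord]]
    blacklist: list[GenomeInterval]
    mappable: list[GenomeInterval]
    truth: dict[str, dict[str, TrueHistory]]
    orthologs: list[str] = field(default_factory=list)  # shared 1:1 gene ids

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every table/track as plain-text files; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def register(name: str, path: Path) -> Path:
            paths[name] = path
            return path

        for sp in self.config.species:
            write_promoter_bed(
                self.promoters[sp],
                register(f"promoters_{sp}", outdir / f"promoters.{sp}.bed"),
                register(f"annotation_{sp}", outdir / f"promoters.{sp}.annotation.tsv"),
            )
            write_alignment_status(
                self.alignment_statuses[sp],
                register(f"status_{sp}", outdir / f"alignment_status.{sp}.tsv"),
            )
            matrix, sheet = self.expression[sp]
            write_expression(
                matrix, sheet,
                register(f"expression_{sp}", outdir / f"expression.{sp}.tsv"),
                register(f"samples_{sp}", outdir / f"samples.{sp}.tsv"),
            )
            repeats, families = self.repeats[sp]
            write_bed(
                repeats,
                register(f"repeats_{sp}", outdir / f"repeats.{sp}.bed"),
                names=[f"rep{i}" for i in range(len(repeats))],
                extra=families,
            )
            write_bedgraph(
                _runs_from_track(self.conservation[sp]),
                register(f"conservation_{sp}", outdir / f"conservation.{sp}.bedGraph"),
            )
            with open(register(f"truth_{sp}", outdir / f"truth.{sp}.tsv"), "w") as fh:
                fh.write("promoter_id\tevent\trepeat_provenance\n")
                for pid in sorted(self.truth[sp]):
                    h = self.truth[sp][pid]
                    fh.write(f"{pid}\t{h.event}\t{h.repeat_provenance}\n")
        for sp, variants in self.variants.items():
            write_variants(variants, register(f"variants_{sp}", outdir / f"variants.{sp}.tsv"))
        write_bed(self.blacklist, register("blacklist", outdir / "blacklist.bed"),
                  names=[f"bl{i}" for i in range(len(self.blacklist))])
        write_bed(self.mappable, register("mappable", outdir / "mappable.bed"),
                  names=[f"mp{i}" for i in range(len(self.mappable))])
        with open(register("orthologs", outdir / "orthologs.tsv"), "w") as fh:
            fh.write("gene_id_a\tgene_id_b\n")
            for gid in self.orthologs:
                fh.write(f"{gid}\t{gid}\n")
        return paths


def _runs_from_track(track: dict[str, np.ndarray]) -> dict[str, list[tuple[int, int, float]]]:
    runs: dict[str, list[tuple[int, int, float]]] = {}
    for chrom in sorted(track):
        arr = track[chrom]
        boundaries = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(arr)]))
        runs[chrom] = [
            (int(s), int(e), float(arr[s])) for s, e in zip(starts, ends)
        ]
    return runs


# ---------------------------------------------------------------------------
# Allele-frequency spectra


def _spectrum_weights(regime: str, n_chrom: int = COHORT_CHROMOSOMES) -> np.ndarray:
    """Unnormalized site-frequency-spectrum weights over derived counts 1..n-1.

    The neutral spectrum is the standard 1/k expectation. Purifying selection
    is modelled as an excess of rare derived alleles: extra weight on
    frequencies below 1.5%. The positive regime symmetrically up-weights
    frequencies above 5%.
    """
    k = np.arange(1, n_chrom)
    w = 1.0 / k
    freq = k / n_chrom
    if regime == "neutral":
        return w
    if regime == "purifying":
        return w * (1.0 + 9.0 * (freq < 0.015))
    if regime == "positive":
        return w * (1.0 + 4.0 * (freq > 0.05))
    raise ValidationError(f"unknown selection regime {regime!r}")


def sample_dafs(regime: str, n_sites: int, rng: np.random.Generator,
                n_chrom: int = COHORT_CHROMOSOMES) -> np.ndarray:
    if n_sites == 0:
        return np.array([])
    w = _spectrum_weights(regime, n_chrom)
    counts = rng.choice(np.arange(1, n_chrom), size=n_sites, p=w / w.sum())
    return counts / n_chrom


def neutral_reference_counts(
    scale: int = 1_000_000,
    rare_max: float = 0.015,
    nonrare_min: float = 0.05,
    n_chrom: int = COHORT_CHROMOSOMES,
) -> tuple[int, int]:
    """Expected genome-wide (rare, nonrare) counts under the neutral spectrum."""
    k = np.arange(1, n_chrom)
    w = _spectrum_weights("neutral", n_chrom)
    p = w / w.sum()
    freq = k / n_chrom
    return (
        int(round(scale * p[freq < rare_max].sum())),
        int(round(scale * p[freq > nonrare_min].sum())),
    )


_BASES = np.array(list("ACGT"))


def _variant_records(
    chroms: np.ndarray,
    positions: np.ndarray,
    dafs: np.ndarray,
    rng: np.random.Generator,
    unresolved_fraction: float = 0.0,
) -> list[VariantRecord]:
    n = len(positions)
    out: list[VariantRecord] = []
    for i in range(n):
        ref, alt = rng.choice(4, size=2, replace=False)
        u = rng.random()
        daf = float(dafs[i])
        if u < unresolved_fraction:
            aa, af = ".", daf
        elif rng.random() < 0.5:
            aa, af = _BASES[ref], daf          # alt is derived
        else:
            aa, af = _BASES[alt], 1.0 - daf    # ref is derived
        out.append(
            VariantRecord(str(chroms[i]), int(positions[i]),
                          str(_BASES[ref]), str(_BASES[alt]), str(aa), float(af))
        )
    return out


def simulate_allele_frequencies(
    regime: str, n_sites: int, seed: int, chrom: str = "chrSim"
) -> list[VariantRecord]:
    """A standalone variant table under one selection regime.

    Sites are laid out consecutively on a single pseudo-chromosome; every
    record carries a resolved ancestral state and a derived allele frequency
    in (0, 1).
    """
    if n_sites < 0:
        raise ValidationError("n_sites must be >= 0")
    rng = np.random.default_rng(seed)
    dafs = sample_dafs(regime, n_sites, rng)
    positions = np.arange(n_sites)
    return _variant_records(np.full(n_sites, chrom), positions, dafs, rng)


# ---------------------------------------------------------------------------
# Genome layout helpers


def _place_segments(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    total_fraction: float,
    segment_length: int,
) -> list[GenomeInterval]:
    """Non-overlapping fixed-length segments covering ~total_fraction of each chrom."""
    out: list[GenomeInterval] = []
    for chrom, length in chrom_lengths.items():
        n_segments = int(total_fraction * length / segment_length)
        occupied = np.zeros(length, dtype=bool)
        placed = 0
        attempts = 0
        while placed < n_segments and attempts < n_segments * 50 + 100:
            attempts += 1
            start = int(rng.integers(0, length - segment_length))
            if occupied[start:start + segment_length].any():
                continue
            occupied[start:start + segment_length] = True
            out.append(GenomeInterval(chrom, start, start + segment_length))
            placed += 1
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


def _complement(
    intervals: list[GenomeInterval], chrom_lengths: dict[str, int]
) -> list[GenomeInterval]:
    out: list[GenomeInterval] = []
    by_chrom: dict[str, list[GenomeInterval]] = {c: [] for c in chrom_lengths}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, length in chrom_lengths.items():
        cursor = 0
        for iv in sorted(by_chrom.get(chrom, []), key=lambda x: x.start):
            if iv.start > cursor:
                out.append(GenomeInterval(chrom, cursor, iv.start))
            cursor = max(cursor, iv.end)
        if cursor < length:
            out.append(GenomeInterval(chrom, cursor, length))
    return out


class _Occupancy:
    """Per-chromosome boolean occupancy used to place non-overlapping features."""

    def __init__(self, chrom_lengths: dict[str, int]) -> None:
        self.masks = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
        self.chroms = list(chrom_lengths)
        self.lengths = np.array([chrom_lengths[c] for c in self.chroms], dtype=float)

    def block(self, intervals: list[GenomeInterval], margin: int = 0) -> None:
        for iv in intervals:
            mask = self.masks[iv.chrom]
            mask[max(0, iv.start - margin):min(len(mask), iv.end + margin)] = True

    def place(self, rng: np.random.Generator, length: int,
              margin: int = 10, max_attempts: int = 2000) -> GenomeInterval:
        probs = self.lengths / self.lengths.sum()
        for _ in range(max_attempts):
            chrom = self.chroms[rng.choice(len(self.chroms), p=probs)]
            mask = self.masks[chrom]
            if len(mask) <= length:
                continue
            start = int(rng.integers(0, len(mask) - length))
            if mask[start:start + length].any():
                continue
            mask[max(0, start - margin):start + length + margin] = True
            strand = "+" if rng.random() < 0.5 else "-"
            return GenomeInterval(chrom, start, start + length, strand)
        raise ValidationError("could not place a segment; genome too crowded")


# ---------------------------------------------------------------------------
# Expression architecture


@dataclass
class _Architecture:
    restricted: bool
    base_means: np.ndarray  # per tissue type


def _draw_architecture(
    rng: np.random.Generator, tissues: list[str], restricted_fraction: float
) -> _Architecture:
    n = len(tissues)
    if rng.random() < restricted_fraction:
        means = np.zeros(n)
        k = int(rng.integers(1, 4))
        active = rng.choice(n, size=min(k, n), replace=False)
        means[active] = np.maximum(1.5, rng.lognormal(np.log(8.0), 0.8, size=len(active)))
        return _Architecture(restricted=True, base_means=means)
    means = rng.lognormal(np.log(5.0), 0.5, size=n)
    if rng.random() < 0.5:
        biased = rng.choice(n, size=int(rng.integers(1, 3)), replace=False)
        means[biased] *= 8.0
    return _Architecture(restricted=False, base_means=means)


def _tissue_panel(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    n = config.n_tissue_types
    n_brain = max(1, round(0.2 * n)) if n >= 4 else 0
    n_imm = max(1, round(0.15 * n)) if n >= 4 else 0
    n_testis = 1 if n >= 2 else 0
    tissues, categories = [], {}
    idx = 0
    for count, cat in ((n_testis, "testis"), (n_imm, "immunity"), (n_brain, "brain")):
        for _ in range(count):
            name = f"{cat}_{idx:02d}"
            tissues.append(name)
            categories[name] = cat
            idx += 1
    while len(tissues) < n:
        name = f"other_{idx:02d}"
        tissues.append(name)
        categories[name] = "other"
        idx += 1
    return tissues, categories


# ---------------------------------------------------------------------------
# The simulator


@dataclass
class _PromoterState:
    """Internal per-ancestral-promoter bookkeeping."""

    interval: GenomeInterval
    promoter_class: str
    gene_id: str | None
    arch: _Architecture
    deleted_from: str | None = None       # species name or None
    expression_lost_in: str | None = None
    diminished_in: str | None = None
    outgroups_retained: tuple[bool, ...] = ()


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generative process; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    sp_a, sp_b = config.species
    chrom_lengths = {
        f"chr{i + 1}": config.genome_length for i in range(config.n_chromosomes)
    }

    # --- masks
    blacklist = _place_segments(rng, chrom_lengths, config.blacklist_fraction, 2000)
    unmappable = _place_segments(rng, chrom_lengths, config.unmappable_fraction, 1000)
    mappable = _complement(unmappable, chrom_lengths)

    # --- ancestral promoters (outside the blacklist, non-overlapping)
    occupancy = _Occupancy(chrom_lengths)
    occupancy.block(blacklist, margin=0)
    tissues, tissue_categories = _tissue_panel(config)
    n_genes = max(1, config.n_ancestral_promoters // 3)
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    lo, hi = config.promoter_length_range

    ancestral: list[_PromoterState] = []
    for _ in range(config.n_ancestral_promoters):
        interval = occupancy.place(rng, int(rng.integers(lo, hi + 1)))
        cls = str(rng.choice(["coding", "noncoding", "anonymous"], p=[0.45, 0.25, 0.30]))
        gene = gene_ids[int(rng.integers(n_genes))] if cls != "anonymous" else None
        ancestral.append(
            _PromoterState(
                interval=interval,
                promoter_class=cls,
                gene_id=gene,
                arch=_draw_architecture(rng, tissues, config.frac_tissue_restricted),
            )
        )

    # --- sequence events
    n_ins = {sp_a: int(rng.poisson(config.insertion_rate_per_lineage)),
             sp_b: int(rng.poisson(config.insertion_rate_per_lineage))}
    n_del = {sp_a: int(rng.poisson(config.deletion_rate_per_lineage)),
             sp_b: int(rng.poisson(config.deletion_rate_per_lineage
                                   * config.mouse_deletion_multiplier))}
    order = rng.permutation(len(ancestral))
    n_del_a, n_del_b = n_del[sp_a], n_del[sp_b]
    cap = int(0.8 * len(ancestral))  # keep a conserved core
    if n_del_a + n_del_b > cap:
        scale = cap / (n_del_a + n_del_b)
        n_del_a, n_del_b = int(n_del_a * scale), int(n_del_b * scale)
    for i in order[:n_del_a]:
        ancestral[i].deleted_from = sp_a
    for i in order[n_del_a:n_del_a + n_del_b]:
        ancestral[i].deleted_from = sp_b

    # --- expression events on sequence-conserved promoters
    for state in ancestral:
        if state.deleted_from is not None:
            continue
        u = rng.random()
        lineage = sp_a if rng.random() < 0.5 else sp_b
        if u < config.expr_turnover_prob:
            state.expression_lost_in = lineage
        elif u < config.expr_turnover_prob + config.diminish_prob:
            state.diminished_in = lineage

    # --- outgroup retention of ancestral sequence (shared by both lineages)
    n_og = len(config.outgroups)
    for state in ancestral:
        retained = tuple(rng.random() >= config.outgroup_loss_prob for _ in range(n_og))
        if state.deleted_from is not None and not any(retained):
            # ancestral sequence must survive in >= 1 outgroup for a deletion
            # to be resolvable; condition the draws accordingly
            forced = int(rng.integers(n_og))
            retained = tuple(i == forced or r for i, r in enumerate(retained))
        state.outgroups_retained = retained

    # --- inserted promoters
    @dataclass
    class _Insertion:
        interval: GenomeInterval
        promoter_class: str
        gene_id: str | None
        arch: _Architecture
        family: str

    family_names = [f for f, _ in config.repeat_family_weights]
    family_probs = np.array([w for _, w in config.repeat_family_weights])
    insertions: dict[str, list[_Insertion]] = {sp_a: [], sp_b: []}
    for sp in (sp_a, sp_b):
        for _ in range(n_ins[sp]):
            interval = occupancy.place(rng, int(rng.integers(lo, hi + 1)))
            if rng.random() < config.repeat_insertion_fraction:
                family = str(rng.choice(family_names, p=family_probs))
            else:
                family = "none"
            cls = str(rng.choice(["coding", "noncoding", "anonymous"],
                                 p=[0.25, 0.30, 0.45]))
            gene = (gene_ids[int(rng.integers(n_genes))]
                    if cls != "anonymous" and rng.random() < 0.8 else None)
            insertions[sp].append(
                _Insertion(
                    interval=interval, promoter_class=cls, gene_id=gene,
                    arch=_draw_architecture(rng, tissues, config.frac_tissue_restricted),
                    family=family,
                )
            )

    # --- per-species promoter lists and truth labels
    promoters: dict[str, list[PromoterRecord]] = {sp_a: [], sp_b: []}
    truth: dict[str, dict[str, TrueHistory]] = {sp_a: {}, sp_b: {}}
    arch_of: dict[str, dict[str, _Architecture]] = {sp_a: {}, sp_b: {}}
    diminished_here: dict[str, set[str]] = {sp_a: set(), sp_b: set()}
    anc_id = {}
    for idx, state in enumerate(ancestral):
        anc_id[idx] = {sp: f"{sp}_anc_{idx:05d}" for sp in (sp_a, sp_b)}
    for idx, state in enumerate(ancestral):
        for sp, other in ((sp_a, sp_b), (sp_b, sp_a)):
            if state.deleted_from == sp or state.expression_lost_in == sp:
                continue  # no active promoter in this species
            pid = anc_id[idx][sp]
            promoters[sp].append(
                PromoterRecord(pid, state.interval, sp,
                               state.promoter_class, state.gene_id)
            )
            arch_of[sp][pid] = state.arch
            if state.diminished_in == sp:
                diminished_here[sp].add(pid)
            if state.deleted_from == other:
                event = f"deleted_from_lineage_{other}"
            elif state.expression_lost_in == other:
                event = f"expression_lost_in_{other}"
            elif state.diminished_in is not None:
                event = f"diminished_in_{state.diminished_in}"
            else:
                event = ANCESTRAL_CONSERVED
            truth[sp][pid] = TrueHistory(event=event)
    for sp in (sp_a, sp_b):
        for j, ins in enumerate(insertions[sp]):
            pid = f"{sp}_ins_{j:05d}"
            promoters[sp].append(
                PromoterRecord(pid, ins.interval, sp, ins.promoter_class, ins.gene_id)
            )
            arch_of[sp][pid] = ins.arch
            truth[sp][pid] = TrueHistory(
                event=f"inserted_in_lineage_{sp}", repeat_provenance=ins.family
            )

    # --- alignment statuses
    statuses = {
        sp_a: _statuses_for_species(rng, config, sp_a, sp_b, ancestral, anc_id,
                                    insertions[sp_a]),
        sp_b: _statuses_for_species(rng, config, sp_b, sp_a, ancestral, anc_id,
                                    insertions[sp_b]),
    }

    # --- expression matrices
    expression = {}
    for sp in (sp_a, sp_b):
        expression[sp] = _expression_matrix(
            rng, config, sp, promoters[sp], arch_of[sp], diminished_here[sp],
            tissues, tissue_categories,
        )

    # --- repeats: genome background plus insertion-derived elements
    repeats: dict[str, tuple[list[GenomeInterval], list[str]]] = {}
    for sp in (sp_a, sp_b):
        ivs: list[GenomeInterval] = []
        fams: list[str] = []
        target = config.genome_repeat_fraction * sum(chrom_lengths.values())
        covered = 0.0
        chroms = list(chrom_lengths)
        probs = np.array([chrom_lengths[c] for c in chroms], dtype=float)
        probs /= probs.sum()
        while covered < target:
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            length = int(rng.integers(150, 800))
            start = int(rng.integers(0, chrom_lengths[chrom] - length))
            ivs.append(GenomeInterval(chrom, start, start + length))
            fams.append(str(rng.choice(family_names, p=family_probs)))
            covered += length
        for ins in insertions[sp]:
            if ins.family == "none":
                continue
            pad_l = int(rng.integers(0, 50))
            pad_r = int(rng.integers(0, 50))
            iv = ins.interval
            ivs.append(
                GenomeInterval(iv.chrom, max(0, iv.start - pad_l),
                               min(chrom_lengths[iv.chrom], iv.end + pad_r))
            )
            fams.append(ins.family)
        order2 = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start))
        repeats[sp] = ([ivs[i] for i in order2], [fams[i] for i in order2])

    # --- conservation track (GERP-like semantics: mean +2 over constrained
    #     promoters, ~0 background, reduced over expression-lost loci)
    conservation: dict[str, dict[str, np.ndarray]] = {}
    for sp in (sp_a, sp_b):
        track: dict[str, np.ndarray] = {}
        tile = 25
        for chrom, length in chrom_lengths.items():
            n_tiles = int(np.ceil(length / tile))
            values = np.repeat(rng.normal(0.0, 0.5, size=n_tiles), tile)[:length]
            track[chrom] = np.round(values, 3)
        for state in ancestral:
            iv = state.interval
            if state.deleted_from is not None:
                continue
            bump = 0.5 if state.expression_lost_in is not None else 2.0
            track[iv.chrom][iv.start:iv.end] = np.round(
                track[iv.chrom][iv.start:iv.end] + bump, 3
            )
        conservation[sp] = track

    # --- variants on the first focal genome
    regimes = dict(config.selection_regimes)
    constrained_mask = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    for state in ancestral:
        if state.deleted_from is None:
            iv = state.interval
            constrained_mask[iv.chrom][iv.start:iv.end] = True
    chrom_names = list(chrom_lengths)
    chrom_probs = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_probs /= chrom_probs.sum()
    chrom_idx = rng.choice(len(chrom_names), size=config.n_variants, p=chrom_probs)
    positions = np.array([
        rng.integers(0, chrom_lengths[chrom_names[i]]) for i in chrom_idx
    ], dtype=int)
    in_promoter = np.array([
        constrained_mask[chrom_names[i]][p] for i, p in zip(chrom_idx, positions)
    ], dtype=bool)
    dafs = np.empty(config.n_variants)
    dafs[in_promoter] = sample_dafs(
        regimes.get("promoter", "purifying"), int(in_promoter.sum()), rng
    )
    dafs[~in_promoter] = sample_dafs(
        regimes.get("background", "neutral"), int((~in_promoter).sum()), rng
    )
    order3 = np.lexsort((positions, chrom_idx))
    variant_list = _variant_records(
        np.array([chrom_names[i] for i in chrom_idx])[order3],
        positions[order3], dafs[order3], rng, unresolved_fraction=0.02,
    )

    return SimulatedDataset(
        config=config,
        chrom_lengths=chrom_lengths,
        promoters=promoters,
        alignment_statuses=statuses,
        expression=expression,
        repeats=repeats,
        conservation=conservation,
        variants={sp_a: variant_list},
        blacklist=blacklist,
        mappable=mappable,
        truth=truth,
        orthologs=gene_ids,
    )


# ---------------------------------------------------------------------------
# Status generation


def _aligned_rows(rng, pid, target_sp, interval) -> list[AlignmentStatus]:
    return [
        AlignmentStatus(pid, target_sp, source, "ALIGNED", interval,
                        float(round(rng.uniform(0.75, 1.0), 4)))
        for source in ("msa", "pairwise")
    ]


def _absent_rows(rng, pid, target_sp) -> list[AlignmentStatus]:
    return [
        AlignmentStatus(pid, target_sp, source,
                        str(rng.choice(["GAPPED", "UNMAPPED"])),
                        None, float(round(rng.uniform(0.0, 0.3), 4)))
        for source in ("msa", "pairwise")
    ]


def _conflict_rows(rng, pid, target_sp, interval) -> list[AlignmentStatus]:
    # the two sources disagree: one confidently aligned, one gapped/unmapped
    return [
        AlignmentStatus(pid, target_sp, "msa", "ALIGNED", interval,
                        float(round(rng.uniform(0.75, 1.0), 4))),
        AlignmentStatus(pid, target_sp, "pairwise",
                        str(rng.choice(["GAPPED", "UNMAPPED"])), None,
                        float(round(rng.uniform(0.0, 0.3), 4))),
    ]


def _statuses_for_species(
    rng: np.random.Generator,
    config: SimulationConfig,
    focal: str,
    opposing: str,
    ancestral: list,
    anc_id: dict[int, dict[str, str]],
    focal_insertions: list,
) -> list[AlignmentStatus]:
    rows: list[AlignmentStatus] = []
    for idx, state in enumerate(ancestral):
        if state.deleted_from == focal or state.expression_lost_in == focal:
            continue
        pid = anc_id[idx][focal]
        iv = state.interval
        # opposing species: sequence present unless deleted there; the locus of
        # an expression-lost ortholog still aligns (silent sequence)
        opposing_has_sequence = state.deleted_from != opposing
        if rng.random() < config.conflict_prob:
            rows.extend(_conflict_rows(rng, pid, opposing, iv))
        elif opposing_has_sequence:
            rows.extend(_aligned_rows(rng, pid, opposing, iv))
        else:
            rows.extend(_absent_rows(rng, pid, opposing))
        for og, retained in zip(config.outgroups, state.outgroups_retained):
            if retained:
                rows.extend(_aligned_rows(rng, pid, og, iv))
            else:
                rows.extend(_absent_rows(rng, pid, og))
    for j, ins in enumerate(focal_insertions):
        pid = f"{focal}_ins_{j:05d}"
        if rng.random() < config.conflict_prob:
            rows.extend(_conflict_rows(rng, pid, opposing, ins.interval))
        else:
            rows.extend(_absent_rows(rng, pid, opposing))
        for og in config.outgroups:
            rows.extend(_absent_rows(rng, pid, og))
    return rows


# ---------------------------------------------------------------------------
# Expression generation


def _expression_matrix(
    rng: np.random.Generator,
    config: SimulationConfig,
    sp: str,
    promoter_list: list[PromoterRecord],
    arch_of: dict[str, "_Architecture"],
    diminished: set[str],
    tissues: list[str],
    tissue_categories: dict[str, str],
) -> tuple[pd.DataFrame, SampleSheet]:
    sample_ids, rows = [], []
    for tissue in tissues:
        for r in range(config.n_replicates_per_sample):
            sample_ids.append(f"{sp}.{tissue}.r{r + 1}")
            rows.append(
                {
                    "sample_id": f"{sp}.{tissue}.r{r + 1}",
                    "species": sp,
                    "tissue_type": tissue,
                    "replicate_group": f"{sp}.{tissue}",
                    "tissue_category": tissue_categories[tissue],
                }
            )
    sheet = SampleSheet(pd.DataFrame(rows))
    n_samples = len(sample_ids)
    tissue_index = {t: i for i, t in enumerate(tissues)}
    sample_tissue = np.array(
        [tissue_index[s.split(".")[1]] for s in sample_ids]
    )
    values = np.zeros((len(promoter_list), n_samples))
    for i, p in enumerate(promoter_list):
        base = arch_of[p.promoter_id].base_means.copy()
        if p.promoter_id in diminished:
            base = base * 0.02
        noise = rng.lognormal(0.0, config.expression_noise_sd, size=n_samples)
        values[i] = base[sample_tissue] * noise
    matrix = pd.DataFrame(
        np.round(values, 4),
        index=[p.promoter_id for p in promoter_list],
        columns=sample_ids,
    )
    return matrix, sheet


# ---------------------------------------------------------------------------
# Truth -> expected classifier labels


def expected_sequence_fate(event: str) -> str:
    """The sequence fate a noise-free classifier must produce for a truth label."""
    if event.startswith("inserted_in_lineage_"):
        return "INSERTED"
    if event.startswith("deleted_from_lineage_"):
        return "DELETED_IN_OPPOSING"
    return "ALIGNED"


def noise_free(config: SimulationConfig) -> SimulationConfig:
    """A copy of the config with all observation noise switched off."""
    return replace(config, conflict_prob=0.0, outgroup_loss_prob=0.0)
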