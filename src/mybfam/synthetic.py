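"""Synthetic proteomes, gene models and count matrices with known truth.

The generators emulate the statistical structure the downstream stages
assume: proteins carrying 0-4 planted MYB repeats inside random flanks,
decoy proteins drawn from the seed-profile background composition, gene
models with controlled exon counts and tandem spacings, and overdispersed
count matrices with known per-sample scale factors and organ-restricted
expression. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import (
    AMINO_ACIDS,
    LANDMARK_RULES_CANONICAL,
    R2_CONSENSUS,
    R2_SPAN,
    R3_CONSENSUS,
    R3_SPAN,
    sample_background_sequence,
)
from .scan import ProteinRecord


class LayoutError(ValueError):
    """Raised when requested gene bodies overlap on one chromosome."""


@dataclass
class PlantedRepeat:
    start: int  # 1-based inclusive protein coordinates
    end: int
    repeat_kind: str  # R2 | R3 | R1-like
    #: (canonical position, consensus residue, planted residue)
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)


@dataclass
class GeneTruth:
    chromosome: str
    start: int
    end: int
    strand: str
    n_exons: int
    tandem_partner: str | None = None
    tandem_distance: int | None = None


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic data set."""

    seed: int
    protein_truth: dict[str, list[PlantedRepeat]] = field(default_factory=dict)
    gene_truth: dict[str, GeneTruth] = field(default_factory=dict)
    scale_factors: dict[str, float] = field(default_factory=dict)
    #: gene id -> boolean per-sample expression pattern (True = expressed)
    organ_patterns: dict[str, list[bool]] = field(default_factory=dict)

    def validate(self, proteins: dict[str, str] | None = None) -> None:
        if proteins:
            for pid, repeats in self.protein_truth.items():
                for rep in repeats:
                    if not (1 <= rep.start <= rep.end <= len(proteins[pid])):
                        raise AssertionError(f"{pid}: repeat outside protein")
        for sf in self.scale_factors.values():
            if sf <= 0:
                raise AssertionError("non-positive true scale factor")


# ---------------------------------------------------------------------------
# proteome


#: repeat layout per requested family class
CLASS_LAYOUTS = {
    "R2R3": ("R2", "R3"),
    "MYB3R": ("R1-like", "R2", "R3"),
    "MYB4R": ("R2", "R3", "R2", "R3"),
    "single": ("R2",),
}

_CONSENSUS = {"R2": (R2_CONSENSUS, R2_SPAN[0]), "R3": (R3_CONSENSUS, R3_SPAN[0]),
              # the R1 slot of three-repeat proteins is planted as a mutated
              # second-repeat copy; positionally it is relabelled R1-like
              "R1-like": (R2_CONSENSUS, R2_SPAN[0])}

#: landmark positions that may never mutate (no tolerated substitution)
_STRICT_LANDMARKS = {p for p, s in LANDMARK_RULES_CANONICAL.items() if s == frozenset("W")}
#: landmark positions with tolerated substitution sets (minus W itself)
_SOFT_LANDMARKS = {
    p: sorted(s - {"W"}) for p, s in LANDMARK_RULES_CANONICAL.items() if s != frozenset("W")
}


def _mutate_repeat(
    kind: str, sub_rate: float, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str]]]:
    consensus, offset = _CONSENSUS[kind]
    out = list(consensus)
    subs = []
    for i, orig in enumerate(consensus):
        canonical = offset + i
        if rng.random() >= sub_rate:
            continue
        if canonical in _STRICT_LANDMARKS:
            continue  # the core tryptophans tolerate no substitution
        if canonical in _SOFT_LANDMARKS:
            new = _SOFT_LANDMARKS[canonical][rng.integers(len(_SOFT_LANDMARKS[canonical]))]
        else:
            others = [a for a in AMINO_ACIDS if a != orig]
            new = others[rng.integers(len(others))]
        out[i] = new
        subs.append((canonical, orig, new))
    return "".join(out), subs


def _background_from_consensus() -> np.ndarray:
    counts = np.full(20, 0.5)
    for ch in R2_CONSENSUS + R3_CONSENSUS:
        counts[AMINO_ACIDS.index(ch)] += 1
    return counts / counts.sum()


def generate_proteome(
    n_r2r3: int = 0,
    n_myb3r: int = 0,
    n_myb4r: int = 0,
    n_single: int = 0,
    n_decoy: int = 0,
    sub_rate: float = 0.0,
    seed: int = 0,
    flank_range: tuple[int, int] = (15, 60),
    linker_len: int = 0,
    decoy_length_range: tuple[int, int] = (150, 450),
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Proteins with planted MYB repeats plus background decoys.

    Each MYB protein is random flank + planted repeat block(s) + random
    flank; repeat residues are substituted at `sub_rate` per position, with
    the tryptophan landmarks either untouched (strict positions) or drawn
    from the tolerated sets (W60 -> F/I/L/Y, W98 -> F/C). Decoy residues are
    drawn from the background amino-acid composition of the seed consensus,
    so false-positive calibration is honest. Deterministic given seed.
    """
    counts = dict(R2R3=n_r2r3, MYB3R=n_myb3r, MYB4R=n_myb4r,
                  single=n_single, decoy=n_decoy)
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative counts")
    if not 0 <= sub_rate < 0.5:
        raise ValueError("sub_rate must be in [0, 0.5)")

    rng = np.random.default_rng(seed)
    background = _background_from_consensus()
    truth = SyntheticTruth(seed=seed)
    proteins: list[ProteinRecord] = []

    for klass, layout in CLASS_LAYOUTS.items():
        for i in range(counts[klass]):
            pid = f"syn_{klass.lower()}_{i + 1:03d}"
            left = int(rng.integers(flank_range[0], flank_range[1] + 1))
            right = int(rng.integers(flank_range[0], flank_range[1] + 1))
            pieces = [sample_background_sequence(rng, left, background)]
            cursor = left
            planted = []
            for k, kind in enumerate(layout):
                if k > 0 and linker_len:
                    pieces.append(sample_background_sequence(rng, linker_len, background))
                    cursor += linker_len
                repeat_seq, subs = _mutate_repeat(kind, sub_rate, rng)
                planted.append(
                    PlantedRepeat(start=cursor + 1, end=cursor + len(repeat_seq),
                                  repeat_kind=kind, substitutions=subs)
                )
                pieces.append(repeat_seq)
                cursor += len(repeat_seq)
            pieces.append(sample_background_sequence(rng, right, background))
            proteins.append(ProteinRecord(id=pid, seq="".join(pieces),
                                          description=f"synthetic {klass}"))
            truth.protein_truth[pid] = planted

    for i in range(counts["decoy"]):
        pid = f"syn_decoy_{i + 1:03d}"
        length = int(rng.integers(decoy_length_range[0], decoy_length_range[1] + 1))
        proteins.append(ProteinRecord(id=pid,
                                      seq=sample_background_sequence(rng, length, background),
                                      description="synthetic decoy"))
        truth.protein_truth[pid] = []

    truth.validate({p.id: p.seq for p in proteins})
    return proteins, truth


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneSpec:
    """Requested layout for one synthetic gene.

    `start` pins the gene; `spacing_from_prev` places it start-to-start
    relative to the previous gene on the same chromosome; otherwise the
    gene is placed after a random intergenic gap.
    """

    gene_id: str
    chrom: str
    n_exons: int = 3
    strand: str = "+"
    start: int | None = None
    length: int | None = None
    spacing_from_prev: int | None = None


def _exon_intervals(start: int, length: int, n_exons: int,
                    rng: np.random.Generator) -> list[tuple[int, int]]:
    if n_exons == 1:
        return [(start, start + length - 1)]
    # cut the span into alternating exon/intron blocks with random sizes
    n_blocks = 2 * n_exons - 1
    if length < n_blocks:
        raise LayoutError(f"gene span {length} too short for {n_exons} exons")
    weights = rng.uniform(0.5, 1.5, size=n_blocks)
    sizes = np.maximum(20, (weights / weights.sum() * length).astype(int))
    sizes[-1] = length - sizes[:-1].sum()
    if sizes[-1] < 20:
        sizes[:] = length // n_blocks
        sizes[-1] = length - sizes[:-1].sum()
    exons = []
    pos = start
    for b, size in enumerate(sizes):
        if b % 2 == 0:
            exons.append((pos, pos + int(size) - 1))
        pos += int(size)
    return exons


def generate_gene_models(
    genes: list[GeneSpec],
    seed: int = 0,
    gap_range: tuple[int, int] = (150_000, 500_000),
    length_range: tuple[int, int] = (1_500, 6_000),
    tandem_threshold: int = 105_000,
) -> tuple[str, SyntheticTruth]:
    """Valid GFF3 (gene/mRNA/exon features, 1-based inclusive) plus truth.

    Truth records per-gene chromosome, exon count and tandem pairing: two
    genes on one chromosome whose start-to-start distance is at most
    `tandem_threshold` are marked partners. Overlapping requested gene
    bodies raise LayoutError. Byte-identical output for identical input.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    placed: dict[str, list[tuple[int, int, str]]] = {}
    rows = []

    cursors: dict[str, int] = {}
    prev_start: dict[str, int] = {}
    for spec in genes:
        length = spec.length or int(rng.integers(length_range[0], length_range[1] + 1))
        if spec.start is not None:
            start = spec.start
        elif spec.spacing_from_prev is not None:
            if spec.chrom not in prev_start:
                raise LayoutError(f"{spec.gene_id}: no previous gene on {spec.chrom}")
            start = prev_start[spec.chrom] + spec.spacing_from_prev
        else:
            gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
            start = cursors.get(spec.chrom, 0) + gap + 1
        end = start + length - 1
        for s, e, other in placed.get(spec.chrom, []):
            if start <= e and end >= s:
                raise LayoutError(
                    f"gene bodies overlap on {spec.chrom}: {spec.gene_id} and {other}"
                )
        placed.setdefault(spec.chrom, []).append((start, end, spec.gene_id))
        cursors[spec.chrom] = max(cursors.get(spec.chrom, 0), end)
        prev_start[spec.chrom] = start

        exons = _exon_intervals(start, length, spec.n_exons, rng)
        rows.append((spec, start, end, exons))
        truth.gene_truth[spec.gene_id] = GeneTruth(
            chromosome=spec.chrom, start=start, end=end, strand=spec.strand,
            n_exons=spec.n_exons,
        )

    # mark tandem pairs from placed coordinates
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gid, gt in truth.gene_truth.items():
        by_chrom.setdefault(gt.chromosome, []).append((gt.start, gid))
    for chrom, entries in by_chrom.items():
        entries.sort()
        for (s1, g1), (s2, g2) in zip(entries, entries[1:]):
            if s2 - s1 <= tandem_threshold:
                truth.gene_truth[g1].tandem_partner = g2
                truth.gene_truth[g1].tandem_distance = s2 - s1
                truth.gene_truth[g2].tandem_partner = g1
                truth.gene_truth[g2].tandem_distance = s2 - s1

    lines = ["##gff-version 3"]
    for spec, start, end, exons in sorted(rows, key=lambda r: (r[0].chrom, r[1])):
        gid = spec.gene_id
        base = f"{spec.chrom}\tmybfam_synthetic\t"
        tail = f"\t.\t{spec.strand}\t."
        lines.append(f"{base}gene\t{start}\t{end}{tail}\tID=gene:{gid}")
        lines.append(f"{base}mRNA\t{start}\t{end}{tail}\tID=mRNA:{gid};Parent=gene:{gid}")
        for x, (es, ee) in enumerate(exons, 1):
            lines.append(
                f"{base}exon\t{es}\t{ee}{tail}\tID=exon:{gid}.{x};Parent=mRNA:{gid}"
            )
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# count matrices


def generate_counts(
    n_genes: int,
    samples: list[str],
    scale_factors: list[float],
    seed: int = 0,
    base_mean_range: tuple[float, float] = (20.0, 500.0),
    dispersion: float = 0.05,
    organ_restricted: dict[str, list[bool]] | None = None,
    n_always_zero: int = 0,
):
    """Overdispersed integer counts with planted per-sample scale factors.

    Per gene g and sample s the mean is mu = base_mean(g) * factor(s)
    (zeroed where the organ pattern switches the gene off) and counts are
    negative-binomial with var = mu + dispersion * mu^2, matching the
    mean-variance structure median-of-ratios normalisation assumes.

    `organ_restricted` maps gene index (as "gene_<i>") to a boolean
    per-sample pattern; `n_always_zero` appends that many all-zero genes.
    Returns (CountMatrix, SyntheticTruth).
    """
    from .expression import CountMatrix

    if len(scale_factors) != len(samples):
        raise ValueError("one scale factor per sample required")
    if any(sf <= 0 for sf in scale_factors):
        raise ValueError("scale factors must be positive")

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    truth.scale_factors = dict(zip(samples, map(float, scale_factors)))

    gene_ids = [f"gene_{i + 1:04d}" for i in range(n_genes + n_always_zero)]
    base_means = np.exp(rng.uniform(np.log(base_mean_range[0]),
                                    np.log(base_mean_range[1]), size=n_genes))
    counts = np.zeros((n_genes + n_always_zero, len(samples)), dtype=np.int64)
    organ_restricted = organ_restricted or {}
    for g in range(n_genes):
        gid = gene_ids[g]
        pattern = organ_restricted.get(gid, [True] * len(samples))
        truth.organ_patterns[gid] = list(pattern)
        for s, sf in enumerate(scale_factors):
            if not pattern[s]:
                continue
            mu = base_means[g] * sf
            if dispersion > 0:
                r = 1.0 / dispersion
                p = r / (r + mu)
                counts[g, s] = rng.negative_binomial(r, p)
            else:
                counts[g, s] = rng.poisson(mu)
    for g in range(n_genes, n_genes + n_always_zero):
        truth.organ_patterns[gene_ids[g]] = [False] * len(samples)

    truth.validate()
    return CountMatrix(gene_ids=gene_ids, samples=list(samples), counts=counts), truth
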