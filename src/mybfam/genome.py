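"""Chromosomal distribution, gene structure and tandem-duplication context.

Gene models come either from GFF3 or from a printed catalogue table.
Chromosome labels follow the reference-genome convention: plain digits for
positioned genes, a "un" suffix for genes assigned to a chromosome without
position, and "rnd"-prefixed scaffold labels for unanchored genes.
Coordinates are 1-based inclusive externally; minus-strand coordinate
pairs are normalised so start <= end, with orientation kept in `strand`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import gffutils
import pandas as pd


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    start: int  # normalised: start <= end
    end: int
    exons: list[tuple[int, int]] | None = None
    family_class: str | None = None
    n_exons_hint: int | None = None  # for catalogue rows without exon intervals

    def __post_init__(self):
        if self.start > self.end:
            self.start, self.end = self.end, self.start

    @property
    def n_exons(self) -> int:
        if self.exons is not None:
            return len(self.exons)
        if self.n_exons_hint is not None:
            return self.n_exons_hint
        raise ValueError(f"{self.gene_id}: exon count unknown")


@dataclass
class SisterPair:
    gene_a: str
    gene_b: str
    chromosome: str
    distance: int  # normalised start-to-start, bp
    intervening_gene_count: int | None = None


def read_gene_models(gff3_path: str) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModels (one per gene feature, exon
    children collected through mRNA features).

    Genes without exon children fall back to the gene body as a single
    exon, with a warning. Malformed lines raise with their line number.
    """
    n_features = 0
    with open(gff3_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{gff3_path}: malformed GFF3 line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
            if not fields[3].isdigit() or not fields[4].isdigit():
                raise ValueError(
                    f"{gff3_path}: malformed GFF3 line {lineno}: "
                    "non-numeric coordinates"
                )
            n_features += 1
    if n_features == 0:
        return []

    try:
        db = gffutils.create_db(
            str(gff3_path), dbfn=":memory:", force=True,
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed GFF3 {gff3_path}: {exc}") from exc

    genes = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = sorted(
            (e.start, e.end) for e in db.children(gene, featuretype="exon")
        )
        gid = gene.id.split(":", 1)[-1]
        if not exons:
            warnings.warn(f"{gid}: gene without exons, using gene body")
            exons = [(gene.start, gene.end)]
        genes.append(
            GeneModel(gene_id=gid, chromosome=gene.seqid, strand=gene.strand,
                      start=gene.start, end=gene.end, exons=exons)
        )
    return genes


def exon_category(gene: GeneModel) -> str:
    """Gene-structure category by exon count: "1", "2", "3" or ">3".

    Three exons (two introns) is the canonical structure of the
    two-repeat MYB genes.
    """
    n = gene.n_exons
    return str(n) if n <= 3 else ">3"


def exon_category_counts(genes: list[GeneModel],
                         class_filter: str | None = None) -> dict[str, int]:
    counts = {"1": 0, "2": 0, "3": 0, ">3": 0}
    for g in genes:
        if class_filter and g.family_class != class_filter:
            continue
        counts[exon_category(g)] += 1
    return counts


def base_chromosome(label: str) -> str | None:
    """Chromosome a gene counts toward: "5" and "5un" both count for 5;
    unanchored scaffold labels return None."""
    lbl = label.removeprefix("chr")
    if lbl.endswith("un"):
        lbl = lbl[:-2]
    return lbl if lbl.isdigit() else None


def chromosome_distribution(
    genes: list[GeneModel],
    class_filter: str | None = None,
    chrom_lengths: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-chromosome gene counts, with unanchored scaffolds aggregated in
    an "unanchored" row. When chromosome lengths (bp) are supplied, the
    density column reports Mb per gene."""
    counts: dict[str, int] = {}
    for g in genes:
        if class_filter and g.family_class != class_filter:
            continue
        chrom = base_chromosome(g.chromosome) or "unanchored"
        counts[chrom] = counts.get(chrom, 0) + 1
    rows = []
    for chrom in sorted(counts, key=lambda c: (c == "unanchored", c.zfill(4))):
        row = {"chromosome": chrom, "n_genes": counts[chrom]}
        if chrom_lengths and chrom in chrom_lengths:
            row["mb_per_gene"] = chrom_lengths[chrom] / 1e6 / counts[chrom]
        rows.append(row)
    return pd.DataFrame(rows)


def detect_sister_pairs(
    genes: list[GeneModel],
    max_distance: int = 105_000,
    require_no_intervening: bool = False,
    annotation: list[GeneModel] | None = None,
) -> list[SisterPair]:
    """Tandem (sister) gene pairs: same chromosome/scaffold label and
    normalised start-to-start distance <= max_distance.

    With `require_no_intervening` and a full gene annotation, pairs with
    annotated genes between their bodies are dropped. Each unordered pair
    is reported once, sorted by chromosome then coordinate.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    pairs = []
    for a, b in combinations(sorted(genes, key=lambda g: (g.chromosome, g.start)), 2):
        if a.chromosome != b.chromosome:
            continue
        distance = abs(b.start - a.start)
        if distance > max_distance:
            continue
        intervening = None
        if annotation is not None:
            lo, hi = min(a.end, b.end), max(a.start, b.start)
            intervening = sum(
                1 for g in annotation
                if g.chromosome == a.chromosome
                and g.gene_id not in (a.gene_id, b.gene_id)
                and g.start > lo and g.end < hi
            )
            if require_no_intervening and intervening > 0:
                continue
        pairs.append(SisterPair(gene_a=a.gene_id, gene_b=b.gene_id,
                                chromosome=a.chromosome, distance=distance,
                                intervening_gene_count=intervening))
    return pairs


def orf_protein_length(orf_bp: int) -> int:
    """Residue count encoded by an open reading frame: one codon per
    residue, minus the stop codon (a 1164 bp ORF encodes 387 residues)."""
    if orf_bp <= 3 or orf_bp % 3:
        raise ValueError("ORF length must be a positive multiple of 3")
    return orf_bp // 3 - 1


@dataclass
class FamilyShare:
    pct_of_proteome: float  # rounded to 2 decimals
    pct_of_tf: float  # rounded to 1 decimal


def family_statistics(n_family: int, n_proteome: int, n_tf: int) -> FamilyShare:
    """Family share of the predicted proteome (2 decimals) and of the
    transcription-factor complement (1 decimal), in percent."""
    if n_proteome <= 0 or n_tf <= 0:
        raise ValueError("denominators must be positive")
    return FamilyShare(
        pct_of_proteome=round(100.0 * n_family / n_proteome, 2),
        pct_of_tf=round(100.0 * n_family / n_tf, 1),
    )
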