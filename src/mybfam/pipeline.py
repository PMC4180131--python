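"""End-to-end orchestration: scan -> classify -> conserve -> motifs ->
genome context -> expression (-> clades), producing a family catalogue
and a summary report.

The pipeline is driven by a flat key=value config. In `simulate` mode the
synthetic generators provide a complete input bundle (proteome, gene
models, counts) from one seed; otherwise input paths are read. Optional
stages without inputs are skipped with a logged notice. All randomness
flows from the config seed, and reports carry no timestamps, so one
config yields byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import datasets, io
from .conservation import align_repeats, export_logo_data, position_frequencies
from .expression import (
    CountMatrix,
    cluster_genes,
    export_heatmap,
    normalize,
    presence_calls,
    size_factors,
)
from .genome import (
    GeneModel,
    chromosome_distribution,
    detect_sister_pairs,
    exon_category_counts,
    family_statistics,
    read_gene_models,
)
from .motifs import (
    BHLH_PATTERN,
    SG7_PATTERN,
    residue_diagnostics,
    scan_motif,
    scan_sg7_terminal,
)
from .scan import extract_domain, scan_proteome
from .synthetic import GeneSpec, generate_counts, generate_gene_models, generate_proteome

log = logging.getLogger("mybfam")


def read_config(path) -> dict:
    """Flat key = value text config; '#' starts a comment."""
    config = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        config[key] = value
    return config


def _as_bool(value, default=False) -> bool:
    if value is None:
        return default
    return str(value).lower() in ("1", "true", "yes", "on")


@dataclass
class PipelineResult:
    catalogue: pd.DataFrame
    report: dict
    out_dir: Path
    truth: object | None = None


def _default_synthetic_bundle(seed: int, sub_rate: float, out_dir: Path):
    """Proteome + gene models + counts with matching identifiers."""
    proteins, truth = generate_proteome(
        n_r2r3=20, n_myb3r=2, n_myb4r=1, n_single=3, n_decoy=20,
        sub_rate=sub_rate, seed=seed,
    )
    myb_ids = [pid for pid, reps in truth.protein_truth.items() if len(reps) >= 2]
    specs = []
    for i, pid in enumerate(myb_ids):
        chrom = str(1 + i % 5)
        specs.append(GeneSpec(gene_id=pid, chrom=chrom, n_exons=3 if i % 4 else 2,
                              strand="+" if i % 2 else "-"))
    # one tandem pair at the spacing seen for the real chromosome-7 pair
    specs.append(GeneSpec(gene_id="syn_tandem_a", chrom="9", n_exons=3))
    specs.append(GeneSpec(gene_id="syn_tandem_b", chrom="9", n_exons=3,
                          spacing_from_prev=102_964))
    gff_text, gene_truth = generate_gene_models(specs, seed=seed + 1)
    gff_path = out_dir / "synthetic_genes.gff3"
    gff_path.write_text(gff_text)

    organs = ["seedling", "taproot", "young_leaf", "old_leaf", "inflorescence", "seed"]
    cm, expr_truth = generate_counts(
        n_genes=len(proteins), samples=organs,
        scale_factors=[1.0, 1.2, 0.8, 0.6, 1.5, 0.9], seed=seed + 2,
    )
    cm.gene_ids = [p.id for p in proteins]  # align count rows with proteins
    truth.gene_truth = gene_truth.gene_truth
    truth.scale_factors = expr_truth.scale_factors
    truth.organ_patterns = expr_truth.organ_patterns
    return proteins, gff_path, cm, truth


def run_pipeline(config: dict | str, out_dir=None) -> PipelineResult:
    """Execute the stages in dependency order and write catalogue +
    report; raises before any stage runs when a mandatory input is
    missing."""
    if not isinstance(config, dict):
        config = read_config(config)
    out_dir = Path(out_dir or config.get("out_dir", "mybfam_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    simulate = _as_bool(config.get("simulate"), default=False)
    seed = config.get("seed")
    if simulate and seed is None:
        raise ValueError("simulate mode requires a seed in the config")
    seed = int(seed) if seed is not None else None
    sub_rate = float(config.get("sub_rate", 0.03))
    presence_threshold = float(config.get("presence_threshold", 0.0))
    max_pair_distance = int(config.get("max_pair_distance", 105_000))

    truth = None
    counts = None
    gff_path = None
    if simulate:
        t0 = time.perf_counter()
        proteins, gff_path, counts, truth = _default_synthetic_bundle(
            seed, sub_rate, out_dir
        )
        log.info("simulate stage: %.2fs", time.perf_counter() - t0)
    else:
        if "proteome_fasta" not in config:
            raise ValueError("config must name proteome_fasta (or set simulate=true)")
        proteins = io.read_fasta(config["proteome_fasta"])
        gff_path = config.get("gff3")
        if config.get("counts_tsv"):
            counts = CountMatrix.from_tsv(config["counts_tsv"])

    # --- scan & classify -------------------------------------------------
    t0 = time.perf_counter()
    profile_r2, profile_r3 = datasets.load_profiles(seed=2014)
    classifications = scan_proteome(
        proteins, profile_r2, profile_r3,
        cdc5_landmark=datasets.load_cdc5_landmark(),
    )
    members = [c for c in classifications if c.is_family_member]
    io.write_classification_tsv(classifications, out_dir / "classification.tsv")
    io.write_repeats_tsv(members, out_dir / "repeats.tsv")
    log.info("scan stage: %d/%d family members, %.2fs",
             len(members), len(proteins), time.perf_counter() - t0)

    proteins_by_id = {p.id: p for p in proteins}

    # --- catalogue rows --------------------------------------------------
    rows = []
    for c in members:
        protein = proteins_by_id[c.protein_id]
        row = {
            "gene_id": c.protein_id,
            "family_class": c.family_class,
            "n_repeats": c.n_repeats,
            "protein_length": len(protein),
            "repeat_coords": ";".join(f"{h.start}-{h.end}" for h in c.repeats),
        }
        row["bhlh_motif"] = bool(scan_motif(protein, BHLH_PATTERN, 0))
        row["sg7_motif"] = bool(scan_motif(protein, SG7_PATTERN, 2))
        sg72 = scan_sg7_terminal(protein)
        row["sg7_2_motif"] = sg72 is not None
        if c.family_class == "R2R3":
            diag = residue_diagnostics(extract_domain(c, protein))
            row["residue_44"] = diag.residues[44]
            row["residue_89"] = diag.residues[89]
            row["residue_98"] = diag.residues[98]
            row["interpretation_89"] = diag.interpretation_89
        rows.append(row)
    catalogue = pd.DataFrame(rows)

    # --- conservation ----------------------------------------------------
    for kind in ("R2", "R3"):
        windows = [
            proteins_by_id[c.protein_id].seq[h.start - 1: h.end]
            for c in members
            for h in c.repeats
            if h.repeat_kind == kind
        ]
        if len(windows) >= 2:
            offset = 1 if kind == "R2" else 54
            fm = position_frequencies(
                align_repeats(windows, kind=kind, canonical_offset=offset)
            )
            fm.freq.to_csv(out_dir / f"frequencies_{kind}.tsv", sep="\t",
                           index_label="position")
            export_logo_data(fm, out_dir / f"logo_{kind}.tsv")

    # --- genome context --------------------------------------------------
    pairs = []
    if gff_path is not None:
        genes = read_gene_models(gff_path)
        class_by_id = {c.protein_id: c.family_class for c in members}
        for g in genes:
            g.family_class = class_by_id.get(g.gene_id)
        gene_by_id = {g.gene_id: g for g in genes}
        chromosome_distribution(genes).to_csv(
            out_dir / "chromosome_distribution.tsv", sep="\t", index=False
        )
        pairs = detect_sister_pairs(genes, max_distance=max_pair_distance)
        pd.DataFrame(
            [(p.gene_a, p.gene_b, p.chromosome, p.distance) for p in pairs],
            columns=["gene_a", "gene_b", "chromosome", "distance"],
        ).to_csv(out_dir / "sister_pairs.tsv", sep="\t", index=False)
        if not catalogue.empty:
            catalogue["chromosome"] = catalogue["gene_id"].map(
                lambda g: gene_by_id[g].chromosome if g in gene_by_id else None
            )
            catalogue["n_exons"] = catalogue["gene_id"].map(
                lambda g: gene_by_id[g].n_exons if g in gene_by_id else None
            )
    else:
        log.info("genome stage skipped: no gene models supplied")

    # --- expression ------------------------------------------------------
    if counts is not None:
        sf = size_factors(counts)
        nm = normalize(counts, sf)
        presence = presence_calls(nm, presence_threshold)
        clustering = cluster_genes(nm)
        sf.to_csv(out_dir / "size_factors.tsv", sep="\t")
        nm.to_csv(out_dir / "normalized.tsv", sep="\t", index_label="gene_id")
        presence.calls.to_csv(out_dir / "presence.tsv", sep="\t",
                              index_label="gene_id")
        export_heatmap(nm, clustering.order, path=out_dir / "heatmap.tsv")
        if not catalogue.empty:
            n_expressed = presence.calls.sum(axis=1)
            catalogue["organs_expressed"] = catalogue["gene_id"].map(
                lambda g: int(n_expressed.get(g, 0))
            )
    else:
        log.info("expression stage skipped: no count matrix supplied")

    # --- report ----------------------------------------------------------
    n_proteome = int(config.get("n_proteome", len(proteins)))
    n_tf = int(config.get("n_tf", 0)) or None
    report = summary_statistics(catalogue, n_proteome=n_proteome, n_tf=n_tf,
                                pairs=pairs)
    report["settings"] = {
        "seed": seed,
        "sub_rate": sub_rate,
        "presence_threshold": presence_threshold,
        "max_pair_distance": max_pair_distance,
        "profile_thresholds": {
            "R2": round(profile_r2.threshold, 6),
            "R3": round(profile_r3.threshold, 6),
        },
    }
    catalogue.to_csv(out_dir / "catalogue.tsv", sep="\t", index=False)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    with open(out_dir / "report.txt", "w") as fh:
        fh.write(format_report(report))
    return PipelineResult(catalogue=catalogue, report=report, out_dir=out_dir,
                          truth=truth)


def summary_statistics(
    catalogue: pd.DataFrame,
    n_proteome: int | None = None,
    n_tf: int | None = None,
    pairs=None,
) -> dict:
    """Family-level tallies recomputed from the catalogue rows."""
    if catalogue.empty:
        raise ValueError("empty catalogue")
    report: dict = {
        "n_family": int(len(catalogue)),
        "class_counts": catalogue["family_class"].value_counts().to_dict(),
    }
    if "chromosome" in catalogue.columns:
        from .genome import base_chromosome

        chroms = catalogue["chromosome"].dropna().map(
            lambda c: base_chromosome(str(c)) or "unanchored"
        )
        report["chromosome_counts"] = chroms.value_counts().sort_index().to_dict()
    if "n_exons" in catalogue.columns and catalogue["n_exons"].notna().any():
        r2r3 = catalogue[catalogue["family_class"] == "R2R3"]
        hist = {"1": 0, "2": 0, "3": 0, ">3": 0}
        for n in r2r3["n_exons"].dropna():
            hist[str(int(n)) if n <= 3 else ">3"] += 1
        report["exon_histogram_r2r3"] = hist
    if pairs:
        report["sister_pairs"] = [
            {"gene_a": p.gene_a, "gene_b": p.gene_b, "distance": p.distance}
            for p in pairs
        ]
    for motif_col in ("bhlh_motif", "sg7_motif", "sg7_2_motif"):
        if motif_col in catalogue.columns:
            report.setdefault("motif_positive", {})[motif_col] = int(
                catalogue[motif_col].sum()
            )
    if n_proteome and n_tf:
        share = family_statistics(len(catalogue), n_proteome, n_tf)
        report["pct_of_proteome"] = share.pct_of_proteome
        report["pct_of_tf"] = share.pct_of_tf
    return report


def format_report(report: dict) -> str:
    lines = ["multi-repeat MYB family summary", "=" * 32]
    settings = report.get("settings", {})
    if settings:
        lines.append("settings: " + json.dumps(settings, sort_keys=True))
    for key in sorted(report):
        if key == "settings":
            continue
        lines.append(f"{key}: {json.dumps(report[key], sort_keys=True)}")
    return "\n".join(lines) + "\n"


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level.upper()),
                        format="%(levelname)s %(name)s: %(message)s")
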