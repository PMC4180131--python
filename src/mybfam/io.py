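"""FASTA and tabular I/O helpers."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scan import MybClassification, ProteinRecord


def read_fasta(path) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=rec.id, seq=str(rec.seq).upper(), description=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[ProteinRecord], path) -> None:
    """FASTA wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_classification_tsv(classifications: list[MybClassification], path) -> None:
    """Per-protein classification table: class, repeat count, repeat
    coordinates (1-based inclusive) and scores."""
    with open(path, "w") as fh:
        fh.write("protein_id\tfamily_class\tn_repeats\trepeat_coords\trepeat_kinds\tscores\n")
        for c in classifications:
            coords = ";".join(f"{h.start}-{h.end}" for h in c.repeats)
            kinds = ";".join(h.repeat_kind for h in c.repeats)
            scores = ";".join(f"{h.score:.2f}" for h in c.repeats)
            fh.write(f"{c.protein_id}\t{c.family_class}\t{c.n_repeats}\t"
                     f"{coords}\t{kinds}\t{scores}\n")


def write_repeats_tsv(classifications: list[MybClassification], path) -> None:
    """Repeat hits as a BED-like table; coordinates are 1-based inclusive
    protein positions (documented in the header)."""
    with open(path, "w") as fh:
        fh.write("# protein repeat hits; start/end are 1-based inclusive "
                 "protein coordinates\n")
        fh.write("protein_id\tstart\tend\trepeat_kind\tscore\n")
        for c in classifications:
            for h in c.repeats:
                fh.write(f"{h.protein_id}\t{h.start}\t{h.end}\t"
                         f"{h.repeat_kind}\t{h.score:.3f}\n")
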