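"""Packaged reference data.

Ships a synthetic stand-in seed alignment for the R2/R3 repeat profiles
(user-replaceable; the published consensus query is not public), a
synthetic CDC5-type landmark protein, and the printed 75-gene catalogue
of the sugar-beet multi-repeat MYB family (the desk-check fixture for the
genome-context statistics).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome import GeneModel
from .profiles import (
    ProfileModel,
    R2_SPAN,
    R3_SPAN,
    build_profile,
    calibrate_threshold,
    landmark_rules_for_span,
)
from .scan import ProteinRecord

#: clade labels of the atypical multi-repeat classes in the catalogue
CLADE_CLASS_MAP = {"C37": "MYB3R", "C42": "MYB4R", "C41": "CDC5-like"}


def _data_path(name: str):
    return resources.files("mybfam.data").joinpath(name)


def load_seed_alignment(kind: str) -> list[str]:
    """Aligned seed repeats ('R2' or 'R3') as equal-length strings."""
    from .io import read_fasta

    name = f"synthetic_seed_{kind.lower()}.afa"
    with resources.as_file(_data_path(name)) as path:
        return [rec.seq for rec in read_fasta(path)]


def load_profiles(
    pseudocount: float = 1.0,
    calibrate: bool = True,
    n_decoys: int = 1000,
    seed: int = 2014,
) -> tuple[ProfileModel, ProfileModel]:
    """Default R2 and R3 profiles built from the packaged seed alignment,
    with thresholds calibrated against the background null."""
    r2 = build_profile(
        load_seed_alignment("r2"), pseudocount, name="R2",
        landmark_rules=landmark_rules_for_span(R2_SPAN),
        canonical_offset=R2_SPAN[0],
    )
    r3 = build_profile(
        load_seed_alignment("r3"), pseudocount, name="R3",
        landmark_rules=landmark_rules_for_span(R3_SPAN),
        canonical_offset=R3_SPAN[0],
    )
    if calibrate:
        calibrate_threshold(r2, n_decoys=n_decoys, seed=seed)
        calibrate_threshold(r3, n_decoys=n_decoys, seed=seed + 1)
    return r2, r3


def load_cdc5_landmark() -> ProteinRecord:
    from .io import read_fasta

    with resources.as_file(_data_path("synthetic_cdc5_landmark.fasta")) as path:
        return read_fasta(path)[0]


def load_catalogue() -> pd.DataFrame:
    """The printed 75-gene family catalogue with a derived family_class
    column (clade C37 -> MYB3R, C42 -> MYB4R, C41 -> CDC5-like, else R2R3)."""
    with resources.as_file(_data_path("bvmyb_catalogue.tsv")) as path:
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"chromosome": str}).fillna({"clade": "", "subgroup": "",
                                                            "landmarks": "", "function": ""})
    df["family_class"] = df["clade"].map(CLADE_CLASS_MAP).fillna("R2R3")
    return df


def catalogue_gene_models(df: pd.DataFrame | None = None) -> list[GeneModel]:
    """Catalogue rows as GeneModels (printed transcription-order coordinates
    are normalised; strand inferred from the printed order)."""
    if df is None:
        df = load_catalogue()
    genes = []
    for row in df.itertuples():
        strand = "+" if row.start <= row.end else "-"
        genes.append(
            GeneModel(
                gene_id=row.gene_id, chromosome=str(row.chromosome),
                strand=strand, start=int(row.start), end=int(row.end),
                family_class=row.family_class, n_exons_hint=int(row.n_exons),
            )
        )
    return genes
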