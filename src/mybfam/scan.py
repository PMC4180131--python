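"""MYB repeat scanning and family classification.

The scanner slides fixed-width repeat profiles (R2 and R3) over a protein,
keeps windows that clear the profile threshold and satisfy the tryptophan
landmark rules, resolves overlaps greedily by descending score, and
classifies the protein by its repeat count: two repeats define the dominant
R2R3 class, three the MYB3R class, four the MYB4R class; multi-repeat
proteins that are globally similar to a CDC5 landmark are set apart as
CDC5-like, and proteins with a single repeat are excluded from the
multi-repeat family set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .profiles import (
    ProfileModel,
    R2_SPAN,
    R3_SPAN,
    sliding_scores,
)

FAMILY_CLASSES = ("R2R3", "MYB3R", "MYB4R", "CDC5-like", "single-repeat", "non-MYB")

#: Classes counted as members of the multi-repeat MYB family.
MULTI_REPEAT_CLASSES = ("R2R3", "MYB3R", "MYB4R", "CDC5-like")


@dataclass
class ProteinRecord:
    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class RepeatHit:
    """One located MYB repeat (1-based inclusive protein coordinates)."""

    protein_id: str
    start: int
    end: int
    score: float
    repeat_kind: str = "unclassified"  # R2 | R3 | R1-like | unclassified
    #: canonical landmark position -> (observed residue, used allowed substitution)
    landmark_evidence: dict[int, tuple[str, bool]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MybClassification:
    protein_id: str
    family_class: str
    repeats: list[RepeatHit] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def is_family_member(self) -> bool:
        return self.family_class in MULTI_REPEAT_CLASSES


def _landmark_evidence(window: str, profile: ProfileModel) -> dict[int, tuple[str, bool]]:
    ev = {}
    for pos, allowed in profile.landmark_rules.items():
        residue = window[pos - 1]
        canonical = pos + profile.canonical_offset - 1
        ev[canonical] = (residue, residue != "W" and residue in allowed)
    return ev


def _resolve_overlaps(candidates: list[RepeatHit]) -> list[RepeatHit]:
    """Greedy selection by descending score, ties broken by leftmost start;
    accepted hits exclude any later candidate overlapping them."""
    chosen: list[RepeatHit] = []
    for hit in sorted(candidates, key=lambda h: (-h.score, h.start)):
        if all(hit.end < c.start or hit.start > c.end for c in chosen):
            chosen.append(hit)
    chosen.sort(key=lambda h: h.start)
    return chosen


def scan_protein(protein: ProteinRecord, profile: ProfileModel) -> list[RepeatHit]:
    """All non-overlapping windows scoring >= threshold that satisfy the
    profile's landmark rules, in sequence order.

    A protein shorter than the profile yields an empty list.
    """
    if not protein.seq:
        raise ValueError(f"{protein.id}: empty sequence")
    scores = sliding_scores(protein.seq, profile)
    candidates = []
    for offset in range(scores.size):
        if scores[offset] < profile.threshold:
            continue
        window = protein.seq[offset: offset + profile.length]
        if not profile.landmarks_satisfied(window):
            continue
        candidates.append(
            RepeatHit(
                protein_id=protein.id,
                start=offset + 1,
                end=offset + profile.length,
                score=float(scores[offset]),
                landmark_evidence=_landmark_evidence(window, profile),
            )
        )
    return _resolve_overlaps(candidates)


def classify_repeat_kind(
    hit: RepeatHit,
    protein: ProteinRecord,
    profile_r2: ProfileModel,
    profile_r3: ProfileModel,
    tie_tolerance: float = 0.1,
) -> str:
    """R2 vs R3 call for one repeat window by mean per-position log-odds
    under each profile, anchored at the hit start.

    A margin below `tie_tolerance` (nats per position) is reported as
    "unclassified". Relabelling of R1-like repeats in three-repeat proteins
    is positional and done in :func:`scan_repeats`.
    """
    start = hit.start - 1
    means = {}
    for prof in (profile_r2, profile_r3):
        window = protein.seq[start: start + prof.length]
        if not window:
            raise ValueError("hit outside protein")
        means[prof.name] = prof.score_window(window) / len(window)
    (k1, m1), (k2, m2) = sorted(means.items(), key=lambda kv: -kv[1])
    if m1 - m2 < tie_tolerance:
        return "unclassified"
    return k1


def scan_repeats(
    protein: ProteinRecord,
    profile_r2: ProfileModel,
    profile_r3: ProfileModel,
    tie_tolerance: float = 0.1,
) -> list[RepeatHit]:
    """Scan with both repeat profiles, jointly resolve overlaps, and assign
    repeat kinds (including the positional R1-like relabelling)."""
    candidates = scan_protein(protein, profile_r2) + scan_protein(protein, profile_r3)
    hits = _resolve_overlaps(candidates)
    for hit in hits:
        hit.repeat_kind = classify_repeat_kind(
            hit, protein, profile_r2, profile_r3, tie_tolerance
        )
    # In a three-repeat protein the repeat immediately upstream of an R2-R3
    # pair is the remnant first repeat (R1-like).
    if len(hits) == 3:
        kinds = [h.repeat_kind for h in hits]
        if kinds[1] == "R2" and kinds[2] == "R3":
            hits[0].repeat_kind = "R1-like"
    return hits


def global_identity(seq_a: str, seq_b: str) -> float:
    """Identity fraction of a global alignment (BLOSUM62, gap open -10,
    extend -1): matches over alignment columns."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a)


def classify_protein(
    hits: list[RepeatHit],
    protein: ProteinRecord,
    cdc5_landmark: ProteinRecord | None = None,
    cdc5_identity_cutoff: float = 0.4,
) -> MybClassification:
    """Family class from the repeat count; the CDC5 similarity check
    overrides the count class for multi-repeat proteins.

    0 hits -> non-MYB; 1 -> single-repeat (excluded from the family set);
    2 -> R2R3; 3 -> MYB3R; 4 -> MYB4R.
    """
    n = len(hits)
    if n == 0:
        family = "non-MYB"
    elif n == 1:
        family = "single-repeat"
    elif n == 2:
        family = "R2R3"
    elif n == 3:
        family = "MYB3R"
    else:
        family = "MYB4R"
    if n >= 2 and cdc5_landmark is not None:
        if global_identity(protein.seq, cdc5_landmark.seq) > cdc5_identity_cutoff:
            family = "CDC5-like"
    return MybClassification(protein_id=protein.id, family_class=family, repeats=list(hits))


@dataclass
class DomainExtract:
    """Combined R2+R3 domain mapped onto canonical positions 1-104."""

    protein_id: str
    sequence: str
    #: canonical position -> 1-based protein coordinate
    mapping: dict[int, int]
    #: full protein sequence the mapping refers into
    protein_seq: str = ""

    def residue_at(self, canonical_pos: int) -> str | None:
        """Residue at a canonical position, or None when unmapped."""
        coord = self.mapping.get(canonical_pos)
        if coord is None or not self.protein_seq:
            return None
        return self.protein_seq[coord - 1]


def extract_domain(
    classification: MybClassification, protein: ProteinRecord
) -> DomainExtract:
    """Map the R2 and R3 windows of an R2R3 protein onto canonical domain
    numbering (R2 = 1-53, R3 = 54-104) and return the mapping table.

    Raises for proteins that are not classified R2R3 or whose two repeats
    are not an ordered R2, R3 pair.
    """
    if classification.family_class != "R2R3":
        raise ValueError(
            f"{classification.protein_id}: extract_domain requires an R2R3 "
            f"protein, got {classification.family_class}"
        )
    kinds = [h.repeat_kind for h in classification.repeats]
    try:
        r2 = classification.repeats[kinds.index("R2")]
        r3 = classification.repeats[kinds.index("R3")]
    except ValueError as exc:
        raise ValueError(
            f"{classification.protein_id}: repeats are {kinds}, need one R2 and one R3"
        ) from exc
    if r3.start <= r2.start:
        raise ValueError(f"{classification.protein_id}: R3 repeat precedes R2")

    mapping: dict[int, int] = {}
    for canonical in range(R2_SPAN[0], R2_SPAN[1] + 1):
        coord = r2.start + (canonical - R2_SPAN[0])
        if coord <= r2.end:
            mapping[canonical] = coord
    for canonical in range(R3_SPAN[0], R3_SPAN[1] + 1):
        coord = r3.start + (canonical - R3_SPAN[0])
        if coord <= r3.end:
            mapping[canonical] = coord

    seq = (
        protein.seq[r2.start - 1: r2.end]
        + protein.seq[r3.start - 1: r3.end]
    )
    return DomainExtract(
        protein_id=protein.id, sequence=seq, mapping=mapping,
        protein_seq=protein.seq,
    )


def scan_proteome(
    proteins: list[ProteinRecord],
    profile_r2: ProfileModel,
    profile_r3: ProfileModel,
    cdc5_landmark: ProteinRecord | None = None,
    cdc5_identity_cutoff: float = 0.4,
) -> list[MybClassification]:
    """Classify every protein of a proteome; proteins shorter than both
    profiles are reported as non-MYB."""
    out = []
    for protein in proteins:
        if not protein.seq:
            warnings.warn(f"skipping empty sequence {protein.id}")
            continue
        hits = scan_repeats(protein, profile_r2, profile_r3)
        out.append(
            classify_protein(hits, protein, cdc5_landmark, cdc5_identity_cutoff)
        )
    return out
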