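"""Functional motif and diagnostic-residue annotation.

Covers the bHLH-interaction consensus [D/E]Lx2[R/K]x3Lx6Lx3R found in the
R3 repeat of MYBs that partner basic helix-loop-helix cofactors, the
C-terminal flavonol-regulator motifs S7/SG7 (GRTxRSxMK) and SG7-2
([W/x][L/x]LS), and the diagnostic residues at canonical domain positions
44, 60, 89 and 98 (position 89 separates anthocyanin-type (A) from
proanthocyanidin-type (G) regulators, with isoleucine marking the
beet-specific C21 type).

Patterns use a Prosite-like bracket notation: `[D/E]` is an alternative
set, `x` a wildcard, and a trailing integer repeats the element
(`x3` = three wildcards). A set containing `x` (as in `[W/x]`) matches
anything and counts as a wildcard for mismatch purposes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .scan import DomainExtract, ProteinRecord

#: bHLH-interaction consensus of the R3 repeat; total width 20 with the
#: subscripts read as exact wildcard counts.
BHLH_PATTERN_STR = "[D/E]Lx2[R/K]x3Lx6Lx3R"
#: subgroup-7 (flavonol regulator) C-terminal motif
SG7_PATTERN_STR = "GRTxRSxMK"
#: variant wildcard placement under which the known one-substitution
#: example GRTSRWAMQ carries a single fixed-position mismatch
SG7_VARIANT_PATTERN_STR = "GRTxRSxMx"


@dataclass
class MotifPattern:
    """Element list: each element is (allowed residue set | None, count);
    None means wildcard. `region` is "global" or "cterm" (last `window`
    residues)."""

    name: str
    elements: list[tuple[frozenset | None, int]]
    region: str = "global"
    window: int | None = None

    @property
    def width(self) -> int:
        return sum(count for _, count in self.elements)

    @property
    def slots(self) -> list[frozenset | None]:
        """Pattern expanded to one entry per position."""
        out = []
        for allowed, count in self.elements:
            out.extend([allowed] * count)
        return out


@dataclass
class MotifHit:
    protein_id: str
    motif: str
    start: int  # 1-based
    matched: str
    mismatches: int
    tier: int | None = None  # SG7-2 match tier (optional positions matched)


@dataclass
class ResidueDiagnostics:
    protein_id: str
    residues: dict[int, str | None]  # canonical 44, 60, 89, 98
    interpretation_89: str
    #: last tryptophan landmark replaced (F or C, the atypical cases)
    atypical_98: bool
    #: residue outside the tolerated set {W, F, C} entirely
    invalid_98: bool


_TOKEN = re.compile(r"\[([A-Zx](?:/[A-Zx])*)\](\d*)|([A-Zx])(\d*)")


def parse_pattern(pattern: str, name: str | None = None,
                  region: str = "global", window: int | None = None) -> MotifPattern:
    """Parse bracket notation into a MotifPattern."""
    elements = []
    pos = 0
    while pos < len(pattern):
        m = _TOKEN.match(pattern, pos)
        if m is None:
            raise ValueError(f"cannot parse pattern at {pattern[pos:]!r}")
        if m.group(1) is not None:
            residues = set(m.group(1).split("/"))
            count = int(m.group(2) or 1)
        else:
            residues = {m.group(3)}
            count = int(m.group(4) or 1)
        allowed = None if "x" in residues else frozenset(residues)
        elements.append((allowed, count))
        pos = m.end()
    return MotifPattern(name=name or pattern, elements=elements,
                        region=region, window=window)


BHLH_PATTERN = parse_pattern(BHLH_PATTERN_STR, name="bHLH-interaction")
SG7_PATTERN = parse_pattern(SG7_PATTERN_STR, name="SG7", region="cterm", window=50)
SG7_VARIANT_PATTERN = parse_pattern(SG7_VARIANT_PATTERN_STR, name="SG7-variant",
                                    region="cterm", window=50)


def scan_motif(protein: ProteinRecord, pattern: MotifPattern,
               max_mismatch: int = 0) -> list[MotifHit]:
    """All placements whose fixed-position mismatch count is within
    tolerance, in left-to-right order. Wildcards are free."""
    seq = protein.seq
    slots = pattern.slots
    width = len(slots)
    if not seq or len(seq) < width:
        return []
    first = 0
    if pattern.region == "cterm" and pattern.window is not None:
        first = max(0, len(seq) - pattern.window)
    hits = []
    for offset in range(first, len(seq) - width + 1):
        window = seq[offset: offset + width]
        mism = sum(
            1 for ch, allowed in zip(window, slots)
            if allowed is not None and ch not in allowed
        )
        if mism <= max_mismatch:
            hits.append(MotifHit(protein_id=protein.id, motif=pattern.name,
                                 start=offset + 1, matched=window, mismatches=mism))
    return hits


def count_motif_positive(proteins: list[ProteinRecord], pattern: MotifPattern,
                         max_mismatch: int = 0) -> int:
    """Number of proteins carrying at least one hit."""
    return sum(bool(scan_motif(p, pattern, max_mismatch)) for p in proteins)


def scan_sg7_terminal(protein: ProteinRecord, window: int = 10) -> MotifHit | None:
    """SG7-2 ([W/x][L/x]LS) search restricted to the last `window` residues.

    Positions 3 (L) and 4 (S) are required; a W at position 1 and/or an L
    at position 2 upgrade the match tier (0 = base, 2 = full WLLS). The
    best (highest-tier, then most C-terminal) match is returned.
    """
    if window < 4:
        raise ValueError("window must be >= 4")
    seq = protein.seq
    if len(seq) < 4:
        return None
    region_start = max(0, len(seq) - window)
    best: MotifHit | None = None
    for offset in range(region_start, len(seq) - 3):
        quad = seq[offset: offset + 4]
        if quad[2] != "L" or quad[3] != "S":
            continue
        tier = int(quad[0] == "W") + int(quad[1] == "L")
        hit = MotifHit(protein_id=protein.id, motif="SG7-2", start=offset + 1,
                       matched=quad, mismatches=0, tier=tier)
        if best is None or (hit.tier, hit.start) >= (best.tier, best.start):
            best = hit
    return best


#: residue -> functional reading of canonical position 89
POSITION_89_MAP = {
    "A": "anthocyanin-type",
    "G": "proanthocyanidin-type",
    "I": "C21-type",
}

#: residues tolerated at the last tryptophan landmark (canonical 98)
CANONICAL_98 = frozenset("WFC")

DIAGNOSTIC_POSITIONS = (44, 60, 89, 98)


def residue_diagnostics(domain: DomainExtract) -> ResidueDiagnostics:
    """Read the diagnostic residues at canonical 44/60/89/98 off an
    extracted domain; unmapped positions are reported as unknown (None)."""
    residues = {pos: domain.residue_at(pos) for pos in DIAGNOSTIC_POSITIONS}
    r89 = residues[89]
    interpretation = POSITION_89_MAP.get(r89, "other") if r89 else "other"
    r98 = residues[98]
    return ResidueDiagnostics(
        protein_id=domain.protein_id, residues=residues,
        interpretation_89=interpretation,
        atypical_98=r98 is not None and r98 != "W",
        invalid_98=r98 is not None and r98 not in CANONICAL_98,
    )
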