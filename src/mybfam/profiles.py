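"""Position-specific scoring profiles for MYB repeat detection.

A MYB repeat is an imperfect ~52-residue sequence unit forming three
alpha-helices; the second and third helix build a helix-turn-helix with
regularly spaced tryptophans forming the hydrophobic core. The dominant
plant family carries two adjacent repeats (R2 and R3) spanning ~104
residues including the linker. We model each repeat as a fixed-width
log-odds profile (PSSM) built from a small seed alignment, plus hard
"landmark" rules for the tryptophan core positions, where only the
substitutions observed in plant MYBs are tolerated.

Canonical numbering of the combined domain: R2 covers positions 1-53,
R3 covers positions 54-104. Tryptophan landmarks sit at 7/26/45 (R2)
and 60/79/98 (R3); the first R3 tryptophan (W60) may be replaced by
F/I/L/Y and the last one (W98) by F/C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Synthetic stand-in consensus for the R2 repeat (canonical positions 1-53).
#: Residues the family fixes or strongly prefers are placed at their canonical
#: positions: G4, E10, D11, L14, G35, R38, K41, C43, R44, R46, N49, L51, P53,
#: with tryptophans at 7, 26 and 45.
R2_CONSENSUS = "LKKGPTWSVEDAILVDYIKAHGEGKWNAVARSTGGLNRCGKSCRWRANNYLRP"

#: Synthetic stand-in consensus for the R3 repeat (canonical positions 54-104):
#: E64, G76, I82, A83, R89, T90, N92, K95, N96 with tryptophans at 60, 79, 98.
R3_CONSENSUS = "NEIKNYWNTHELKKKLIKSGIDGPQWHLIANHLEGRTDNEIKNHWNSTLKR"

#: Canonical spans of the two repeat windows in the combined domain.
R2_SPAN = (1, 53)
R3_SPAN = (54, 104)

#: Tryptophan landmark rules, keyed by canonical position. The allowed sets
#: beyond W itself are the substitutions tolerated in plant MYB domains:
#: W60 -> F/I/L/Y, W98 -> F/C. The remaining core tryptophans are strict.
LANDMARK_RULES_CANONICAL: dict[int, frozenset] = {
    7: frozenset("W"),
    26: frozenset("W"),
    45: frozenset("W"),
    60: frozenset("WFILY"),
    79: frozenset("W"),
    98: frozenset("WFC"),
}


def landmark_rules_for_span(span: tuple[int, int]) -> dict[int, frozenset]:
    """Landmark rules restricted to a canonical span, re-keyed to 1-based
    window positions."""
    lo, hi = span
    return {
        pos - lo + 1: allowed
        for pos, allowed in LANDMARK_RULES_CANONICAL.items()
        if lo <= pos <= hi
    }


@dataclass
class ProfileModel:
    """Fixed-width log-odds profile over one MYB repeat.

    Attributes
    ----------
    name : str
        "R2" or "R3" (or a user label).
    length : int
        Number of window positions.
    log_odds : ndarray, shape (length, 20)
        Per-position per-residue scores in nats. Unknown residues (X)
        score 0 (background).
    background : ndarray, shape (20,)
        Residue frequencies of the seed alignment, used for decoys and
        null calibration.
    landmark_rules : dict[int, frozenset]
        1-based window position -> allowed residue set. A window is only
        a hit when every landmark position carries an allowed residue.
    threshold : float
        Minimum window score for a hit.
    canonical_offset : int
        Canonical position of window position 1 (1 for R2, 54 for R3).
    """

    name: str
    length: int
    log_odds: np.ndarray
    background: np.ndarray
    landmark_rules: dict[int, frozenset] = field(default_factory=dict)
    threshold: float = 0.0
    canonical_offset: int = 1

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.log_odds.argmax(axis=1))

    def score_window(self, window: str) -> float:
        """Plain sum of per-position log-odds; non-standard residues add 0."""
        total = 0.0
        for i, ch in enumerate(window[: self.length]):
            j = AA_INDEX.get(ch)
            if j is not None:
                total += self.log_odds[i, j]
        return total

    def landmarks_satisfied(self, window: str) -> bool:
        for pos, allowed in self.landmark_rules.items():
            if pos - 1 >= len(window) or window[pos - 1] not in allowed:
                return False
        return True


def build_profile(
    seed_repeats: list[str],
    pseudocount: float = 1.0,
    *,
    name: str = "repeat",
    landmark_rules: dict[int, frozenset] | None = None,
    canonical_offset: int = 1,
    background: np.ndarray | None = None,
) -> ProfileModel:
    """Build a log-odds profile from an aligned (equal-length) repeat set.

    Per position p and residue a:

        score(p, a) = log((count(p, a) + pseudocount * bg(a)) / (n + pseudocount))
                      - log(bg(a))

    which is the log of the pseudocount-smoothed column frequency over the
    background frequency. The background-expected score per column is
    -KL(bg || smoothed column) <= 0.
    """
    if not seed_repeats:
        raise ValueError("empty seed alignment")
    if len(seed_repeats) < 2:
        raise ValueError("need at least 2 seed sequences")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    length = len(seed_repeats[0])
    if any(len(s) != length for s in seed_repeats):
        raise ValueError("ragged seed alignment: sequences differ in length")

    counts = np.zeros((length, 20))
    for seq in seed_repeats:
        for i, ch in enumerate(seq.upper()):
            j = AA_INDEX.get(ch)
            if j is not None:
                counts[i, j] += 1

    if background is None:
        total = counts.sum(axis=0)
        background = (total + 0.01) / (total + 0.01).sum()
    n = len(seed_repeats)
    freq = (counts + pseudocount * background) / (n + pseudocount)
    log_odds = np.log(freq) - np.log(background)

    return ProfileModel(
        name=name,
        length=length,
        log_odds=log_odds,
        background=np.asarray(background, dtype=float),
        landmark_rules=dict(landmark_rules or {}),
        canonical_offset=canonical_offset,
    )


def sample_background_sequence(rng: np.random.Generator, length: int,
                               background: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=background / background.sum())
    return "".join(AMINO_ACIDS[i] for i in idx)


def calibrate_threshold(
    profile: ProfileModel,
    n_decoys: int = 1000,
    decoy_length: int = 300,
    quantile: float = 0.999,
    seed: int = 2014,
) -> float:
    """Set the hit threshold from the null max-window score distribution.

    Scores `n_decoys` random sequences drawn from the profile background and
    takes the given quantile of the per-sequence maximum window score. The
    profile is updated in place and the threshold returned.
    """
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_decoys)
    for d in range(n_decoys):
        seq = sample_background_sequence(rng, decoy_length, profile.background)
        scores = sliding_scores(seq, profile)
        maxima[d] = scores.max() if scores.size else -np.inf
    profile.threshold = float(np.quantile(maxima, quantile))
    return profile.threshold


def encode_sequence(seq: str) -> np.ndarray:
    """Residues as 0..19 indices; unknown letters map to 20."""
    arr = np.full(len(seq), 20, dtype=np.int64)
    for i, ch in enumerate(seq.upper()):
        j = AA_INDEX.get(ch)
        if j is not None:
            arr[i] = j
    return arr


def sliding_scores(seq: str, profile: ProfileModel) -> np.ndarray:
    """Window score at every offset (vectorised); empty if seq is shorter
    than the profile."""
    enc = encode_sequence(seq)
    L, W = len(enc), profile.length
    if L < W:
        return np.empty(0)
    # pad the score matrix with a zero column for unknown residues
    lo = np.hstack([profile.log_odds, np.zeros((W, 1))])
    n_win = L - W + 1
    idx = np.arange(W)[None, :] + np.arange(n_win)[:, None]
    return lo[np.arange(W)[None, :], enc[idx]].sum(axis=1)
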