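"""Repeat-domain conservation profiling (sequence-logo data).

Because repeat windows are fixed-width and landmark-anchored, repeats of
one kind already share coordinates: the "alignment" is column stacking.
Per-position residue frequencies, information content in bits
(log2 20 - entropy, no small-sample correction) and conservation classes
(invariant / highly conserved / variable) reproduce what a sequence logo
of the family displays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import AMINO_ACIDS

GAP_CHARS = {"-", ".", "*"}

MAX_BITS = float(np.log2(20))


@dataclass
class RepeatBlock:
    """Columnar stack of same-kind repeat windows with canonical numbering."""

    kind: str
    sequences: list[str]
    canonical_offset: int = 1

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    @property
    def positions(self) -> list[int]:
        return list(range(self.canonical_offset, self.canonical_offset + self.width))


@dataclass
class FrequencyMatrix:
    """Per-position amino-acid relative frequencies over an aligned block."""

    freq: pd.DataFrame  # index = canonical positions, columns = residues
    n_sequences: int
    information: pd.Series  # bits per position

    @property
    def positions(self) -> list[int]:
        return list(self.freq.index)


@dataclass
class ConservationCall:
    position: int
    conservation: str  # invariant | highly_conserved | variable
    modal_residue: str
    modal_frequency: float


def align_repeats(
    sequences: list[str],
    kind: str | None = None,
    kinds: list[str] | None = None,
    canonical_offset: int = 1,
) -> RepeatBlock:
    """Stack fixed-width repeat windows of one kind into a block.

    Mixed repeat kinds or ragged windows raise; sequences keep their
    columns, so recorded substitutions stay at their canonical positions.
    """
    if not sequences:
        raise ValueError("no repeats to align")
    if kinds is not None:
        distinct = set(kinds)
        if len(distinct) > 1:
            raise ValueError(f"mixed repeat kinds: {sorted(distinct)}")
        kind = kind or distinct.pop()
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise ValueError("repeat windows differ in width")
    return RepeatBlock(kind=kind or "repeat", sequences=[s.upper() for s in sequences],
                       canonical_offset=canonical_offset)


def position_frequencies(block: RepeatBlock) -> FrequencyMatrix:
    """Relative frequencies by direct tally, gaps excluded from the
    denominator; information = log2 20 - entropy."""
    if not block.sequences:
        raise ValueError("empty block")
    counts = pd.DataFrame(
        0.0, index=block.positions, columns=list(AMINO_ACIDS)
    )
    for seq in block.sequences:
        for pos, ch in zip(block.positions, seq):
            if ch in GAP_CHARS:
                continue
            if ch in counts.columns:
                counts.loc[pos, ch] += 1
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-gap column in block")
    freq = counts.div(totals, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq.values > 0, freq.values * np.log2(freq.values), 0.0)
    entropy = -plogp.sum(axis=1)
    information = pd.Series(MAX_BITS - entropy, index=freq.index).clip(0.0, MAX_BITS)
    return FrequencyMatrix(freq=freq, n_sequences=len(block.sequences),
                           information=information)


def conservation_calls(
    fm: FrequencyMatrix, high_cutoff: float = 0.9
) -> list[ConservationCall]:
    """Classify every canonical position by its modal residue frequency:
    1.0 -> invariant, >= high_cutoff -> highly_conserved, else variable."""
    if not 0.5 < high_cutoff < 1:
        raise ValueError("high_cutoff must be in (0.5, 1)")
    calls = []
    for pos in fm.positions:
        row = fm.freq.loc[pos]
        modal = row.idxmax()
        f = float(row[modal])
        if f >= 1.0 - 1e-12:
            klass = "invariant"
        elif f >= high_cutoff:
            klass = "highly_conserved"
        else:
            klass = "variable"
        calls.append(ConservationCall(position=pos, conservation=klass,
                                      modal_residue=modal, modal_frequency=f))
    return sorted(calls, key=lambda c: c.position)


def export_logo_data(fm: FrequencyMatrix, path=None) -> pd.DataFrame:
    """Stack heights (frequency x information) per position and residue,
    the quantity a sequence-logo renderer draws."""
    heights = fm.freq.mul(fm.information, axis=0)
    if path is not None:
        heights.to_csv(path, sep="\t", index_label="position")
    return heights


def plot_logo(fm: FrequencyMatrix, path):
    """Best-effort stacked-bar logo rendering (not a faithful sequence-logo
    facsimile)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    heights = export_logo_data(fm)
    fig, ax = plt.subplots(figsize=(max(6, len(heights) / 6), 3))
    bottom = np.zeros(len(heights))
    for residue in heights.columns:
        vals = heights[residue].values
        if vals.sum() == 0:
            continue
        ax.bar(heights.index, vals, bottom=bottom, width=0.9, label=residue)
        bottom += vals
    ax.set_xlabel("canonical position")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
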