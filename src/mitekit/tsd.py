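"""TSD position-frequency profiling and hAT family assignment.

Target site duplications of hAT-superfamily transposons are 8 bp; the
two hAT families differ partly in target preference, and the Buster
family's TSD consensus carries a central TA (5'-nnnTAnnn-3'). Observed
TSDs are tallied into a position-frequency matrix, a dominance-based
consensus is called, and the family is assigned from the central
dinucleotide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

_BASES = "ACGT"
_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PositionFrequencyMatrix:
    length: int
    counts: np.ndarray      # (length, 4) over A,C,G,T
    n_sites: int
    n_excluded: np.ndarray  # per position: sites with N there

    def frequencies(self) -> np.ndarray:
        valid = (self.n_sites - self.n_excluded)[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(valid > 0, self.counts / valid, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, columns=list(_BASES),
            index=[f"pos{i + 1}" for i in range(self.length)],
        )


def build_pfm(tsds: Sequence[str]) -> PositionFrequencyMatrix:
    """Tally per-position base counts over equal-length TSD sites."""
    if not tsds:
        raise ValueError("need at least one TSD site")
    L = len(tsds[0])
    if any(len(t) != L for t in tsds):
        raise ValueError("TSD sites have mixed lengths")
    counts = np.zeros((L, 4), dtype=np.int64)
    excluded = np.zeros(L, dtype=np.int64)
    for site in tsds:
        for i, ch in enumerate(site.upper()):
            j = _INDEX.get(ch)
            if j is None:
                excluded[i] += 1
            else:
                counts[i, j] += 1
    return PositionFrequencyMatrix(L, counts, len(tsds), excluded)


def call_consensus(pfm: PositionFrequencyMatrix, dominance: float = 0.5) -> str:
    """Dominance consensus: a base is called where its frequency meets
    ``dominance``, otherwise the position is written as ``n``."""
    freqs = pfm.frequencies()
    out = []
    for i in range(pfm.length):
        j = int(np.argmax(freqs[i]))
        out.append(_BASES[j] if freqs[i, j] >= dominance else "n")
    return "".join(out)


def classify_family(consensus: str) -> str:
    """Assign hAT family from an 8-bp TSD consensus.

    ``buster`` iff the central dinucleotide (positions 4-5, 1-based)
    is TA; everything else is ``unassigned``. The classifier is binary
    because only the Buster target motif is modelled here; other
    family motifs can be added as further rules.
    """
    if len(consensus) != 8:
        raise ValueError(f"TSD consensus must be 8 bp, got {len(consensus)}")
    return "buster" if consensus[3].upper() == "T" and consensus[4].upper() == "A" else "unassigned"


def information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Shannon information (bits) per position, as in a sequence logo."""
    freqs = pfm.frequencies()
    ic = np.zeros(pfm.length)
    for i in range(pfm.length):
        h = 0.0
        for f in freqs[i]:
            if f > 0:
                h -= f * math.log2(f)
        ic[i] = 2.0 - h
    return ic


def text_logo(pfm: PositionFrequencyMatrix) -> str:
    """Crude text rendering of the per-position information content."""
    ic = information_content(pfm)
    cons = call_consensus(pfm)
    lines = ["pos base bits"]
    for i in range(pfm.length):
        bar = "#" * int(round(10 * ic[i] / 2.0))
        lines.append(f"{i + 1:>3} {cons[i]:>4} {ic[i]:5.2f} {bar}")
    return "\n".join(lines)
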