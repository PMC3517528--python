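"""Reference-anchored stacking of element copies and majority consensus.

Copies are each aligned globally to the reference element and projected
into a single gapped matrix sharing the reference coordinate system;
copy-specific insertions open shared insertion columns (one block per
reference position, sized to the longest insertion observed there).
The family consensus is then read column by column as the most common
residue — the standard way a transposable-element family sequence is
reconstructed from its dispersed, individually decayed copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .mining import ElementCopy
from .seqio import SequenceRecord, parse_species

GAP = "-"
_SYMBOLS = "ACGT-"


@dataclass
class StackedAlignment:
    """Gapped matrix of rows over {A,C,G,T,N,-}, all equal length."""

    row_ids: list[str]
    species: list[Optional[str]]
    matrix: list[str]

    def __post_init__(self) -> None:
        if len(self.matrix) < 2:
            raise ValueError("alignment needs at least 2 rows")
        ncol = len(self.matrix[0])
        if ncol < 1 or any(len(r) != ncol for r in self.matrix):
            raise ValueError("alignment rows must share a positive length")

    @property
    def n_rows(self) -> int:
        return len(self.matrix)

    @property
    def n_cols(self) -> int:
        return len(self.matrix[0])


@dataclass
class ConsensusProfile:
    counts: np.ndarray          # (n_cols, 5) over A,C,G,T,-
    consensus: str              # gap/low-coverage columns dropped
    coverage: np.ndarray        # per-column non-gap fraction
    kept_columns: np.ndarray    # indices of columns present in consensus


def default_scores() -> dict:
    return dict(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)


def global_align(a: str, b: str, scores: dict | None = None) -> tuple[str, str]:
    """Optimal global alignment of two sequences; returns gapped strings."""
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    s = scores or default_scores()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = s["match"]
    aligner.mismatch_score = s["mismatch"]
    aligner.open_gap_score = s["gap_open"]
    aligner.extend_gap_score = s["gap_extend"]
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _project(ref_gapped: str, copy_gapped: str, ref_len: int):
    """Split a pairwise alignment into per-reference-position pieces.

    Returns (bases, insertions): ``bases[i]`` is the copy symbol over
    reference position i (a base or '-'); ``insertions[i]`` is the copy
    sequence inserted immediately before reference position i
    (``insertions[ref_len]`` holds a trailing insertion).
    """
    bases = [GAP] * ref_len
    insertions = [""] * (ref_len + 1)
    ref_pos = 0
    for rc, cc in zip(ref_gapped, copy_gapped):
        if rc == GAP:
            insertions[ref_pos] += cc
        else:
            bases[ref_pos] = cc
            ref_pos += 1
    return bases, insertions


def stack_on_reference(copies: Sequence[ElementCopy], reference: SequenceRecord,
                       scores: dict | None = None) -> StackedAlignment:
    """Anchor every copy to the reference coordinate system.

    The reference is the first row. Insertions relative to the
    reference are merged into shared columns: at each reference
    position the insertion block spans the longest insertion any copy
    carries there, shorter insertions padded right with gaps.
    """
    if not copies:
        raise ValueError("need at least one copy to stack")
    ref = reference.residues
    n = len(ref)
    projections = []
    for c in copies:
        rg, cg = global_align(ref, c.copy_seq, scores)
        projections.append(_project(rg, cg, n))
    ins_len = [0] * (n + 1)
    for _, ins in projections:
        for i, s in enumerate(ins):
            ins_len[i] = max(ins_len[i], len(s))

    def build_row(bases, ins):
        parts = []
        for i in range(n + 1):
            if ins_len[i]:
                parts.append(ins[i].ljust(ins_len[i], GAP))
            if i < n:
                parts.append(bases[i])
        return "".join(parts)

    ref_row = build_row(list(ref), [""] * (n + 1))
    rows = [ref_row] + [build_row(b, ins) for b, ins in projections]
    ids = [reference.id] + [c.copy_id or f"copy{i+1}" for i, c in enumerate(copies)]
    species = [parse_species(i) for i in ids]
    return StackedAlignment(ids, species, rows)


def read_alignment(path, species_delimiter: str = "|") -> StackedAlignment:
    """Load an externally produced multiple alignment (aligned FASTA)."""
    from Bio import AlignIO

    aln = AlignIO.read(str(path), "fasta")
    ids = [r.id for r in aln]
    rows = [str(r.seq).upper().replace(".", GAP) for r in aln]
    return StackedAlignment(ids, [parse_species(i, species_delimiter) for i in ids], rows)


def write_alignment(aln: StackedAlignment, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.row_ids, aln.matrix):
            fh.write(f">{rid}\n{row}\n")


def majority_consensus(aln: StackedAlignment, min_coverage: float = 0.5,
                       tie_rule: str = "alphabetical") -> ConsensusProfile:
    """Per-column majority call over {A,C,G,T,-}; N is not counted.

    Columns whose winning symbol is the gap, or whose non-gap coverage
    falls below ``min_coverage``, are dropped from the consensus
    string. Ties among bases are resolved alphabetically (A<C<G<T); a
    base beats the gap on an exact tie so that borderline columns are
    retained rather than silently deleted.
    """
    if tie_rule != "alphabetical":
        raise ValueError(f"unsupported tie rule: {tie_rule!r}")
    ncol = aln.n_cols
    nrow = aln.n_rows
    counts = np.zeros((ncol, 5), dtype=np.int64)
    idx = {s: j for j, s in enumerate(_SYMBOLS)}
    for row in aln.matrix:
        for i, ch in enumerate(row):
            j = idx.get(ch)
            if j is not None:
                counts[i, j] += 1
    coverage = counts[:, :4].sum(axis=1) / nrow
    cons_chars = []
    kept = []
    for i in range(ncol):
        col = counts[i]
        best_base = int(np.argmax(col[:4]))  # argmax keeps alphabetical tie rule
        if col[4] > col[best_base] or col[:4].sum() == 0:
            continue  # gap wins the column
        if coverage[i] < min_coverage:
            continue
        cons_chars.append(_SYMBOLS[best_base])
        kept.append(i)
    return ConsensusProfile(
        counts=counts,
        consensus="".join(cons_chars),
        coverage=coverage,
        kept_columns=np.array(kept, dtype=np.int64),
    )
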