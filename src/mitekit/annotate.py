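"""Structural annotation of mined element copies.

Each copy is annotated for terminal inverted repeats (TIRs), target
site duplications (TSDs), coding capacity (a six-frame ORF scan) and
gene context, and classified as an intact MITE, a degenerate copy or a
full-length-element candidate. MITEs of the hAT superfamily carry
short TIRs (11 bp for the family modelled here) and are flanked by an
8-bp TSD created on insertion; a copy retaining both hallmarks at
near-reference length is evidence of recent mobilization, while long
degenerate copies retaining TIRs are relics of a former autonomous
element.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .mining import ElementCopy
from .seqio import GenomicInterval, revcomp

CODON_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class TIRAnnotation:
    length: int
    left_seq: str
    right_seq: str
    mismatches: int
    present: bool


@dataclass
class TSDAnnotation:
    length: int
    left_seq: str
    right_seq: str
    mismatches: int
    present: bool


@dataclass
class CopyClass:
    label: str  # intact_mite | degenerate | full_length_candidate
    rationale: str


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def detect_tir(copy_seq: str, min_tir: int = 5, max_tir: int = 30,
               budget: int = 1) -> TIRAnnotation:
    """Find the longest terminal inverted repeat within a mismatch budget.

    Scans candidate lengths L from ``max_tir`` down to ``min_tir`` and
    compares the copy prefix of length L with the reverse complement of
    its suffix; the first (longest) L whose Hamming distance is within
    ``budget`` is called. When no L qualifies the annotation records
    the best candidate (fewest mismatches, longest on ties) with
    ``present=False``.
    """
    if len(copy_seq) < 2 * max_tir:
        raise ValueError(
            f"copy of length {len(copy_seq)} too short for max_tir={max_tir}"
        )
    best: Optional[tuple[int, int]] = None  # (mismatches, L)
    for L in range(max_tir, min_tir - 1, -1):
        left = copy_seq[:L]
        right = copy_seq[-L:]
        mm = _hamming(left, revcomp(right))
        if mm <= budget:
            return TIRAnnotation(L, left, right, mm, True)
        if best is None or mm < best[0]:
            best = (mm, L)
    mm, L = best  # type: ignore[misc]
    return TIRAnnotation(L, copy_seq[:L], copy_seq[-L:], mm, False)


def detect_tsd(left_flank: str, right_flank: str, tsd_len: int = 8,
               budget: int = 1) -> TSDAnnotation:
    """Compare the flanking words immediately 5' and 3' of a copy.

    The TSD is a direct duplication of host sequence, so the
    ``tsd_len``-mer ending at the copy's 5' boundary should match the
    one starting at its 3' boundary; ``present`` means the Hamming
    distance is within ``budget``.
    """
    if len(left_flank) < tsd_len or len(right_flank) < tsd_len:
        raise ValueError(f"flanks shorter than tsd_len={tsd_len}")
    left = left_flank[-tsd_len:]
    right = right_flank[:tsd_len]
    mm = _hamming(left, right)
    return TSDAnnotation(tsd_len, left, right, mm, mm <= budget)


@dataclass
class ClassifyParams:
    full_len_factor: float = 1.5
    len_lo: float = 0.8
    len_hi: float = 1.2


def classify_copy(copy: ElementCopy, tir: TIRAnnotation, tsd: TSDAnnotation,
                  reference_len: int, params: ClassifyParams | None = None) -> CopyClass:
    """Classify copy integrity from its structural annotations.

    Rules, in order: a copy at least ``full_len_factor`` times the
    reference length is a full-length candidate (a relic of the
    autonomous element); a copy with TIRs and TSD present at
    near-reference length is an intact MITE; anything else is
    degenerate.
    """
    params = params or ClassifyParams()
    n = len(copy.copy_seq)
    if n >= params.full_len_factor * reference_len:
        return CopyClass(
            "full_length_candidate",
            f"length {n} >= {params.full_len_factor} x reference ({reference_len})",
        )
    lo = params.len_lo * reference_len
    hi = params.len_hi * reference_len
    checks = []
    checks.append(("tir", tir.present))
    checks.append(("tsd", tsd.present))
    checks.append(("length", lo <= n <= hi))
    failed = [name for name, ok in checks if not ok]
    if not failed:
        return CopyClass(
            "intact_mite",
            f"TIR present ({tir.length} bp, {tir.mismatches} mm), "
            f"TSD present ({tsd.mismatches} mm), length {n} in [{lo:.0f}, {hi:.0f}]",
        )
    return CopyClass("degenerate", "failed: " + ", ".join(failed))


def orf_scan(seq: str, min_aa: int = 100) -> list[tuple[int, int, int, int]]:
    """All ORFs (ATG..stop, stop required) of >= min_aa codons, six frames.

    Returns (frame, start, end, aa_length) tuples with 0-based
    half-open nucleotide coordinates on the input string; frames are
    +1,+2,+3 on the input and -1,-2,-3 on its reverse complement.
    ``aa_length`` counts residues including the initiator Met and
    excluding the stop.
    """
    out: list[tuple[int, int, int, int]] = []
    n = len(seq)
    for sense, s in ((1, seq), (-1, revcomp(seq))):
        for off in range(3):
            frame = sense * (off + 1)
            i = off
            start: Optional[int] = None
            while i + 3 <= len(s):
                codon = s[i : i + 3]
                if start is None:
                    if codon == "ATG":
                        start = i
                elif codon in CODON_STOPS:
                    aa = (i - start) // 3
                    if aa >= min_aa:
                        lo, hi = start, i + 3
                        if sense == -1:
                            lo, hi = n - (i + 3), n - start
                        out.append((frame, lo, hi, aa))
                    start = None
                i += 3
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def gene_context(copies: Sequence[ElementCopy], genes: Sequence[GenomicInterval],
                 near_bp: int = 2000,
                 known_seq_ids: Optional[set[str]] = None) -> list[str]:
    """Label each copy inside / near / distal relative to gene intervals.

    ``inside``: the copy interval overlaps a gene; ``near``: the gap
    between the half-open intervals is strictly less than ``near_bp``
    (0 means adjacent); otherwise ``distal``. Gene intervals naming a
    sequence absent from ``known_seq_ids`` (when provided) raise.
    """
    if known_seq_ids is not None:
        for g in genes:
            if g.seq_id not in known_seq_ids:
                raise ValueError(f"gene interval on unknown sequence {g.seq_id!r}")
    by_seq: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        by_seq.setdefault(g.seq_id, []).append(g)
    labels: list[str] = []
    for c in copies:
        iv = c.interval
        best = None
        for g in by_seq.get(iv.seq_id, ()):
            if iv.start < g.end and g.start < iv.end:
                best = -1  # overlap
                break
            gap = max(g.start - iv.end, iv.start - g.end)
            best = gap if best is None else min(best, gap)
        if best is None:
            labels.append("distal")
        elif best < 0:
            labels.append("inside")
        elif best < near_bp:
            labels.append("near")
        else:
            labels.append("distal")
    return labels


def annotate_copies(copies: Sequence[ElementCopy], reference_len: int,
                    min_tir: int = 5, max_tir: int = 30, tir_budget: int = 1,
                    tsd_len: int = 8, tsd_budget: int = 1,
                    classify_params: ClassifyParams | None = None,
                    orf_min_aa: int = 100) -> None:
    """Annotate every copy in place (fills ``copy.annotations``)."""
    for c in copies:
        n = len(c.copy_seq)
        if n >= 2 * max_tir:
            tir = detect_tir(c.copy_seq, min_tir, max_tir, tir_budget)
        else:
            tir = TIRAnnotation(0, "", "", max_tir, False)
        if len(c.left_flank) >= tsd_len and len(c.right_flank) >= tsd_len:
            tsd = detect_tsd(c.left_flank, c.right_flank, tsd_len, tsd_budget)
        else:
            tsd = TSDAnnotation(tsd_len, "", "", tsd_len, False)
        cls = classify_copy(c, tir, tsd, reference_len, classify_params)
        orfs = orf_scan(c.copy_seq, orf_min_aa)
        c.annotations.update(
            tir_len=tir.length,
            tir_mm=tir.mismatches,
            tir_present=tir.present,
            tsd_seq=tsd.left_seq,
            tsd_mm=tsd.mismatches,
            tsd_present=tsd.present,
            n_orfs=len(orfs),
            copy_class=cls.label,
            class_rationale=cls.rationale,
        )
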