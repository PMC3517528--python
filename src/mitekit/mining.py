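"""Homology mining: find copies of a reference element in genome sequence.

The search is a seed-and-extend screen: exact k-mer seeds shared between
the query element and the genome (both strands) are clustered by strand
and alignment diagonal, and each cluster is resolved by a local
alignment of the query against a bounded genome window. Retained hits
must pass minimum aligned-length and identity thresholds — a practical
re-expression of the "long, nearly full-length, high-identity hit"
filter used when screening dispersed repeat families, stated here as
explicit length/identity cutoffs rather than an E-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import Align

from .seqio import GenomicInterval, SequenceRecord, revcomp


@dataclass(frozen=True)
class SeedMatch:
    """An exact k-mer shared by query and genome (on the stated strand)."""

    query_pos: int
    subject_interval: GenomicInterval
    k: int


@dataclass
class ElementCopy:
    """A mined genomic occurrence of the reference element.

    ``copy_seq`` is always in the element's plus-strand orientation
    (reverse-complemented from the genome for minus-strand hits);
    flanks are genome sequence immediately outside the interval, also
    reoriented so that ``left_flank`` abuts the element's 5' end.
    """

    interval: GenomicInterval
    aligned_query_span: tuple[int, int]
    identity: float
    copy_seq: str
    left_flank: str
    right_flank: str
    copy_id: str = ""
    annotations: dict = field(default_factory=dict)


@dataclass
class MiningParams:
    k: int = 12
    min_len: int = 200
    min_identity: float = 0.75
    merge_gap: int = 20
    flank: int = 30
    band: int = 50          # diagonal tolerance when clustering seeds
    end_extension: int = 15  # max clipped terminal bases restored per end
    window_pad: int = 60    # extra genome context around a seed cluster
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1


def _aligner(params: MiningParams, mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open
    a.extend_gap_score = params.gap_extend
    return a


def find_seeds(genome: SequenceRecord, query: SequenceRecord, k: int) -> list[SeedMatch]:
    """All exact k-mers shared between query and genome, both strands.

    Seed positions are the leftmost base of the word on the genome plus
    strand; ``query_pos`` is the leftmost base of the word on the query.
    For minus-strand seeds the genome word equals the reverse complement
    of the query word.
    """
    if k < 8:
        raise ValueError(f"seed size k must be >= 8, got {k}")
    if len(query.residues) < k:
        raise ValueError("query shorter than seed size k")
    fwd: dict[str, list[int]] = {}
    rev: dict[str, list[int]] = {}
    q = query.residues
    for i in range(len(q) - k + 1):
        word = q[i : i + k]
        if "N" in word:
            continue
        fwd.setdefault(word, []).append(i)
        rev.setdefault(revcomp(word), []).append(i)
    seeds: list[SeedMatch] = []
    g = genome.residues
    gid = genome.id
    for j in range(len(g) - k + 1):
        word = g[j : j + k]
        for qpos in fwd.get(word, ()):
            seeds.append(
                SeedMatch(qpos, GenomicInterval(gid, j, j + k, "+"), k)
            )
        for qpos in rev.get(word, ()):
            seeds.append(
                SeedMatch(qpos, GenomicInterval(gid, j, j + k, "-"), k)
            )
    return seeds


def _cluster_seeds(seeds: list[SeedMatch], qlen: int, params: MiningParams):
    """Group seeds by strand and alignment diagonal.

    Two seeds belong to the same cluster when they lie on the same
    strand, their diagonals differ by at most ``band`` (tolerating
    indel drift within one copy) and their genome positions are within
    one query length of each other. Distinct nearby copies occupy
    well-separated diagonals and therefore stay in separate clusters.
    """
    clusters: list[list[SeedMatch]] = []
    for strand in "+-":
        sub = [s for s in seeds if s.subject_interval.strand == strand]
        if not sub:
            continue

        def diag(s: SeedMatch) -> int:
            if strand == "+":
                return s.subject_interval.start - s.query_pos
            return s.subject_interval.start + s.query_pos

        sub.sort(key=lambda s: (diag(s), s.subject_interval.start))
        current = [sub[0]]
        for s in sub[1:]:
            prev = current[-1]
            same_diag = abs(diag(s) - diag(prev)) <= params.band
            near = abs(s.subject_interval.start - prev.subject_interval.start) <= qlen + params.band
            if same_diag and near:
                current.append(s)
            else:
                clusters.append(current)
                current = [s]
        clusters.append(current)
    return clusters


def _align_window(genome: SequenceRecord, query: str, w_start: int, w_end: int,
                  strand: str, params: MiningParams) -> Optional[tuple]:
    """Locally align query (element orientation) against a genome window.

    Returns (interval, qspan, identity) or None when nothing aligns.
    """
    window = genome.residues[w_start:w_end]
    target = window if strand == "+" else revcomp(window)
    aligner = _aligner(params, "local")
    try:
        aln = aligner.align(target, query)[0]
    except (IndexError, ValueError):
        return None
    blocks_t, blocks_q = aln.aligned
    if len(blocks_t) == 0:
        return None
    t0, t1 = int(blocks_t[0][0]), int(blocks_t[-1][1])
    q0, q1 = int(blocks_q[0][0]), int(blocks_q[-1][1])
    counts = aln.counts()
    identities = counts.identities
    ncols = identities + counts.mismatches + counts.gaps
    # local alignment clips mismatching element termini; restore them by
    # ungapped projection so copy boundaries stay on the element ends
    # (bounded, so genuinely truncated fragments are left alone)
    if 0 < q0 <= params.end_extension:
        ext = min(q0, t0)
        identities += sum(
            target[t0 - ext + i] == query[q0 - ext + i] for i in range(ext)
        )
        ncols += q0
        t0 -= ext
        q0 -= ext
    right_missing = len(query) - q1
    if 0 < right_missing <= params.end_extension:
        ext = min(right_missing, len(target) - t1)
        identities += sum(
            target[t1 + i] == query[q1 + i] for i in range(ext)
        )
        ncols += right_missing
        t1 += ext
        q1 += ext
    identity = identities / ncols if ncols else 0.0
    if strand == "+":
        g0, g1 = w_start + t0, w_start + t1
    else:
        # target was the reverse complement of the window
        g0 = w_start + (len(window) - t1)
        g1 = w_start + (len(window) - t0)
    return GenomicInterval(genome.id, g0, g1, strand), (q0, q1), identity


def extend_and_chain(seeds: list[SeedMatch], genome: SequenceRecord,
                     query: SequenceRecord, params: MiningParams | None = None) -> list[ElementCopy]:
    """Resolve seed clusters into element copies by windowed local alignment.

    Copies whose genome intervals are separated by at most ``merge_gap``
    on the same strand with collinear query spans are merged and
    realigned as one; each retained copy passes ``min_len`` and
    ``min_identity``. Output is sorted by (seq_id, start); ties keep
    the leftmost-start then longest hit.
    """
    params = params or MiningParams()
    if not seeds:
        return []
    q = query.residues
    qlen = len(q)
    glen = len(genome.residues)
    hits: list[tuple] = []
    for cluster in _cluster_seeds(seeds, qlen, params):
        s_lo = min(s.subject_interval.start for s in cluster)
        s_hi = max(s.subject_interval.end for s in cluster)
        q_lo = min(s.query_pos for s in cluster)
        q_hi = max(s.query_pos + s.k for s in cluster)
        strand = cluster[0].subject_interval.strand
        # allow the alignment to extend to the full query on both sides
        if strand == "+":
            left_need, right_need = q_lo, qlen - q_hi
        else:
            left_need, right_need = qlen - q_hi, q_lo
        w0 = max(0, s_lo - left_need - params.window_pad)
        w1 = min(glen, s_hi + right_need + params.window_pad)
        res = _align_window(genome, q, w0, w1, strand, params)
        if res is not None:
            hits.append(res)

    hits = _merge_collinear(hits, genome, q, params)

    copies: list[ElementCopy] = []
    seen: set[tuple] = set()
    for interval, qspan, identity in hits:
        key = (interval.start, interval.end, interval.strand)
        if key in seen:
            continue
        seen.add(key)
        if len(interval) < params.min_len or identity < params.min_identity:
            continue
        copies.append(_make_copy(interval, qspan, identity, genome, params))

    # suppress redundant sub-hits of the same locus: keep the longest
    # (then highest-identity) hit among same-strand copies overlapping
    # by more than half of the shorter one
    copies.sort(key=lambda c: (-len(c.interval), -c.identity, c.interval.start))
    kept: list[ElementCopy] = []
    for c in copies:
        redundant = False
        for k in kept:
            if k.interval.strand != c.interval.strand:
                continue
            ov = min(k.interval.end, c.interval.end) - max(k.interval.start, c.interval.start)
            if ov > 0.5 * len(c.interval):
                redundant = True
                break
        if not redundant:
            kept.append(c)
    kept.sort(key=lambda c: (c.interval.seq_id, c.interval.start, -len(c.interval)))
    return kept


def _merge_collinear(hits: list[tuple], genome: SequenceRecord, query: str,
                     params: MiningParams) -> list[tuple]:
    """Merge same-strand hits with collinear query spans and small genome gaps."""
    if len(hits) < 2:
        return hits
    hits = sorted(hits, key=lambda h: (h[0].strand, h[0].start))
    merged: list[tuple] = []
    cur = hits[0]
    for nxt in hits[1:]:
        iv_a, qs_a, _ = cur
        iv_b, qs_b, _ = nxt
        gap = iv_b.start - iv_a.end
        if iv_a.strand == iv_b.strand and -params.band <= gap <= params.merge_gap:
            collinear = (qs_a[0] < qs_b[0]) if iv_a.strand == "+" else (qs_b[0] < qs_a[0])
            if collinear:
                res = _align_window(
                    genome, query,
                    max(0, iv_a.start - params.window_pad),
                    min(len(genome.residues), iv_b.end + params.window_pad),
                    iv_a.strand, params,
                )
                if res is not None:
                    cur = res
                    continue
        merged.append(cur)
        cur = nxt
    merged.append(cur)
    return merged


def _make_copy(interval: GenomicInterval, qspan: tuple[int, int], identity: float,
               genome: SequenceRecord, params: MiningParams) -> ElementCopy:
    g = genome.residues
    raw = g[interval.start : interval.end]
    left = g[max(0, interval.start - params.flank) : interval.start]
    right = g[interval.end : interval.end + params.flank]
    if interval.strand == "-":
        raw, left, right = revcomp(raw), revcomp(right), revcomp(left)
    return ElementCopy(
        interval=interval,
        aligned_query_span=qspan,
        identity=identity,
        copy_seq=raw,
        left_flank=left,
        right_flank=right,
    )


def mine_copies(genomes: list[SequenceRecord], query: SequenceRecord,
                params: MiningParams | None = None) -> list[ElementCopy]:
    """Run the seed-and-extend screen over every genome sequence.

    Deterministic: copies are sorted by (seq_id, start) and labelled
    copy1..copyN in that order.
    """
    params = params or MiningParams()
    if len(query.residues) < params.min_len:
        raise ValueError(
            f"query length {len(query.residues)} below min_len {params.min_len}"
        )
    copies: list[ElementCopy] = []
    for genome in genomes:
        seeds = find_seeds(genome, query, params.k)
        copies.extend(extend_and_chain(seeds, genome, query, params))
    copies.sort(key=lambda c: (c.interval.seq_id, c.interval.start))
    for i, c in enumerate(copies):
        c.copy_id = f"copy{i + 1}"
    return copies
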