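"""In-silico PCR: primer-site location and amplicon prediction.

A primer binds where it matches the template within a mismatch budget
AND its three 3'-terminal bases match exactly (a crude but standard
proxy for polymerase extensibility; annealing thermodynamics are not
modelled). A product is predicted for every convergent primer pair
within a length cap, measured from the 5' end of the forward match to
the 3' end of the reverse-match locus.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import GenomicInterval, SequenceRecord, revcomp

# primers used in the original wet-lab screen of the Mar element
MAR_F = "CGCGAATCGTATGTGAA"
MAR_R = "CGATGTGAGCACGAAGTACA"
MAR2_F = "CGGACGAAAGGGTATTAACT"
MAR2_R = "GCCGTTACACTTGTTTCCTA"


@dataclass(frozen=True)
class PrimerSite:
    primer_id: str
    interval: GenomicInterval
    mismatches: int
    orientation: str  # forward_on_plus | forward_on_minus


def _matches(primer: str, window: str, budget: int) -> int:
    """Mismatch count if within budget and 3'-exact, else -1."""
    if primer[-3:] != window[-3:]:
        return -1
    mm = 0
    for p, w in zip(primer, window):
        if p != w:
            mm += 1
            if mm > budget:
                return -1
    return mm


def find_primer_sites(template: SequenceRecord, primer: str, budget: int = 2,
                      primer_id: str = "primer") -> list[PrimerSite]:
    """All template positions (both strands) where the primer anneals.

    ``forward_on_plus`` sites read the primer 5'->3' along the plus
    strand; ``forward_on_minus`` sites are where the primer anneals to
    the minus strand (its reverse complement appears on the plus
    strand).
    """
    primer = primer.upper()
    if len(primer) < 10:
        raise ValueError("primer must be at least 10 nt")
    t = template.residues
    L = len(primer)
    rc = revcomp(primer)
    sites: list[PrimerSite] = []
    for i in range(len(t) - L + 1):
        window = t[i : i + L]
        mm = _matches(primer, window, budget)
        if mm >= 0:
            sites.append(
                PrimerSite(primer_id, GenomicInterval(template.id, i, i + L, "+"),
                           mm, "forward_on_plus")
            )
        # primer on minus strand == revcomp(primer) on plus; the primer's
        # 3' end maps to the window start, so compare in primer orientation
        mm = _matches(primer, revcomp(window), budget)
        if mm >= 0:
            sites.append(
                PrimerSite(primer_id, GenomicInterval(template.id, i, i + L, "-"),
                           mm, "forward_on_minus")
            )
    return sites


def predict_amplicons(template: SequenceRecord, fwd: str, rev: str,
                      budget: int = 2, max_len: int = 5000) -> list[tuple[GenomicInterval, int]]:
    """Predicted PCR products for a primer pair on a template.

    Both orientations of the pair are considered (forward primer on
    either strand with the reverse primer converging), so the product
    set is invariant under reverse-complementing the template. Each
    product spans from the 5' end of one primer's match to the 3' end
    of the other's; products longer than ``max_len`` are discarded.
    """
    fwd_sites = find_primer_sites(template, fwd, budget, "fwd")
    rev_sites = find_primer_sites(template, rev, budget, "rev")
    products: dict[tuple[int, int], GenomicInterval] = {}
    for plus, minus, strand in (
        (fwd_sites, rev_sites, "+"),
        (rev_sites, fwd_sites, "-"),
    ):
        for f in plus:
            if f.orientation != "forward_on_plus":
                continue
            for r in minus:
                if r.orientation != "forward_on_minus":
                    continue
                if r.interval.start < f.interval.end:
                    continue
                length = r.interval.end - f.interval.start
                if length > max_len:
                    continue
                iv = GenomicInterval(template.id, f.interval.start,
                                     r.interval.end, strand)
                products.setdefault((iv.start, iv.end), iv)
    return [(iv, iv.end - iv.start) for _, iv in sorted(products.items())]


def read_primer_tsv(path) -> dict[str, str]:
    """2-column TSV (id, sequence) -> mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, seq = line.split("\t")[:2]
            out[pid] = seq.upper()
    return out
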