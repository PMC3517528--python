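"""Sequence and annotation I/O shared by all pipeline stages.

Internal coordinates are 0-based half-open throughout the package; GFF3
emitted here is converted to the standard 1-based inclusive convention.
Species labels are parsed from FASTA headers using a configurable
delimiter (default: the text before the first ``|``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

ALPHABET = frozenset("ACGTN")

# after uppercasing: U->T, every IUPAC ambiguity code except N collapsed to N
_NORMALIZE = str.maketrans("U" + "RYSWKMBDHV", "T" + "N" * 10)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed or empty input files."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    residues: str
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def normalize_residues(raw: str) -> str:
    """Uppercase, map U->T, collapse ambiguity codes other than N to N."""
    out = raw.upper().translate(_NORMALIZE)
    bad = set(out) - ALPHABET
    if bad:
        raise FormatError(f"unrecognized sequence characters: {sorted(bad)}")
    return out


def parse_species(header_id: str, delimiter: str = "|") -> Optional[str]:
    """Species label = text before the first delimiter, if present."""
    if delimiter in header_id:
        return header_id.split(delimiter, 1)[0]
    return None


def read_fasta(path, species_delimiter: str = "|") -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Residues are uppercased, U mapped to T and ambiguity codes other
    than N mapped to N. Record order is preserved. Raises
    :class:`FormatError` on an empty file and on duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=normalize_residues(str(rec.seq)),
                species=parse_species(rec.id, species_delimiter),
            )
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def revcomp(s: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement characters: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# GFF3

_GFF_HEADER = "##gff-version 3"


def write_annotations(copies, path, seq_lengths: Optional[dict] = None) -> None:
    """Write mined element copies as GFF3 (1-based inclusive coordinates).

    ``copies`` is a list of objects exposing ``interval`` and an
    ``annotations`` mapping (see :class:`mitekit.mining.ElementCopy`).
    Rows are ordered by (seq_id, start) for determinism.
    """
    rows = sorted(copies, key=lambda c: (c.interval.seq_id, c.interval.start))
    with open(path, "w") as fh:
        fh.write(_GFF_HEADER + "\n")
        for i, c in enumerate(rows):
            iv = c.interval
            if seq_lengths is not None and iv.end > seq_lengths.get(iv.seq_id, iv.end):
                raise ValueError(
                    f"interval {iv} out of bounds for {iv.seq_id}"
                )
            attrs = {"ID": getattr(c, "copy_id", f"copy{i + 1}")}
            attrs.update(
                {k: str(v) for k, v in getattr(c, "annotations", {}).items()}
            )
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            ident = getattr(c, "identity", None)
            score = f"{ident:.4f}" if ident is not None else "."
            fh.write(
                "\t".join(
                    [
                        iv.seq_id,
                        "mitekit",
                        "mobile_genetic_element",
                        str(iv.start + 1),
                        str(iv.end),
                        score,
                        iv.strand,
                        ".",
                        attr_s,
                    ]
                )
                + "\n"
            )


def read_gff3_intervals(path, feature_types: Optional[Sequence[str]] = None) -> list[GenomicInterval]:
    """Read intervals from a GFF3 file (converted to 0-based half-open).

    Only the coordinate columns are used; attributes are ignored. If
    ``feature_types`` is given, rows with other types are skipped.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise FormatError(f"malformed GFF3 line: {line!r}")
            if feature_types and cols[2] not in feature_types:
                continue
            strand = cols[6] if cols[6] in ("+", "-") else "+"
            out.append(
                GenomicInterval(cols[0], int(cols[3]) - 1, int(cols[4]), strand)
            )
    return out
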