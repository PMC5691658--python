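"""Core sequence types and coordinate arithmetic for circular genomes.

Baculovirus genomes are circular double-stranded DNA molecules; every
downstream stage (ORF scanning, repeat detection, variant effect calls)
has to reason about features that may cross the arbitrary linearization
point of the deposited sequence.  This module owns the conventions:

* coordinates are 1-based inclusive (GenBank style) in the data model;
* a feature with ``start > end`` wraps the origin of a circular genome;
* sequences are uppercased on ingest — input case is not semantic;
* ``N`` is tolerated but flagged by consumers, never silently scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field


VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside the accepted DNA alphabet."""


@dataclass
class CircularGenome:
    """A genome sequence with explicit topology.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header word).
    sequence : str
        IUPAC DNA over ``{A, C, G, T, N}``; lowercase input is uppercased.
    topology : {"circular", "linear"}
        Circular genomes allow features and scans that wrap the origin.
    """

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise SequenceAlphabetError(
                f"genome {self.id!r}: invalid characters {sorted(bad)!r} "
                "(only A, C, G, T, N are accepted)"
            )
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def base(self, position: int) -> str:
        """Base at a 1-based position, wrapping on circular genomes."""
        idx = position - 1
        if self.is_circular:
            idx %= self.length
        elif not 0 <= idx < self.length:
            raise IndexError(f"position {position} outside linear genome of {self.length} nt")
        return self.sequence[idx]

    def fetch(self, start: int, length: int) -> str:
        """``length`` nt starting at 1-based ``start``, wrapping if circular."""
        if length < 0:
            raise ValueError("length must be non-negative")
        idx = start - 1
        if self.is_circular:
            idx %= self.length
            doubled = self.sequence + self.sequence
            if length > self.length:
                raise ValueError("cannot fetch more than one full circle")
            return doubled[idx : idx + length]
        if idx < 0 or idx + length > self.length:
            raise IndexError(f"span {start}..{start + length - 1} outside linear genome")
        return self.sequence[idx : idx + length]

    def rotate(self, offset: int) -> "CircularGenome":
        """Rotate the linearization point left by ``offset`` nt (circular only)."""
        if not self.is_circular:
            raise ValueError("cannot rotate a linear genome")
        k = offset % self.length
        return CircularGenome(self.id, self.sequence[k:] + self.sequence[:k], self.topology)


@dataclass
class FeatureRecord:
    """A located genome feature in GenBank-style coordinates.

    ``start > end`` is legal only for features wrapping the origin of a
    circular genome (``wraps`` is then True).
    """

    feature_id: str
    start: int
    end: int
    strand: str
    kind: str  # ORF | hr | repeat_unit
    attributes: dict = field(default_factory=dict)
    wraps: bool = False

    def validate(self, genome: CircularGenome) -> None:
        L = genome.length
        if not (1 <= self.start <= L and 1 <= self.end <= L):
            raise ValueError(
                f"feature {self.feature_id}: coordinates {self.start}..{self.end} "
                f"outside genome of {L} nt"
            )
        if self.start > self.end and not (self.wraps and genome.is_circular):
            raise ValueError(
                f"feature {self.feature_id}: start > end is only legal for "
                "origin-wrapping features on circular genomes"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")

    def span_length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement over {A,C,G,T,N}; an involution."""
    s = seq.upper()
    bad = set(s) - VALID_BASES
    if bad:
        raise SequenceAlphabetError(f"invalid characters for reverse_complement: {sorted(bad)!r}")
    return s.translate(_COMPLEMENT)[::-1]


def gc_content(genome: CircularGenome | str) -> float:
    """G+C percentage over unambiguous bases, reported to 2 decimals.

    ``N`` is excluded from the denominator; a sequence of only ``N`` (or an
    empty one) has no defined G+C content and raises ``ValueError``.
    """
    seq = genome.sequence if isinstance(genome, CircularGenome) else genome.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("G+C content undefined: no unambiguous bases")
    return round(100.0 * (counts["G"] + counts["C"]) / denom, 2)


def circular_segments(start0: int, length: int, genome_length: int) -> list[tuple[int, int]]:
    """Decompose a circular footprint into 1–2 linear half-open segments.

    ``start0`` is 0-based; returns ``[(lo, hi), ...]`` with ``0 <= lo < hi <= L``.
    """
    if length <= 0:
        return []
    if length > genome_length:
        raise ValueError("footprint longer than the genome")
    s = start0 % genome_length
    if s + length <= genome_length:
        return [(s, s + length)]
    return [(s, genome_length), (0, s + length - genome_length)]


def circular_overlap(a_start0: int, a_len: int, b_start0: int, b_len: int, genome_length: int) -> int:
    """Number of genomic nucleotides shared by two circular footprints."""
    total = 0
    for alo, ahi in circular_segments(a_start0, a_len, genome_length):
        for blo, bhi in circular_segments(b_start0, b_len, genome_length):
            total += max(0, min(ahi, bhi) - max(alo, blo))
    return total
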