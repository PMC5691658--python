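"""Readers and writers for the plain-text formats the pipeline touches.

FASTA parsing goes through Biopython; GFF3 and BED are written directly
(the emitted subset is small and conventions — multi-part origin-wrapping
features, 0-based BED at the boundary — are the point).
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import AlignIO, SeqIO

from .genome import CircularGenome, FeatureRecord


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | os.PathLike, topology: str = "circular") -> list[CircularGenome]:
    """Read FASTA records as genomes (default topology circular).

    Raises on an empty file or malformed records; use ``topology="linear"``
    for gene or protein-coding nucleotide sequences.
    """
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(CircularGenome(rec.id, str(rec.seq), topology))
    except ValueError as exc:  # Biopython signals malformed FASTA via ValueError
        raise FastaParseError(f"{path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def read_fasta_proteins(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a protein FASTA as ``(id, sequence)`` pairs (uppercased)."""
    pairs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not pairs:
        raise FastaParseError(f"{path}: no FASTA records found")
    return pairs


def write_fasta(records: Iterable[CircularGenome | tuple[str, str]], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, CircularGenome):
                name, seq = rec.id, rec.sequence
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_GFF3_TYPE = {"ORF": "CDS", "hr": "repeat_region", "repeat_unit": "repeat_unit"}


def write_gff3(features: list[FeatureRecord], genome: CircularGenome,
               path: str | os.PathLike, source: str = "obgenome") -> None:
    """Write GFF3 with 1-based inclusive coordinates.

    Origin-wrapping features are emitted as two part-lines sharing an ID
    (the GFF3 multi-part convention); all features are validated against
    the genome before anything is written.
    """
    for f in features:
        f.validate(genome)
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {genome.length}"]
    for f in features:
        ftype = _GFF3_TYPE.get(f.kind, f.kind)
        attrs = ";".join([f"ID={f.feature_id}"] +
                         [f"{k}={v}" for k, v in sorted(f.attributes.items())])
        parts = ([(f.start, genome.length), (1, f.end)] if f.wraps
                 else [(f.start, f.end)])
        for lo, hi in parts:
            lines.append("\t".join([genome.id, source, ftype, str(lo), str(hi),
                                    ".", f.strand, ".", attrs]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_bed(features: list[FeatureRecord], genome: CircularGenome,
              path: str | os.PathLike) -> None:
    """Write features as BED (0-based half-open, converted at this boundary).

    Wrapping features become two BED lines with the same name.
    """
    with open(path, "w") as fh:
        for f in features:
            f.validate(genome)
            parts = ([(f.start - 1, genome.length), (0, f.end)] if f.wraps
                     else [(f.start - 1, f.end)])
            for lo, hi in parts:
                fh.write(f"{genome.id}\t{lo}\t{hi}\t{f.feature_id}\t0\t{f.strand}\n")


def read_alignment_file(path: str | os.PathLike):
    """Read one FASTA or Clustal alignment file into (taxa, rows)."""
    path = str(path)
    fmt = "clustal" if open(path).readline().upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(path, fmt)
    return [rec.id for rec in aln], [str(rec.seq).upper() for rec in aln]
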