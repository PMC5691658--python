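"""Intra-isolate polymorphism calling from per-position read pileups.

The canonical input is a pileup TSV (position, ref, depth, A/C/G/T counts,
insertion and deletion observations): the study's raw reads are not part
of the artifact, so the caller operates on this minimal exchangeable
summary of a read alignment.  Calls are threshold filters, not a genotype
model: at sufficient depth, every non-reference allele above a count and
frequency floor becomes one call, and calls inside accepted ORFs are
classified for their coding effect by codon substitution on the ORF's
strand and frame.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import pandas as pd

from .genome import CircularGenome
from .orfs import OrfAnnotation, translate_codon

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class PileupColumn:
    position: int  # 1-based
    ref_base: str
    depth: int
    base_counts: dict[str, int] = field(default_factory=dict)
    ins_counts: dict[str, int] = field(default_factory=dict)  # inserted seq -> reads
    del_counts: dict[int, int] = field(default_factory=dict)  # deletion length -> reads

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"position {self.position}: negative depth")
        if sum(self.base_counts.values()) > self.depth:
            raise ValueError(
                f"position {self.position}: base counts exceed depth {self.depth}"
            )


@dataclass
class Polymorphism:
    position: int
    ref: str
    alt: str  # SNP: base; insertion: inserted sequence; deletion: length as text
    kind: str  # SNP | insertion | deletion
    alt_count: int
    depth: int
    frequency: float  # percent, 2 decimals
    effect: str = ""  # synonymous | nonsynonymous | nonsense | intergenic | frameshift
    orf_id: str = ""


def _encode_counts(d: dict) -> str:
    return ";".join(f"{k}:{v}" for k, v in sorted(d.items(), key=lambda kv: str(kv[0]))) or "."


def _decode_counts(s: str, key_type=str) -> dict:
    if not s or s == ".":
        return {}
    out = {}
    for item in s.split(";"):
        k, v = item.rsplit(":", 1)
        out[key_type(k)] = int(v)
    return out


PILEUP_COLUMNS = ["position", "ref", "depth", "A", "C", "G", "T", "ins", "del"]


def write_pileup(columns: list[PileupColumn], path: str | os.PathLike) -> None:
    rows = []
    for c in columns:
        rows.append({
            "position": c.position, "ref": c.ref_base, "depth": c.depth,
            **{b: c.base_counts.get(b, 0) for b in "ACGT"},
            "ins": _encode_counts(c.ins_counts),
            "del": _encode_counts(c.del_counts),
        })
    pd.DataFrame(rows, columns=PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pileup(path: str | os.PathLike) -> list[PileupColumn]:
    """Read a pileup TSV; columns come back position-sorted.

    Missing positions are allowed (treated as depth 0 downstream).  A row
    whose base counts exceed its depth raises, naming the position.
    """
    if os.path.getsize(path) == 0:
        return []
    df = pd.read_csv(path, sep="\t", dtype={"ins": str, "del": str}, keep_default_na=False)
    if df.empty:
        return []
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pileup columns {missing}")
    out = []
    for row in df.to_dict("records"):  # "del" is a keyword, so no itertuples
        out.append(PileupColumn(
            position=int(row["position"]), ref_base=str(row["ref"]).upper(),
            depth=int(row["depth"]),
            base_counts={b: int(row[b]) for b in "ACGT" if int(row[b])},
            ins_counts=_decode_counts(str(row["ins"]), str),
            del_counts=_decode_counts(str(row["del"]), int),
        ))
    out.sort(key=lambda c: c.position)
    return out


def call_polymorphisms(columns: list[PileupColumn], min_depth: int = 20,
                       min_alt: int = 2, min_freq: float = 1.0) -> list[Polymorphism]:
    """Enumerate SNP/indel calls passing depth, count, and frequency floors.

    Frequencies are percentages of column depth (indels use the same
    denominator) reported to 2 decimals; multi-allelic columns produce one
    call per alternate allele.  Filters never raise.
    """
    calls: list[Polymorphism] = []
    for col in sorted(columns, key=lambda c: c.position):
        if col.depth < min_depth:
            continue

        def _emit(alt: str, kind: str, count: int) -> None:
            freq = round(100.0 * count / col.depth, 2)
            if count >= min_alt and freq >= min_freq:
                calls.append(Polymorphism(col.position, col.ref_base, alt, kind,
                                          count, col.depth, freq))

        for base, count in sorted(col.base_counts.items()):
            if base != col.ref_base:
                _emit(base, "SNP", count)
        for seq, count in sorted(col.ins_counts.items()):
            _emit(seq, "insertion", count)
        for dlen, count in sorted(col.del_counts.items()):
            _emit(str(dlen), "deletion", count)
    return calls


def _codon_context(cand, genome: CircularGenome, pos0: int):
    """(codon, offset-in-codon, codon genomic positions) for a genome position inside an ORF."""
    L = genome.length
    if cand.strand == "+":
        t = (pos0 - (cand.start - 1)) % L
        cidx, off = divmod(t, 3)
        gpos = [((cand.start - 1) + 3 * cidx + k) % L for k in range(3)]
        codon = "".join(genome.sequence[p] for p in gpos)
    else:
        t = ((cand.start - 1) - pos0) % L
        cidx, off = divmod(t, 3)
        gpos = [((cand.start - 1) - 3 * cidx - k) % L for k in range(3)]
        codon = "".join(_COMPLEMENT[genome.sequence[p]] for p in gpos)
    return codon, off, gpos


def classify_effect(p: Polymorphism, annotations: list[OrfAnnotation],
                    genome: CircularGenome) -> list[Polymorphism]:
    """Classify the coding effect of one call against accepted ORFs.

    Returns one record per overlapping accepted ORF (a call inside two
    overlapping ORFs is reported once per ORF) or a single intergenic
    record.  SNPs are translated on the ORF's strand/frame; indels whose
    length is not divisible by 3 are frameshifts, in-frame indels are
    reported as nonsynonymous.
    """
    if not 1 <= p.position <= genome.length:
        raise ValueError(f"position {p.position} outside genome of {genome.length} nt")
    pos0 = p.position - 1
    hits = []
    for ann in annotations:
        if not ann.accepted:
            continue
        cand = ann.candidate
        f0, n = cand.footprint(genome.length)
        rel = (pos0 - f0) % genome.length
        if rel < n:
            hits.append(ann)
    if not hits:
        return [replace(p, effect="intergenic", orf_id="")]
    out = []
    for ann in hits:
        cand = ann.candidate
        if p.kind in ("insertion", "deletion"):
            length = len(p.alt) if p.kind == "insertion" else int(p.alt)
            effect = "frameshift" if length % 3 else "nonsynonymous"
        else:
            codon, off, _ = _codon_context(cand, genome, pos0)
            alt_base = p.alt if cand.strand == "+" else _COMPLEMENT[p.alt]
            alt_codon = codon[:off] + alt_base + codon[off + 1 :]
            aa_ref, aa_alt = translate_codon(codon), translate_codon(alt_codon)
            if aa_alt == aa_ref:
                effect = "synonymous"
            elif aa_alt == "*":
                effect = "nonsense"
            else:
                effect = "nonsynonymous"
        out.append(replace(p, effect=effect, orf_id=cand.orf_id))
    return out


def classify_all(calls: list[Polymorphism], annotations: list[OrfAnnotation],
                 genome: CircularGenome) -> list[Polymorphism]:
    out = []
    for c in calls:
        out.extend(classify_effect(c, annotations, genome))
    return out


def summarize_frequencies(polys: list[Polymorphism],
                          thresholds: list[float] = (6.0, 8.0),
                          top_k: int = 10) -> dict:
    """Frequency-spectrum summary: counts around thresholds and the top-k list."""
    freqs = sorted((p.frequency for p in polys), reverse=True)
    top = sorted(polys, key=lambda p: (-p.frequency, p.position))[:top_k]
    return {
        "total": len(polys),
        "ge": {t: sum(1 for f in freqs if f >= t) for t in thresholds},
        "le": {t: sum(1 for f in freqs if f <= t) for t in thresholds},
        "top": [(p.position, p.frequency) for p in top],
    }


def calls_to_frame(calls: list[Polymorphism]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"position": c.position, "ref": c.ref, "alt": c.alt, "kind": c.kind,
          "alt_count": c.alt_count, "depth": c.depth,
          "frequency": f"{c.frequency:.2f}", "effect": c.effect, "orf_id": c.orf_id}
         for c in calls],
        columns=["position", "ref", "alt", "kind", "alt_count", "depth",
                 "frequency", "effect", "orf_id"],
    )
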