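"""ORF enumeration on circular genomes and annotation selection rules.

The selection policy mirrors standard baculovirus genome annotation
practice: candidate ORFs of at least ``min_codons`` codons (stop codon
excluded) are kept when they have amino-acid homology support, or — when
they lack homology — only if they overlap no larger accepted ORF by
``max_overlap`` (default 75) or more nucleotides AND are predicted to be
protein-coding by both ab initio gene finders consulted (fgenesV and
ZCURVE_V outputs are consumed as an evidence table, never re-run here).

Six reading frames are scanned; on circular genomes the scan continues
across the origin.  Reading codons in steps of three around a circle of
length L partitions positions into 3 cycles when L % 3 == 0 and a single
cycle of length L otherwise; ORFs are delimited per cycle between
consecutive stop codons, reporting the most upstream qualifying start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .genome import CircularGenome, circular_overlap, reverse_complement

START_CODONS = frozenset({"ATG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE = {}


def _codon_table() -> dict:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon (translation table 1; '*' = stop, 'X' = ambiguous)."""
    return _codon_table().get(codon.upper(), "X")


@dataclass
class OrfCandidate:
    """A start-to-stop open reading frame on a (possibly circular) genome.

    ``start``/``end`` are transcript-oriented 1-based coordinates: ``start``
    is the first nucleotide of the start codon and ``end`` the last
    nucleotide of the stop codon.  On the minus strand ``start`` is the
    higher genomic coordinate.  ``n_codons`` excludes the stop codon.
    """

    orf_id: str
    start: int
    end: int
    strand: str
    frame: int
    n_codons: int
    wraps: bool = False
    contains_n: bool = False

    def span_nt(self) -> int:
        return 3 * (self.n_codons + 1)

    def footprint(self, genome_length: int) -> tuple[int, int]:
        """(0-based genomic start, length) of the occupied footprint."""
        n = self.span_nt()
        if self.strand == "+":
            return (self.start - 1) % genome_length, n
        # minus strand: footprint runs from the genomic position of the
        # stop codon's last nucleotide forward to the start codon's first.
        return (self.end - 1) % genome_length, n

    def genomic_positions(self, genome_length: int) -> list[int]:
        """Transcript-ordered 0-based genomic positions of the ORF."""
        n = self.span_nt()
        if self.strand == "+":
            return [((self.start - 1) + k) % genome_length for k in range(n)]
        return [((self.start - 1) - k) % genome_length for k in range(n)]

    def protein(self, genome: CircularGenome) -> str:
        pos = self.genomic_positions(genome.length)
        seq = "".join(genome.sequence[p] for p in pos)
        if self.strand == "-":
            seq = "".join(reverse_complement(b) for b in seq)  # per-base complement, order kept
        return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - 3, 3))


@dataclass
class EvidenceRecord:
    """Per-ORF annotation evidence consumed from homology/ab initio tables."""

    orf_id: str
    has_homology: bool = False
    best_subject: str = ""
    best_identity: float | None = None
    fgenes_pred: bool = False
    zcurve_pred: bool = False
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.has_homology and not self.best_subject:
            raise ValueError(f"{self.orf_id}: homology evidence requires a subject")


@dataclass
class OrfAnnotation:
    candidate: OrfCandidate
    accepted: bool
    rejection_reason: str = "none"  # none | too_short | overlap_no_evidence | no_evidence
    conservation_class: str = "unique"  # core | alpha_beta_conserved | subset | unique
    product: str = ""

    def __post_init__(self) -> None:
        if self.accepted and self.rejection_reason != "none":
            raise ValueError("accepted ORFs cannot carry a rejection reason")


def _strand_scan(seq: str, genome_length: int, circular: bool, min_codons: int,
                 start_codons: frozenset[str]) -> list[tuple[int, int, int, int]]:
    """Scan one strand; return (start0, stop0, frame, n_codons) in strand coordinates."""
    L = genome_length
    if L < 3:
        return []
    ext = seq + seq[:2] if circular else seq
    is_stop = [False] * L
    is_start = [False] * L
    limit = L if circular else L - 2
    for p in range(limit):
        codon = ext[p : p + 3]
        if codon in STOP_CODONS:
            is_stop[p] = True
        if codon in start_codons:
            is_start[p] = True

    cycles: list[list[int]] = []
    if circular:
        if L % 3 == 0:
            cycles = [list(range(f, L, 3)) for f in range(3)]
        else:
            cyc, p = [], 0
            for _ in range(L):
                cyc.append(p)
                p = (p + 3) % L
            cycles = [cyc]
    else:
        cycles = [list(range(f, L - 2, 3)) for f in range(3)]

    out = []
    max_codons_total = L // 3  # an ORF may not overlap itself on the circle
    for cyc in cycles:
        stop_idx = [i for i, p in enumerate(cyc) if is_stop[p]]
        m = len(cyc)
        if circular:
            if not stop_idx:
                continue  # a stop-free cycle offers no delimited ORFs
            segments = [(stop_idx[k - 1], stop_idx[k]) for k in range(len(stop_idx))]
        else:
            # linear: segment ends at each stop, starting after the previous stop
            segments = []
            prev = -1
            for si in stop_idx:
                segments.append((prev, si))
                prev = si
        for prev_i, stop_i in segments:
            # walk from the codon after the previous stop to the stop, take first start
            span = (stop_i - prev_i - 1) % m if circular else stop_i - prev_i - 1
            for off in range(1, span + 1):
                i = (prev_i + off) % m if circular else prev_i + off
                p = cyc[i]
                if is_start[p]:
                    n_codons = (stop_i - i) % m if circular else stop_i - i
                    if n_codons + 1 > max_codons_total:
                        continue  # would overlap itself on the circle; try next start
                    if n_codons >= min_codons:
                        out.append((p, cyc[stop_i], p % 3, n_codons))
                    break
    return out


def find_orfs(genome: CircularGenome, min_codons: int = 50,
              start_codons: frozenset[str] | set[str] = START_CODONS) -> list[OrfCandidate]:
    """Enumerate candidate ORFs in all six frames, sorted by genomic start.

    For each stop codon the reported candidate is the longest start-to-stop
    ORF (most upstream qualifying start codon).  ``n_codons`` excludes the
    stop codon; candidates shorter than ``min_codons`` are not reported.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    start_codons = frozenset(s.upper() for s in start_codons)
    L = genome.length
    if L < 3:
        return []
    candidates: list[OrfCandidate] = []
    for strand, seq in (("+", genome.sequence), ("-", reverse_complement(genome.sequence))):
        for p, stop_p, frame, n_codons in _strand_scan(
            seq, L, genome.is_circular, min_codons, start_codons
        ):
            stop_last = (stop_p + 2) % L if genome.is_circular else stop_p + 2
            if strand == "+":
                start1, end1 = p + 1, stop_last + 1
            else:
                start1, end1 = L - p, L - stop_last
            wraps = genome.is_circular and (p + 3 * (n_codons + 1) > L)
            cand = OrfCandidate("", start1, end1, strand, frame, n_codons, wraps=wraps)
            f0, n = cand.footprint(L)
            cand.contains_n = "N" in genome.fetch(f0 + 1, n)
            candidates.append(cand)
    candidates.sort(key=lambda c: (min(c.start, c.end), c.strand, -c.n_codons))
    for i, c in enumerate(candidates, start=1):
        c.orf_id = f"orf{i:03d}"
    return candidates


def _size_order_key(cand: OrfCandidate, genome_length: int):
    # "larger" compares codon counts; ties broken by earlier linearized start
    return (-cand.n_codons, cand.footprint(genome_length)[0], cand.strand)


def resolve_overlaps(candidates: list[OrfCandidate],
                     evidence: list[EvidenceRecord],
                     genome_length: int,
                     max_overlap: int = 75,
                     min_codons: int = 50) -> list[OrfAnnotation]:
    """Apply the acceptance rules and record per-candidate rejection reasons.

    A candidate is accepted iff it has homology evidence, or it overlaps
    every larger already-accepted ORF by fewer than ``max_overlap``
    nucleotides (shared genomic positions on the circle, strand-agnostic)
    and both ab initio predictors flag it.  Candidates are processed in
    decreasing size order so "larger" is well defined; the result is
    deterministic and independent of input order.
    """
    ev_by_id = {}
    known = {c.orf_id for c in candidates}
    for ev in evidence:
        if ev.orf_id not in known:
            raise KeyError(f"evidence references unknown ORF id {ev.orf_id!r}")
        if ev.orf_id in ev_by_id:
            raise ValueError(f"duplicate evidence for {ev.orf_id!r}")
        ev_by_id[ev.orf_id] = ev

    ordered = sorted(candidates, key=lambda c: _size_order_key(c, genome_length))
    accepted_footprints: list[tuple[int, int]] = []
    decisions: dict[str, OrfAnnotation] = {}
    for cand in ordered:
        ev = ev_by_id.get(cand.orf_id, EvidenceRecord(cand.orf_id))
        if cand.n_codons < min_codons:
            decisions[cand.orf_id] = OrfAnnotation(cand, False, "too_short")
            continue
        if ev.has_homology:
            ok, reason = True, "none"
        elif not (ev.fgenes_pred and ev.zcurve_pred):
            ok, reason = False, "no_evidence"
        else:
            f0, n = cand.footprint(genome_length)
            ok, reason = True, "none"
            for a0, an in accepted_footprints:
                if circular_overlap(f0, n, a0, an, genome_length) >= max_overlap:
                    ok, reason = False, "overlap_no_evidence"
                    break
        if ok:
            accepted_footprints.append(cand.footprint(genome_length))
        decisions[cand.orf_id] = OrfAnnotation(
            cand, ok, reason, product=ev.best_subject if ev.has_homology else ""
        )
    # report in genomic order
    return [decisions[c.orf_id]
            for c in sorted(candidates, key=lambda c: (c.footprint(genome_length)[0], c.orf_id))]


def classify_conservation(annotations: list[OrfAnnotation], core_hits,
                          evidence: list[EvidenceRecord] | None = None) -> list[OrfAnnotation]:
    """Label accepted ORFs as core / alpha_beta_conserved / subset / unique.

    ``core_hits`` come from the homology module's inventory; remaining
    accepted ORFs with homology evidence are "alpha_beta_conserved" when
    the evidence table flags them as conserved in all alpha/betabaculoviruses
    (attribute ``conserved=alpha_beta``) and "subset" otherwise; ORFs with
    no evidence are "unique".
    """
    core_orfs = {h.best_orf: h.core_gene for h in core_hits if h.found}
    ev_by_id = {e.orf_id: e for e in (evidence or [])}
    out = []
    for ann in annotations:
        cls = "unique"
        ev = ev_by_id.get(ann.candidate.orf_id)
        if ann.candidate.orf_id in core_orfs:
            cls = "core"
            if not ann.product:
                ann = replace(ann, product=core_orfs[ann.candidate.orf_id])
        elif ev is not None and ev.has_homology:
            cls = ("alpha_beta_conserved"
                   if ev.attributes.get("conserved") == "alpha_beta" else "subset")
        out.append(replace(ann, conservation_class=cls))
    return out


def conservation_counts(annotations: list[OrfAnnotation]) -> dict[str, int]:
    counts = {"core": 0, "alpha_beta_conserved": 0, "subset": 0, "unique": 0}
    for ann in annotations:
        if ann.accepted:
            counts[ann.conservation_class] += 1
    return counts
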