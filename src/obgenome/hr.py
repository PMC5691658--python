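"""Homologous repeat (hr) region detection from a degenerate consensus.

Baculovirus hr regions are clusters of imperfect palindromic repeat units
recurring at several genomic loci.  Detection here is seeded: a mixed-case
48-bp consensus describes the unit, with uppercase letters marking
invariant ("strict") positions and lowercase letters variable ones.  The
scanner slides the consensus over both strands of the (circular) genome
under a total mismatch budget; in strict mode the uppercase positions must
match exactly.  Matches are clustered into regions by single-linkage along
the circle, and a case-convention consensus with black/gray shading can be
rendered from the aligned units.

Indels within repeat units are not modelled (fixed-length windows); units
are aligned to each other implicitly by consensus coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import CircularGenome, circular_overlap, reverse_complement

#: The default 48-bp imperfect inverted-repeat unit consensus.
HR_CONSENSUS = "aACGAtCcgtcgcAgcAATTtaaaattaAATTtgTgCGatagatcGTt"

_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class DegenerateConsensus:
    """A mixed-case DNA consensus; uppercase positions are strict."""

    sequence: str = HR_CONSENSUS

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGTacgt"):
            raise ValueError("consensus must be nonempty mixed-case A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def strict_positions(self) -> frozenset[int]:
        return frozenset(i for i, c in enumerate(self.sequence) if c.isupper())


@dataclass
class HrRepeatMatch:
    position: int  # 1-based genomic start of the window (leftmost nt)
    strand: str
    matched_seq: str  # strand-oriented window compared against the consensus
    mismatch_total: int
    mismatch_strict: int
    ir_score: float
    contains_n: bool = False


@dataclass
class HrRegion:
    region_id: str
    span_start: int
    span_end: int
    repeats: list[HrRepeatMatch] = field(default_factory=list)
    wraps: bool = False

    @property
    def copy_count(self) -> int:
        return len(self.repeats)


def ir_score(seq: str) -> float:
    """Fraction of positions complementary to their mirror position.

    Quantifies the imperfection of an inverted repeat: 1.0 for a perfect
    palindrome.  The center position of odd-length input is excluded.
    """
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    if set(s) - set("ACGT"):
        raise ValueError(f"non-DNA characters in {seq!r}")
    L = len(s)
    positions = [i for i in range(L) if L % 2 == 0 or i != L // 2]
    hits = sum(1 for i in positions if _COMPLEMENT[s[i]] == s[L - 1 - i])
    return hits / len(positions)


def _window_mismatches(seq: str, circular: bool, cons: DegenerateConsensus):
    """Vectorized mismatch counts of every window on one strand."""
    K = cons.length
    L = len(seq)
    ext = seq + seq[: K - 1] if circular else seq
    n_win = L if circular else L - K + 1
    if n_win <= 0:
        return np.zeros((0,), int), np.zeros((0,), int), np.zeros((0,), bool)
    arr = np.frombuffer(ext.encode(), dtype=np.uint8)
    cons_codes = np.frombuffer(cons.sequence.upper().encode(), dtype=np.uint8)
    strict = np.array([c.isupper() for c in cons.sequence])
    n_code = ord("N")
    total = np.zeros(n_win, dtype=np.int64)
    strict_mm = np.zeros(n_win, dtype=np.int64)
    has_n = np.zeros(n_win, dtype=bool)
    for j in range(K):
        col = arr[j : j + n_win]
        mm = col != cons_codes[j]
        total += mm
        if strict[j]:
            strict_mm += mm
        has_n |= col == n_code
    return total, strict_mm, has_n


def scan_degenerate(genome: CircularGenome,
                    consensus: DegenerateConsensus | str | None = None,
                    max_mismatch: int = 12,
                    strict_mode: bool = True) -> list[HrRepeatMatch]:
    """Find all windows matching the degenerate consensus on both strands.

    A window matches when its total mismatch count is <= ``max_mismatch``
    and, in strict mode, its uppercase consensus positions match exactly.
    Windows containing N count those positions as mismatches and are
    flagged.  Overlapping matches are resolved by keeping the
    lower-mismatch one (ties: lower position, then plus strand).
    """
    if consensus is None:
        consensus = DegenerateConsensus()
    elif isinstance(consensus, str):
        consensus = DegenerateConsensus(consensus)
    K = consensus.length
    if K > genome.length:
        raise ValueError("consensus longer than the genome")
    if max_mismatch >= K:
        raise ValueError("max_mismatch >= consensus length makes the scan vacuous")

    raw: list[HrRepeatMatch] = []
    L = genome.length
    for strand, seq in (("+", genome.sequence), ("-", reverse_complement(genome.sequence))):
        total, strict_mm, has_n = _window_mismatches(seq, genome.is_circular, consensus)
        keep = total <= max_mismatch
        if strict_mode:
            keep &= strict_mm == 0
        for w in np.flatnonzero(keep):
            w = int(w)
            if strand == "+":
                pos0 = w
                window = (seq + seq)[w : w + K] if genome.is_circular else seq[w : w + K]
            else:
                pos0 = (L - K - w) % L
                window = (seq + seq)[w : w + K] if genome.is_circular else seq[w : w + K]
            raw.append(HrRepeatMatch(
                position=pos0 + 1, strand=strand, matched_seq=window,
                mismatch_total=int(total[w]), mismatch_strict=int(strict_mm[w]),
                ir_score=ir_score(window) if "N" not in window else 0.0,
                contains_n=bool(has_n[w]),
            ))

    raw.sort(key=lambda m: (m.mismatch_total, m.position, 0 if m.strand == "+" else 1))
    kept: list[HrRepeatMatch] = []
    for m in raw:
        clash = any(
            circular_overlap(m.position - 1, K, k.position - 1, K, L) > 0 for k in kept
        )
        if not clash:
            kept.append(m)
    kept.sort(key=lambda m: m.position)
    return kept


def cluster_matches(matches: list[HrRepeatMatch], genome_length: int,
                    max_gap: int = 1000, unit_length: int = len(HR_CONSENSUS)) -> list[HrRegion]:
    """Single-linkage clustering of repeat matches along the circle.

    Consecutive matches whose start-to-start distance is <= ``max_gap``
    join one region; on circular genomes the gap between the last and
    first match (across the origin) is considered too, so a region may
    wrap.  Regions are ordered by span start.
    """
    if not matches:
        return []
    ms = sorted(matches, key=lambda m: m.position)
    clusters: list[list[HrRepeatMatch]] = [[ms[0]]]
    for m in ms[1:]:
        if m.position - clusters[-1][-1].position <= max_gap:
            clusters[-1].append(m)
        else:
            clusters.append([m])
    wrapped = False
    if len(clusters) > 1:
        gap_around = (ms[0].position + genome_length) - clusters[-1][-1].position
        if gap_around <= max_gap:
            clusters[0] = clusters.pop() + clusters[0]
            wrapped = True
    regions = []
    for members in clusters:
        first, last = members[0], members[-1]
        span_end = (last.position + unit_length - 1)
        wraps = False
        if wrapped and members is clusters[0] and first.position > last.position:
            wraps = True
        elif span_end > genome_length:
            span_end -= genome_length
            wraps = True
        regions.append(HrRegion("", first.position, span_end, list(members), wraps=wraps))
    regions.sort(key=lambda r: r.span_start)
    for i, r in enumerate(regions, start=1):
        r.region_id = f"hr{i}"
    return regions


@dataclass
class RepeatConsensus:
    consensus: str
    column_identity: list[float]
    shading: list[str]  # black | gray | none per column


def build_consensus(repeats: list[str]) -> RepeatConsensus:
    """Render a case-convention consensus from equal-length aligned units.

    Per column: all residues identical -> uppercase letter, black shading;
    one residue occupying > 50% -> lowercase letter, black; otherwise, if
    the purine or pyrimidine class occupies > 50% -> gray shading with the
    lowercase plurality letter when one is unique (else 'n'); otherwise no
    shading and 'n'.
    """
    if len(repeats) < 2:
        raise ValueError("need at least 2 repeat units")
    seqs = [r.upper() for r in repeats]
    K = len(seqs[0])
    if any(len(s) != K for s in seqs):
        raise ValueError("repeat units must all have the same length")
    letters, identity, shading = [], [], []
    n = len(seqs)
    for j in range(K):
        col = [s[j] for s in seqs]
        counts = {b: col.count(b) for b in set(col)}
        best = max(counts, key=lambda b: (counts[b], -ord(b)))
        frac = counts[best] / n
        identity.append(frac)
        if frac == 1.0:
            letters.append(best.upper())
            shading.append("black")
        elif frac > 0.5:
            letters.append(best.lower())
            shading.append("black")
        else:
            pur = sum(counts.get(b, 0) for b in _PURINES) / n
            pyr = sum(counts.get(b, 0) for b in _PYRIMIDINES) / n
            top = [b for b, c in counts.items() if c == counts[best]]
            letter = best.lower() if len(top) == 1 else "n"
            if pur > 0.5 or pyr > 0.5:
                letters.append(letter)
                shading.append("gray")
            else:
                letters.append("n")
                shading.append("none")
    return RepeatConsensus("".join(letters), identity, shading)
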