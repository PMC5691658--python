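"""Pairwise global alignment, percent identity, and the core-gene inventory.

Every sequenced baculovirus genome carries a set of 38 core genes; their
presence is the first sanity check on a new genome annotation, and their
pairwise identities to homologs in other viruses summarize how divergent
an isolate is.  This module computes optimal global alignments under
affine gap penalties (Needleman–Wunsch–Gotoh, provided by Biopython's
PairwiseAligner), derives percent identity under an explicit
column-counting policy, and matches a proteome against a reference set of
core-gene sequences by best global identity.

BLASTp-style local search is deliberately not reimplemented: presence/
absence at the configured identity floor only needs global alignment
against curated references.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring: a protein matrix or nucleotide match/mismatch pair.

    Gap penalties are magnitudes: a gap of length k costs
    ``gap_open + k * gap_extend``.
    """

    matrix_name: str | None = "BLOSUM62"
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes and must be >= 0")


#: Community-default protein scoring.
PROTEIN_SCHEME = ScoringScheme("BLOSUM62", gap_open=11.0, gap_extend=1.0)
#: Nucleotide scoring (match +2 / mismatch -3 / open 5 / extend 2).
NUCLEOTIDE_SCHEME = ScoringScheme(None, match=2.0, mismatch=-3.0, gap_open=5.0, gap_extend=2.0)


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    columns_counted: int


def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    if scheme.matrix_name:
        al.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    else:
        al.match_score = scheme.match
        al.mismatch_score = scheme.mismatch
    # Biopython scores the first gapped position with open_gap_score
    al.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    al.extend_gap_score = -scheme.gap_extend
    return al


def global_align(a: str, b: str, scheme: ScoringScheme = PROTEIN_SCHEME,
                 policy: str = "excl_terminal_gaps") -> PairwiseAlignment:
    """Optimal global alignment of two sequences under affine gaps.

    The traceback is deterministic (Biopython's canonical first alignment).
    Raises when a sequence is empty or contains characters outside the
    scheme's alphabet.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    al = _aligner(scheme)
    if scheme.matrix_name:
        alphabet = set(str(al.substitution_matrix.alphabet))
        bad = (set(a) | set(b)) - alphabet
        if bad:
            raise ValueError(f"characters {sorted(bad)!r} absent from {scheme.matrix_name}")
    elif (set(a) | set(b)) - set("ACGTN"):
        raise ValueError("nucleotide scheme expects A/C/G/T/N sequences")
    aln = al.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    pa = PairwiseAlignment(ga, gb, float(aln.score), 0.0, 0)
    pa.identity_pct = percent_identity(pa, policy)
    return pa


def percent_identity(aln: PairwiseAlignment, policy: str = "excl_terminal_gaps") -> float:
    """Percent of identical residue pairs over counted columns (2 decimals).

    Under ``excl_terminal_gaps`` (default), columns inside leading or
    trailing gap runs of either row are excluded, so a partial sequence is
    compared over its overlap with a full-length one; ``aligned_columns``
    counts every column.
    """
    ga, gb = aln.aligned_a, aln.aligned_b
    if len(ga) != len(gb):
        raise ValueError("aligned rows differ in length")
    lo, hi = 0, len(ga)
    if policy == "excl_terminal_gaps":
        for row in (ga, gb):
            first = len(row) - len(row.lstrip("-"))
            last = len(row.rstrip("-"))
            lo, hi = max(lo, first), min(hi, last)
    elif policy != "aligned_columns":
        raise ValueError(f"unknown identity policy {policy!r}")
    if hi <= lo:
        raise ValueError("no columns to count under this policy")
    cols = range(lo, hi)
    ident = sum(1 for i in cols if ga[i] == gb[i] and ga[i] != "-")
    aln.columns_counted = hi - lo
    return round(100.0 * ident / (hi - lo), 2)


#: The canonical 38 baculovirus core genes (replication, transcription,
#: packaging/assembly, and per os infectivity factors), including ac110 (pif-8).
CORE_GENE_NAMES = (
    "lef-1", "lef-2", "dnapol", "helicase",                      # replication
    "lef-4", "lef-5", "lef-8", "lef-9", "p47",                   # transcription
    "p6.9", "vp39", "vp1054", "vlf-1", "vp91", "38k",            # nucleocapsid
    "ac53", "ac78", "gp41", "ac81", "p33", "odv-e25", "p18",     # assembly/ODV
    "odv-e18", "odv-ec27", "ac109", "p49", "ac142", "desmoplakin",
    "p74", "pif-1", "pif-2", "pif-3", "pif-4", "pif-5",          # per os infectivity
    "pif-6", "ac110", "odv-e56-like", "ac68",
)
assert len(CORE_GENE_NAMES) == 38


@dataclass
class CoreGeneHit:
    core_gene: str
    query_taxon: str
    best_orf: str
    identity_pct: float
    found: bool


def inventory_core_genes(proteins: list[tuple[str, str]],
                         reference_set: list[tuple[str, str]],
                         floor: float = 15.0,
                         query_taxon: str = "query",
                         scheme: ScoringScheme = PROTEIN_SCHEME) -> list[CoreGeneHit]:
    """Best-identity match of each reference core gene against a proteome.

    For each reference, every protein is globally aligned and the highest
    identity wins (ties: first ORF id in input order); the gene is
    ``found`` when that identity reaches ``floor`` percent.  An empty
    proteome yields all-not-found hits, not an error.
    """
    hits = []
    for gene, ref_seq in reference_set:
        best_orf, best_id = "", 0.0
        for orf_id, seq in proteins:
            if not seq:
                continue
            ident = global_align(seq, ref_seq, scheme).identity_pct
            if ident > best_id:
                best_orf, best_id = orf_id, ident
        found = bool(best_orf) and best_id >= floor
        hits.append(CoreGeneHit(gene, query_taxon, best_orf if found else "",
                                best_id, found))
    return hits


@dataclass
class IdentitySummary:
    per_gene: list[tuple[str, float]]
    min: float
    max: float
    median: float


def identity_summary(hits: list[CoreGeneHit]) -> IdentitySummary:
    """Min / max / median identity over found hits (even count: mean of central pair)."""
    found = [(h.core_gene, h.identity_pct) for h in hits if h.found]
    if not found:
        raise ValueError("no found core-gene hits to summarize")
    vals = [v for _, v in found]
    return IdentitySummary(found, min(vals), max(vals), float(median(vals)))
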