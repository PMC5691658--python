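"""Synthetic genomes, pileups, and alignments with recorded ground truth.

Every generator here is a pure function of its configuration and seed, and
returns the planted truth alongside the data, so each pipeline stage can be
tested as a recovery experiment: the ORF caller against planted coding
regions, the hr scanner against mutated copies of the 48-bp unit consensus,
the variant caller against planted allele frequencies sampled binomially at
the target depth, and the tree builder against alignments evolved on a
known phylogeny.

The default fixture emulates the headline structure of a group II
alphabaculovirus isolate sequenced deeply from a single population:
a circular ~120 kb genome at 40% G+C carrying 130 non-overlapping coding
regions, five hr regions with 1–4 unit copies each, and 878 low-frequency
polymorphisms (ten at >= 8%, the rest in a 3.0–5.5% bulk) observed at an
average read depth of 941x.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .genome import CircularGenome, reverse_complement
from .hr import HR_CONSENSUS, DegenerateConsensus
from .homology import CORE_GENE_NAMES
from .orfs import STOP_CODONS, translate_codon
from .phylogeny import GeneAlignment, PhylogeneticTree
from .variants import PileupColumn

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BASES = np.array(list("ACGT"))
_STOPS = sorted(STOP_CODONS)


# ---------------------------------------------------------------------------
# Configuration and truth records

@dataclass
class VariantPlan:
    """One planted polymorphism.

    ``effect`` requests placement inside a planted coding region with the
    stated coding consequence; ``group`` ties several plans to the same
    host region (used for the two co-located high-frequency substitutions).
    """

    frequency: float  # percent of reads carrying the alternate allele
    kind: str = "SNP"  # SNP | deletion | insertion
    effect: str | None = None  # synonymous | nonsynonymous | None = anywhere
    position: int | None = None  # explicit 1-based site, optional
    length: int = 4  # indel length
    group: int | None = None


def default_variant_plans() -> list[VariantPlan]:
    """The named high-frequency variants of the default fixture.

    Five reported substitutions at {17.44, 14.63, 12.5, 11.08, 10.10}%
    (one synonymous, four nonsynonymous, two of them 11 nt apart in one
    gene), five further >= 8% variants placed just below the least frequent
    reported one — at least 2 binomial SE above the 8% reporting boundary
    at 941x depth — and two 4-nt deletions at ~5% inside coding regions.
    The low-frequency bulk is configured separately (``n_bulk_snps``).
    """
    return [
        VariantPlan(17.44, effect="synonymous"),
        VariantPlan(14.63, effect="nonsynonymous"),
        VariantPlan(12.5, effect="nonsynonymous"),
        VariantPlan(11.08, effect="nonsynonymous", group=1),
        VariantPlan(10.10, effect="nonsynonymous", group=1),
        VariantPlan(9.90), VariantPlan(9.95), VariantPlan(10.00),
        VariantPlan(10.05), VariantPlan(10.08),
        VariantPlan(5.2, kind="deletion", length=4, effect="host_orf"),
        VariantPlan(5.2, kind="deletion", length=4, effect="host_orf"),
    ]


@dataclass
class GenomeSimConfig:
    length: int = 120_000
    gc: float = 0.40
    n_orfs: int = 130
    orf_codon_range: tuple[int, int] = (50, 300)
    hr_plan: list[tuple[int, float]] = field(
        default_factory=lambda: [(1, 0.08), (2, 0.08), (3, 0.08), (4, 0.08), (4, 0.08)]
    )
    variant_plans: list[VariantPlan] = field(default_factory=default_variant_plans)
    n_bulk_snps: int = 866
    bulk_freq_range: tuple[float, float] = (3.0, 5.5)
    depth: float = 941.0
    seed: int = 42
    hr_consensus: str = HR_CONSENSUS
    hr_unit_gap_range: tuple[int, int] = (60, 200)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be a fraction in [0, 1]")
        for cc, p in self.hr_plan:
            if cc < 1 or not 0.0 <= p <= 1.0:
                raise ValueError("hr_plan entries need copy_count >= 1 and prob in [0, 1]")


@dataclass
class PlantedOrf:
    start: int  # transcript-oriented, first nt of start codon (1-based)
    end: int  # last nt of stop codon
    strand: str
    n_codons: int
    protein: str


@dataclass
class PlantedRepeat:
    position: int  # 1-based leftmost genomic nt
    strand: str
    sequence: str  # strand-oriented unit as planted
    n_mutations: int


@dataclass
class PlantedHrRegion:
    copy_count: int
    units: list[PlantedRepeat]


@dataclass
class PlantedVariant:
    position: int
    ref: str
    alt: str  # SNP: base on the reference strand; deletion: length; insertion: seq
    kind: str
    frequency: float
    effect: str  # intended coding effect, "" when unconstrained
    orf_index: int  # index into GroundTruth.orfs, -1 when intergenic/unconstrained


@dataclass
class GroundTruth:
    seed: int
    genome_length: int
    orfs: list[PlantedOrf] = field(default_factory=list)
    hr_regions: list[PlantedHrRegion] = field(default_factory=list)
    variants: list[PlantedVariant] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            seed=d["seed"], genome_length=d["genome_length"],
            orfs=[PlantedOrf(**o) for o in d["orfs"]],
            hr_regions=[PlantedHrRegion(r["copy_count"],
                                        [PlantedRepeat(**u) for u in r["units"]])
                        for r in d["hr_regions"]],
            variants=[PlantedVariant(**v) for v in d["variants"]],
        )


# ---------------------------------------------------------------------------
# Genome simulation

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _codon_probs(gc: float) -> np.ndarray:
    """Base composition for sense codons hitting the target G+C.

    Rejecting stop codons (all A/T-rich) biases accepted codons toward
    G+C, so the sampling composition is solved (bisection) such that the
    expected G+C *conditional on not drawing a stop* equals the target.
    """

    def cond_gc(x: float) -> float:
        pa = pt = (1 - x) / 2
        pg = x / 2
        p_stop = pt * pa * (pa + 2 * pg)  # TAA, TAG, TGA
        return (3 * x - 2 * pt * pa * pg) / (3 * (1 - p_stop))

    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if cond_gc(mid) < gc:
            lo = mid
        else:
            hi = mid
    return _base_probs((lo + hi) / 2)


def _random_codons(n: int, rng: np.random.Generator, probs: np.ndarray) -> list[str]:
    """n sense codons drawn from the background composition (stops rejected)."""
    out: list[str] = []
    while len(out) < n:
        draw = rng.choice(4, size=(n - len(out), 3), p=probs)
        for trip in draw:
            codon = "".join(_BASES[trip])
            if codon not in STOP_CODONS:
                out.append(codon)
    return out


def _mutate_unit(consensus: DegenerateConsensus, prob: float,
                 rng: np.random.Generator) -> tuple[str, int]:
    """Mutate non-strict (lowercase) consensus positions with per-base prob."""
    seq = list(consensus.sequence.upper())
    strict = consensus.strict_positions
    n_mut = 0
    for i in range(len(seq)):
        if i in strict or rng.random() >= prob:
            continue
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[i] = choices[rng.integers(len(choices))]
        n_mut += 1
    return "".join(seq), n_mut


def _place_blocks(length: int, hr_blocks: list[int], orf_lengths: list[int],
                  rng: np.random.Generator, hr_min_sep: int = 5000):
    """Lay out hr region blocks at dispersed anchors, then ORFs in the gaps.

    Returns (hr_starts, orf_starts) as 0-based genomic offsets; raises
    RuntimeError when the requested features cannot be packed.
    """
    used: list[tuple[int, int]] = []  # half-open, non-overlapping, sorted
    hr_starts: list[int] = []
    k = len(hr_blocks)
    for i, blk in enumerate(hr_blocks):
        anchor = int(length * (i + 0.5) / k)
        jitter = int(rng.integers(-length // 50, length // 50 + 1))
        start = max(0, min(length - blk, anchor + jitter))
        hr_starts.append(start)
        used.append((start, start + blk))
    used.sort()
    for (a, b), (c, _) in zip(used, used[1:]):
        if c - a < hr_min_sep:
            raise RuntimeError("hr regions too close for unambiguous clustering")

    free: list[tuple[int, int]] = []
    cursor = 0
    for a, b in used:
        if a > cursor:
            free.append((cursor, a))
        cursor = b
    if cursor < length:
        free.append((cursor, length))
    if not hr_blocks:
        free = [(0, length)]

    orf_starts: list[tuple[int, int]] = []  # (plan index, start)
    order = sorted(range(len(orf_lengths)), key=lambda i: -orf_lengths[i])
    for idx in order:
        need = orf_lengths[idx] + 2  # keep a >=1 nt margin on each side
        fits = [i for i, (a, b) in enumerate(free) if b - a >= need]
        if not fits:
            raise RuntimeError("infeasible packing of planted coding regions")
        weights = np.array([free[i][1] - free[i][0] - need + 1 for i in fits], float)
        gi = fits[rng.choice(len(fits), p=weights / weights.sum())]
        a, b = free[gi]
        off = int(rng.integers(0, b - a - need + 1))
        start = a + off + 1
        orf_starts.append((idx, start))
        free[gi : gi + 1] = [s for s in [(a, start - 1), (start + orf_lengths[idx] + 1, b)]
                             if s[1] - s[0] > 0]
    orf_starts.sort(key=lambda t: t[0])
    return hr_starts, [s for _, s in orf_starts]


def _pick_effect_site(orf: PlantedOrf, cds: str, effect: str,
                      rng: np.random.Generator,
                      paired_offset: int | None = None) -> tuple[int, str] | None:
    """Find (transcript offset, transcript alt base) realizing a coding effect.

    Skips the start and stop codons.  With ``paired_offset`` the returned
    offset also admits a nonsynonymous change at offset + paired_offset.
    """

    def alt_for(t: int, want: str) -> str | None:
        cidx, off = divmod(t, 3)
        codon = cds[3 * cidx : 3 * cidx + 3]
        aa = translate_codon(codon)
        for alt in rng.permutation(list("ACGT")):
            if alt == codon[off]:
                continue
            alt_codon = codon[:off] + alt + codon[off + 1 :]
            alt_aa = translate_codon(alt_codon)
            if want == "synonymous" and alt_aa == aa:
                return alt
            if want == "nonsynonymous" and alt_aa not in (aa, "*"):
                return alt
        return None

    lo, hi = 3, 3 * orf.n_codons  # skip ATG and stop codon
    for t in rng.permutation(np.arange(lo, hi)):
        t = int(t)
        if paired_offset is not None and not lo <= t + paired_offset < hi:
            continue
        alt = alt_for(t, effect)
        if alt is None:
            continue
        if paired_offset is not None and alt_for(t + paired_offset, "nonsynonymous") is None:
            continue
        return t, alt
    return None


def _transcript_to_genomic(orf: PlantedOrf, t: int, length: int) -> int:
    """0-based genomic position of transcript offset t."""
    if orf.strand == "+":
        return (orf.start - 1 + t) % length
    return (orf.start - 1 - t) % length


def simulate_genome(cfg: GenomeSimConfig) -> tuple[CircularGenome, GroundTruth]:
    """Build a circular genome with planted ORFs, hr regions, and variants.

    The background is drawn i.i.d. at the target G+C; coding regions are
    ATG + stop-free codons + stop on random strands; hr units are copies of
    the consensus mutated only at its variable (lowercase) positions; the
    variant plan is resolved to concrete genomic sites, honoring requested
    coding effects inside planted ORFs.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.length
    probs = _base_probs(cfg.gc)
    seq = _BASES[rng.choice(4, size=L, p=probs)]

    consensus = DegenerateConsensus(cfg.hr_consensus)
    K = consensus.length
    glo, ghi = cfg.hr_unit_gap_range

    # resolve hr block layouts (unit offsets within each region block)
    hr_layouts = []
    hr_block_lengths = []
    for cc, prob in cfg.hr_plan:
        offsets, pos = [], 0
        for u in range(cc):
            offsets.append(pos)
            pos += K + (int(rng.integers(glo, ghi + 1)) if u < cc - 1 else 0)
        hr_layouts.append((offsets, prob))
        hr_block_lengths.append(pos)

    lo_c, hi_c = cfg.orf_codon_range
    orf_codons = [int(rng.integers(lo_c, hi_c + 1)) for _ in range(cfg.n_orfs)]
    orf_nt = [3 * (n + 1) for n in orf_codons]

    hr_starts, orf_starts = _place_blocks(L, hr_block_lengths, orf_nt, rng)

    truth = GroundTruth(seed=cfg.seed, genome_length=L)

    for (offsets, prob), block_start in zip(hr_layouts, hr_starts):
        units = []
        for off in offsets:
            unit, n_mut = _mutate_unit(consensus, prob, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            planted = unit if strand == "+" else reverse_complement(unit)
            s = block_start + off
            seq[s : s + K] = list(planted)
            units.append(PlantedRepeat(s + 1, strand, unit, n_mut))
        truth.hr_regions.append(PlantedHrRegion(len(units), units))

    orf_cds: list[str] = []
    codon_probs = _codon_probs(cfg.gc)
    for n_codons, s in zip(orf_codons, orf_starts):
        cds = "ATG" + "".join(_random_codons(n_codons - 1, rng, codon_probs)) \
              + _STOPS[rng.integers(3)]
        strand = "+" if rng.random() < 0.5 else "-"
        planted = cds if strand == "+" else reverse_complement(cds)
        seq[s : s + len(cds)] = list(planted)
        if strand == "+":
            start1, end1 = s + 1, s + len(cds)
        else:
            start1, end1 = s + len(cds), s + 1
        protein = "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds) - 3, 3))
        truth.orfs.append(PlantedOrf(start1, end1, strand, n_codons, protein))
        orf_cds.append(cds)

    genome = CircularGenome("synthetic_genome", "".join(seq))

    # --- resolve the variant plan to concrete sites -----------------------
    used_positions: set[int] = set()
    eligible = [i for i, o in enumerate(truth.orfs) if o.n_codons >= 30]
    host_pool = [eligible[k] for k in rng.permutation(len(eligible))]
    group_hosts: dict[int, int] = {}
    group_anchor: dict[int, int] = {}

    def next_host() -> int:
        if not host_pool:
            raise RuntimeError("variant plan needs more planted coding regions")
        return host_pool.pop()

    for plan in cfg.variant_plans:
        if plan.position is not None:
            pos0 = plan.position - 1
            ref = genome.sequence[pos0]
            if plan.kind == "SNP":
                alt = [b for b in "ACGT" if b != ref][rng.integers(3)]
            else:
                alt = str(plan.length)
            truth.variants.append(PlantedVariant(plan.position, ref, alt, plan.kind,
                                                 plan.frequency, plan.effect or "", -1))
            used_positions.add(pos0)
            continue
        if plan.kind in ("deletion", "insertion"):
            oi = next_host()
            orf = truth.orfs[oi]
            t = int(rng.integers(3, 3 * orf.n_codons - plan.length))
            pos0 = _transcript_to_genomic(orf, t, L)
            ref = genome.sequence[pos0]
            if plan.kind == "insertion":
                alt = "".join(_BASES[rng.choice(4, size=plan.length, p=probs)])
            else:
                alt = str(plan.length)
            truth.variants.append(PlantedVariant(pos0 + 1, ref, alt, plan.kind,
                                                 plan.frequency,
                                                 "frameshift" if plan.length % 3 else "nonsynonymous",
                                                 oi))
            used_positions.add(pos0)
        elif plan.effect in ("synonymous", "nonsynonymous"):
            if plan.group is not None and plan.group in group_hosts:
                # the paired site 11 nt downstream of the group anchor
                oi = group_hosts[plan.group]
                orf = truth.orfs[oi]
                t = group_anchor[plan.group] + 11
                cidx, off = divmod(t, 3)
                codon = orf_cds[oi][3 * cidx : 3 * cidx + 3]
                aa = translate_codon(codon)
                alt_t = None
                for alt in rng.permutation(list("ACGT")):
                    alt = str(alt)
                    if alt == codon[off]:
                        continue
                    alt_aa = translate_codon(codon[:off] + alt + codon[off + 1 :])
                    if alt_aa not in (aa, "*"):
                        alt_t = alt
                        break
                t_use, alt_base_t = t, alt_t
            else:
                oi = next_host()
                orf = truth.orfs[oi]
                paired = 11 if plan.group is not None else None
                found = _pick_effect_site(orf, orf_cds[oi], plan.effect, rng,
                                          paired_offset=paired)
                if found is None:
                    raise RuntimeError("could not realize requested coding effect")
                t_use, alt_base_t = found
                if plan.group is not None:
                    group_hosts[plan.group] = oi
                    group_anchor[plan.group] = t_use
            pos0 = _transcript_to_genomic(orf, t_use, L)
            alt_ref_strand = (alt_base_t if orf.strand == "+"
                              else reverse_complement(alt_base_t))
            truth.variants.append(PlantedVariant(pos0 + 1, genome.sequence[pos0],
                                                 alt_ref_strand, "SNP",
                                                 plan.frequency, plan.effect, oi))
            used_positions.add(pos0)
        else:  # unconstrained SNP, placed anywhere free
            while True:
                pos0 = int(rng.integers(L))
                if pos0 not in used_positions:
                    break
            ref = genome.sequence[pos0]
            alt = [b for b in "ACGT" if b != ref][rng.integers(3)]
            truth.variants.append(PlantedVariant(pos0 + 1, ref, alt, "SNP",
                                                 plan.frequency, "", -1))
            used_positions.add(pos0)

    flo, fhi = cfg.bulk_freq_range
    for _ in range(cfg.n_bulk_snps):
        while True:
            pos0 = int(rng.integers(L))
            if pos0 not in used_positions:
                break
        ref = genome.sequence[pos0]
        alt = [b for b in "ACGT" if b != ref][rng.integers(3)]
        freq = round(float(rng.uniform(flo, fhi)), 2)
        truth.variants.append(PlantedVariant(pos0 + 1, ref, alt, "SNP", freq, "", -1))
        used_positions.add(pos0)

    truth.variants.sort(key=lambda v: v.position)
    return genome, truth


# ---------------------------------------------------------------------------
# Pileup simulation

def simulate_pileup(genome: CircularGenome, truth: GroundTruth, depth: float = 941.0,
                    error_rate: float = 0.001, seed: int = 0) -> list[PileupColumn]:
    """Per-position read pileup: Poisson depth, binomial alternate alleles.

    Planted variants draw their read support binomially at the planted
    frequency; sequencing errors convert reference reads to uniformly
    chosen other bases at ``error_rate``.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    L = genome.length
    depths = (rng.poisson(depth, size=L) if depth > 0
              else np.zeros(L, dtype=np.int64))

    alt_counts = np.zeros(L, dtype=np.int64)
    variant_support: dict[int, list[tuple[PlantedVariant, int]]] = {}
    for v in truth.variants:
        pos0 = v.position - 1
        d_avail = int(depths[pos0] - alt_counts[pos0])
        k = int(rng.binomial(max(d_avail, 0), v.frequency / 100.0))
        alt_counts[pos0] += k
        variant_support.setdefault(pos0, []).append((v, k))

    ref_pool = depths - alt_counts
    errors = rng.binomial(ref_pool, error_rate)
    e1 = rng.binomial(errors, 1 / 3)
    e2 = rng.binomial(errors - e1, 1 / 2)
    e3 = errors - e1 - e2

    columns: list[PileupColumn] = []
    err_split = np.stack([e1, e2, e3], axis=1)
    nonzero_err = errors > 0
    for pos0 in range(L):
        d = int(depths[pos0])
        if d == 0:
            continue
        ref = genome.sequence[pos0]
        counts = {ref: int(ref_pool[pos0] - errors[pos0])}
        if nonzero_err[pos0]:
            others = [b for b in "ACGT" if b != ref]
            for b, e in zip(others, err_split[pos0]):
                if e:
                    counts[b] = counts.get(b, 0) + int(e)
        ins: dict[str, int] = {}
        dels: dict[int, int] = {}
        for v, k in variant_support.get(pos0, []):
            if k == 0:
                continue
            if v.kind == "SNP":
                counts[v.alt] = counts.get(v.alt, 0) + k
            elif v.kind == "insertion":
                ins[v.alt] = ins.get(v.alt, 0) + k
            else:
                dels[int(v.alt)] = dels.get(int(v.alt), 0) + k
        columns.append(PileupColumn(pos0 + 1, ref, d,
                                    {b: c for b, c in counts.items() if c > 0},
                                    ins, dels))
    return columns


# ---------------------------------------------------------------------------
# Alignment evolution on a tree

def _parse_tree(tree) -> "dendropy.Tree":
    import dendropy

    if isinstance(tree, PhylogeneticTree):
        tree = tree.to_newick()
    if isinstance(tree, str):
        return dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    return tree


def evolve_alignment(tree, n_sites: int, seed: int = 0,
                     gene: str = "gene") -> GeneAlignment:
    """Evolve amino-acid sequences down a tree with branch lengths.

    The root sequence is uniform over the 20 amino acids; substitution
    events arrive per site as a Poisson process at the branch-length rate
    and each event replaces the residue with one of the other 19, chosen
    uniformly.  (The exactly matching distance inversion is the ``jc20``
    model; the Poisson correction is its large-alphabet limit.)  Leaf rows
    come back gap-free; a zero-length tree yields identical rows.
    """
    rng = np.random.default_rng(seed)
    t = _parse_tree(tree)
    root_state = rng.integers(0, 20, size=n_sites)
    states = {t.seed_node: root_state}
    taxa, rows = [], []
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        b = node.edge.length or 0.0
        parent = states[node.parent_node].copy()
        if b > 0:
            events = rng.poisson(b, size=n_sites)
            for site in np.flatnonzero(events):
                s = parent[site]
                for _ in range(int(events[site])):
                    s = (s + 1 + rng.integers(19)) % 20
                parent[site] = s
        states[node] = parent
        if node.is_leaf():
            taxa.append(node.taxon.label)
            rows.append("".join(AMINO_ACIDS[i] for i in parent))
    return GeneAlignment(gene, taxa, rows)


def evolve_gene_alignments(tree, gene_lengths: list[int], seed: int = 0) -> list[GeneAlignment]:
    """Independent per-gene alignments on one tree (seeds spawned per gene)."""
    return [evolve_alignment(tree, n, seed=(seed * 10_007 + i + 1) % (2**31 - 1),
                             gene=f"gene{i + 1:02d}")
            for i, n in enumerate(gene_lengths)]


# ---------------------------------------------------------------------------
# Synthetic core-gene references

def synthetic_core_gene_references(seed: int = 7,
                                   length_range: tuple[int, int] = (120, 400)
                                   ) -> list[tuple[str, str]]:
    """A synthetic stand-in reference set for the 38 baculovirus core genes.

    Random amino-acid sequences labelled with the canonical core-gene
    names; real reference proteomes are swappable wherever this set is
    accepted.  Synthetic: carries no biological signal beyond its role as
    planted truth.
    """
    rng = np.random.default_rng(seed)
    refs = []
    for name in CORE_GENE_NAMES:
        n = int(rng.integers(*length_range))
        refs.append((name, "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))))
    return refs


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def mutated_proteome(references: list[tuple[str, str]], rate: float = 0.30,
                     n_decoys: int = 5, seed: int = 11) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Proteome of mutated reference copies plus unrelated decoys.

    Returns (proteome, truth) where truth maps each reference gene to the
    ORF id carrying its mutated copy.
    """
    rng = np.random.default_rng(seed)
    entries = []
    truth = {}
    for gene, ref in references:
        entries.append(("ref", gene, mutate_protein(ref, rate, rng)))
    for d in range(n_decoys):
        n = int(rng.integers(120, 400))
        entries.append(("decoy", f"decoy{d}", "".join(AMINO_ACIDS[i]
                                                      for i in rng.integers(0, 20, n))))
    entries = [entries[k] for k in rng.permutation(len(entries))]
    proteome = []
    for i, (kind, label, seq) in enumerate(entries, start=1):
        orf_id = f"orf{i:03d}"
        proteome.append((orf_id, seq))
        if kind == "ref":
            truth[label] = orf_id
    return proteome, truth
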