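# Methods

This note records the models, conventions, and numerical choices behind
`obgenome`, and what the synthetic-data experiments do and do not establish.

## Coordinates and the circle

All coordinates in the data model and GFF3 output are 1-based inclusive
(GenBank convention). A feature with `start > end` plus a `wraps` flag denotes
an origin-crossing feature on a circular genome; GFF3 emits it as two
part-lines sharing an ID. ORF records are transcript-oriented (`start` is the
first nucleotide of the start codon), so minus-strand ORFs have `start > end`
in genomic terms; the feature/GFF3 layer converts to min/max plus strand. The
code never assumes a particular rotation of the circle: rotating the genome
permutes coordinates but preserves the multiset of (strand, length, protein)
of called ORFs, which is property-tested.

`N` is tolerated in genomes; ORF candidates and repeat matches containing `N`
are flagged (`contains_n`) rather than silently scored, and `N` is excluded
from the G+C denominator. Ambiguity codes beyond `N` are rejected at ingest.

## ORF calling and selection

Reading codons in steps of three around a circle of length `L` partitions the
positions of each strand into 3 cycles when `L ≡ 0 (mod 3)` and a single
cycle of length `L` otherwise. ORFs are delimited per cycle between
consecutive stop codons; for each stop the most upstream start codon gives
the reported candidate (ties cannot arise), with a cap of one full circle so
no ORF overlaps itself. Start codons default to `{ATG}` — every named gene in
the genomes this models initiates at ATG — and stops are `{TAA, TAG, TGA}`
(translation table 1). Equality with an exhaustive per-position oracle is
enforced on dozens of random genomes, circular and linear, including lengths
not divisible by 3.

Selection: a candidate of ≥ `min_codons` (default 50, stop excluded) is
accepted iff it has homology evidence, or it overlaps every larger
already-accepted ORF by fewer than `max_overlap` nt (default 75; shared
genomic positions on the circle, strand-agnostic) and both ab initio
predictors flag it. "Larger" compares codon counts with ties broken by
earlier linearized start, and candidates are processed in that order, so the
accepted set is deterministic and independent of input order. BLASTp,
fgenesV, and ZCURVE are consumed as an evidence TSV, never re-run; the
significance cutoff applied upstream of that table is the supplier's
(conventionally E ≤ 1e-5).

## hr detection

The unit repeat is described by a mixed-case degenerate consensus (default:
the 48-bp imperfect inverted repeat; 19 uppercase = invariant positions).
Scanning is windowed (no indels within units — units are implicitly aligned
by consensus coordinates; a unit with an internal indel would need the
aligner and is a known limitation). Default budget: ≤ 12 total mismatches
(25% of 48) with strict mode on (uppercase positions exact). The 25% budget
tolerates the degenerate copies while keeping the random-match probability
negligible — with 19 exact positions, a random 120 kb background yields zero
hits (seed-fixed test). Because the consensus is itself ~79% palindromic, a
unit is usually detected on both strands; overlapping windows are resolved by
keeping the lower-mismatch one (ties: lower position, then plus strand).

Clustering is single-linkage along the circle with `max_gap` = 1000 nt
start-to-start (regions in the genomes modeled here have intra-region
neighbor distances well under 1 kb and inter-region distances of tens of kb);
the gap between the last and first match across the origin is considered, so
a region may wrap. The rendered consensus follows the case/shading
convention: all-identical column → uppercase, black; majority (> 50%)
residue → lowercase, black; otherwise purine or pyrimidine class > 50% →
gray (letter = unique plurality residue, else `n`); otherwise unshaded `n`.

## Polymorphism calling

Canonical input is a pileup TSV (position, ref, depth, A/C/G/T counts,
insertion and deletion observations) — the assembler's read stack summarized
one row per position; the study this emulates did not deposit raw reads, so
the caller deliberately starts from this minimal exchangeable format. Calls
are threshold filters, not genotype likelihoods: depth ≥ 20, alt reads ≥ 2,
frequency ≥ 1% (percent of column depth, also for indels; multi-allelic
columns give one call per allele). The low floors are intentional — sub-6%
variants are biologically meaningful here — but at moderate depth (~200×) a
sequencing-error doublet can clear 1%, so the reliable regime is deep data
(at 941× an error doublet sits at 0.2%). Effects are classified by
substituting the alt base into the ORF-strand codon: identical amino acid →
synonymous; stop gain → nonsense; otherwise nonsynonymous; indels of length
≢ 0 (mod 3) inside an ORF → frameshift, in-frame indels → nonsynonymous; a
call inside two overlapping ORFs is reported once per ORF.

## Alignment and the core-gene inventory

Global affine alignment is Needleman–Wunsch–Gotoh via Biopython's
`PairwiseAligner` (deterministic first traceback), BLOSUM62 with gap
open 11 / extend 1 for proteins and +2/−3, open 5 / extend 2 for
nucleotides — community defaults, since no single tool's parameters are
canonical for this task. Percent identity counts identical residue pairs
over counted columns; the default policy excludes leading/trailing gap runs
of either row so a partial sequence is compared over its overlap. Scores are
verified against exhaustive enumeration of all alignments for short inputs.

The inventory takes each reference core gene, aligns it against every
proteome entry, and keeps the best identity (found iff ≥ 15%). Local
BLASTp-style search is intentionally not reimplemented — presence/absence at
that floor only needs global alignment against curated references. The
packaged reference set is **synthetic** (random sequences labelled with the
canonical 38 core-gene names, generated deterministically): it carries no
biological signal and exists so the inventory can be exercised as a planted
recovery experiment (references mutated at 30% of sites are all recovered
and correctly mapped). Real reference proteomes drop in via `--refs`.

## Distances, neighbor joining, bootstrap

Gap handling is pairwise deletion throughout (a column is dropped only for
sequence pairs gapped in it). Models on the observed difference fraction `p`:

| model     | d(p)                       | exact for                         |
|-----------|----------------------------|-----------------------------------|
| `p`       | p                          | —                                 |
| `poisson` | −ln(1−p)                   | infinite-alphabet Poisson process |
| `gamma`   | a((1−p)^(−1/a) − 1)        | rate variation, shape `a`         |
| `jc20`    | −(19/20)·ln(1 − 20p/19)    | 20-state equal-rates process      |

Maximum-likelihood (e.g. JTT) distances are not implemented; the gamma
correction with a user-supplied shape (default 1.0) is the stand-in, and
shape estimation from data is out of scope. Saturated pairs (`p` at the
model bound, or no comparable columns) raise a dedicated error.

Neighbor joining uses the Q-criterion with deterministic tie-breaks (lowest
index pair); negative branch lengths are clamped to zero with a warning; the
unrooted tree is serialized as Newick with a trifurcating root. On additive
matrices NJ is exact — verified against the generating trees and against
brute-force least-squares search over every unrooted topology (≤ 6 taxa),
and cross-checked against scikit-bio's implementation on generic matrices.
Bootstrap resamples the full concatenated column set with replacement;
support of an internal edge is the percent of successful replicate trees
containing the same bipartition (replicates with saturated distances are
dropped and counted; > 10% dropped is an error). Percents are formatted to
2 decimals and branch lengths to 6, making outputs byte-diffable.

## The synthetic-data generator

The generator emulates a deeply sequenced, low-diversity isolate of a large
circular dsDNA virus; its defaults are the study conditions of the pipeline:

* **Genome**: 120,000 nt i.i.d. background at 40% G+C. 130 non-overlapping
  coding regions (50–300 codons, random strands) are planted as
  ATG + stop-free codons + stop; the codon base composition is solved by
  bisection so that expected G+C conditional on rejecting stop codons equals
  the target (naive rejection would inflate G+C by ~0.6 pp at this coding
  density). Realized G+C concentrates within 0.5 pp of target.
* ***hr* regions**: five regions with copy counts (1, 2, 3, 4, 4), units
  spaced 60–200 nt apart, regions anchored at dispersed loci ≫ the
  clustering gap. Units mutate only the variable (lowercase) consensus
  positions, each with probability 0.08, so strict-mode scanning is a fair
  recovery test.
* **Variants**: 878 planted polymorphisms at 941× mean depth (Poisson per
  position; alternate reads binomial at the planted frequency; sequencing
  errors at 0.001/base). Five high-frequency substitutions at
  {17.44, 14.63, 12.5, 11.08, 10.10}% — one synonymous, four nonsynonymous,
  two of them 11 nt apart in one gene; five further variants at
  {9.90–10.08}%, placed just below the least frequent of the five (they are
  modeled as the unreported balance of the ten ≥ 8% variants) and ≥ 2
  binomial SE above the 8% boundary; two 4-nt deletions at 5.2% inside
  coding regions; and an 866-SNP bulk at uniform(3.0, 5.5)%. The bulk band
  keeps every planted variant ≥ 3 SE inside the caller's thresholds on both
  sides, so 100% recall and zero false positives are the *expected* outcome
  at this depth, not seed luck; the number of *planted* variants at ≥ 8% is
  exactly ten by construction, while the number of *called* variants at
  ≥ 8% fluctuates by ±1 across seeds because sampled frequencies of the
  near-boundary variants move by ~1 SE (≈ 0.95 pp).
* **Alignments**: sequences evolve down a user tree; per site and branch,
  substitution events arrive Poisson at the branch-length rate, each
  replacing the residue with one of the other 19 uniformly. The exactly
  matching distance inversion is `jc20`; the Poisson correction is its
  large-alphabet limit and is mildly biased at high divergence (−0.036 at
  d = 1.0), so consistency tests use `jc20` or moderate distances.

Every generator is a pure function of configuration + seed (bit-identical
reruns, property-tested).

### What passing tests show — and what they don't

Planted-truth recovery establishes internal correctness: the scanner finds
exactly what the generator hid, under the generator's noise model. Real data
differ in ways the generator does not emulate: codon usage and compositional
skews, overlapping genes, repeat units with internal indels, mapping
artifacts and strand-biased sequencing error, and homology that must be
established by search rather than by construction. Accession-dependent
results (genome length, G+C, ORF and *hr* counts of the deposited isolate,
and identities to its partial-gene comparators) therefore require the real
records, which are not redistributable with the package; the corresponding
test states the drop-in path and fails until they are supplied.

## Problem sizes

The test suite and the acceptance script run the full 120 kb fixture
(941× pileup, ~250 ORF candidates), a 38 × ~250-residue inventory, and a
10-taxon / 38-gene / 5,000-column phylogeny with 100 bootstrap replicates —
sizes chosen so the whole battery completes in well under a minute while
keeping every statistical margin (3 SE bounds, support thresholds) at the
study's own depth and scale. The production bootstrap default stays 500
replicates.
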