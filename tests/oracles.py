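"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (per-position scans, exhaustive
enumeration, least-squares fits over all topologies) and shares no code
with the implementation paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from obgenome.genome import CircularGenome, reverse_complement
from obgenome.orfs import STOP_CODONS

# ---------------------------------------------------------------------------
# ORF scanning


def brute_force_orfs(genome: CircularGenome, min_codons: int = 50,
                     starts=frozenset({"ATG"})) -> set[tuple[str, int, int]]:
    """Every (strand, stop-codon strand position, n_codons), longest per stop.

    Tests every position on both strands independently: extend codon by
    codon from each start codon until a stop, capped at one full circle.
    """
    L = genome.length
    best: dict[tuple[str, int], int] = {}
    for strand in "+-":
        seq = genome.sequence if strand == "+" else reverse_complement(genome.sequence)
        ext = seq + seq + seq if genome.is_circular else seq

        def codon(q):
            return ext[q : q + 3]

        limit = L if genome.is_circular else L - 2
        for p in range(limit):
            if codon(p) not in starts:
                continue
            s = None
            k = 1
            while 3 * (k + 1) <= L:
                q = p + 3 * k
                if not genome.is_circular and q + 2 >= L:
                    break
                if codon(q) in STOP_CODONS:
                    s = k
                    break
                k += 1
            if s is not None and s >= min_codons:
                key = (strand, (p + 3 * s) % L if genome.is_circular else p + 3 * s)
                if best.get(key, -1) < s:
                    best[key] = s
    return {(strand, stop, n) for (strand, stop), n in best.items()}


def candidates_as_oracle_keys(candidates, genome_length: int) -> set[tuple[str, int, int]]:
    """Convert OrfCandidate records to the oracle's (strand, stop, n) keys."""
    out = set()
    for c in candidates:
        if c.strand == "+":
            p = c.start - 1
        else:
            p = genome_length - c.start
        stop = (p + 3 * c.n_codons) % genome_length
        out.add((c.strand, stop, c.n_codons))
    return out


def random_genome(rng: np.random.Generator, length: int,
                  topology: str = "circular") -> CircularGenome:
    bases = np.array(list("ACGT"))
    return CircularGenome("rand", "".join(bases[rng.integers(0, 4, length)]), topology)


# ---------------------------------------------------------------------------
# Alignment


def exhaustive_align_score(a: str, b: str, match: float, mismatch: float,
                           gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap score by enumerating every alignment.

    A gap run of length k costs gap_open + k * gap_extend.  Feasible for
    sequences of length <= ~6.
    """
    best = -float("inf")

    def rec(i: int, j: int, state: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):
            cost = gap_extend + (gap_open if state != "A" else 0)
            rec(i + 1, j, "A", score - cost)
        if j < len(b):
            cost = gap_extend + (gap_open if state != "B" else 0)
            rec(i, j + 1, "B", score - cost)

    rec(0, 0, "", 0.0)
    return best


def column_scan_identity(row_a: str, row_b: str, exclude_terminal: bool) -> float:
    """Direct per-column identity oracle over an existing alignment."""
    lo, hi = 0, len(row_a)
    if exclude_terminal:
        for row in (row_a, row_b):
            lo = max(lo, len(row) - len(row.lstrip("-")))
            hi = min(hi, len(row.rstrip("-")))
    ident = total = 0
    for i in range(lo, hi):
        total += 1
        if row_a[i] == row_b[i] and row_a[i] != "-":
            ident += 1
    return round(100.0 * ident / total, 2)


# ---------------------------------------------------------------------------
# Trees

Edge = tuple[str, str]


def enumerate_topologies(taxa: list[str]) -> list[list[Edge]]:
    """All unrooted binary topologies as edge lists (3 -> 1, ..., 7 -> 945)."""
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    trees: list[tuple[list[Edge], int]] = [([("I0", t) for t in taxa[:3]], 1)]
    for t in taxa[3:]:
        nxt = []
        for edges, ni in trees:
            for k, (u, v) in enumerate(edges):
                w = f"I{ni}"
                nxt.append((edges[:k] + edges[k + 1 :] + [(u, w), (w, v), (w, t)], ni + 1))
        trees = nxt
    return [e for e, _ in trees]


def edge_splits(edges: list[Edge], taxa: list[str]) -> list[frozenset]:
    """For each edge (in order), the leaf set on one fixed side of it."""
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = []
    for u, v in edges:
        # component containing v with edge (u, v) removed
        seen, stack = {v}, [v]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if (x, y) in ((u, v), (v, u)):
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        splits.append(frozenset(s for s in seen if s in set(taxa)))
    return splits


def normalize_split(side: frozenset, taxa: list[str]) -> frozenset:
    full = set(taxa)
    return frozenset(side) if taxa[0] not in side else frozenset(full - side)


def nontrivial_splits(edges: list[Edge], taxa: list[str]) -> set[frozenset]:
    out = set()
    for s in edge_splits(edges, taxa):
        if 2 <= len(s) <= len(taxa) - 2:
            out.add(normalize_split(s, taxa))
    return out


def ols_fit(edges: list[Edge], taxa: list[str], dist: np.ndarray):
    """Least-squares branch lengths for a topology; returns (lengths, residual)."""
    splits = edge_splits(edges, taxa)
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    X = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        y[r] = dist[i, j]
        for c, side in enumerate(splits):
            if (taxa[i] in side) != (taxa[j] in side):
                X[r, c] = 1.0
    lengths, *_ = np.linalg.lstsq(X, y, rcond=None)
    residual = float(np.linalg.norm(X @ lengths - y))
    return lengths, residual


def best_topology_exhaustive(taxa: list[str], dist: np.ndarray):
    """The minimum-residual topology over every unrooted binary tree.

    For an additive matrix the residual of the generating topology is ~0
    and unique; returns (nontrivial splits, split -> OLS length).
    """
    best = None
    for edges in enumerate_topologies(taxa):
        lengths, res = ols_fit(edges, taxa, dist)
        if best is None or res < best[0]:
            best = (res, edges, lengths)
    res, edges, lengths = best
    by_split = {}
    for (u, v), side, ln in zip(edges, edge_splits(edges, taxa), lengths):
        by_split[normalize_split(side, taxa)] = float(ln)
    return nontrivial_splits(edges, taxa), by_split


def random_additive_tree(taxa: list[str], rng: np.random.Generator,
                         low: float = 0.1, high: float = 1.0):
    """A random binary topology with random branch lengths and its distances.

    Returns (distance matrix, nontrivial splits, split -> length map over
    all edges including pendants keyed by the leaf-side split).
    """
    topo = enumerate_topologies(taxa)
    edges = topo[int(rng.integers(len(topo)))]
    lengths = rng.uniform(low, high, size=len(edges))
    splits = edge_splits(edges, taxa)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        tot = sum(ln for side, ln in zip(splits, lengths)
                  if (taxa[i] in side) != (taxa[j] in side))
        d[i, j] = d[j, i] = tot
    by_split = {normalize_split(s, taxa): float(ln) for s, ln in zip(splits, lengths)}
    return d, nontrivial_splits(edges, taxa), by_split


def tree_split_lengths(tree, taxa: list[str]) -> dict[frozenset, float]:
    """(normalized split -> branch length) for every edge of a PhylogeneticTree."""
    full = set(taxa)
    out: dict[frozenset, float] = {}

    def walk(node):
        if node.is_leaf:
            return {node.name}
        below = set()
        for child, ln in node.children:
            cb = walk_child(child, ln)
            below |= cb
        return below

    def walk_child(child, ln):
        below = walk(child)
        side = below if taxa[0] not in below else full - below
        out[frozenset(side)] = out.get(frozenset(side), 0.0) + ln
        return below

    walk(tree.root)
    return out
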