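"""Concatenated-alignment distance phylogenetics with bootstrap supports.

The family-level phylogeny of baculoviruses is anchored on concatenated
amino-acid alignments of the 38 core genes.  This module concatenates
per-gene alignments into a partitioned superalignment, computes pairwise
distances under simple substitution models (p-distance, Poisson
correction, gamma rate-variation correction) with pairwise deletion of
gap sites, infers a minimum-evolution-style tree with the neighbor-joining
heuristic, and attaches nonparametric bootstrap supports obtained by
resampling alignment columns.

Distance formulas (p = observed fraction of differing sites):

* ``p``       d = p
* ``poisson`` d = -ln(1 - p)
* ``gamma``   d = a * ((1 - p)^(-1/a) - 1)          (shape a)
* ``jc20``    d = -(19/20) * ln(1 - 20 p / 19)       (20-state equal-rates)

Maximum-likelihood distances (e.g. JTT) are not implemented; the gamma
correction with a user-set shape is the stand-in, with pairwise deletion
for gaps throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")


@dataclass
class GeneAlignment:
    gene: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError(f"{self.gene}: taxa/rows mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"{self.gene}: duplicate taxa")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError(f"{self.gene}: rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass
class Superalignment:
    taxa: list[str]
    rows: list[str]
    partitions: dict[str, tuple[int, int]]  # gene -> (first, last), 1-based inclusive

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def concatenate(alignments: list[GeneAlignment]) -> Superalignment:
    """Join per-gene alignments taxon-wise, recording the partition table.

    Every alignment must contain exactly the same taxon set (no silent
    gap-filling); rows are ordered by the first alignment's taxa.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    taxa = list(alignments[0].taxa)
    ref = set(taxa)
    for aln in alignments[1:]:
        diff = ref.symmetric_difference(aln.taxa)
        if diff:
            raise ValueError(
                f"alignment {aln.gene!r} taxon set differs: {sorted(diff)}"
            )
    rows = ["".join(aln.row(t) for aln in alignments) for t in taxa]
    partitions, pos = {}, 1
    for aln in alignments:
        partitions[aln.gene] = (pos, pos + aln.length - 1)
        pos += aln.length
    return Superalignment(taxa, rows, partitions)


def p_distance(row_a: str, row_b: str) -> float:
    """Fraction of differing residues over pairwise-deletion columns.

    Columns where either row has a gap are skipped for this pair only;
    raises when no comparable columns remain.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows have unequal lengths")
    comparable = diffs = 0
    for x, y in zip(row_a, row_b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        comparable += 1
        diffs += x != y
    if comparable == 0:
        raise ValueError("no comparable (ungapped) columns between rows")
    return diffs / comparable


@dataclass(frozen=True)
class DistanceModel:
    name: str = "p"  # p | poisson | gamma | jc20
    gamma_shape: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ("p", "poisson", "gamma", "jc20"):
            raise ValueError(f"unknown distance model {self.name!r}")
        if self.name == "gamma" and (self.gamma_shape is None or self.gamma_shape <= 0):
            raise ValueError("gamma model requires a positive shape")


class SaturatedDistanceError(ValueError):
    """Observed divergence at or beyond the model's saturation bound."""


def model_distance(p: float, model: DistanceModel) -> float:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-distance {p} outside [0, 1]")
    if model.name == "p":
        return p
    if model.name == "jc20":
        if p >= 0.95:
            raise SaturatedDistanceError(f"p = {p} saturates the 20-state model")
        return -(19.0 / 20.0) * math.log(1.0 - 20.0 * p / 19.0)
    if p >= 1.0:
        raise SaturatedDistanceError(f"p = {p} saturates the {model.name} model")
    if model.name == "poisson":
        return -math.log(1.0 - p)
    a = model.gamma_shape
    return a * ((1.0 - p) ** (-1.0 / a) - 1.0)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if not np.all(np.isfinite(m)):
            raise ValueError("distance matrix contains non-finite entries")
        self.matrix = m


def _encode_rows(rows: list[str]) -> np.ndarray:
    return np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])


def distance_matrix(super_aln: Superalignment, model: DistanceModel,
                    columns: np.ndarray | None = None) -> DistanceMatrix:
    """All pairwise model distances (vectorized; optional column resample)."""
    enc = _encode_rows(super_aln.rows)
    if columns is not None:
        enc = enc[:, columns]
    gap = np.isin(enc, np.frombuffer(b"-.", dtype=np.uint8))
    n = len(super_aln.taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            comparable = int(ok.sum())
            if comparable == 0:
                raise SaturatedDistanceError(
                    f"no comparable columns between {super_aln.taxa[i]} and {super_aln.taxa[j]}"
                )
            p = float((enc[i, ok] != enc[j, ok]).mean())
            m[i, j] = m[j, i] = model_distance(p, model)
    return DistanceMatrix(list(super_aln.taxa), m)


# ---------------------------------------------------------------------------
# Trees

@dataclass
class TreeNode:
    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick(node: TreeNode, length: float | None) -> str:
    if node.is_leaf:
        body = _quote(node.name)
    else:
        inner = ",".join(_newick(c, bl) for c, bl in node.children)
        label = "" if node.support is None else f"{node.support:g}"
        body = f"({inner}){label}"
    return body if length is None else f"{body}:{length:.6f}"


@dataclass
class PhylogeneticTree:
    root: TreeNode
    taxa: list[str]

    def to_newick(self) -> str:
        return _newick(self.root, None) + ";"

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial bipartitions keyed by the side excluding the first taxon."""
        full = set(self.taxa)
        ref = self.taxa[0]
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> set:
            if node.is_leaf:
                return {node.name}
            below = set()
            for child, _ in node.children:
                below |= walk(child)
            side = below if ref not in below else full - below
            if 2 <= len(side) <= len(full) - 2:
                out[frozenset(side)] = node
            return below

        walk(self.root)
        return out


def nj_tree(matrix: DistanceMatrix) -> PhylogeneticTree:
    """Neighbor joining with the Q-criterion (the standard greedy heuristic
    for minimum evolution).

    Tie-breaks are deterministic: the lowest (i, j) index pair wins.
    Negative branch lengths are clamped to 0 with a warning.  The unrooted
    tree is returned with a trifurcating root (the final three-way join).
    """
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(t) for t in matrix.taxa]
    d = matrix.matrix.copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("negative branch length %.6f clamped to 0", x)
            return 0.0
        return x

    edge_len: dict[int, dict[int, float]] = {}
    next_id = n
    all_nodes = {i: nodes[i] for i in range(n)}
    joined_children: dict[int, list[tuple[int, float]]] = {}

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = clamp(0.5 * dij + (r[a] - r[b]) / (2 * (m - 2)))
        lj = clamp(dij - (0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))))
        new = TreeNode(children=[(all_nodes[i], li), (all_nodes[j], lj)])
        u = next_id
        next_id += 1
        all_nodes[u] = new
        # grow the distance matrix by one row/column for the new node
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    (x, y, z) = active
    lx = clamp(0.5 * (d[x, y] + d[x, z] - d[y, z]))
    ly = clamp(0.5 * (d[x, y] + d[y, z] - d[x, z]))
    lz = clamp(0.5 * (d[x, z] + d[y, z] - d[x, y]))
    root = TreeNode(children=[(all_nodes[x], lx), (all_nodes[y], ly), (all_nodes[z], lz)])
    return PhylogeneticTree(root, list(matrix.taxa))


def bootstrap_support(super_aln: Superalignment, model: DistanceModel,
                      n_reps: int = 500, seed: int = 0) -> PhylogeneticTree:
    """Point-estimate NJ tree with column-resampling bootstrap supports.

    Each replicate resamples the full concatenated length of columns with
    replacement; supports are the percent of successful replicate trees
    containing the same bipartition.  Replicates with a saturated or
    undefined distance are dropped and counted; more than 10% dropped is
    an error.  Fully seeded and reproducible.
    """
    if len(super_aln.taxa) < 4:
        raise ValueError("bootstrap supports need at least 4 taxa")
    point = nj_tree(distance_matrix(super_aln, model))
    if n_reps == 0:
        return point
    rng = np.random.default_rng(seed)
    L = super_aln.length
    counts: dict[frozenset, int] = {bp: 0 for bp in point.bipartitions()}
    dropped = 0
    successful = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        try:
            rep_tree = nj_tree(distance_matrix(super_aln, model, columns=cols))
        except SaturatedDistanceError:
            dropped += 1
            continue
        successful += 1
        rep_bps = set(rep_tree.bipartitions())
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if dropped > 0.1 * n_reps:
        raise SaturatedDistanceError(
            f"{dropped}/{n_reps} bootstrap replicates dropped (saturation)"
        )
    if dropped:
        logger.warning("dropped %d/%d bootstrap replicates", dropped, n_reps)
    for bp, node in point.bipartitions().items():
        node.support = round(100.0 * counts[bp] / successful, 1)
    return point


def robinson_foulds(tree_a: PhylogeneticTree, tree_b: PhylogeneticTree) -> int:
    """Unweighted Robinson–Foulds distance (symmetric bipartition difference)."""
    if set(tree_a.taxa) != set(tree_b.taxa):
        raise ValueError("trees have different taxon sets")
    a = set(tree_a.bipartitions())
    b = set(tree_b.bipartitions())
    return len(a ^ b)
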