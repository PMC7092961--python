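"""Evolutionary Trace ranking of alignment columns.

The trace procedure builds a rooted UPGMA tree over the aligned sequences and
walks it from the root outward. Cutting the tree just below its first n−1
internal nodes (ordered by distance from the root) partitions the leaves into
n groups; a column that is already invariant within every group at level n
carries no further evolutionary signal at that depth.

Two rank variants are provided. Integer ET counts the levels at which a
column still varies inside some group:

    r_i = 1 + sum_{n=1}^{N-1} delta(n),   delta(n) = 0 iff invariant in all
                                          groups at level n

Real-value ET (rvET) replaces the 0/1 penalty with the mean Shannon entropy
of the column within the level's groups (natural log, gap counted as a fifth
symbol):

    r_i = 1 + sum_{n=1}^{N-1} (1/n) * sum_{g=1}^{n} H(column | group g)

Ranks are normalized to percentile *coverage*: after sorting ascending,
coverage(i) = 100 * (last position tied with i) / L, so a fully conserved
column sits at the best (smallest) coverage and ties share one value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .seqio import Alignment, InputError

N_SYMBOLS = 6  # A C G U - N


@dataclass
class PhyloTree:
    """Rooted binary ultrametric tree from UPGMA agglomeration.

    Leaves are 0..N-1 in alignment order; internal nodes N..2N-2 in creation
    order. ``merges[k]`` = (left, right, height) describes internal node N+k.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise InputError("binary tree must have N-1 internal nodes")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    def children(self, node: int) -> tuple[int, int]:
        left, right, _ = self.merges[node - self.n_leaves]
        return left, right

    def height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        return self.merges[node - self.n_leaves][2]

    def leaves_under(self, node: int) -> list[int]:
        if node < self.n_leaves:
            return [node]
        left, right = self.children(node)
        return self.leaves_under(left) + self.leaves_under(right)

    def split_order(self) -> list[int]:
        """Internal nodes in the order they are split during the trace.

        A frontier walk from the root: at each step the splittable internal
        node closest to the root goes first (ties by creation order). Children
        only become splittable after their parent, so the partitions are
        nested even when branch lengths are zero.
        """
        root_h = self.height(self.root)
        order: list[int] = []
        frontier = [self.root]
        while frontier:
            # min root distance = max height; ties -> earliest creation
            node = min(frontier, key=lambda x: (root_h - self.height(x), x))
            frontier.remove(node)
            order.append(node)
            for child in self.children(node):
                if child >= self.n_leaves:
                    frontier.append(child)
        return order

    def groups(self, n: int) -> list[list[int]]:
        """Partition of leaves into exactly n groups (level-n cut)."""
        if not 1 <= n <= self.n_leaves - 1:
            raise InputError(f"level must be in [1, N-1], got {n}")
        active = [self.root]
        for node in self.split_order()[: n - 1]:
            active.remove(node)
            active.extend(self.children(node))
        return [sorted(self.leaves_under(a)) for a in active]

    def to_newick(self) -> str:
        def render(node: int, parent_h: float) -> str:
            blen = parent_h - self.height(node)
            if node < self.n_leaves:
                return f"{self.leaf_ids[node]}:{blen:.6f}"
            left, right = self.children(node)
            h = self.height(node)
            return f"({render(left, h)},{render(right, h)}):{blen:.6f}"

        return render(self.root, self.height(self.root)) + ";"


@dataclass
class TraceResult:
    """Per-column ranks and percentile coverage for one scoring method."""

    ranks: np.ndarray  # absolute rank, >= 1
    coverage: np.ndarray  # percentile in (0, 100]
    method: str  # "integer" | "rvET" | "entropy"

    @property
    def L(self) -> int:
        return self.ranks.size

    def to_dataframe(self, aln: Alignment | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "aln_column": np.arange(1, self.L + 1),
                "rank": self.ranks,
                "coverage": self.coverage,
            }
        )
        if aln is not None:
            qrow = aln.query_row()
            df.insert(1, "base", list(qrow))
            residue = np.where(np.array(list(qrow)) != "-",
                               np.cumsum([c != "-" for c in qrow]), 0)
            df.insert(1, "query_residue", residue)
        return df


def hamming_distance_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise normalized Hamming distance, gaps counted as a symbol."""
    arr = aln.to_array()
    eq = (arr[:, None, :] == arr[None, :, :]).mean(axis=2)
    return 1.0 - eq


def build_upgma(aln: Alignment) -> PhyloTree:
    """UPGMA tree on normalized Hamming distances (gap = fifth symbol).

    Agglomeration is deterministic: among minimum-distance cluster pairs the
    lexicographically lowest pair of current cluster indices merges first.
    """
    n = aln.N
    dist = hamming_distance_matrix(aln)
    # active clusters: id -> (size, matrix row index)
    size = {i: 1 for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = min(
            ((d[(min(a, b), max(a, b))], (a, b))
             for ia, a in enumerate(active) for b in active[ia + 1:]),
            key=lambda t: (t[0], t[1]),
        )
        dmin, (a, b) = best
        merges.append((a, b, dmin / 2.0))
        active = [c for c in active if c not in (a, b)]
        for c in active:
            dac = d.pop((min(a, c), max(a, c)))
            dbc = d.pop((min(b, c), max(b, c)))
            d[(min(next_id, c), max(next_id, c))] = (
                size[a] * dac + size[b] * dbc
            ) / (size[a] + size[b])
        d.pop((min(a, b), max(a, b)))
        size[next_id] = size[a] + size[b]
        active.append(next_id)
        next_id += 1
    return PhyloTree(list(aln.ids), merges)


# ---------------------------------------------------------------------------
# internal: per-cluster column statistics


def _node_counts(aln: Alignment, tree: PhyloTree) -> np.ndarray:
    """(2N-1, N_SYMBOLS, L) symbol counts of each column within each node's leaves."""
    arr = aln.to_array()
    n, L = arr.shape
    counts = np.zeros((2 * n - 1, N_SYMBOLS, L), dtype=np.int32)
    cols = np.arange(L)
    for leaf in range(n):
        counts[leaf, arr[leaf], cols] = 1
    for k, (left, right, _) in enumerate(tree.merges):
        counts[n + k] = counts[left] + counts[right]
    return counts


def _entropy_from_counts(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) per column from a (N_SYMBOLS, L) count block."""
    total = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / total
        terms = np.where(counts > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=0)


def _check_tree(aln: Alignment, tree: PhyloTree) -> None:
    if list(tree.leaf_ids) != list(aln.ids):
        raise InputError("tree leaves do not match alignment ids")


def integer_et(aln: Alignment, tree: PhyloTree) -> TraceResult:
    """First-generation integer ET: r in [1, N]."""
    _check_tree(aln, tree)
    counts = _node_counts(aln, tree)
    variant = (counts > 0).sum(axis=1) > 1  # (nodes, L): column varies within node
    n = aln.N
    ranks = np.ones(aln.L_aln)
    n_variant = variant[tree.root].astype(int).copy()
    order = tree.split_order()
    for level in range(1, n):
        ranks += (n_variant > 0)
        if level < n - 1:
            node = order[level - 1]
            left, right = tree.children(node)
            n_variant += (
                variant[left].astype(int)
                + variant[right].astype(int)
                - variant[node].astype(int)
            )
    return TraceResult(ranks, _coverage_of(ranks), "integer")


def rvet(aln: Alignment, tree: PhyloTree, alphabet_size: int = 5) -> TraceResult:
    """Real-value ET: entropy-weighted ranks, r in [1, 1 + H_N-1 * ln(alphabet_size)].

    ``alphabet_size`` only bounds the maximum attainable rank (5 for
    A/C/G/U/gap, 6 when N is treated as its own symbol); the computation uses
    observed symbol frequencies either way.
    """
    _check_tree(aln, tree)
    counts = _node_counts(aln, tree)
    H = np.stack([_entropy_from_counts(counts[k]) for k in range(counts.shape[0])])
    n = aln.N
    ranks = np.ones(aln.L_aln)
    level_sum = H[tree.root].copy()  # sum of group entropies at current level
    order = tree.split_order()
    for level in range(1, n):
        ranks += level_sum / level
        if level < n - 1:
            node = order[level - 1]
            left, right = tree.children(node)
            level_sum += H[left] + H[right] - H[node]
    return TraceResult(ranks, _coverage_of(ranks), "rvET")


def shannon_conservation(aln: Alignment) -> TraceResult:
    """Tree-free baseline: whole-alignment column entropy, as 1 + H (nats)."""
    arr = aln.to_array()
    counts = np.zeros((N_SYMBOLS, aln.L_aln), dtype=np.int64)
    for s in range(N_SYMBOLS):
        counts[s] = (arr == s).sum(axis=0)
    ranks = 1.0 + _entropy_from_counts(counts)
    return TraceResult(ranks, _coverage_of(ranks), "entropy")


def _coverage_of(ranks: np.ndarray) -> np.ndarray:
    # ties share the largest sorted position
    return 100.0 * rankdata(ranks, method="max") / ranks.size


def coverage(ranks: np.ndarray, method: str = "custom") -> TraceResult:
    """Percentile coverage of arbitrary rank values (ties share the worst position)."""
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size < 1:
        raise InputError("need at least one column")
    return TraceResult(ranks, _coverage_of(ranks), method)
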