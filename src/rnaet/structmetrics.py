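"""Contact graphs and structural statistics for ET selections.

A selection's Selection Clustering Weight w is the number of contact-graph
edges with both endpoints selected. Its excess over a uniformly random
selection of the same size is expressed as the clustering z-score
z_c = (w - <w>) / sigma, with <w> and sigma obtained in closed form from the
graph's edge count E and 2-path count T under sampling without replacement:

    <w>     = E * p2
    sigma^2 = E*p2 + 2T*p3 + (E(E-1) - 2T)*p4 - (E*p2)^2
    p_j     = k(k-1)...(k-j+1) / (L(L-1)...(L-j+1))

The per-coverage-bin z profile averages bins at coverage <= 35% (zc35%).
ET smoothness SMT = sum over adjacent pairs of squared rank difference;
lower SMT means evolutionary importance varies smoothly over the structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .seqio import InputError, SecondaryStructure, StructureModel


@dataclass
class ContactGraph:
    """Symmetric 0/1 adjacency over L positions (no self-contacts)."""

    A: np.ndarray  # (L, L) bool
    context: str  # "tertiary" | "secondary" | "primary"
    cutoff: float | None = None  # Å, tertiary only

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=bool)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise InputError("adjacency must be square")
        if not np.array_equal(self.A, self.A.T):
            raise InputError("adjacency must be symmetric")
        if np.any(np.diag(self.A)):
            raise InputError("self-contacts not allowed")

    @property
    def L(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.A.sum()) // 2

    @property
    def n_two_paths(self) -> int:
        """Number of unordered position triples forming a path of two edges."""
        deg = self.A.sum(axis=1)
        return int((deg * (deg - 1) // 2).sum())

    def edges(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.A))
        return list(zip((ii + 1).tolist(), (jj + 1).tolist()))  # 1-based

    def subgraph(self, keep: list[int]) -> "ContactGraph":
        """Induced subgraph on 1-based positions ``keep`` (order preserved)."""
        idx = np.asarray(keep) - 1
        return ContactGraph(self.A[np.ix_(idx, idx)], self.context, self.cutoff)


def contact_graph_3d(struct: StructureModel, cutoff: float = 4.0,
                     exclude_neighbors: int = 1,
                     atoms: str = "heavy") -> ContactGraph:
    """Tertiary contacts: minimum inter-residue atom distance <= cutoff (Å).

    ``atoms`` is "heavy" (all non-hydrogen atoms, the default) or "c1p"
    (first atom of each residue only). Residue pairs closer than
    ``exclude_neighbors`` in chain ordinal are never contacts; the default 1
    drops covalently linked backbone neighbors, which cluster trivially.
    """
    L = len(struct)
    if L < 2:
        raise InputError("need at least 2 residues")
    coord_sets = [
        res.coords if atoms == "heavy" else res.coords[:1]
        for res in struct.residues
    ]
    A = np.zeros((L, L), dtype=bool)
    for i in range(L):
        for j in range(i + 1, L):
            if j - i <= exclude_neighbors:
                continue
            if cdist(coord_sets[i], coord_sets[j]).min() <= cutoff:
                A[i, j] = A[j, i] = True
    return ContactGraph(A, "tertiary", cutoff)


def contact_graph_2d(ss: SecondaryStructure, L: int) -> ContactGraph:
    """Secondary-structure contacts: base pairs plus backbone neighbors (i, i+1)."""
    A = _backbone(L)
    for i, j in ss.pairs:
        if not (1 <= i <= L and 1 <= j <= L):
            raise InputError(f"pair ({i},{j}) outside 1..{L}")
        A[i - 1, j - 1] = A[j - 1, i - 1] = True
    return ContactGraph(A, "secondary")


def contact_graph_1d(L: int) -> ContactGraph:
    """Primary-sequence contacts: backbone neighbors (i, i+1) only."""
    return ContactGraph(_backbone(L), "primary")


def _backbone(L: int) -> np.ndarray:
    A = np.zeros((L, L), dtype=bool)
    idx = np.arange(L - 1)
    A[idx, idx + 1] = A[idx + 1, idx] = True
    return A


# ---------------------------------------------------------------------------
# Selection clustering weight and z-score


def scw(selection: set[int] | np.ndarray, g: ContactGraph) -> int:
    """Number of contacts internal to the selection (1-based positions)."""
    mask = _as_mask(selection, g.L)
    return int(g.A[np.ix_(mask, mask)].sum()) // 2


def _as_mask(selection, L: int) -> np.ndarray:
    if isinstance(selection, np.ndarray) and selection.dtype == bool:
        if selection.size != L:
            raise InputError("selection mask length mismatch")
        return selection
    sel = np.zeros(L, dtype=bool)
    idx = np.asarray(sorted(selection), dtype=int)
    if idx.size and (idx.min() < 1 or idx.max() > L):
        raise InputError("selection outside 1..L")
    sel[idx - 1] = True
    return sel


def scw_moments(g: ContactGraph, k: int) -> tuple[float, float]:
    """Analytic (mean, variance) of w for a uniform size-k selection."""
    L, E, T = g.L, g.n_edges, g.n_two_paths

    def p(j: int) -> float:
        num, den = 1.0, 1.0
        for t in range(j):
            num *= k - t
            den *= L - t
        return num / den if den and k >= j else 0.0

    p2, p3, p4 = p(2), p(3), p(4)
    mean = E * p2
    var = E * p2 + 2 * T * p3 + (E * (E - 1) - 2 * T) * p4 - mean**2
    return mean, max(var, 0.0)


def clustering_z(selection, g: ContactGraph, mode: str = "analytic",
                 n_perm: int = 10000, seed: int | None = None) -> float:
    """Clustering z-score of a selection; NaN when undefined.

    The full-universe selection (k = L) has zero excess by construction and
    returns 0.0. Selections with k in {0, 1} or graphs without edges have no
    variance and return NaN (flagged undefined).
    """
    mask = _as_mask(selection, g.L)
    k = int(mask.sum())
    if k == g.L:
        return 0.0
    if k < 2 or g.n_edges == 0:
        return float("nan")
    w = scw(mask, g)
    if mode == "analytic":
        mean, var = scw_moments(g, k)
        if var <= 1e-12:
            return 0.0 if abs(w - mean) <= 1e-9 else float("nan")
        return (w - mean) / np.sqrt(var)
    if mode == "permutation":
        if seed is None:
            raise InputError("permutation mode requires a seed")
        rng = np.random.default_rng(seed)
        ws = np.empty(n_perm)
        for t in range(n_perm):
            perm = np.zeros(g.L, dtype=bool)
            perm[rng.choice(g.L, size=k, replace=False)] = True
            ws[t] = g.A[np.ix_(perm, perm)].sum() // 2
        sd = ws.std()
        if sd == 0:
            return 0.0 if w == ws.mean() else float("nan")
        return (w - ws.mean()) / sd
    raise InputError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Cumulative coverage-bin z profile


@dataclass
class ZProfile:
    """Per-coverage-bin z values with the 0–35% summary mean.

    ``bins`` columns: bin, coverage, size, z, valid, z_filled. A bin is valid
    when its coverage value is actually attained by some position and its z is
    defined; invalid bins inherit z from the closest valid bin (ties toward
    lower coverage).
    """

    bins: pd.DataFrame
    mean_0_35: float
    threshold: float = 35.0


def z_profile(ranks: np.ndarray, g: ContactGraph, threshold: float = 35.0,
              mode: str = "analytic", n_perm: int = 10000,
              seed: int | None = None) -> ZProfile:
    """Cumulative clustering z profile over coverage bins b = 1..L.

    ``ranks`` are per-position rank values aligned with the graph (lower =
    more important); coverage is computed here so restricted universes
    re-normalize cleanly.
    """
    ranks = np.asarray(ranks, dtype=float)
    L = g.L
    if ranks.size != L:
        raise InputError("ranks and graph disagree on L")
    cov = 100.0 * rankdata(ranks, method="max") / L
    rows = []
    for b in range(1, L + 1):
        c = 100.0 * b / L
        mask = cov <= c
        size = int(mask.sum())
        attained = size == b
        z = clustering_z(mask, g, mode=mode, n_perm=n_perm, seed=seed) if attained else float("nan")
        w = scw(mask, g) if attained else np.nan
        mean, var = scw_moments(g, size) if attained else (np.nan, np.nan)
        rows.append((b, c, size, w, mean, np.sqrt(var) if var == var else np.nan,
                     z, attained and z == z))
    df = pd.DataFrame(
        rows, columns=["bin", "coverage", "size", "w", "expected_w", "sigma",
                       "z", "valid"],
    )
    df["z_filled"] = _fill_bins(df)
    sel = df["coverage"] <= threshold
    if not sel.any():
        sel = df.index == 0  # degenerate L: first bin already beyond threshold
    mean_0_35 = float(df.loc[sel, "z_filled"].mean())
    return ZProfile(df, mean_0_35, threshold)


def _fill_bins(df: pd.DataFrame) -> np.ndarray:
    """Invalid bins inherit the closest valid bin's z (ties toward lower coverage)."""
    valid = df.index[df["valid"]].to_numpy()
    if valid.size == 0:
        raise InputError("no valid z bin in profile")
    out = np.empty(len(df))
    for i in range(len(df)):
        if df.at[i, "valid"]:
            out[i] = df.at[i, "z"]
        else:
            dist = np.abs(valid - i)
            # ties toward lower coverage: prefer the smaller index
            j = valid[np.lexsort((valid, dist))[0]]
            out[i] = df.at[int(j), "z"]
    return out


# ---------------------------------------------------------------------------
# ET smoothness


def smoothness(x: np.ndarray, g: ContactGraph) -> float:
    """SMT = sum over adjacent pairs of squared rank difference.

    ``x`` is typically coverage (percentile) so values are comparable across
    molecules; pass absolute ranks for the raw variant.
    """
    x = np.asarray(x, dtype=float)
    if x.size != g.L:
        raise InputError("ranks and graph disagree on L")
    diff2 = (x[:, None] - x[None, :]) ** 2
    return float((diff2 * g.A).sum()) / 2.0
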