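"""Overlap of ET selections with functional sites.

For a selection of n of N positions and a site of M members, the number k of
site members recovered follows the hypergeometric distribution under random
selection, with

    m     = n * M / N
    sigma = sqrt( n * (M/N) * (1 - M/N) * (N - n) / (N - 1) )
    z_o   = (k - m) / sigma

z_o is evaluated at every cumulative coverage bin exactly as the clustering
z-score is, including the empty-bin fill rule, so zo35% and zc35% are
directly comparable. Site-specific evaluation removes other annotated sites
from the universe (they count neither as positives nor negatives).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

from .seqio import ColumnResidueMap, FunctionalSite, InputError
from .structmetrics import ZProfile, _fill_bins
from .trace import TraceResult


def overlap_moments(n: int, M: int, N_pos: int) -> tuple[float, float]:
    """Hypergeometric mean and standard deviation of the overlap count."""
    if not (0 < n < N_pos) or not (0 < M < N_pos):
        raise InputError("need 0 < n < N and 0 < M < N")
    frac = M / N_pos
    m = n * frac
    var = n * frac * (1 - frac) * (N_pos - n) / (N_pos - 1)
    return m, np.sqrt(var)


def overlap_z(n: int, M: int, N_pos: int, k: int) -> float:
    """Overlap z-score z_o = (k - m)/sigma; NaN when sigma = 0."""
    m, sigma = overlap_moments(n, M, N_pos)
    if sigma <= 1e-12:
        return float("nan")
    return (k - m) / sigma


@dataclass
class OverlapResult:
    """Per-bin overlap statistics, the filled z profile and the ROC AUC."""

    bins: pd.DataFrame
    mean_0_35: float
    auc: float
    site: str
    universe_size: int

    @property
    def profile(self) -> ZProfile:
        return ZProfile(self.bins, self.mean_0_35)


def overlap_profile(trace: TraceResult, site: FunctionalSite,
                    cmap: ColumnResidueMap | None = None,
                    exclude_sites: Iterable[FunctionalSite] = (),
                    threshold: float = 35.0) -> OverlapResult:
    """Cumulative overlap z profile of a trace against one functional site.

    ``cmap`` maps alignment columns to structure residues; when None the
    trace is taken to live directly on residue indices 1..L. Members of
    ``exclude_sites`` (minus members of ``site`` itself) are removed from the
    universe before binning, and coverage is recomputed on what remains.
    """
    if cmap is not None:
        residues = np.array(cmap.mapped_residues())
        ranks = np.array([trace.ranks[cmap.res_to_col[r] - 1] for r in residues])
    else:
        residues = np.arange(1, trace.L + 1)
        ranks = trace.ranks.copy()

    excluded = set().union(*(s.members for s in exclude_sites)) - set(site.members)
    keep = ~np.isin(residues, sorted(excluded))
    residues, ranks = residues[keep], ranks[keep]

    N_pos = residues.size
    site_mask = np.isin(residues, sorted(site.members))
    M = int(site_mask.sum())
    if M == 0:
        raise InputError(f"site {site.name!r} empty after exclusion/mapping")

    cov = 100.0 * rankdata(ranks, method="max") / N_pos
    rows = []
    for b in range(1, N_pos + 1):
        c = 100.0 * b / N_pos
        sel = cov <= c
        n = int(sel.sum())
        attained = n == b
        k = int((sel & site_mask).sum()) if attained else 0
        if attained and n == N_pos:
            z, m, sigma = 0.0, float(M), 0.0  # full universe: zero excess
        elif attained and 0 < M < N_pos:
            m, sigma = overlap_moments(n, M, N_pos)
            z = (k - m) / sigma if sigma > 1e-12 else float("nan")
        else:
            z, m, sigma = float("nan"), np.nan, np.nan
        rows.append((b, c, n, k, m, sigma, z, attained and z == z))
    df = pd.DataFrame(
        rows, columns=["bin", "coverage", "size", "k", "expected_k", "sigma",
                       "z", "valid"],
    )
    df["z_filled"] = _fill_bins(df)
    selbins = df["coverage"] <= threshold
    if not selbins.any():
        selbins = df.index == 0
    mean_0_35 = float(df.loc[selbins, "z_filled"].mean())
    auc = roc_auc(ranks, site_mask) if 0 < M < N_pos else float("nan")
    return OverlapResult(df, mean_0_35, auc, site.name, N_pos)


def roc_auc(ranks: np.ndarray, positive: np.ndarray) -> float:
    """ROC AUC by pair counting (Mann–Whitney), ties credited 0.5.

    Lower rank (better coverage) counts as the higher score. Equals the
    trapezoidal area under the ROC curve.
    """
    ranks = np.asarray(ranks, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InputError("need at least one positive and one negative")
    scores = rankdata(-ranks, method="average")
    return float((scores[positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def hypergeom_2x2(k1: int, n1: int, k2: int, n2: int) -> float:
    """One-sided hypergeometric tail P[X >= k1] for a 2x2 contingency table.

    X counts successes in n1 draws without replacement from a pooled
    population of n1+n2 containing k1+k2 successes.
    """
    if k1 > n1 or k2 > n2:
        raise InputError("successes cannot exceed draws")
    return float(hypergeom.sf(k1 - 1, n1 + n2, k1 + k2, n1))
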