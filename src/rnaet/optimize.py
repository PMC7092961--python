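"""Alignment-quality experiments and input-alignment selection.

Sequence selection is the main lever on trace quality. Two tools here:

* a degradation experiment — progressively corrupt an alignment and watch
  clustering (zc35%), overlap (zo35%) and smoothness (SMT) deteriorate
  together;
* ensemble optimization — draw random sub-alignments, trace each, and keep
  the one maximizing either mean ET clustering (zc35) or the product of Rank
  Entropy with inverted normalized smoothness (re_smt). Rank Entropy,
  RE = −Σ_r f_r ln f_r over the frequencies of distinct rank values, guards
  against collapsing onto a few highly invariant sequences whose trace is
  smooth but uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .overlap import overlap_profile
from .seqio import Alignment, ColumnResidueMap, FunctionalSite, InputError
from .structmetrics import ContactGraph, smoothness, z_profile
from .trace import TraceResult, build_upgma, rvet


@dataclass
class RankEntropy:
    RE: float
    frequencies: dict[float, float]  # distinct rank value -> fraction of columns


def rank_entropy(trace: TraceResult, decimals: int = 9) -> RankEntropy:
    """Entropy (nats) of the distribution of distinct rank values over columns.

    Zero iff every column shares one rank; maximal, ln(L), iff all ranks are
    distinct. Ranks are rounded to ``decimals`` before grouping so that
    floating-point noise does not split genuine ties.
    """
    if trace.L < 1:
        raise InputError("need at least one column")
    vals, counts = np.unique(np.round(trace.ranks, decimals), return_counts=True)
    f = counts / trace.L
    re = float(-(f * np.log(f)).sum())
    return RankEntropy(re, dict(zip(vals.tolist(), f.tolist())))


def degrade_alignment(aln: Alignment, shuffle_rate: float, seed: int,
                      mode: str = "resample") -> Alignment:
    """Corrupt a fraction ``shuffle_rate`` of non-gap characters.

    mode "resample" replaces each chosen character with a uniform base from
    {A,C,G,U} (expected per-site identity 0.25 at rate 1); mode "permute"
    instead permutes the chosen characters within their column. Gaps are
    never touched; column positions never move.
    """
    if not 0.0 <= shuffle_rate <= 1.0:
        raise InputError("shuffle_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mat = np.array([list(r) for r in aln.rows])
    nz = np.argwhere(mat != "-")
    n_pick = round(shuffle_rate * len(nz))
    picked = nz[rng.choice(len(nz), size=n_pick, replace=False)] if n_pick else nz[:0]
    if mode == "resample":
        mat[picked[:, 0], picked[:, 1]] = rng.choice(list("ACGU"), size=n_pick)
    elif mode == "permute":
        for col in np.unique(picked[:, 1]):
            rows = picked[picked[:, 1] == col, 0]
            mat[rng.permutation(rows), col] = mat[rows, col].copy()
    else:
        raise InputError(f"unknown mode {mode!r}")
    return Alignment(list(aln.ids), ["".join(r) for r in mat],
                     query_id=aln.query_id, ss_cons=aln.ss_cons)


# ---------------------------------------------------------------------------
# Shared scoring of one alignment against a structure


@dataclass
class TraceScores:
    zc35: float
    zo35: float | None
    smt: float
    re: float
    trace: TraceResult


def score_alignment(aln: Alignment, graph: ContactGraph,
                    cmap: ColumnResidueMap | None = None,
                    site: FunctionalSite | None = None,
                    threshold: float = 35.0) -> TraceScores:
    """Trace an alignment (rvET) and score it on a structure contact graph.

    ``cmap`` maps alignment columns to the graph's positions; None means the
    trace columns are the graph positions 1..L. ``site`` adds zo35%.
    """
    tree = build_upgma(aln)
    trace = rvet(aln, tree)
    if cmap is not None:
        residues = cmap.mapped_residues()
        ranks = np.array([trace.ranks[cmap.res_to_col[r] - 1] for r in residues])
        sub = graph.subgraph(residues)
    else:
        ranks, sub = trace.ranks, graph
    prof = z_profile(ranks, sub, threshold=threshold)
    cov = 100.0 * rankdata(ranks, method="max") / len(ranks)
    smt = smoothness(cov, sub)
    zo = None
    if site is not None:
        zo = overlap_profile(trace, site, cmap, threshold=threshold).mean_0_35
    return TraceScores(prof.mean_0_35, zo, smt, rank_entropy(trace).RE, trace)


# ---------------------------------------------------------------------------
# Degradation study


def degradation_study(aln: Alignment, graph: ContactGraph,
                      site: FunctionalSite,
                      cmap: ColumnResidueMap | None = None,
                      rates: list[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                      reps: int = 5, seed: int = 0,
                      mode: str = "resample") -> tuple[pd.DataFrame, dict[str, float]]:
    """Mean zo35/zc35/SMT per corruption rate, plus cross-rate correlations.

    Returns (table, correlations) where correlations holds Pearson r between
    the per-rate mean overlap and clustering ("zo_zc") and between overlap
    and smoothness ("zo_smt").
    """
    rates = list(rates)
    if len(rates) < 3:
        raise InputError("need at least 3 rate bins for correlations")
    rows = []
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=(len(rates), reps))
    for ri, rate in enumerate(rates):
        zc, zo, smt = [], [], []
        for rep in range(reps):
            degraded = degrade_alignment(aln, rate, int(base[ri, rep]), mode=mode)
            s = score_alignment(degraded, graph, cmap, site)
            zc.append(s.zc35)
            zo.append(s.zo35)
            smt.append(s.smt)
        rows.append((rate, float(np.mean(zo)), float(np.mean(zc)), float(np.mean(smt))))
    table = pd.DataFrame(rows, columns=["rate", "mean_zo35", "mean_zc35", "mean_smt"])
    corr = {
        "zo_zc": float(np.corrcoef(table["mean_zo35"], table["mean_zc35"])[0, 1]),
        "zo_smt": float(np.corrcoef(table["mean_zo35"], table["mean_smt"])[0, 1]),
    }
    return table, corr


# ---------------------------------------------------------------------------
# Ensemble optimization


@dataclass
class EnsembleRecord:
    member_id: int
    removed_sequences: list[str]
    zc35: float
    smt: float
    re: float
    combined_score: float
    seed: int


def optimize_alignment(ref_aln: Alignment, graph: ContactGraph,
                       cmap: ColumnResidueMap | None = None,
                       ensemble_size: int = 100,
                       criterion: str = "zc35",
                       min_keep: int = 20, seed: int = 0,
                       threshold: float = 35.0,
                       ) -> tuple[Alignment, list[EnsembleRecord]]:
    """Pick the best random sub-alignment of an over-inclusive input.

    Each ensemble member removes a uniform-random number n, 0 < n < N −
    min_keep, of non-query sequences (the query is always retained so the
    structure mapping survives). Members are traced and scored; criterion
    "zc35" maximizes mean clustering z, "re_smt" maximizes min-max-normalized
    RE × (1 − normalized SMT) over the ensemble (smoothness is a cost), and
    "smt" minimizes raw SMT (provided to expose its known failure mode).
    Ties go to the lowest member_id. Deterministic under ``seed``.
    """
    N = ref_aln.N
    if N <= min_keep:
        raise InputError(f"need more than min_keep={min_keep} sequences")
    if ensemble_size < 1:
        raise InputError("ensemble_size >= 1")
    if criterion not in {"zc35", "re_smt", "smt"}:
        raise InputError(f"unknown criterion {criterion!r}")
    rng = np.random.default_rng(seed)
    removable = [i for i in ref_aln.ids if i != ref_aln.query_id]
    records: list[EnsembleRecord] = []
    members: list[Alignment] = []
    for mid in range(ensemble_size):
        n_remove = int(rng.integers(1, N - min_keep)) if N - min_keep > 1 else 1
        removed = list(rng.choice(removable, size=min(n_remove, len(removable)),
                                  replace=False))
        sub = ref_aln.subset([i for i in ref_aln.ids if i not in set(removed)])
        s = score_alignment(sub, graph, cmap, site=None, threshold=threshold)
        records.append(EnsembleRecord(mid, removed, s.zc35, s.smt, s.re,
                                      float("nan"), seed))
        members.append(sub)

    zc = np.array([r.zc35 for r in records])
    smt = np.array([r.smt for r in records])
    re_ = np.array([r.re for r in records])
    if criterion == "zc35":
        score = np.where(np.isfinite(zc), zc, -np.inf)
    elif criterion == "smt":
        score = -smt
    else:
        score = _minmax(re_) * (1.0 - _minmax(smt))
    for r, sc in zip(records, score):
        r.combined_score = float(sc)
    if not np.any(np.isfinite(score)):
        raise InputError("all ensemble scores invalid")
    best = int(np.nanargmax(np.where(np.isfinite(score), score, -np.inf)))
    return members[best], records


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi - lo <= 1e-12:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def records_to_dataframe(records: list[EnsembleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "member_id": [r.member_id for r in records],
            "n_removed": [len(r.removed_sequences) for r in records],
            "zc35": [r.zc35 for r in records],
            "smt": [r.smt for r in records],
            "re": [r.re for r in records],
            "combined_score": [r.combined_score for r in records],
            "seed": [r.seed for r in records],
            "removed_sequences": [",".join(r.removed_sequences) for r in records],
        }
    )
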