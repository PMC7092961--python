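"""Synthetic tree-structured alignments and toy 3D structures.

The generator plants three column classes on a balanced binary tree of
sequences:

* conserved — one base shared by every leaf;
* clade-specific — fixed within each clade at ``clade_depth`` (two top-level
  clades by default, echoing families whose members split into two deeply
  diverged classes), distinct between clades;
* random — i.i.d. per leaf from a per-column base distribution drawn from a
  symmetric Dirichlet (``random_alpha``). Skewed per-site base usage is what
  real alignments show, and it is what makes the clade class informative:
  some random columns drift toward low flat entropy by chance, so a
  tree-blind conservation score confuses them with clade-specific columns
  while the trace does not.

The toy structure places one pseudo-atom per query position on a helix-like
curve (configurable rise, twist and radius). Curve slots are permuted so the
planted functional site — drawn from the conserved and clade-specific
columns — occupies a spatially contiguous stretch, giving the top-ranked
positions a real 3D cluster to find. With the default geometry (radius 4 Å,
twist 90°, rise 0.9 Å) the only contacts at the 4 Å cutoff are between slots
one full turn apart, so contact density is uniform along the curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import (
    Alignment,
    FunctionalSite,
    InputError,
    StructResidue,
    StructureModel,
    write_alignment,
    write_pdb,
    write_sites,
)

BASES = "ACGU"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture."""

    n_leaves: int = 16
    L: int = 60
    class_fractions: tuple[float, float, float] = (0.2, 0.2, 0.6)  # conserved, clade, random
    clade_depth: int = 1
    rise: float = 0.9  # Å per curve slot
    twist: float = 90.0  # degrees per slot
    radius: float = 4.0  # Å
    atoms_per_residue: int = 1
    random_alpha: float = 0.6  # Dirichlet concentration of random-column base usage
    contact_cutoff: float = 4.0
    site_name: str = "planted"
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_leaves
        if n < 4 or (n & (n - 1)) != 0:
            raise InputError("n_leaves must be a power of 2, >= 4")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise InputError("class fractions must sum to 1")
        if not 1 <= self.clade_depth <= int(np.log2(n)) - 1:
            raise InputError("clade_depth out of range for tree size")
        if self.atoms_per_residue < 1:
            raise InputError("atoms_per_residue >= 1")


@dataclass
class FixtureBundle:
    alignment: Alignment
    structure: StructureModel
    site: FunctionalSite
    labels: dict[int, str]  # 1-based column -> "conserved" | "clade" | "random"
    spec: FixtureSpec = field(repr=False, default=None)

    @property
    def site_columns(self) -> list[int]:
        return sorted(self.site.members)  # query is gapless: column == residue


def _class_counts(spec: FixtureSpec) -> tuple[int, int, int]:
    n_cons = round(spec.class_fractions[0] * spec.L)
    n_clade = round(spec.class_fractions[1] * spec.L)
    return n_cons, n_clade, spec.L - n_cons - n_clade


def make_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate (alignment, structure, planted site, truth labels) from a spec.

    The planted site is the full set of conserved + clade-specific columns;
    fixtures without such columns (pure-random null fixtures) get a site of
    the first quarter of positions instead, useful only as a null control.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_leaves, spec.L
    n_cons, n_clade, n_rand = _class_counts(spec)

    cols = rng.permutation(L)
    cons_cols = np.sort(cols[:n_cons])
    clade_cols = np.sort(cols[n_cons:n_cons + n_clade])
    labels = {int(c) + 1: "random" for c in range(L)}
    labels.update({int(c) + 1: "conserved" for c in cons_cols})
    labels.update({int(c) + 1: "clade" for c in clade_cols})

    n_clades = 2**spec.clade_depth
    clade_of = np.repeat(np.arange(n_clades), n // n_clades)

    mat = np.empty((n, L), dtype="<U1")
    base_arr = np.array(list(BASES))
    for c in range(L):
        cls = labels[c + 1]
        if cls == "conserved":
            mat[:, c] = rng.choice(base_arr)
        elif cls == "clade":
            picks = rng.choice(base_arr, size=n_clades, replace=n_clades > 4)
            mat[:, c] = picks[clade_of]
        else:
            probs = rng.dirichlet([spec.random_alpha] * 4)
            mat[:, c] = rng.choice(base_arr, size=n, p=probs)
    ids = [f"seq{i+1:03d}" for i in range(n)]
    aln = Alignment(ids, ["".join(r) for r in mat], query_id=ids[0])

    site_cols = sorted(int(c) + 1 for c in np.concatenate([cons_cols, clade_cols]))
    if not site_cols:
        site_cols = list(range(1, L // 4 + 1))
    site = FunctionalSite(spec.site_name, frozenset(site_cols))

    structure = _make_structure(spec, site_cols, aln.query_row(), rng)
    return FixtureBundle(aln, structure, site, labels, spec)


def _make_structure(spec: FixtureSpec, site_cols: list[int], query: str,
                    rng: np.random.Generator) -> StructureModel:
    """Helix-curve coordinates; site columns occupy the first curve slots."""
    L = spec.L
    slots_per_turn = round(360.0 / spec.twist)
    if slots_per_turn * spec.rise > spec.contact_cutoff and len(site_cols) > slots_per_turn:
        raise InputError(
            "infeasible geometry: one helix turn exceeds the contact cutoff, "
            "the planted site cannot form a contiguous contact stretch"
        )
    order = site_cols + [c for c in range(1, L + 1) if c not in set(site_cols)]
    slot_of = {col: s for s, col in enumerate(order)}
    theta = np.deg2rad(spec.twist)
    residues = []
    for col in range(1, L + 1):
        s = slot_of[col]
        center = np.array([
            spec.radius * np.cos(s * theta),
            spec.radius * np.sin(s * theta),
            s * spec.rise,
        ])
        if spec.atoms_per_residue == 1:
            coords = center[None, :]
        else:
            jitter = rng.normal(scale=0.3, size=(spec.atoms_per_residue - 1, 3))
            coords = np.vstack([center, center + jitter])
        residues.append(StructResidue("A", col, query[col - 1], coords))
    return StructureModel(residues)


def contaminate(aln: Alignment, n_decoys: int, seed: int,
                mode: str = "misaligned") -> Alignment:
    """Append decoy sequences emulating curation errors.

    mode "misaligned" (default) copies random member sequences cyclically
    shifted by 2–6 columns — the register error a mis-anchored homolog
    introduces, which pollutes conserved columns with off-register bases.
    mode "random" appends i.i.d. uniform sequences (phylogenetically
    unrelated noise), which leaves column ranking order largely intact.
    """
    rng = np.random.default_rng(seed)
    base_arr = np.array(list(BASES))
    rows = list(aln.rows)
    ids = list(aln.ids)
    for d in range(n_decoys):
        ids.append(f"decoy{d+1:03d}")
        if mode == "misaligned":
            src = rows[int(rng.integers(0, aln.N))]
            shift = int(rng.integers(2, 7)) * (1 if rng.random() < 0.5 else -1)
            rows.append(src[-shift:] + src[:-shift])
        elif mode == "random":
            rows.append("".join(rng.choice(base_arr, size=aln.L_aln)))
        else:
            raise InputError(f"unknown contamination mode {mode!r}")
    return Alignment(ids, rows, query_id=aln.query_id, ss_cons=aln.ss_cons)


def write_fixture(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write Stockholm alignment, PDB structure, sites TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": outdir / "alignment.sto",
        "structure": outdir / "structure.pdb",
        "sites": outdir / "sites.tsv",
        "truth": outdir / "truth.json",
    }
    write_alignment(bundle.alignment, paths["alignment"], fmt="stockholm")
    write_pdb(bundle.structure, paths["structure"])
    write_sites([bundle.site], paths["sites"])
    truth = {
        "labels": {str(k): v for k, v in sorted(bundle.labels.items())},
        "site": sorted(bundle.site.members),
        "query_id": bundle.alignment.query_id,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1) + "\n")
    return paths
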