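"""Input/output for alignments, secondary structures, 3D structures and site lists.

All alignment columns are 1-based. Structure residues are indexed by their
1-based ordinal position in the chain; author numbering is kept for reporting
only. Sequence characters are normalized to the alphabet {A, C, G, U, N, -}:
T becomes U, lowercase is uppercased, any of ``.``, ``~``, ``-`` becomes the
gap character ``-``, and anything else becomes N. The gap is a first-class
fifth symbol everywhere downstream (frequency counts, distances, entropies).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import Align, AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGU-N"
SYMBOL_INDEX = {c: i for i, c in enumerate(ALPHABET)}

_GAP_CHARS = ".~-"
_NORMALIZE = str.maketrans(
    {**{c: "-" for c in _GAP_CHARS}, "T": "U", "t": "U"}
)


class FormatError(ValueError):
    """Raised when a file does not parse in the declared dialect."""


class InputError(ValueError):
    """Raised when parsed input violates a precondition."""


class MappingError(ValueError):
    """Raised when alignment-to-structure mapping exceeds the mismatch budget."""


def normalize_sequence(raw: str) -> str:
    s = raw.upper().translate(_NORMALIZE)
    return "".join(c if c in SYMBOL_INDEX else "N" for c in s)


@dataclass
class Alignment:
    """A normalized RNA multiple sequence alignment.

    rows are equal-length strings over {A,C,G,U,N,-}; ``query_id`` names the
    reference sequence used for structure mapping (defaults to the first id).
    """

    ids: list[str]
    rows: list[str]
    query_id: str | None = None
    ss_cons: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in length")
        if self.N < 2:
            raise InputError("alignment needs at least 2 sequences")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise FormatError(f"ragged alignment rows (widths {sorted(widths)})")
        self.rows = [normalize_sequence(r) for r in self.rows]
        if self.query_id is None:
            self.query_id = self.ids[0]
        if self.query_id not in self.ids:
            raise InputError(f"query_id {self.query_id!r} not in alignment")

    @property
    def N(self) -> int:
        return len(self.rows)

    @property
    def L_aln(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def query_row(self) -> str:
        return self.row(self.query_id)

    def to_array(self) -> np.ndarray:
        """(N, L) int8 matrix of symbol indices into ALPHABET."""
        flat = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        out = np.empty(flat.shape, dtype=np.int8)
        for sym, idx in SYMBOL_INDEX.items():
            out[flat == ord(sym)] = idx
        return out.reshape(self.N, self.L_aln)

    def subset(self, keep_ids: Sequence[str]) -> "Alignment":
        """Sub-alignment restricted to ``keep_ids`` (order preserved); columns unchanged."""
        keep = set(keep_ids)
        ids = [i for i in self.ids if i in keep]
        rows = [r for i, r in zip(self.ids, self.rows) if i in keep]
        q = self.query_id if self.query_id in keep else None
        return Alignment(ids, rows, query_id=q, ss_cons=self.ss_cons)


@dataclass(frozen=True)
class SecondaryStructure:
    """Base pairs as a set of 1-based column pairs (i, j) with i < j."""

    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not i < j:
                raise InputError(f"pair ({i},{j}) not ordered i<j")
            if i in seen or j in seen:
                raise InputError(f"column in more than one pair: ({i},{j})")
            seen.update((i, j))


@dataclass(frozen=True)
class StructResidue:
    chain: str
    number: int
    base: str  # one-letter base identity (A/C/G/U/N)
    coords: np.ndarray  # (n_atoms, 3) heavy-atom coordinates, Å

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise InputError(f"non-finite coordinates in residue {self.chain}{self.number}")


@dataclass
class StructureModel:
    """One RNA chain: ordered residues with heavy-atom coordinates."""

    residues: list[StructResidue]

    def __post_init__(self) -> None:
        keys = {(r.chain, r.number) for r in self.residues}
        if len(keys) != len(self.residues):
            raise InputError("duplicate (chain, residue_number)")

    @property
    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FunctionalSite:
    """A named functional site: a set of 1-based structure residue indices."""

    name: str
    members: frozenset[int]

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError(f"site {self.name!r} is empty")

    @property
    def M(self) -> int:
        return len(self.members)


@dataclass
class ColumnResidueMap:
    """Injective map between 1-based alignment columns and structure residues.

    ``mismatches`` lists mapped pairs whose base identities disagree.
    """

    col_to_res: dict[int, int]
    mismatches: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.col_to_res.values())) != len(self.col_to_res):
            raise InputError("column→residue map is not injective")
        self.res_to_col = {r: c for c, r in self.col_to_res.items()}

    @property
    def mismatch_fraction(self) -> float:
        return len(self.mismatches) / len(self.col_to_res) if self.col_to_res else 0.0

    def mapped_columns(self) -> list[int]:
        return sorted(self.col_to_res)

    def mapped_residues(self) -> list[int]:
        return sorted(self.res_to_col)


# ---------------------------------------------------------------------------
# Alignment reading/writing


def read_alignment(path: str | Path, fmt: str | None = None,
                   query_id: str | None = None) -> Alignment:
    """Read a Stockholm or aligned-FASTA alignment and normalize it.

    ``fmt`` is ``"stockholm"`` or ``"fasta"``; if None it is guessed from the
    suffix (.sto/.stk/.stockholm → stockholm, else fasta). A Stockholm
    ``#=GC SS_cons`` line is captured verbatim on the returned Alignment.
    """
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "fasta"
    if fmt not in {"stockholm", "fasta"}:
        raise FormatError(f"unsupported alignment format {fmt!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in msa]
    rows = [str(rec.seq) for rec in msa]
    ss = msa.column_annotations.get("secondary_structure") if fmt == "stockholm" else None
    return Alignment(ids, rows, query_id=query_id, ss_cons=ss)


def write_alignment(aln: Alignment, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "fasta"
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(aln.ids, aln.rows)]
    )
    if fmt == "stockholm" and aln.ss_cons is not None:
        msa.column_annotations["secondary_structure"] = aln.ss_cons
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, fmt)


# ---------------------------------------------------------------------------
# WUSS secondary-structure notation

_OPEN_BY_FAMILY = {"()": "(", "<>": "<", "[]": "[", "{}": "{"}


def parse_wuss(ss_string: str) -> SecondaryStructure:
    """Parse a WUSS/dot-bracket string into base pairs (1-based columns).

    Bracket families (), <>, [], {} nest independently; uppercase/lowercase
    letter pairs (Aa, Bb, ...) mark pseudoknots. Every other character is
    unpaired.
    """
    stacks: dict[str, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    closer_of = {")": "()", ">": "<>", "]": "[]", "}": "{}"}
    opener_of = {"(": "()", "<": "<>", "[": "[]", "{": "{}"}
    for pos, ch in enumerate(ss_string, start=1):
        if ch in opener_of:
            stacks.setdefault(opener_of[ch], []).append(pos)
        elif ch in closer_of:
            fam = closer_of[ch]
            stack = stacks.get(fam, [])
            if not stack:
                raise FormatError(f"unbalanced {fam!r} at column {pos}")
            pairs.add((stack.pop(), pos))
        elif ch in string.ascii_uppercase:
            stacks.setdefault(ch, []).append(pos)
        elif ch in string.ascii_lowercase:
            fam = ch.upper()
            stack = stacks.get(fam, [])
            if not stack:
                raise FormatError(f"unbalanced pseudoknot family {fam!r} at column {pos}")
            pairs.add((stack.pop(), pos))
    leftovers = {fam for fam, st in stacks.items() if st}
    if leftovers:
        raise FormatError(f"unbalanced families: {sorted(leftovers)}")
    return SecondaryStructure(frozenset(pairs))


def render_wuss(ss: SecondaryStructure, length: int) -> str:
    """Render nested pairs as dot-bracket (inverse of parse_wuss on nested input)."""
    out = ["."] * length
    for i, j in ss.pairs:
        out[i - 1], out[j - 1] = "(", ")"
    return "".join(out)


# ---------------------------------------------------------------------------
# 3D structure reading


def _base_letter(resname: str) -> str | None:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_nucleic_acid():
        return None
    one = info.one_letter_code.upper()
    if one == "T":
        one = "U"
    return one if one in "ACGU" else "N"


def read_structure(path: str | Path, chain: str) -> StructureModel:
    """Read one RNA chain from a PDB or mmCIF file (first model only).

    Hydrogens are dropped; residues appear in chain order with heavy-atom
    coordinates only. Raises InputError if the chain is missing or carries no
    nucleic residues.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise InputError(f"{path}: no models")
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise InputError(f"{path}: chain {chain!r} not found")
    residues: list[StructResidue] = []
    for res in ch:
        base = _base_letter(res.name)
        if base is None:
            continue
        coords = np.array(
            [[a.pos.x, a.pos.y, a.pos.z] for a in res if not a.is_hydrogen()],
            dtype=float,
        )
        if coords.size == 0:
            continue
        residues.append(StructResidue(chain, res.seqid.num, base, coords))
    if not residues:
        raise InputError(f"{path}: chain {chain!r} has no nucleic residues")
    return StructureModel(residues)


def write_pdb(struct: StructureModel, path: str | Path) -> None:
    """Write a minimal PDB file (deterministic bytes for a given model)."""
    lines = []
    serial = 0
    for resnum, res in enumerate(struct.residues, start=1):
        for k, (x, y, z) in enumerate(res.coords):
            serial += 1
            name = "C1'" if k == 0 else f"C{k+1}'"
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {res.base:>3s} {res.chain:1s}"
                f"{res.number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"           C"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Column ↔ residue mapping


def _pairwise_map(query: str, struct_seq: str) -> list[tuple[int, int]]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(query, struct_seq)[0]
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        pairs.extend((qs + off, ts + off) for off in range(qe - qs))
    return pairs  # 0-based (query position, structure position)


def map_columns(aln: Alignment, struct: StructureModel,
                max_mismatch: float = 0.10) -> ColumnResidueMap:
    """Map alignment columns to structure residues through the query row.

    The ungapped query is matched to the structure sequence by exact substring
    search first (either direction), falling back to global pairwise alignment.
    Raises MappingError when the mismatch fraction among mapped positions
    exceeds ``max_mismatch``.
    """
    qrow = aln.query_row()
    cols = [c for c, ch in enumerate(qrow, start=1) if ch != "-"]  # 1-based
    qseq = "".join(qrow[c - 1] for c in cols)
    sseq = struct.sequence

    pairs: list[tuple[int, int]]  # 0-based (query pos, struct pos)
    if sseq in qseq:
        off = qseq.index(sseq)
        pairs = [(off + i, i) for i in range(len(sseq))]
    elif qseq in sseq:
        off = sseq.index(qseq)
        pairs = [(i, off + i) for i in range(len(qseq))]
    else:
        pairs = _pairwise_map(qseq, sseq)

    col_to_res = {cols[q]: s + 1 for q, s in pairs}
    mismatches = [
        (cols[q], s + 1) for q, s in pairs
        if qseq[q] != sseq[s] and "N" not in (qseq[q], sseq[s])
    ]
    cmap = ColumnResidueMap(col_to_res, mismatches)
    if cmap.col_to_res and cmap.mismatch_fraction > max_mismatch:
        raise MappingError(
            f"mismatch fraction {cmap.mismatch_fraction:.2f} exceeds {max_mismatch:.2f}"
        )
    return cmap


# ---------------------------------------------------------------------------
# Functional-site lists


def read_sites(path: str | Path) -> dict[str, FunctionalSite]:
    """Read functional sites from a two-column TSV (site_name, residue_index)."""
    groups: dict[str, set[int]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        name, idx = fields
        try:
            groups.setdefault(name, set()).add(int(idx))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad residue index {idx!r}") from exc
    return {name: FunctionalSite(name, frozenset(members)) for name, members in groups.items()}


def write_sites(sites: Iterable[FunctionalSite], path: str | Path) -> None:
    lines = [
        f"{site.name}\t{idx}"
        for site in sites
        for idx in sorted(site.members)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
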