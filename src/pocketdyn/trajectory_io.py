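"""Conformational-ensemble I/O and frame/atom bookkeeping.

Ensembles are carried as multi-model PDB files and held in memory as a
:class:`FrameEnsemble`: an ``(M, N, 3)`` coordinate array in Ångström plus a
:class:`Topology` describing the ``N`` atoms.  Residues are always identified
by the ``(chain, number, insertion_code)`` triple — serine-protease
(chymotrypsinogen) numbering relies on insertion codes (e.g. the 60A loop of
thrombin), so the bare residue number is never a valid key.

PDB parsing and writing are delegated to :mod:`biotite`; this module only
adapts between biotite's ``AtomArrayStack`` and the ensemble contract used by
the metric modules.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueID",
    "Topology",
    "FrameEnsemble",
    "AtomSelection",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_residue_set",
    "write_residue_set",
    "select",
    "split_blocks",
]


@dataclass(frozen=True, order=True)
class ResidueID:
    """Identity of a residue: ``(chain, number, insertion_code)``.

    ``name`` (3-letter code) is carried for reporting but excluded from
    equality/hashing so that the same residue matched in two ensembles
    compares equal even if one file uses a variant residue name.
    """

    chain: str
    number: int
    insertion_code: str = ""
    name: str = field(default="", compare=False)

    def label(self) -> str:
        """Compact text form, e.g. ``"H:60A"`` or ``"H:195"``."""
        return f"{self.chain}:{self.number}{self.insertion_code}"

    @classmethod
    def from_label(cls, label: str, name: str = "") -> "ResidueID":
        m = re.fullmatch(r"\s*([^:\s]+):(-?\d+)([A-Za-z]?)\s*", label)
        if m is None:
            raise ValueError(f"malformed residue label {label!r}; expected 'CHAIN:NUMBER[ICODE]'")
        return cls(chain=m.group(1), number=int(m.group(2)), insertion_code=m.group(3), name=name)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label()


@dataclass
class Topology:
    """Atom-level description shared by all frames of an ensemble.

    ``atom_residue_index[i]`` points into ``residues`` for atom ``i``; atom
    order is the frame coordinate order.
    """

    atom_names: np.ndarray  # (N,) str
    elements: np.ndarray  # (N,) str
    atom_residue_index: np.ndarray  # (N,) int
    residues: list[ResidueID]

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.atom_residue_index = np.asarray(self.atom_residue_index, dtype=int)
        n = len(self.atom_names)
        if not (len(self.elements) == len(self.atom_residue_index) == n):
            raise ValueError("topology arrays must have one entry per atom")
        if n and (self.atom_residue_index.min() < 0 or self.atom_residue_index.max() >= len(self.residues)):
            raise ValueError("atom references a residue outside the residue list")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate (chain, number, insertion_code) residue identity in topology")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_of_atom(self, i: int) -> ResidueID:
        return self.residues[self.atom_residue_index[i]]

    def atoms_of_residue(self, res: ResidueID) -> np.ndarray:
        try:
            ri = self.residues.index(res)
        except ValueError:
            raise KeyError(f"residue {res.label()} not in topology") from None
        return np.flatnonzero(self.atom_residue_index == ri)


@dataclass
class FrameEnsemble:
    """``M`` frames × ``N`` atoms of Cartesian coordinates (Å) plus topology."""

    topology: Topology
    coordinates: np.ndarray  # (M, N, 3) float
    frame_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (M, N, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate array has {self.coordinates.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates in ensemble")
        if self.frame_labels is not None:
            self.frame_labels = np.asarray(self.frame_labels)
            if len(self.frame_labels) != self.n_frames:
                raise ValueError("frame_labels length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> "FrameEnsemble":
        """Single-frame view (degenerate ensemble) of frame ``i``."""
        return FrameEnsemble(self.topology, self.coordinates[i : i + 1].copy())


@dataclass
class AtomSelection:
    """Ordered, duplicate-free atom index set with a human-readable origin."""

    indices: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1:
            raise ValueError("selection indices must be 1-D")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("duplicate atom indices in selection")

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _stack_to_ensemble(stack) -> FrameEnsemble:
    import biotite.structure as struc

    n_atoms = stack.array_length()
    chain = stack.chain_id
    res_id = stack.res_id
    icode = stack.ins_code
    res_name = stack.res_name

    residues: list[ResidueID] = []
    index_of: dict[ResidueID, int] = {}
    atom_res_index = np.empty(n_atoms, dtype=int)
    for i in range(n_atoms):
        rid = ResidueID(str(chain[i]), int(res_id[i]), str(icode[i]).strip(), str(res_name[i]))
        j = index_of.get(rid)
        if j is None:
            j = len(residues)
            index_of[rid] = j
            residues.append(rid)
        atom_res_index[i] = j

    elements = np.asarray(stack.element, dtype=object)
    if any(e == "" for e in elements):
        warnings.warn("element column missing for some atoms; inferred from atom names")
        import biotite.structure.info  # noqa: F401

        guessed = [struc.infer_elements([n])[0] if e == "" else e
                   for n, e in zip(stack.atom_name, elements)]
        elements = np.asarray(guessed, dtype=object)

    topo = Topology(
        atom_names=np.asarray(stack.atom_name, dtype=object),
        elements=elements,
        atom_residue_index=atom_res_index,
        residues=residues,
    )
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None, :, :]
    return FrameEnsemble(topo, coords)


def read_multimodel_pdb(path: str | Path) -> FrameEnsemble:
    """Read a (multi-)model PDB file into a :class:`FrameEnsemble`.

    One frame per ``MODEL`` record; a file without ``MODEL`` records yields a
    degenerate single-frame ensemble.  Alternate locations other than blank or
    ``'A'`` are dropped with a warning.  Models with differing atom counts are
    a hard error.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    pdb = PDBFile.read(str(path))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            stack = pdb.get_structure(model=None, altloc="first")
    except Exception as exc:  # biotite raises on inconsistent models
        raise ValueError(f"inconsistent models in {path.name}: {exc}") from exc
    return _stack_to_ensemble(stack)


def write_multimodel_pdb(path: str | Path, ensemble: FrameEnsemble) -> None:
    """Write the ensemble as a multi-model PDB file (one MODEL per frame)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    topo = ensemble.topology
    n = topo.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = ensemble.coordinates[0]
    arr.chain_id = np.array([topo.residues[j].chain for j in topo.atom_residue_index])
    arr.res_id = np.array([topo.residues[j].number for j in topo.atom_residue_index])
    arr.ins_code = np.array([topo.residues[j].insertion_code for j in topo.atom_residue_index])
    arr.res_name = np.array([topo.residues[j].name or "UNK" for j in topo.atom_residue_index])
    arr.atom_name = np.asarray(topo.atom_names, dtype="U6")
    arr.element = np.asarray(topo.elements, dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([arr] * ensemble.n_frames)
    stack.coord = np.asarray(ensemble.coordinates, dtype=np.float32)
    out = PDBFile()
    out.set_structure(stack)
    out.write(str(path))


def read_residue_set(path: str | Path) -> list[ResidueID]:
    """Read a plain-text residue set, one ``CHAIN:NUMBER[ICODE]`` per line."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(ResidueID.from_label(line))
    return out


def write_residue_set(path: str | Path, residues: Iterable[ResidueID]) -> None:
    Path(path).write_text("".join(f"{r.label()}\n" for r in residues))


# ---------------------------------------------------------------------------
# Selection mini-grammar
# ---------------------------------------------------------------------------
#
#   expr    := term ( "or" term )*
#   term    := factor ( "and" factor )*
#   factor  := "not" factor | "(" expr ")" | clause
#   clause  := "name" WORD+ | "chain" WORD+ | "resid" RESID+
#            | "resname" WORD+ | "resfile" PATH | "all"
#
# Multiple values after a keyword are OR-ed ("name N CA C").

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"name", "chain", "resid", "resname", "resfile", "all", "and", "or", "not"}


class SelectionSyntaxError(ValueError):
    """Raised for malformed selection queries; carries the token position."""


class _Parser:
    def __init__(self, query: str, topo: Topology):
        self.query = query
        self.topo = topo
        self.tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(query)]
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.query))

    def _next(self):
        tok = self._peek()
        self.pos += 1
        return tok

    def _error(self, msg: str, at: int):
        raise SelectionSyntaxError(f"selection syntax error at position {at}: {msg} (query: {self.query!r})")

    def parse(self) -> np.ndarray:
        if not self.tokens:
            self._error("empty query", 0)
        mask = self._expr()
        tok, at = self._peek()
        if tok is not None:
            self._error(f"unexpected token {tok!r}", at)
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while self._peek()[0] == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while self._peek()[0] == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self) -> np.ndarray:
        tok, at = self._peek()
        if tok == "not":
            self._next()
            return ~self._factor()
        if tok == "(":
            self._next()
            mask = self._expr()
            tok2, at2 = self._next()
            if tok2 != ")":
                self._error("expected ')'", at2)
            return mask
        return self._clause()

    def _values(self, at: int) -> list[str]:
        vals = []
        while True:
            tok, _ = self._peek()
            if tok is None or tok in _KEYWORDS or tok in "()":
                break
            vals.append(self._next()[0])
        if not vals:
            self._error("keyword needs at least one value", at)
        return vals

    def _clause(self) -> np.ndarray:
        topo = self.topo
        tok, at = self._next()
        if tok is None:
            self._error("unexpected end of query", at)
        if tok == "all":
            return np.ones(topo.n_atoms, dtype=bool)
        if tok == "name":
            vals = set(self._values(at))
            return np.array([a in vals for a in topo.atom_names])
        if tok == "chain":
            vals = set(self._values(at))
            return np.array([topo.residues[j].chain in vals for j in topo.atom_residue_index])
        if tok == "resname":
            vals = set(self._values(at))
            return np.array([topo.residues[j].name in vals for j in topo.atom_residue_index])
        if tok == "resid":
            wanted = set()
            for v in self._values(at):
                m = re.fullmatch(r"(-?\d+)([A-Za-z]?)", v)
                if m is None:
                    self._error(f"malformed resid {v!r}", at)
                wanted.add((int(m.group(1)), m.group(2)))
            return np.array(
                [(topo.residues[j].number, topo.residues[j].insertion_code) in wanted
                 for j in topo.atom_residue_index]
            )
        if tok == "resfile":
            vals = self._values(at)
            if len(vals) != 1:
                self._error("resfile takes exactly one path", at)
            wanted = set(read_residue_set(vals[0]))
            return np.array([topo.residues[j] in wanted for j in topo.atom_residue_index])
        self._error(f"unknown keyword {tok!r}", at)


def select(ensemble: FrameEnsemble | Topology, query: str) -> AtomSelection:
    """Resolve a selection query against an ensemble's topology.

    The grammar supports ``name``, ``chain``, ``resid`` (insertion codes
    attached, e.g. ``resid 60A``), ``resname``, ``resfile PATH`` and ``all``,
    combined with ``and`` / ``or`` / ``not`` and parentheses.  Selection is
    deterministic and order-preserving (topology atom order).  Empty results
    are allowed but logged.
    """
    topo = ensemble if isinstance(ensemble, Topology) else ensemble.topology
    mask = _Parser(query, topo).parse()
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        logger.warning("selection %r matched no atoms", query)
    return AtomSelection(indices=indices, description=query)


def select_residues(ensemble: FrameEnsemble | Topology, residues: Iterable[ResidueID],
                    atom_name: str | None = None) -> AtomSelection:
    """Select all atoms (or one named atom) of an explicit residue list."""
    topo = ensemble if isinstance(ensemble, Topology) else ensemble.topology
    wanted = set(residues)
    mask = np.array([topo.residues[j] in wanted for j in topo.atom_residue_index])
    if atom_name is not None:
        mask &= np.array([a == atom_name for a in topo.atom_names])
    return AtomSelection(np.flatnonzero(mask), description=f"{len(wanted)} residues" +
                         (f" and name {atom_name}" if atom_name else ""))


def split_blocks(ensemble: FrameEnsemble, k: int) -> list[FrameEnsemble]:
    """Split frames into ``k`` contiguous, near-equal blocks.

    Block size is ``M // k``; remainder frames go to the last block, so
    concatenating the blocks reproduces the original frame order exactly.
    """
    m = ensemble.n_frames
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m:
        raise ValueError(f"cannot split {m} frames into {k} blocks")
    base = m // k
    bounds = [i * base for i in range(k)] + [m]
    blocks = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        labels = None if ensemble.frame_labels is None else ensemble.frame_labels[lo:hi]
        blocks.append(FrameEnsemble(ensemble.topology, ensemble.coordinates[lo:hi].copy(), labels))
    return blocks
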