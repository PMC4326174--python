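"""Structure, trajectory and parameter-table I/O.

The only mandatory coordinate format is the classic fixed-width PDB dialect
(``ATOM``/``HETATM``/``MODEL``/``ENDMDL``); trajectories are multi-model PDB
files, one ``MODEL`` per frame.  The reader is deliberately strict: malformed
coordinate fields raise an error naming the offending line, insertion codes
are rejected, and for alternate locations only the first altloc of each atom
is kept.  Residue numbering is taken verbatim from the file — author
numbering is never rewritten.

Atom selections use a small documented mini-grammar (see :class:`Selection`).
Resolution against a structure is deterministic and ordered by file order.

Units: coordinates and distances in Å, times in ns, energies in kcal/mol,
forces in pN (see :data:`UNITS`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNITS",
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Selection",
    "NonbondParamTable",
    "StructureError",
    "PDBParseError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
    "read_params",
    "write_params",
    "write_series",
    "read_series",
]

#: Canonical units used by every module and echoed in report manifests.
UNITS = {
    "length": "angstrom",
    "time": "ns",
    "energy": "kcal/mol",
    "force": "pN",
    "angle": "degree",
    "charge": "e",
}

#: Residue names treated as solvent/counter-ions by the ``solvent`` keyword.
SOLVENT_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "NA", "CL", "SOD", "CLA", "POT", "K"})


class StructureError(ValueError):
    """Invalid structure, trajectory or parameter-table content."""


class PDBParseError(StructureError):
    """Malformed PDB-dialect input; the message names the offending line."""


class SelectionError(StructureError):
    """Selection expression failed to parse or matched no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus Cartesian position in Å."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray  # shape (3,), Å
    element: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise StructureError(f"atom {self.serial}: position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.serial}: non-finite coordinates")
        object.__setattr__(self, "position", pos)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


class Structure:
    """An ordered set of atoms; atom order is file order and is preserved."""

    def __init__(self, atoms: Sequence[AtomRecord], label: str = "") -> None:
        atoms = list(atoms)
        if not atoms:
            raise StructureError("structure must contain at least one atom")
        seen: set[tuple[str, int, str]] = set()
        for a in atoms:
            if a.key in seen:
                raise StructureError(
                    f"duplicate atom (chain {a.chain_id!r}, residue {a.residue_number}, "
                    f"name {a.atom_name!r})"
                )
            seen.add(a.key)
        self.atoms: list[AtomRecord] = atoms
        self.label = label

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"Structure({self.label!r}, {len(self)} atoms)"

    @property
    def coords(self) -> np.ndarray:
        """N×3 coordinate array (a copy), Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """Same topology with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise StructureError(f"expected coordinates of shape ({len(self)}, 3)")
        atoms = [
            AtomRecord(a.serial, a.atom_name, a.residue_name, a.chain_id,
                       a.residue_number, coords[i], a.element)
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms, self.label if label is None else label)


class Trajectory:
    """Frames of coordinates sharing one topology; times in ns, strictly increasing."""

    def __init__(self, topology: Structure, frames: Sequence[np.ndarray],
                 times: Sequence[float] | None = None) -> None:
        frames = [np.asarray(f, dtype=float) for f in frames]
        if not frames:
            raise StructureError("trajectory must contain at least one frame")
        n = len(topology)
        for i, f in enumerate(frames):
            if f.shape != (n, 3):
                raise StructureError(
                    f"frame {i}: expected {n} atoms, got shape {f.shape}"
                )
        if times is None:
            times = np.arange(len(frames), dtype=float)
        times = np.asarray(times, dtype=float)
        if times.shape != (len(frames),):
            raise StructureError("times must have one entry per frame")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise StructureError("times must be strictly increasing")
        self.topology = topology
        self.frames = frames
        self.times = times

    def __len__(self) -> int:
        return len(self.frames)

    def __repr__(self) -> str:
        return f"Trajectory({self.topology.label!r}, {len(self)} frames)"

    @property
    def xyz(self) -> np.ndarray:
        """F×N×3 coordinate array (a copy), Å."""
        return np.stack(self.frames)


# ---------------------------------------------------------------------------
# PDB dialect reading and writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> AtomRecord | None:
    """Parse one ATOM/HETATM line; None if the atom is a skipped altloc duplicate."""
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: truncated ATOM record")
    icode = line[26:27]
    if icode.strip():
        raise PDBParseError(f"line {lineno}: insertion codes are not supported "
                            f"(found {icode!r})")
    try:
        serial = int(line[6:11])
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed numeric field ({exc})") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    return AtomRecord(
        serial=serial,
        atom_name=line[12:16].strip(),
        residue_name=line[17:20].strip(),
        chain_id=line[21:22].strip() or " ",
        residue_number=resnum,
        position=np.array([x, y, z]),
        element=element,
    )


def _scan_models(path: Path) -> list[list[AtomRecord]]:
    """All MODELs of a PDB-dialect file; a file without MODEL cards is one model."""
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    seen_keys: set[tuple[str, int, str]] = set()
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    models.append(current)
                current, seen_keys, in_model = [], set(), True
            elif rec == "ENDMDL":
                models.append(current)
                current, seen_keys, in_model = [], set(), False
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                altloc = line[16:17].strip()
                if altloc and atom.key in seen_keys:
                    continue  # first altloc kept
                seen_keys.add(atom.key)
                current.append(atom)
            # TER / REMARK / anything else: ignored
    if current:
        models.append(current)
    return [m for m in models if m]


def read_structure(path: str | Path, label: str | None = None) -> Structure:
    """Read the first MODEL of a PDB-dialect file as a :class:`Structure`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    models = _scan_models(path)
    if not models or not models[0]:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(models[0], label=path.stem if label is None else label)


def _format_atom_line(a: AtomRecord) -> str:
    name = a.atom_name
    # standard PDB name justification: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"ATOM  {a.serial % 100000:5d} {name_field}"
        f" {a.residue_name:>3.3s} {a.chain_id:1.1s}{a.residue_number:4d}    "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"  1.00  0.00          {a.element:>2.2s}"
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB-dialect file (0.001 Å precision)."""
    with open(path, "w") as fh:
        for a in structure.atoms:
            fh.write(_format_atom_line(a) + "\n")
        fh.write("END\n")


def read_trajectory(path: str | Path, topology: Structure,
                    times: Sequence[float] | None = None,
                    dt_ns: float = 1.0) -> Trajectory:
    """Read a multi-model PDB file as a trajectory over ``topology``.

    Every MODEL must have the same atom count and order as ``topology``; a
    mismatch raises an error naming the 1-based MODEL index.  ``times``
    overrides the default frame-index × ``dt_ns`` time stamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    models = _scan_models(path)
    if not models:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    n = len(topology)
    frames = []
    for i, model in enumerate(models, start=1):
        if len(model) != n:
            raise PDBParseError(
                f"{path}: MODEL {i} has {len(model)} atoms, topology has {n}"
            )
        frames.append(np.array([a.position for a in model]))
    if times is None:
        times = np.arange(len(frames), dtype=float) * dt_ns
    return Trajectory(topology, frames, times)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB-dialect file."""
    with open(path, "w") as fh:
        for m, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for a, pos in zip(traj.topology.atoms, frame):
                fh.write(_format_atom_line(
                    AtomRecord(a.serial, a.atom_name, a.residue_name, a.chain_id,
                               a.residue_number, pos, a.element)) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selection mini-grammar
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_KEYWORDS = {"and", "or", "not", "(", ")"}


class _Parser:
    """Recursive-descent parser for the selection grammar.

    ::

        expr    := or_expr
        or_expr := and_expr ('or' and_expr)*
        and_expr:= unary ('and' unary)*
        unary   := 'not' unary | '(' expr ')' | primary
        primary := 'resid'   N | N-M | N:M   (residue-number ranges, inclusive)
                 | 'resname' NAME            (3-letter residue name)
                 | 'name'    NAME            (atom name, e.g. CA)
                 | 'chain'   C               (chain identifier)
                 | 'heavy'                   (element is not hydrogen)
                 | 'ca'                      (atom name CA)
                 | 'solvent'                 (water / counter-ion residue names)
                 | 'all'
    """

    def __init__(self, tokens: list[str], expression: str) -> None:
        self.tokens = tokens
        self.pos = 0
        self.expression = expression

    def _fail(self, msg: str) -> SelectionError:
        return SelectionError(f"selection {self.expression!r}: {msg}")

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise self._fail("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self, structure: Structure) -> np.ndarray:
        mask = self.or_expr(structure)
        if self.peek() is not None:
            raise self._fail(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self, s: Structure) -> np.ndarray:
        mask = self.and_expr(s)
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr(s)
        return mask

    def and_expr(self, s: Structure) -> np.ndarray:
        mask = self.unary(s)
        while self.peek() == "and":
            self.take()
            mask = mask & self.unary(s)
        return mask

    def unary(self, s: Structure) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.unary(s)
        if tok == "(":
            self.take()
            mask = self.or_expr(s)
            if self.take() != ")":
                raise self._fail("missing closing parenthesis")
            return mask
        return self.primary(s)

    def primary(self, s: Structure) -> np.ndarray:
        tok = self.take()
        atoms = s.atoms
        if tok == "resid":
            lo, hi = self._range(self.take())
            return np.array([lo <= a.residue_number <= hi for a in atoms])
        if tok == "resname":
            name = self.take().upper()
            return np.array([a.residue_name.upper() == name for a in atoms])
        if tok == "name":
            name = self.take().upper()
            return np.array([a.atom_name.upper() == name for a in atoms])
        if tok == "chain":
            cid = self.take()
            return np.array([a.chain_id == cid for a in atoms])
        if tok == "heavy":
            return np.array([not _is_hydrogen(a) for a in atoms])
        if tok == "ca":
            return np.array([a.atom_name.upper() == "CA" for a in atoms])
        if tok == "solvent":
            return np.array([a.residue_name.upper() in SOLVENT_RESNAMES for a in atoms])
        if tok == "all":
            return np.ones(len(atoms), dtype=bool)
        raise self._fail(f"unknown keyword {tok!r}")

    def _range(self, tok: str) -> tuple[int, int]:
        m = re.fullmatch(r"(-?\d+)(?:[-:](-?\d+))?", tok)
        if not m:
            raise self._fail(f"bad residue range {tok!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if hi < lo:
            raise self._fail(f"empty residue range {tok!r}")
        return lo, hi


def _is_hydrogen(a: AtomRecord) -> bool:
    if a.element:
        return a.element.upper() in ("H", "D")
    return a.atom_name[:1].upper() == "H"


@dataclass(frozen=True)
class Selection:
    """An atom-selection expression in the mini-grammar (see :class:`_Parser`)."""

    expression: str

    def resolve(self, structure: Structure) -> np.ndarray:
        """Ordered (file-order) atom indices matched in ``structure``.

        Deterministic; an empty match is an error — every selection used by
        the analyses is expected to be non-empty.
        """
        tokens = _TOKEN_RE.findall(self.expression)
        if not tokens:
            raise SelectionError(f"selection {self.expression!r}: empty expression")
        mask = _Parser(tokens, self.expression).parse(structure)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(
                f"selection {self.expression!r} matched no atoms in "
                f"{structure.label or 'structure'}"
            )
        return idx


def resolve_selection(sel: Selection | str, structure: Structure) -> np.ndarray:
    """Resolve a selection (expression string or :class:`Selection`)."""
    if isinstance(sel, str):
        sel = Selection(sel)
    return sel.resolve(structure)


# ---------------------------------------------------------------------------
# Nonbond parameter table
# ---------------------------------------------------------------------------

PARAM_COLUMNS = ["residue_name", "atom_name", "charge_e", "epsilon_kcal", "rmin_half_A"]


class NonbondParamTable:
    """Per-atom-type nonbond parameters keyed by (residue_name, atom_name).

    charge in e; Lennard-Jones well depth ε ≥ 0 in kcal/mol; Rmin/2 > 0 in Å.
    """

    def __init__(self, rows: Mapping[tuple[str, str], tuple[float, float, float]]) -> None:
        self.rows: dict[tuple[str, str], tuple[float, float, float]] = {}
        for (resn, name), (q, eps, rminh) in rows.items():
            if eps < 0:
                raise StructureError(f"param ({resn},{name}): epsilon must be >= 0")
            if rminh <= 0:
                raise StructureError(f"param ({resn},{name}): rmin_half must be > 0")
            self.rows[(resn.upper(), name.upper())] = (float(q), float(eps), float(rminh))

    def resolve(self, structure: Structure,
                indices: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(charge, epsilon, rmin_half) arrays for the given atoms.

        Every atom must have exactly one row; a missing row is an error.
        """
        atoms = structure.atoms
        if indices is None:
            indices = np.arange(len(atoms))
        q = np.empty(len(indices))
        eps = np.empty(len(indices))
        rminh = np.empty(len(indices))
        for k, i in enumerate(indices):
            a = atoms[int(i)]
            key = (a.residue_name.upper(), a.atom_name.upper())
            if key not in self.rows:
                raise StructureError(
                    f"no nonbond parameters for residue {a.residue_name!r} "
                    f"atom {a.atom_name!r}"
                )
            q[k], eps[k], rminh[k] = self.rows[key]
        return q, eps, rminh


def read_params(path: str | Path) -> NonbondParamTable:
    """Read a nonbond parameter table from CSV.

    Header must be ``residue_name,atom_name,charge_e,epsilon_kcal,rmin_half_A``.
    """
    df = pd.read_csv(path)
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise StructureError(f"{path}: missing parameter columns {missing}")
    rows = {
        (str(r.residue_name), str(r.atom_name)):
            (float(r.charge_e), float(r.epsilon_kcal), float(r.rmin_half_A))
        for r in df.itertuples()
    }
    return NonbondParamTable(rows)


def write_params(table: NonbondParamTable, path: str | Path) -> None:
    recs = [
        {"residue_name": resn, "atom_name": name, "charge_e": q,
         "epsilon_kcal": eps, "rmin_half_A": rminh}
        for (resn, name), (q, eps, rminh) in sorted(table.rows.items())
    ]
    pd.DataFrame(recs, columns=PARAM_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tabular series output
# ---------------------------------------------------------------------------

def write_series(table: Mapping[str, Iterable], path: str | Path) -> None:
    """Write named equal-length columns as CSV with a mandatory header.

    Numeric values round-trip at 9 significant digits.  Ragged columns are an
    error.
    """
    cols = {k: np.asarray(v) for k, v in table.items()}
    lengths = {k: len(v) for k, v in cols.items()}
    if len(set(lengths.values())) > 1:
        raise StructureError(f"ragged columns: {lengths}")
    df = pd.DataFrame(cols, columns=list(cols))
    df.to_csv(path, index=False, float_format="%.9g")


def read_series(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
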