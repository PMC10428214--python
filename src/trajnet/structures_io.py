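"""Structures, trajectories and PDB I/O.

Fixed-column PDB (ATOM/HETATM, MODEL/ENDMDL) is the canonical on-disk
format; everything downstream consumes the in-memory :class:`Structure`
and :class:`Trajectory` types defined here.

Conventions:

* Residue numbering is preserved exactly as printed in the file
  (including insertion codes, which are part of the residue identity).
* Alternate locations are resolved at parse time: the highest-occupancy
  altloc wins, ties go to the first record encountered.
* HETATM records are retained and flagged; waters and common monoatomic
  ions are not considered ligand candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import PDBParseError, SelectionError, TopologyError

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "read_pdb",
    "read_multimodel_pdb",
    "write_pdb",
    "write_multimodel_pdb",
    "select_atoms",
]

#: residue names excluded from ligand candidacy
_SOLVENT_RESNAMES = frozenset(
    {"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC",
     "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "SOD", "CLA", "POT"}
)

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}


@dataclass(frozen=True)
class Atom:
    """A single atom record.

    ``residue_seq`` keeps the number printed in the source file; together
    with ``chain`` and ``icode`` it identifies the residue.
    """

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_seq: int
    element: str
    coord: tuple[float, float, float]
    icode: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if len(self.coord) != 3 or not all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial}: coord must be a finite 3-vector")

    @property
    def residue_id(self) -> str:
        """Stable residue identifier ``chain:seq[icode]``."""
        return f"{self.chain}:{self.residue_seq}{self.icode}"

    @property
    def element_guess(self) -> str:
        """Element symbol; falls back to the first letter of the atom name."""
        if self.element:
            return self.element.upper()
        stripped = self.name.lstrip("0123456789")
        return stripped[:1].upper()


@dataclass
class Structure:
    """Ordered atom list plus derived residue bookkeeping."""

    atoms: list[Atom]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Å."""
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, residue_seq, residue_name), file order."""
        seen: dict[tuple[str, int, str, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.residue_seq, a.icode, a.residue_name), None)
        return [(c, s, n) for (c, s, _i, n) in seen]

    def residue_atom_indices(self) -> dict[str, list[int]]:
        """Map residue_id -> atom indices in topology order."""
        out: dict[str, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_id, []).append(i)
        return out

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise TopologyError(
                f"coordinate array shape {coords.shape} does not match "
                f"{self.n_atoms} atoms"
            )
        return Structure(
            [replace(a, coord=tuple(c)) for a, c in zip(self.atoms, coords)]
        )


@dataclass
class Trajectory:
    """A topology plus ordered coordinate frames (Å)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: list[float] | None = None  # ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TopologyError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames carry {self.frames.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if len(t) != self.n_frames:
                raise TopologyError("frame_times length mismatch")
            if np.any(np.diff(t) <= 0):
                raise TopologyError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> Atom:
    def _float(colspan: tuple[int, int], what: str) -> float:
        raw = line[colspan[0]:colspan[1]].strip()
        try:
            return float(raw)
        except ValueError:
            raise PDBParseError(
                f"line {lineno}: malformed {what} field {raw!r}"
            ) from None

    try:
        serial = int(line[6:11].strip() or "0")
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed serial field") from None
    name = line[12:16].strip()
    if not name:
        raise PDBParseError(f"line {lineno}: empty atom name")
    altloc = line[16:17].strip()
    resname = line[17:20].strip()
    chain = line[21:22].strip() or "A"
    try:
        resseq = int(line[22:26].strip())
    except ValueError:
        raise PDBParseError(f"line {lineno}: malformed residue number") from None
    icode = line[26:27].strip()
    x = _float((30, 38), "x coordinate")
    y = _float((38, 46), "y coordinate")
    z = _float((46, 54), "z coordinate")
    occ_raw = line[54:60].strip()
    occupancy = float(occ_raw) if occ_raw else 1.0
    element = line[76:78].strip()
    return Atom(
        serial=serial,
        name=name,
        residue_name=resname,
        chain=chain,
        residue_seq=resseq,
        element=element,
        coord=(x, y, z),
        icode=icode,
        altloc=altloc,
        occupancy=occupancy,
        is_hetatm=line.startswith("HETATM"),
    )


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy altloc per atom site; ties -> first seen."""
    best: dict[tuple[str, int, str, str], tuple[int, Atom]] = {}
    order: list[tuple[str, int, str, str]] = []
    for pos, a in enumerate(atoms):
        key = (a.chain, a.residue_seq, a.icode, a.name)
        if key not in best:
            best[key] = (pos, a)
            order.append(key)
        elif a.occupancy > best[key][1].occupancy:
            best[key] = (best[key][0], a)  # keep original position
    return [best[k][1] for k in sorted(order, key=lambda k: best[k][0])]


def read_pdb(text: str) -> Structure:
    """Parse a PDB-format string into a :class:`Structure`.

    Raises :class:`PDBParseError` (naming the line) on malformed fields and
    on inputs containing zero ATOM/HETATM records.
    """
    atoms: list[Atom] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM", "ATOM\t")) or (
            line.startswith("ATOM") and len(line) > 54
        ):
            atoms.append(_parse_atom_line(line, lineno))
    if not atoms:
        raise PDBParseError("no ATOM/HETATM records found (empty input)")
    return Structure(_resolve_altlocs(atoms))


def read_multimodel_pdb(text: str) -> Trajectory:
    """Parse a multi-model PDB into a :class:`Trajectory`.

    The topology is taken from the first MODEL; every subsequent MODEL must
    repeat the exact atom layout or a :class:`TopologyError` is raised naming
    the offending model index.
    """
    blocks: list[list[str]] = []
    current: list[str] | None = None
    loose: list[str] = []
    for line in text.splitlines():
        if line.startswith("MODEL"):
            current = []
        elif line.startswith("ENDMDL"):
            if current is None:
                raise PDBParseError("ENDMDL without matching MODEL")
            blocks.append(current)
            current = None
        elif current is not None:
            current.append(line)
        else:
            loose.append(line)
    if current is not None:
        blocks.append(current)
    if not blocks:
        # no MODEL records: treat the whole file as a single frame
        blocks = [loose]
        loose = []

    structures = [read_pdb("\n".join(b)) for b in blocks]
    topo = structures[0]
    ref_layout = [(a.chain, a.residue_seq, a.icode, a.name) for a in topo.atoms]
    frames = np.empty((len(structures), topo.n_atoms, 3), dtype=float)
    for m, s in enumerate(structures, start=1):
        layout = [(a.chain, a.residue_seq, a.icode, a.name) for a in s.atoms]
        if layout != ref_layout:
            raise TopologyError(
                f"model {m}: atom layout differs from model 1 "
                f"({s.n_atoms} vs {topo.n_atoms} atoms)"
            )
        frames[m - 1] = s.coords
    return Trajectory(topology=topo, frames=frames)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str) -> str:
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _atom_line(a: Atom, serial: int) -> str:
    for c in a.coord:
        if abs(c) >= 1e4:
            raise ValueError(
                f"coordinate magnitude {c} ≥ 10^4 Å cannot be formatted"
            )
    record = "HETATM" if a.is_hetatm else "ATOM  "
    return (
        f"{record}{serial:>5d} {_format_atom_name(a.name)}{a.altloc or ' '}"
        f"{a.residue_name:>3s} {a.chain[:1] or 'A'}{a.residue_seq:>4d}"
        f"{a.icode or ' '}   "
        f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
        f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element_guess:>2s}"
    )


def write_pdb(structure: Structure) -> str:
    """Serialise a Structure to fixed-column PDB text."""
    if structure.n_atoms == 0:
        raise ValueError("cannot write a structure with zero atoms")
    lines = [_atom_line(a, i + 1) for i, a in enumerate(structure.atoms)]
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_multimodel_pdb(trajectory: Trajectory) -> str:
    """Serialise a Trajectory to a MODEL/ENDMDL multi-model PDB."""
    if trajectory.n_frames == 0:
        raise ValueError("cannot write a trajectory with zero frames")
    out: list[str] = []
    for f in range(trajectory.n_frames):
        out.append(f"MODEL     {f + 1:>4d}")
        frame_struct = trajectory.topology.with_coords(trajectory.frames[f])
        out.extend(
            _atom_line(a, i + 1) for i, a in enumerate(frame_struct.atoms)
        )
        out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "chain", "resname", "resid", "resid_range", "name", "element",
    "network_node", "hetatm",
}


def is_ligand_candidate(atom: Atom) -> bool:
    """HETATM record that is neither solvent nor a common monoatomic ion."""
    return atom.is_hetatm and atom.residue_name not in _SOLVENT_RESNAMES


def _node_atom_name(residue_name: str) -> str:
    return "CA" if residue_name == "GLY" else "CB"


def select_atoms(structure: Structure, spec: Mapping[str, object]) -> list[int]:
    """Return topology-order atom indices matching a conjunctive selection.

    Supported predicate keys:

    ``chain``        chain identifier (str)
    ``resname``      residue name (str or iterable of str)
    ``resid``        residue sequence number (int)
    ``resid_range``  inclusive (lo, hi) pair of residue numbers
    ``name``         atom name (str or iterable of str)
    ``element``      element symbol (str)
    ``hetatm``       bool: require (or forbid) HETATM records
    ``network_node`` truthy: the residue-network node atom — CB, CA for
                     glycine, or the given ligand node atom name (a string
                     value names the ligand node atom; ``True`` means "C2")

    Unknown keys raise :class:`SelectionError`.
    """
    unknown = set(spec) - _KNOWN_KEYS
    if unknown:
        raise SelectionError(f"unknown selection key(s): {sorted(unknown)}")

    def _as_set(v: object) -> set[str]:
        if isinstance(v, str):
            return {v}
        if isinstance(v, Iterable):
            return {str(x) for x in v}
        return {str(v)}

    ligand_node_atom = "C2"
    if "network_node" in spec and isinstance(spec["network_node"], str):
        ligand_node_atom = str(spec["network_node"])

    out: list[int] = []
    for i, a in enumerate(structure.atoms):
        if "chain" in spec and a.chain != spec["chain"]:
            continue
        if "resname" in spec and a.residue_name not in _as_set(spec["resname"]):
            continue
        if "resid" in spec and a.residue_seq != int(spec["resid"]):  # type: ignore[arg-type]
            continue
        if "resid_range" in spec:
            lo, hi = spec["resid_range"]  # type: ignore[misc]
            if not (int(lo) <= a.residue_seq <= int(hi)):
                continue
        if "name" in spec and a.name not in _as_set(spec["name"]):
            continue
        if "element" in spec and a.element_guess != str(spec["element"]).upper():
            continue
        if "hetatm" in spec and a.is_hetatm != bool(spec["hetatm"]):
            continue
        if spec.get("network_node"):
            if is_ligand_candidate(a):
                if a.name != ligand_node_atom:
                    continue
            elif a.is_hetatm:
                continue  # solvent/ion HETATM never a node
            elif a.name != _node_atom_name(a.residue_name):
                continue
        out.append(i)
    return out
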