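"""Trajectory and topology I/O plus atom-role selections.

This module owns the three carrier types used by every analysis —
:class:`Topology`, :class:`Frame`, :class:`Trajectory` — and the plain-text
readers/writers (PDB with CONECT records, multi-frame XYZ, optional DCD via
MDAnalysis).  Atom roles are assigned from pattern rules rather than inferred
from chemistry, so the same analysis code runs on all-atom topologies and on
coarse synthetic fixtures alike.

Conventions: coordinates in Å, time in ps, temperature in K.  Only
orthorhombic periodic boxes are supported; triclinic cells are rejected.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ROLE_TAGS",
    "WATER_ROLES",
    "POLYMER_ROLES",
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "TrajectoryIOError",
    "RoleAssignmentError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "read_xyz_multi",
    "write_xyz_multi",
    "read_dcd",
    "write_dcd",
    "assign_roles",
    "select",
]

#: All recognised atom-role tags.
ROLE_TAGS = frozenset(
    {
        "backbone",
        "sidechain",
        "terminal_carbon",
        "mainchain_oxygen",
        "sidechain_oxygen",
        "water_oxygen",
        "water_hydrogen",
    }
)
WATER_ROLES = frozenset({"water_oxygen", "water_hydrogen"})
POLYMER_ROLES = ROLE_TAGS - WATER_ROLES


class TrajectoryIOError(RuntimeError):
    """Raised on malformed or inconsistent trajectory/topology files."""


class RoleAssignmentError(ValueError):
    """Raised when role assignment leaves required atoms unclassified."""


class SelectionError(KeyError):
    """Raised when selecting an unknown role tag."""


@dataclass(frozen=True)
class Atom:
    """One atom record: name, element symbol, residue bookkeeping and roles."""

    name: str
    element: str
    residue_index: int
    residue_name: str = ""
    roles: frozenset = frozenset()


@dataclass
class Topology:
    """Ordered atom list, bond set and polymer size.

    Parameters
    ----------
    atoms
        Ordered atom records; index into this list is the atom index used
        everywhere else.
    bonds
        Set of 2-tuples ``(i, j)`` with ``i < j``; unordered atom-index pairs.
    n_residues_polymer
        Degree of polymerization ``N`` (number of polymer residues).  Zero is
        permitted for water-only fixtures; operations that need ``N`` validate
        it themselves.
    """

    atoms: list
    bonds: set = field(default_factory=set)
    n_residues_polymer: int = 0

    def __post_init__(self) -> None:
        self.bonds = {tuple(sorted(map(int, b))) for b in self.bonds}
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) references a missing atom")
        for idx, atom in enumerate(self.atoms):
            bad = set(atom.roles) - ROLE_TAGS
            if bad:
                raise ValueError(f"atom {idx} has unknown roles {sorted(bad)}")
            if atom.roles & WATER_ROLES and atom.roles & POLYMER_ROLES:
                raise ValueError(
                    f"atom {idx} mixes water and polymer roles: {sorted(atom.roles)}"
                )
            if "terminal_carbon" in atom.roles and "sidechain" not in atom.roles:
                raise ValueError(
                    f"atom {idx}: terminal_carbon must also be tagged sidechain"
                )
            if {"mainchain_oxygen", "sidechain_oxygen"} <= atom.roles:
                raise ValueError(
                    f"atom {idx} tagged both mainchain_oxygen and sidechain_oxygen"
                )
        if self.n_residues_polymer < 0:
            raise ValueError("n_residues_polymer must be >= 0")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def bonded_to(self, index: int) -> list:
        """Atom indices covalently bonded to ``index`` (ascending)."""
        out = set()
        for i, j in self.bonds:
            if i == index:
                out.add(j)
            elif j == index:
                out.add(i)
        return sorted(out)


@dataclass
class Frame:
    """One snapshot: per-atom coordinates (Å), optional orthorhombic box, time (ps)."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise ValueError("box edges must be > 0")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def require_box(self) -> np.ndarray:
        if self.box is None:
            raise ValueError(
                "frame has no periodic box; PBC-dependent operations need one"
            )
        return self.box


@dataclass
class Trajectory:
    """A topology with one or more frames and an optional temperature label (K)."""

    topology: Topology
    frames: list
    temperature: float | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(
                    f"frame {k} has {fr.n_atoms} atoms, topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_array(self) -> np.ndarray:
        """Stacked coordinates, shape ``(n_frames, n_atoms, 3)``."""
        return np.stack([f.coordinates for f in self.frames])


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _pdb_element(name: str, explicit: str) -> str:
    if explicit:
        return explicit.strip().capitalize()
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def read_pdb(path) -> tuple:
    """Read a PDB file into ``(Topology, Frame)``.

    ATOM/HETATM records become atoms in file order (roles unassigned),
    CONECT records become bonds, and CRYST1 — if present and orthorhombic —
    becomes the frame box.  Missing CRYST1 leaves the box unset; downstream
    PBC operations reject box-less frames.

    Raises
    ------
    TrajectoryIOError
        On malformed records (the message names the offending line number)
        or a triclinic CRYST1 cell.
    """
    path = Path(path)
    atoms: list = []
    coords: list = []
    bonds: set = set()
    box = None
    serial_to_index: dict = {}
    residue_keys: list = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    resseq = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise TrajectoryIOError(
                        f"{path}: malformed {rec.strip()} record at line {lineno}: {exc}"
                    ) from exc
                element = _pdb_element(name, line[76:78] if len(line) >= 78 else "")
                key = (resname, resseq)
                if key not in residue_keys:
                    residue_keys.append(key)
                atoms.append(
                    Atom(
                        name=name,
                        element=element,
                        residue_index=residue_keys.index(key),
                        residue_name=resname,
                    )
                )
                serial_to_index[serial] = len(atoms) - 1
                coords.append((x, y, z))
            elif rec == "CRYST1":
                try:
                    a, b, c = (
                        float(line[6:15]),
                        float(line[15:24]),
                        float(line[24:33]),
                    )
                    alpha, beta, gamma = (
                        float(line[33:40]),
                        float(line[40:47]),
                        float(line[47:54]),
                    )
                except ValueError as exc:
                    raise TrajectoryIOError(
                        f"{path}: malformed CRYST1 at line {lineno}: {exc}"
                    ) from exc
                if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
                    raise TrajectoryIOError(
                        f"{path}: triclinic cell at line {lineno}; "
                        "only orthorhombic boxes are supported"
                    )
                box = np.array([a, b, c])
            elif rec == "CONECT":
                fields = line.split()[1:]
                try:
                    serials = [int(f) for f in fields]
                except ValueError as exc:
                    raise TrajectoryIOError(
                        f"{path}: malformed CONECT at line {lineno}: {exc}"
                    ) from exc
                if serials:
                    center = serials[0]
                    for other in serials[1:]:
                        if center in serial_to_index and other in serial_to_index:
                            i, j = serial_to_index[center], serial_to_index[other]
                            if i != j:
                                bonds.add(tuple(sorted((i, j))))
    if not atoms:
        raise TrajectoryIOError(f"{path}: no ATOM/HETATM records found")
    topology = Topology(atoms=atoms, bonds=bonds)
    frame = Frame(coordinates=np.array(coords), box=box)
    return topology, frame


def write_pdb(path, topology: Topology, frame: Frame) -> None:
    """Write topology + frame as PDB (CRYST1 when the frame has a box, CONECT bonds)."""
    path = Path(path)
    lines = []
    if frame.box is not None:
        a, b, c = frame.box
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    for i, (atom, xyz) in enumerate(zip(topology.atoms, frame.coordinates)):
        name = atom.name[:4]
        # PDB convention: 1-2 char element names start in column 14
        namefield = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"ATOM  {i + 1:5d} {namefield:<4s} {atom.residue_name[:3]:<3s}  "
            f"{(atom.residue_index + 1) % 10000:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {atom.element[:2]:>2s}"
        )
    neighbours: dict = {}
    for i, j in sorted(topology.bonds):
        neighbours.setdefault(i, []).append(j)
        neighbours.setdefault(j, []).append(i)
    for i in sorted(neighbours):
        partners = "".join(f"{j + 1:5d}" for j in sorted(neighbours[i]))
        lines.append(f"CONECT{i + 1:5d}{partners}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz_multi(path, box=None) -> list:
    """Read a multi-frame XYZ file into a list of :class:`Frame`.

    All frames share the supplied ``box`` (may be ``None``).  The comment
    line is scanned for a ``time=<ps>`` token.

    Raises
    ------
    TrajectoryIOError
        On an empty file, a malformed count line, or an atom-count mismatch
        between frames.
    """
    path = Path(path)
    if box is not None:
        box = np.asarray(box, dtype=float).reshape(3)
    frames: list = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    n_expected = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise TrajectoryIOError(
                f"{path}: expected atom count at line {pos + 1}"
            ) from exc
        if n_expected is None:
            n_expected = natoms
        elif natoms != n_expected:
            raise TrajectoryIOError(
                f"{path}: frame {len(frames)} has {natoms} atoms, "
                f"previous frames have {n_expected}"
            )
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        time = 0.0
        for token in comment.split():
            if token.startswith("time="):
                try:
                    time = float(token[5:])
                except ValueError:
                    pass
        body = lines[pos + 2 : pos + 2 + natoms]
        if len(body) < natoms:
            raise TrajectoryIOError(
                f"{path}: truncated frame {len(frames)} "
                f"({len(body)}/{natoms} atom rows)"
            )
        coords = np.empty((natoms, 3))
        for k, row in enumerate(body):
            parts = row.split()
            if len(parts) < 4:
                raise TrajectoryIOError(
                    f"{path}: malformed atom row at line {pos + 3 + k}"
                )
            coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(Frame(coordinates=coords, box=box, time=time))
        pos += 2 + natoms
    if not frames:
        raise TrajectoryIOError(f"{path}: empty XYZ file")
    return frames


def write_xyz_multi(path, frames: Sequence, elements: Sequence | None = None) -> None:
    """Write frames as multi-frame XYZ with 8-decimal coordinates."""
    path = Path(path)
    out = []
    for k, fr in enumerate(frames):
        n = fr.n_atoms
        elems = elements if elements is not None else ["X"] * n
        out.append(str(n))
        out.append(f"frame={k} time={fr.time:g}")
        for e, xyz in zip(elems, fr.coordinates):
            out.append(f"{e} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# DCD (optional; delegates to MDAnalysis)
# ---------------------------------------------------------------------------

def _mdanalysis():
    try:
        import MDAnalysis  # noqa: F401
        return MDAnalysis
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise TrajectoryIOError(
            "DCD support requires MDAnalysis (install extra 'dcd'); "
            "XYZ+PDB is the reference path"
        ) from exc


def _dcd_header_size(path) -> int | None:
    """Byte offset of the first frame record, from the three header records.

    Returns ``None`` when the framing looks non-standard (the size check is
    then skipped; MDAnalysis still validates what it reads).
    """
    import struct

    try:
        with open(path, "rb") as fh:
            offset = 0
            for _ in range(3):  # fixed header, titles, natoms
                raw = fh.read(4)
                (reclen,) = struct.unpack("<i", raw)
                if reclen <= 0 or reclen > 10_000:
                    return None
                fh.seek(reclen + 4, 1)
                offset += 8 + reclen
            return offset
    except (OSError, struct.error):
        return None


def read_dcd(path, topology: Topology) -> list:
    """Read a CHARMM/NAMD DCD file into frames, using the topology atom count.

    Optional feature: requires MDAnalysis.  Raises
    :class:`TrajectoryIOError` on an atom-count mismatch or a truncated file
    (the message reports how many frames were read).
    """
    mda = _mdanalysis()
    from MDAnalysis.coordinates.DCD import DCDReader

    frames: list = []
    try:
        reader = DCDReader(str(path))
    except Exception as exc:
        raise TrajectoryIOError(f"{path}: cannot open DCD: {exc}") from exc
    # a trailing partial frame means the file was truncated mid-write
    if reader.n_atoms > 0:
        header_end = _dcd_header_size(path)
        if header_end is not None:
            # per frame: unit-cell record (6 doubles) + 3 coordinate records
            frame_size = (8 + 48) + 3 * (8 + 4 * reader.n_atoms)
            tail = (Path(path).stat().st_size - header_end) % frame_size
            if tail:
                raise TrajectoryIOError(
                    f"{path}: truncated DCD ({tail} trailing bytes after "
                    f"{reader.n_frames} whole frames)"
                )
    with reader:
        if reader.n_atoms != topology.n_atoms:
            raise TrajectoryIOError(
                f"{path}: DCD has {reader.n_atoms} atoms, "
                f"topology has {topology.n_atoms}"
            )
        try:
            for ts in reader:
                dims = ts.dimensions
                box = None
                if dims is not None and np.all(dims[:3] > 0):
                    if not np.allclose(dims[3:], 90.0, atol=1e-3):
                        raise TrajectoryIOError(
                            f"{path}: triclinic DCD cell; only orthorhombic supported"
                        )
                    box = np.array(dims[:3], dtype=float)
                frames.append(
                    Frame(
                        coordinates=np.array(ts.positions, dtype=float),
                        box=box,
                        time=float(ts.time),
                    )
                )
        except TrajectoryIOError:
            raise
        except Exception as exc:
            raise TrajectoryIOError(
                f"{path}: DCD read failed after {len(frames)} frames: {exc}"
            ) from exc
    return frames


def write_dcd(path, frames: Sequence) -> None:
    """Write frames to DCD (optional feature; requires MDAnalysis)."""
    mda = _mdanalysis()

    n = frames[0].n_atoms
    universe = mda.Universe.empty(n, trajectory=True)
    with mda.Writer(str(path), n_atoms=n) as w:
        for fr in frames:
            universe.atoms.positions = fr.coordinates.astype(np.float32)
            if fr.box is not None:
                universe.dimensions = [*fr.box, 90.0, 90.0, 90.0]
            w.write(universe.atoms)


# ---------------------------------------------------------------------------
# Role assignment and selections
# ---------------------------------------------------------------------------

def _normalise_rules(role_map: Iterable) -> list:
    rules = []
    for rule in role_map:
        if isinstance(rule, dict):
            res = rule.get("residue", "*")
            atom = rule.get("atom", "*")
            roles = rule.get("roles", [])
        else:
            res, atom, roles = rule
        roles = frozenset(roles)
        bad = roles - ROLE_TAGS
        if bad:
            raise RoleAssignmentError(f"unknown role tags in rule: {sorted(bad)}")
        rules.append((str(res), str(atom), roles))
    return rules


def assign_roles(topology: Topology, role_map: Iterable) -> Topology:
    """Return a copy of ``topology`` with roles assigned from pattern rules.

    ``role_map`` is an iterable of rules, each either a mapping with keys
    ``residue``, ``atom``, ``roles`` or a tuple ``(residue_pattern,
    atom_pattern, roles)``; patterns are shell-style (:mod:`fnmatch`).  All
    matching rules contribute roles (union).

    Post-conditions enforced here:

    * every oxygen in a non-water residue carries exactly one of
      ``mainchain_oxygen`` / ``sidechain_oxygen``;
    * every residue containing sidechain atoms has exactly one
      ``terminal_carbon``;
    * water residues carry water roles only (checked by ``Topology.validate``).

    ``n_residues_polymer`` is recomputed as the number of residues holding at
    least one polymer-role atom.
    """
    rules = _normalise_rules(role_map)
    new_atoms = []
    for atom in topology.atoms:
        roles: frozenset = frozenset()
        for res_pat, atom_pat, rule_roles in rules:
            if fnmatch.fnmatchcase(atom.residue_name, res_pat) and fnmatch.fnmatchcase(
                atom.name, atom_pat
            ):
                roles |= rule_roles
        new_atoms.append(replace(atom, roles=roles))

    water_residues = {
        a.residue_index for a in new_atoms if a.roles & WATER_ROLES
    }
    unclassified = [
        (i, a)
        for i, a in enumerate(new_atoms)
        if a.element == "O"
        and a.residue_index not in water_residues
        and not a.roles & {"mainchain_oxygen", "sidechain_oxygen"}
    ]
    if unclassified:
        detail = ", ".join(
            f"atom {i} ({a.name}, residue {a.residue_index})"
            for i, a in unclassified[:10]
        )
        raise RoleAssignmentError(
            f"polymer oxygens left unclassified by the role map: {detail}"
        )

    sidechain_residues: dict = {}
    for a in new_atoms:
        if "sidechain" in a.roles:
            sidechain_residues.setdefault(a.residue_index, 0)
        if "terminal_carbon" in a.roles:
            sidechain_residues[a.residue_index] = (
                sidechain_residues.get(a.residue_index, 0) + 1
            )
    bad_residues = [r for r, c in sidechain_residues.items() if c != 1]
    if bad_residues:
        raise RoleAssignmentError(
            "each side chain needs exactly one terminal_carbon; offending "
            f"residues: {sorted(bad_residues)}"
        )

    polymer_residues = {
        a.residue_index for a in new_atoms if a.roles & POLYMER_ROLES
    }
    return Topology(
        atoms=new_atoms,
        bonds=set(topology.bonds),
        n_residues_polymer=len(polymer_residues),
    )


def select(topology: Topology, role: str) -> np.ndarray:
    """Indices of atoms tagged ``role``, in deterministic ascending order.

    An empty result is valid; an unknown role tag raises
    :class:`SelectionError`.
    """
    if role not in ROLE_TAGS:
        raise SelectionError(f"unknown role tag: {role!r}")
    return np.array(
        [i for i, a in enumerate(topology.atoms) if role in a.roles], dtype=int
    )
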