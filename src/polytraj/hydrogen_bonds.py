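"""Geometric hydrogen-bond detection and class-resolved averages.

A donor-H/acceptor triple (D, H, A) counts as a hydrogen bond iff

    dist(D, A) <= d_max   and   angle(D-H...A) >= angle_min

with the angle measured at H and all distances minimum-imaged.  Both
comparisons are inclusive at the boundary.  Default criteria: 3.5 Å / 150°
(a documented choice; geometric cutoffs in the literature vary).

Candidate D-A pairs come from a cell-list neighbour search when the box
accommodates at least 3 cells per edge at the cutoff, otherwise from the
dense distance matrix; both routes return identical bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import minimum_image, pair_distances
from .trajectory_io import Frame, Topology, Trajectory, select

__all__ = [
    "HBondCriteria",
    "HBondStats",
    "find_hbonds",
    "water_donor_pairs",
    "polymer_donor_pairs",
    "hbond_averages",
    "intrapolymer_hbonds",
]


@dataclass(frozen=True)
class HBondCriteria:
    d_max: float = 3.5  # donor-heavy-atom to acceptor distance cutoff (Å)
    angle_min: float = 150.0  # D-H...A angle cutoff (degrees)

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")
        if not (0 < self.angle_min <= 180):
            raise ValueError("angle_min must be in (0, 180]")


def _candidate_pairs(
    donor_xyz: np.ndarray,
    acceptor_xyz: np.ndarray,
    box: np.ndarray | None,
    cutoff: float,
) -> np.ndarray:
    """Indices (i, j) of donor/acceptor pairs with min-image distance <= cutoff."""
    n_d, n_a = len(donor_xyz), len(acceptor_xyz)
    use_cells = box is not None and np.all(np.floor(box / cutoff) >= 3)
    if not use_cells:
        d = pair_distances(donor_xyz, acceptor_xyz, box)
        i, j = np.nonzero(d <= cutoff)
        return np.column_stack([i, j])
    n_cells = np.floor(box / cutoff).astype(int)
    cell_size = box / n_cells

    def cell_of(xyz: np.ndarray) -> np.ndarray:
        wrapped = xyz - box * np.floor(xyz / box)
        return np.minimum((wrapped / cell_size).astype(int), n_cells - 1)

    acc_cells: dict = {}
    for j, c in enumerate(map(tuple, cell_of(acceptor_xyz))):
        acc_cells.setdefault(c, []).append(j)
    offsets = [
        (dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    ]
    pairs: list = []
    donor_cells = cell_of(donor_xyz)
    for i in range(n_d):
        cx, cy, cz = donor_cells[i]
        cand: list = []
        for dx, dy, dz in offsets:
            key = (
                (cx + dx) % n_cells[0],
                (cy + dy) % n_cells[1],
                (cz + dz) % n_cells[2],
            )
            cand.extend(acc_cells.get(key, ()))
        if not cand:
            continue
        cand = np.array(cand)
        disp = minimum_image(acceptor_xyz[cand] - donor_xyz[i], box)
        dist = np.linalg.norm(disp, axis=1)
        for j in cand[dist <= cutoff]:
            pairs.append((i, j))
    return (
        np.array(pairs, dtype=int) if pairs else np.empty((0, 2), dtype=int)
    )


def find_hbonds(
    frame: Frame,
    topology: Topology,
    donor_pairs,
    acceptors,
    criteria: HBondCriteria = HBondCriteria(),
) -> list:
    """All (donor, H, acceptor) triples satisfying the geometric criteria.

    ``donor_pairs`` is a sequence of ``(heavy_atom_index, hydrogen_index)``
    tuples; each H must be covalently bonded to its heavy atom in the
    topology (``ValueError`` otherwise).  ``acceptors`` is a sequence of
    acceptor atom indices.  Triples with ``donor == acceptor`` are excluded.
    The list is sorted by (donor, H, acceptor).
    """
    donor_pairs = [(int(d), int(h)) for d, h in donor_pairs]
    acceptors = np.asarray(acceptors, dtype=int)
    for d, h in donor_pairs:
        if tuple(sorted((d, h))) not in topology.bonds:
            raise ValueError(f"hydrogen {h} is not bonded to its donor {d}")
    if not donor_pairs or acceptors.size == 0:
        return []
    box = frame.box
    coords = frame.coordinates
    donors = np.array(sorted({d for d, _ in donor_pairs}))
    hydrogens_of: dict = {}
    for d, h in donor_pairs:
        hydrogens_of.setdefault(d, []).append(h)
    cand = _candidate_pairs(coords[donors], coords[acceptors], box, criteria.d_max)
    cos_min = np.cos(np.radians(criteria.angle_min))
    bonds: list = []
    for di, aj in cand:
        d = int(donors[di])
        a = int(acceptors[aj])
        if d == a:
            continue
        for h in hydrogens_of[d]:
            hd = minimum_image(coords[d] - coords[h], box)
            ha = minimum_image(coords[a] - coords[h], box)
            denom = np.linalg.norm(hd) * np.linalg.norm(ha)
            if denom == 0:
                continue
            cos_angle = float(np.dot(hd, ha) / denom)
            # angle >= angle_min  <=>  cos(angle) <= cos(angle_min)
            if cos_angle <= cos_min + 1e-12:
                bonds.append((d, h, a))
    return sorted(bonds)


def water_donor_pairs(topology: Topology) -> list:
    """(O, H) donor pairs for every water molecule, from the bond list."""
    pairs = []
    for o in select(topology, "water_oxygen"):
        for j in topology.bonded_to(int(o)):
            if "water_hydrogen" in topology.atoms[j].roles:
                pairs.append((int(o), j))
    return pairs


def polymer_donor_pairs(topology: Topology, include_ch_donors: bool = False) -> list:
    """(heavy, H) donor pairs among polymer atoms.

    Default donors are O-H and N-H; ``include_ch_donors`` adds C-H for
    sensitivity analysis.  Pure-ether polymers have no default donors, so
    their intrapolymer count is exactly zero by construction.
    """
    donor_elements = {"O", "N"} | ({"C"} if include_ch_donors else set())
    water = {
        i for i, a in enumerate(topology.atoms) if a.roles & {"water_oxygen", "water_hydrogen"}
    }
    pairs = []
    for i, atom in enumerate(topology.atoms):
        if i in water or atom.element not in donor_elements:
            continue
        for j in topology.bonded_to(i):
            if j in water:
                continue
            if topology.atoms[j].element == "H":
                pairs.append((i, j))
    return pairs


@dataclass
class HBondStats:
    """Per-frame and averaged polymer-water hydrogen-bond counts by acceptor class."""

    per_frame_mainchain: np.ndarray
    per_frame_sidechain: np.ndarray
    n_mainchain_oxygens: int
    n_sidechain_oxygens: int
    criteria: HBondCriteria = field(default_factory=HBondCriteria)

    @property
    def mean_mainchain(self) -> float:
        return float(self.per_frame_mainchain.mean())

    @property
    def mean_sidechain(self) -> float:
        return float(self.per_frame_sidechain.mean())

    @property
    def per_oxygen_mainchain(self) -> float:
        if self.n_mainchain_oxygens == 0:
            return 0.0
        return self.mean_mainchain / self.n_mainchain_oxygens

    @property
    def per_oxygen_sidechain(self) -> float:
        if self.n_sidechain_oxygens == 0:
            return 0.0
        return self.mean_sidechain / self.n_sidechain_oxygens


def hbond_averages(
    trajectory: Trajectory, criteria: HBondCriteria = HBondCriteria()
) -> HBondStats:
    """Polymer-water hydrogen-bond statistics split by acceptor oxygen class.

    Waters donate (O-H pairs from the bond list); polymer oxygens accept.
    Counts are per frame, averaged over the trajectory and normalised per
    oxygen of each class.
    """
    topo = trajectory.topology
    donors = water_donor_pairs(topo)
    main_o = select(topo, "mainchain_oxygen")
    side_o = select(topo, "sidechain_oxygen")
    if main_o.size == 0 and side_o.size == 0:
        raise ValueError("no polymer oxygens tagged as acceptors")
    main_set, side_set = set(main_o.tolist()), set(side_o.tolist())
    acceptors = np.concatenate([main_o, side_o])
    per_main = np.zeros(trajectory.n_frames)
    per_side = np.zeros(trajectory.n_frames)
    for k, fr in enumerate(trajectory.frames):
        for _, _, a in find_hbonds(fr, topo, donors, acceptors, criteria):
            if a in main_set:
                per_main[k] += 1
            elif a in side_set:
                per_side[k] += 1
    return HBondStats(
        per_frame_mainchain=per_main,
        per_frame_sidechain=per_side,
        n_mainchain_oxygens=int(main_o.size),
        n_sidechain_oxygens=int(side_o.size),
        criteria=criteria,
    )


def intrapolymer_hbonds(
    trajectory: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    include_ch_donors: bool = False,
) -> float:
    """Mean per-frame hydrogen-bond count within the polymer.

    Donors are polymer O-H/N-H pairs (optionally C-H); acceptors are the
    tagged polymer oxygens.  Directly bonded donor-acceptor pairs are
    excluded.  Ether-only polymers have no donors and return exactly 0.0.
    """
    topo = trajectory.topology
    donors = polymer_donor_pairs(topo, include_ch_donors=include_ch_donors)
    acceptors = np.concatenate(
        [select(topo, "mainchain_oxygen"), select(topo, "sidechain_oxygen")]
    )
    if not donors or acceptors.size == 0:
        return 0.0
    total = 0
    for fr in trajectory.frames:
        for d, _, a in find_hbonds(fr, topo, donors, acceptors, criteria):
            if tuple(sorted((d, a))) in topo.bonds:
                continue
            total += 1
    return total / trajectory.n_frames
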