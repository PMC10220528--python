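"""Synthetic-input generators with known ground truth.

Every analysis stage in the package is exercised against data whose target
statistics are planted by construction: freely jointed chains with exact
ideal-chain moments, uniform point clouds (the g(r) = 1 limit), solvent
clouds with a prescribed Gaussian first-shell profile, hydrogen-bond
fixtures with auditable margins, and a small bead-spring Langevin simulator
that produces temperature series end-to-end.  All generators are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from ._geometry import pair_distances, wrap
from .hydrogen_bonds import HBondCriteria
from .solvation_rdf import PeakCurve
from .trajectory_io import (
    Atom,
    Frame,
    Topology,
    Trajectory,
    write_pdb,
    write_xyz_multi,
)

__all__ = [
    "FjcSpec",
    "ShellSpec",
    "ToySimSpec",
    "gen_fjc",
    "gen_ideal_gas",
    "gen_shell_cloud",
    "gen_hbond_fixture",
    "run_toy_langevin",
    "gen_peak_curve",
    "write_fixture",
]


# ---------------------------------------------------------------------------
# Freely jointed chains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FjcSpec:
    """Freely jointed chain ensemble: ``n_bonds`` steps of length ``bond_length``."""

    n_bonds: int
    bond_length: float
    n_samples: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bonds < 1:
            raise ValueError("n_bonds must be >= 1")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def gen_fjc(spec: FjcSpec) -> Trajectory:
    """Ensemble of freely jointed chain configurations as a Trajectory.

    Each frame is one independent random walk of ``n_bonds`` uniformly
    oriented fixed-length steps over ``n_bonds + 1`` beads (no box).  The
    topology carries consecutive backbone bonds and sets
    ``n_residues_polymer = n_bonds`` so the ideal-chain reference
    ``1/sqrt(N)`` refers to the number of statistical segments.
    """
    rng = np.random.default_rng(spec.seed)
    steps = rng.normal(size=(spec.n_samples, spec.n_bonds, 3))
    steps /= np.linalg.norm(steps, axis=-1, keepdims=True)
    steps *= spec.bond_length
    positions = np.concatenate(
        [np.zeros((spec.n_samples, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    n_beads = spec.n_bonds + 1
    atoms = [
        Atom(name="C", element="C", residue_index=i, residue_name="FJC",
             roles=frozenset({"backbone"}))
        for i in range(n_beads)
    ]
    bonds = {(i, i + 1) for i in range(n_beads - 1)}
    topology = Topology(atoms=atoms, bonds=bonds, n_residues_polymer=spec.n_bonds)
    frames = [
        Frame(coordinates=positions[k], box=None, time=float(k))
        for k in range(spec.n_samples)
    ]
    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# Uniform (ideal-gas) clouds
# ---------------------------------------------------------------------------

def gen_ideal_gas(n_points: int, box, seed: int = 0) -> Frame:
    """``n_points`` i.i.d. uniform points in an orthorhombic box."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    box = np.asarray(box, dtype=float).reshape(3) if np.ndim(box) else np.full(3, float(box))
    if box.size != 3:
        box = np.full(3, float(box))
    rng = np.random.default_rng(seed)
    return Frame(coordinates=rng.uniform(0.0, box, size=(n_points, 3)), box=box)


# ---------------------------------------------------------------------------
# Shell clouds with a planted radial profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShellSpec:
    """Planted first-shell profile around fixed reference atoms.

    The expected radial density around each reference is ``rho * g*(r)``
    with ``g*(r) = 1 + (A - 1) exp(-(r - r0)^2 / (2 sigma^2))`` and
    far-field density ``rho``.
    """

    r0: float  # shell radius (Å)
    sigma: float  # shell width (Å)
    amplitude: float  # A: target g at r0
    bulk_density: float  # rho (Å^-3)
    box: float  # cubic box edge (Å)
    n_ref: int
    n_frames: int
    seed: int = 0
    temperature: float | None = None

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.sigma <= 0:
            raise ValueError("r0 and sigma must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.bulk_density <= 0:
            raise ValueError("bulk_density must be > 0")
        if self.n_ref < 1 or self.n_frames < 1:
            raise ValueError("n_ref and n_frames must be >= 1")
        if self.r0 + 4 * self.sigma >= self.box / 2:
            raise ValueError("need r0 + 4*sigma < box/2")


def _reference_lattice(spec: ShellSpec) -> np.ndarray:
    """Deterministic reference positions with non-overlapping shells."""
    spacing = 2.0 * (spec.r0 + 4.0 * spec.sigma)
    per_axis = int(spec.box // spacing)
    if per_axis**3 < spec.n_ref:
        raise ValueError(
            f"cannot place {spec.n_ref} references with inter-reference "
            f"distance >= {spacing:g} in a box of {spec.box:g}"
        )
    pts = []
    for ix in range(per_axis):
        for iy in range(per_axis):
            for iz in range(per_axis):
                pts.append(
                    (
                        (ix + 0.5) * spec.box / per_axis,
                        (iy + 0.5) * spec.box / per_axis,
                        (iz + 0.5) * spec.box / per_axis,
                    )
                )
                if len(pts) == spec.n_ref:
                    positions = np.array(pts)
                    box = np.full(3, spec.box)
                    if spec.n_ref > 1:
                        d = pair_distances(positions, positions, box)
                        np.fill_diagonal(d, np.inf)
                        if d.min() < spacing:
                            raise ValueError(
                                "reference shells overlap: minimum inter-"
                                f"reference distance {d.min():g} < {spacing:g}"
                            )
                    return positions
    raise AssertionError("unreachable")


def gen_shell_cloud(spec: ShellSpec) -> Trajectory:
    """Trajectory of 'water oxygen' clouds with a planted g(r) shell.

    Reference atoms sit on a fixed lattice (shells pairwise non-overlapping,
    enforced); per frame, point positions are drawn by accept-reject against
    the planted profile ``g*`` evaluated at the distance to the nearest
    reference.  The per-frame point count is fixed at
    ``round(rho * (V + n_ref (A-1) S))`` with ``S`` the integrated shell
    excess, so the far-field density equals ``rho``.
    """
    rng = np.random.default_rng(spec.seed)
    refs = _reference_lattice(spec)
    box = np.full(3, spec.box)
    volume = spec.box**3
    a, r0, sig = spec.amplitude, spec.r0, spec.sigma
    shell_excess = 4.0 * math.pi * math.sqrt(2.0 * math.pi) * sig * (r0**2 + sig**2)
    v_eff = volume + spec.n_ref * (a - 1.0) * shell_excess
    n_points = max(1, int(round(spec.bulk_density * v_eff)))
    g_max = max(1.0, a)

    frames = []
    for k in range(spec.n_frames):
        accepted = []
        n_acc = 0
        while n_acc < n_points:
            batch = max(1024, int(1.2 * (n_points - n_acc) * g_max))
            cand = rng.uniform(0.0, spec.box, size=(batch, 3))
            r_near = pair_distances(cand, refs, box).min(axis=1)
            g_star = 1.0 + (a - 1.0) * np.exp(-((r_near - r0) ** 2) / (2.0 * sig**2))
            keep = rng.random(batch) < g_star / g_max
            accepted.append(cand[keep])
            n_acc += int(keep.sum())
        pts = np.concatenate(accepted)[:n_points]
        frames.append(
            Frame(coordinates=np.vstack([refs, pts]), box=box, time=float(k))
        )

    atoms = [
        Atom(name="C", element="C", residue_index=i, residue_name="REF",
             roles=frozenset({"sidechain", "terminal_carbon"}))
        for i in range(spec.n_ref)
    ]
    atoms += [
        Atom(name="O", element="O", residue_index=spec.n_ref + j,
             residue_name="HOH", roles=frozenset({"water_oxygen"}))
        for j in range(n_points)
    ]
    topology = Topology(atoms=atoms, bonds=set(), n_residues_polymer=spec.n_ref)
    return Trajectory(topology=topology, frames=frames, temperature=spec.temperature)


# ---------------------------------------------------------------------------
# Hydrogen-bond fixtures with explicit margins
# ---------------------------------------------------------------------------

def _place_water(
    acceptor: np.ndarray,
    d_oa: float,
    angle_deg: float,
    rng: np.random.Generator,
    r_oh: float = 0.96,
) -> tuple:
    """Water (O, H1, H2) positions with exact D...A distance and D-H...A angle.

    The donor oxygen D sits at ``d_oa`` from the acceptor along a random
    direction; H1 is placed in a random plane through the D-A axis so that
    the angle at H1 is exactly ``angle_deg``.  H2 points away from the
    acceptor and can never satisfy the angle criterion.
    """
    theta = math.radians(angle_deg)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    v = rng.normal(size=3)
    v -= u * np.dot(u, v)
    v /= np.linalg.norm(v)
    d_pos = acceptor + d_oa * u
    sin_alpha = r_oh * math.sin(theta) / d_oa
    if sin_alpha > 1.0:
        raise ValueError("infeasible hydrogen-bond geometry")
    alpha = math.asin(sin_alpha)
    beta = math.pi - theta - alpha  # angle at the donor
    # H1 at r_oh from D, tilted by beta off the D->A axis
    h1 = d_pos + r_oh * (math.cos(beta) * (-u) + math.sin(beta) * v)
    h2 = d_pos + r_oh * u
    return d_pos, h1, h2


def gen_hbond_fixture(
    n_bonded: int,
    n_near_miss_distance: int,
    n_near_miss_angle: int,
    criteria: HBondCriteria = HBondCriteria(),
    seed: int = 0,
    distance_margin: float = 0.2,
    miss_distance_margin: float = 0.3,
    angle_margin: float = 10.0,
    miss_angle_margin: float = 10.0,
) -> tuple:
    """(Topology, Frame) with planted hydrogen-bond geometry.

    ``n_bonded`` acceptor/water units satisfy both criteria with margin
    (``d = d_max - distance_margin``, ``angle = angle_min + angle_margin``);
    the near-miss units violate exactly one criterion
    (``d = d_max + miss_distance_margin`` or
    ``angle = angle_min - miss_angle_margin``).  Margins are parameters so
    boundary conventions can be audited at ±1e-6.  Units are spaced far
    apart; exactly ``n_bonded`` bonds are detectable.
    """
    units = (
        [("bonded", criteria.d_max - distance_margin, criteria.angle_min + angle_margin)]
        * n_bonded
        + [
            (
                "miss_d",
                criteria.d_max + miss_distance_margin,
                criteria.angle_min + angle_margin,
            )
        ]
        * n_near_miss_distance
        + [
            (
                "miss_a",
                criteria.d_max - distance_margin,
                criteria.angle_min - miss_angle_margin,
            )
        ]
        * n_near_miss_angle
    )
    if not units:
        raise ValueError("fixture needs at least one unit")
    for _, d, ang in units:
        if d <= 0.96 or not (0 < ang < 180):
            raise ValueError(f"infeasible planted geometry d={d:g}, angle={ang:g}")
    rng = np.random.default_rng(seed)
    spacing = 3.0 * (criteria.d_max + miss_distance_margin + 2.0)
    per_axis = max(1, math.ceil(len(units) ** (1.0 / 3.0)))
    box = np.full(3, per_axis * spacing)

    atoms: list = []
    coords: list = []
    bonds: set = set()
    residue = 0
    slot = 0
    for kind, d_oa, angle in units:
        ix, rem = divmod(slot, per_axis * per_axis)
        iy, iz = divmod(rem, per_axis)
        slot += 1
        acceptor = (np.array([ix, iy, iz]) + 0.5) * spacing
        d_pos, h1, h2 = _place_water(acceptor, d_oa, angle, rng)
        atoms.append(
            Atom(name="OM", element="O", residue_index=residue, residue_name="PGE",
                 roles=frozenset({"mainchain_oxygen"}))
        )
        coords.append(acceptor)
        residue += 1
        o_idx = len(atoms)
        atoms.append(
            Atom(name="OW", element="O", residue_index=residue, residue_name="HOH",
                 roles=frozenset({"water_oxygen"}))
        )
        atoms.append(
            Atom(name="H1", element="H", residue_index=residue, residue_name="HOH",
                 roles=frozenset({"water_hydrogen"}))
        )
        atoms.append(
            Atom(name="H2", element="H", residue_index=residue, residue_name="HOH",
                 roles=frozenset({"water_hydrogen"}))
        )
        coords.extend([d_pos, h1, h2])
        bonds.add((o_idx, o_idx + 1))
        bonds.add((o_idx, o_idx + 2))
        residue += 1
    topology = Topology(
        atoms=atoms, bonds=bonds, n_residues_polymer=len(units)
    )
    frame = Frame(coordinates=np.array(coords), box=box)
    return topology, frame


# ---------------------------------------------------------------------------
# Bead-spring Langevin toy simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToySimSpec:
    """Overdamped NVT bead-spring model in reduced units (kB = 1, m = 1).

    A linear backbone of ``n_monomers`` beads, one pendant terminal bead per
    monomer, and ``solvent_count`` solvent beads in a cubic periodic box.
    All beads repel via WCA; solvent and terminal beads additionally attract
    through a Lennard-Jones tail of depth ``terminal_epsilon``.
    """

    n_monomers: int
    bond_k: float  # harmonic bond stiffness (energy / Å^2)
    bead_sigma: float  # bead diameter (Å)
    solvent_count: int
    box: float  # cubic box edge (Å)
    temperature: float  # K (reduced)
    friction: float  # ps^-1
    dt: float  # ps
    n_steps: int
    terminal_epsilon: float  # solvent-terminal attraction depth (energy)
    seed: int = 0
    sample_every: int | None = None
    equil_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_monomers < 1 or self.solvent_count < 0:
            raise ValueError("need n_monomers >= 1 and solvent_count >= 0")
        if self.dt <= 0 or self.friction <= 0:
            raise ValueError("dt and friction must be > 0")
        if self.dt * self.friction >= 1.0:
            raise ValueError("unstable step: require dt * friction < 1")
        if self.box <= 0 or self.n_steps < 1:
            raise ValueError("box must be > 0 and n_steps >= 1")
        if self.terminal_epsilon < 0:
            raise ValueError("terminal_epsilon must be >= 0")
        n_beads = 2 * self.n_monomers + self.solvent_count
        packing = n_beads * (math.pi / 6.0) * self.bead_sigma**3 / self.box**3
        if packing > 0.45:
            raise ValueError(f"bead packing fraction {packing:.2f} exceeds 0.45")


def _toy_topology(spec: ToySimSpec) -> Topology:
    atoms: list = []
    for i in range(spec.n_monomers):
        atoms.append(
            Atom(name="B", element="C", residue_index=i, residue_name="MON",
                 roles=frozenset({"backbone"}))
        )
    for i in range(spec.n_monomers):
        atoms.append(
            Atom(name="T", element="C", residue_index=i, residue_name="MON",
                 roles=frozenset({"sidechain", "terminal_carbon"}))
        )
    for j in range(spec.solvent_count):
        atoms.append(
            Atom(name="O", element="O", residue_index=spec.n_monomers + j,
                 residue_name="SOL", roles=frozenset({"water_oxygen"}))
        )
    n = spec.n_monomers
    bonds = {(i, i + 1) for i in range(n - 1)} | {(i, n + i) for i in range(n)}
    return Topology(atoms=atoms, bonds=bonds, n_residues_polymer=n)


def run_toy_langevin(spec: ToySimSpec) -> Trajectory:
    """Integrate the toy model and return sampled frames.

    Euler-Maruyama overdamped update
    ``x <- x + F dt / friction + sqrt(2 T dt / friction) eta`` with
    minimum-image periodic boundaries.  The first ``equil_fraction`` of the
    steps is discarded; thereafter every ``sample_every``-th step is stored
    (wrapped coordinates).  A non-finite coordinate aborts with the step
    index.  Identical specs (including seed) reproduce identical
    trajectories.
    """
    rng = np.random.default_rng(spec.seed)
    topo = _toy_topology(spec)
    n_mono = spec.n_monomers
    n_poly = 2 * n_mono
    n = n_poly + spec.solvent_count
    sig = spec.bead_sigma
    box = np.full(3, spec.box)

    # initial configuration: extended chain + non-overlapping solvent
    x = np.zeros((n, 3))
    for i in range(n_mono):
        x[i] = [(i + 0.5) * sig * 1.05, spec.box / 2.0, spec.box / 2.0]
        x[n_mono + i] = x[i] + [0.0, sig * 1.05, 0.0]
    placed = 0
    while placed < spec.solvent_count:
        cand = rng.uniform(0.0, spec.box, size=3)
        d = pair_distances(cand[None, :], x[: n_poly + placed], box)
        if d.min() > 0.85 * sig:
            x[n_poly + placed] = cand
            placed += 1

    bond_pairs = np.array(sorted(topo.bonds))
    bi, bj = bond_pairs[:, 0], bond_pairs[:, 1]

    rc_wca = 2.0 ** (1.0 / 6.0) * sig
    rc_att = 2.5 * sig
    eps = np.ones((n, n))
    cutoff = np.full((n, n), rc_wca)
    if spec.terminal_epsilon > 0 and spec.solvent_count > 0:
        term = slice(n_mono, n_poly)
        solv = slice(n_poly, n)
        eps[term, solv] = spec.terminal_epsilon
        eps[solv, term] = spec.terminal_epsilon
        cutoff[term, solv] = rc_att
        cutoff[solv, term] = rc_att

    mobility = spec.dt / spec.friction
    noise_scale = math.sqrt(2.0 * spec.temperature * spec.dt / spec.friction)
    equil = int(spec.equil_fraction * spec.n_steps)
    sample_every = spec.sample_every or max(1, (spec.n_steps - equil) // 100)

    frames: list = []
    for step in range(1, spec.n_steps + 1):
        disp = x[:, None, :] - x[None, :, :]
        disp -= box * np.round(disp / box)
        r2 = np.einsum("ijk,ijk->ij", disp, disp)
        np.fill_diagonal(r2, np.inf)
        within = r2 < cutoff**2
        inv_r2 = np.where(within, 1.0 / np.maximum(r2, 1e-12), 0.0)
        s6 = (sig**2 * inv_r2) ** 3
        fmag = 24.0 * eps * (2.0 * s6 * s6 - s6) * inv_r2  # F/r along disp
        forces = np.einsum("ij,ijk->ik", fmag, disp)

        db = disp[bi, bj]
        rb = np.sqrt(np.einsum("ij,ij->i", db, db))
        fb = -2.0 * spec.bond_k * (rb - sig) / np.maximum(rb, 1e-12)
        bond_force = fb[:, None] * db
        np.add.at(forces, bi, bond_force)
        np.add.at(forces, bj, -bond_force)

        x = x + forces * mobility + noise_scale * rng.normal(size=(n, 3))
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"toy simulation diverged at step {step} (non-finite coordinate)"
            )
        if step > equil and (step - equil) % sample_every == 0:
            frames.append(
                Frame(coordinates=wrap(x, box), box=box.copy(), time=step * spec.dt)
            )
    if not frames:
        frames.append(
            Frame(coordinates=wrap(x, box), box=box.copy(), time=spec.n_steps * spec.dt)
        )
    return Trajectory(topology=topo, frames=frames, temperature=spec.temperature)


# ---------------------------------------------------------------------------
# Direct peak curves and fixture export
# ---------------------------------------------------------------------------

def gen_peak_curve(temperatures, intensity) -> PeakCurve:
    """Tabulate a (T, intensity) curve for direct crossing-statistic tests.

    ``intensity`` is either a callable evaluated at each temperature or a
    sequence of the same length.
    """
    temps = np.asarray(list(temperatures), dtype=float)
    if callable(intensity):
        values = np.array([float(intensity(t)) for t in temps])
    else:
        values = np.asarray(list(intensity), dtype=float)
    order = np.argsort(temps)
    return PeakCurve(
        temperatures=temps[order],
        first_peak_r=np.full(len(temps), np.nan),
        first_peak_intensity=values[order],
    )


def write_fixture(
    directory,
    trajectory: Trajectory,
    prefix: str = "fixture",
    include_dcd: bool = False,
) -> dict:
    """Write a trajectory through the standard I/O path.

    Emits ``<prefix>.pdb`` (topology + first frame), ``<prefix>.xyz``
    (all frames), and ``<prefix>_roles.yaml`` (role rules derived from the
    topology, plus box / temperature / polymer size metadata) so synthetic
    data flows through exactly the same readers as real data.  Optionally
    also writes a DCD twin (requires MDAnalysis).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    topo = trajectory.topology
    paths = {
        "pdb": directory / f"{prefix}.pdb",
        "xyz": directory / f"{prefix}.xyz",
        "roles": directory / f"{prefix}_roles.yaml",
    }
    write_pdb(paths["pdb"], topo, trajectory.frames[0])
    write_xyz_multi(
        paths["xyz"], trajectory.frames, elements=[a.element for a in topo.atoms]
    )
    rules = sorted(
        {
            (a.residue_name, a.name, tuple(sorted(a.roles)))
            for a in topo.atoms
            if a.roles
        }
    )
    meta = {
        "box": None
        if trajectory.frames[0].box is None
        else [float(v) for v in trajectory.frames[0].box],
        "temperature": trajectory.temperature,
        "n_residues_polymer": topo.n_residues_polymer,
        "roles": [
            {"residue": res, "atom": name, "roles": list(roles)}
            for res, name, roles in rules
        ],
    }
    paths["roles"].write_text(yaml.safe_dump(meta, sort_keys=False))
    if include_dcd:
        from .trajectory_io import write_dcd

        paths["dcd"] = directory / f"{prefix}.dcd"
        write_dcd(paths["dcd"], trajectory.frames)
    return paths
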