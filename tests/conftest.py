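"""Shared fixtures and programmatic fixture builders."""

from __future__ import annotations

import numpy as np
import pytest

from polytraj.trajectory_io import Atom, Frame, Topology, Trajectory


def make_mege_like_topology(n_residues: int = 4) -> Topology:
    """Minimal polymer topology: per residue one backbone C, one backbone O,
    one side-chain O and one terminal side-chain C, chained along the backbone."""
    atoms, bonds = [], set()
    for r in range(n_residues):
        base = 4 * r
        atoms += [
            Atom("C1", "C", r, "MGE"),
            Atom("OM", "O", r, "MGE"),
            Atom("CS", "C", r, "MGE"),
            Atom("OS", "O", r, "MGE"),
        ]
        bonds |= {(base, base + 1), (base, base + 2), (base + 2, base + 3)}
        if r > 0:
            bonds.add((base - 3, base))  # previous OM to this C1
    return Topology(atoms=atoms, bonds=bonds)


MEGE_ROLE_MAP = [
    {"residue": "MGE", "atom": "C1", "roles": ["backbone"]},
    {"residue": "MGE", "atom": "OM", "roles": ["backbone", "mainchain_oxygen"]},
    {"residue": "MGE", "atom": "CS", "roles": ["sidechain", "terminal_carbon"]},
    {"residue": "MGE", "atom": "OS", "roles": ["sidechain", "sidechain_oxygen"]},
    {"residue": "HOH", "atom": "O*", "roles": ["water_oxygen"]},
    {"residue": "HOH", "atom": "H*", "roles": ["water_hydrogen"]},
]


def make_water_dimer(d_oa: float = 2.8, linear: bool = True):
    """Donor water + acceptor oxygen at ideal hydrogen-bond geometry."""
    coords = np.array(
        [
            [0.0, 0.0, 0.0],  # donor O
            [0.96, 0.0, 0.0],  # H on the D->A axis (angle 180)
            [-0.24, 0.93, 0.0],  # second H, off axis
            [d_oa, 0.0, 0.0],  # acceptor O
        ]
    )
    atoms = [
        Atom("OW", "O", 0, "HOH", frozenset({"water_oxygen"})),
        Atom("H1", "H", 0, "HOH", frozenset({"water_hydrogen"})),
        Atom("H2", "H", 0, "HOH", frozenset({"water_hydrogen"})),
        Atom("OM", "O", 1, "PGE", frozenset({"mainchain_oxygen"})),
    ]
    topo = Topology(atoms=atoms, bonds={(0, 1), (0, 2)}, n_residues_polymer=1)
    return topo, Frame(coordinates=coords)


def build_multistage_trajectory(
    amplitude: float, temperature: float, seed: int, n_frames: int = 25
) -> Trajectory:
    """Polymer + planted-shell solvent trajectory exercising every pipeline stage.

    Takes a shell cloud (terminal-carbon references with a planted g(r)
    profile of height ``amplitude``) and dresses each reference with a
    backbone bead and main/side-chain oxygens so that chain, side-chain and
    hydrogen-bond stages all have the atoms they need.
    """
    from polytraj.synthetic_data import ShellSpec, gen_shell_cloud

    cloud = gen_shell_cloud(
        ShellSpec(
            r0=3.6,
            sigma=0.3,
            amplitude=amplitude,
            bulk_density=0.05,
            box=20.0,
            n_ref=4,
            n_frames=n_frames,
            seed=seed,
            temperature=temperature,
        )
    )
    n_ref = 4
    ref_xyz = cloud.frames[0].coordinates[:n_ref]
    water_atoms = cloud.topology.atoms[n_ref:]

    atoms, bonds = [], set()
    poly_xyz = []
    for r in range(n_ref):
        base = 4 * r
        atoms += [
            Atom("C1", "C", r, "MON", frozenset({"backbone"})),
            Atom("OM", "O", r, "MON", frozenset({"backbone", "mainchain_oxygen"})),
            Atom("OS", "O", r, "MON", frozenset({"sidechain", "sidechain_oxygen"})),
            Atom("CT", "C", r, "MON", frozenset({"sidechain", "terminal_carbon"})),
        ]
        anchor = ref_xyz[r] + [0.0, 0.0, 1.4]
        poly_xyz += [
            anchor,
            anchor + [0.9, 0.0, 0.0],
            anchor + [0.0, 0.9, 0.7],
            ref_xyz[r],
        ]
        bonds |= {(base, base + 1), (base, base + 2), (base + 2, base + 3)}
        if r > 0:
            bonds.add((base - 3, base))  # previous OM into this C1: O sits in-chain
    n_poly = len(atoms)
    atoms += [
        Atom(a.name, a.element, n_ref + j, a.residue_name, a.roles)
        for j, a in enumerate(water_atoms)
    ]
    frames = [
        Frame(
            coordinates=np.vstack([poly_xyz, fr.coordinates[n_ref:]]),
            box=fr.box,
            time=fr.time,
        )
        for fr in cloud.frames
    ]
    topo = Topology(atoms=atoms, bonds=bonds, n_residues_polymer=n_ref)
    assert topo.n_atoms == n_poly + len(water_atoms)
    return Trajectory(topology=topo, frames=frames, temperature=temperature)


@pytest.fixture
def mege_topology():
    return make_mege_like_topology()
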