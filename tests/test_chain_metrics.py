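import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polytraj.chain_metrics import (
    RgSeries,
    ZIGZAG_FACTOR,
    chain_extension_stats,
    cv,
    end_to_end_length,
    ideal_chain_reference,
    lmax,
    radius_of_gyration,
    rg_distribution,
    rg_series,
    round_half_up,
    sample_sd,
    side_chain_lengths,
    side_chain_temperature_stats,
    temperature_average,
)
from polytraj.synthetic_data import FjcSpec, gen_fjc
from polytraj.trajectory_io import Atom, Frame, Topology, Trajectory, select


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class TestScalarStats:
    def test_constant_values(self):
        assert sample_sd([1.0, 1.0, 1.0]) == 0.0
        assert cv([1.0, 1.0, 1.0]) == 0.0

    def test_printed_extension_ratios_sd(self):
        # five per-temperature extension ratios -> tabulated SD 0.027
        assert round_half_up(sample_sd([0.14, 0.17, 0.21, 0.16, 0.15]), 3) == 0.027

    def test_zero_mean_cv_is_error(self):
        with pytest.raises(ValueError, match="zero mean"):
            cv([-1.0, 1.0])

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            sample_sd([1.0])

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=50,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_two_pass_oracle(self, values):
        mean = sum(values) / len(values)
        two_pass = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
        assert sample_sd(values) == pytest.approx(two_pass, abs=1e-12, rel=1e-12)

    def test_round_half_up(self):
        assert round_half_up(0.165, 2) == 0.17
        assert round_half_up(0.0265, 3) == 0.027
        assert round_half_up(-0.125, 2) == -0.13


class TestIdealChainReference:
    @pytest.mark.parametrize(
        "n,expected",
        [(28, 0.19), (24, 0.20), (19, 0.23), (17, 0.24), (14, 0.27),
         (15, 0.26), (9, 0.33), (37, 0.16)],
    )
    def test_reproduces_printed_reference_column(self, n, expected):
        assert round_half_up(ideal_chain_reference(n), 2) == expected

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            ideal_chain_reference(0)


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        fr = Frame(coordinates=np.array([[1.0, 2.0, 3.0]]))
        assert radius_of_gyration(fr, [0]) == 0.0

    def test_two_atoms_half_distance(self):
        fr = Frame(coordinates=np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]]))
        assert radius_of_gyration(fr, [0, 1]) == pytest.approx(1.5)

    def test_empty_selection_is_error(self):
        fr = Frame(coordinates=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="empty"):
            radius_of_gyration(fr, [])

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(-5, 5, (20, 3))
        fr = Frame(coordinates=coords)
        ref = radius_of_gyration(fr, np.arange(20))
        for _ in range(5):
            moved = coords @ random_rotation(rng).T + rng.uniform(-50, 50, 3)
            assert radius_of_gyration(
                Frame(coordinates=moved), np.arange(20)
            ) == pytest.approx(ref, abs=1e-9)

    def test_mass_weighted_option(self):
        fr = Frame(coordinates=np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]))
        unweighted = radius_of_gyration(fr, [0, 1])
        weighted = radius_of_gyration(fr, [0, 1], masses=np.array([3.0, 1.0]))
        assert unweighted == pytest.approx(1.0)
        assert weighted == pytest.approx(math.sqrt(0.75), abs=1e-12)


class TestRgDistribution:
    def test_constant_series(self):
        series = RgSeries(times=np.arange(10.0), values=np.full(10, 4.2))
        dist = rg_distribution(series, bin_width=0.1)
        assert dist.sd == pytest.approx(0.0, abs=1e-12)
        assert dist.principal_peak == pytest.approx(4.2, abs=0.1)
        assert not dist.multimodal

    def test_planted_bimodality(self):
        rng = np.random.default_rng(5)
        values = np.concatenate(
            [rng.normal(6.0, 0.2, 8000), rng.normal(9.0, 0.2, 8000)]
        )
        dist = rg_distribution(RgSeries(times=np.arange(len(values), dtype=float),
                                        values=values))
        assert dist.multimodal
        assert len(dist.peaks) >= 2
        locations = sorted(r for r, _ in dist.peaks[:2])
        assert locations[0] == pytest.approx(6.0, abs=0.2)
        assert locations[1] == pytest.approx(9.0, abs=0.2)

    def test_planted_gaussian_parameters(self):
        rng = np.random.default_rng(6)
        values = rng.normal(9.0, 0.5, 20000)
        dist = rg_distribution(RgSeries(times=np.arange(20000.0), values=values),
                               bin_width=0.1)
        assert dist.principal_peak == pytest.approx(9.0, abs=0.1)
        assert dist.sd == pytest.approx(0.5, rel=0.1)

    def test_density_normalised(self):
        rng = np.random.default_rng(7)
        values = rng.normal(8.0, 0.7, 5000)
        dist = rg_distribution(RgSeries(times=np.arange(5000.0), values=values))
        widths = np.diff(dist.bin_edges)
        assert np.sum(dist.density * widths) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            rg_distribution(RgSeries(times=np.arange(2.0), values=np.array([1.0, 2.0])))


class TestEndToEnd:
    def test_straight_rod(self):
        coords = np.array([[float(i), 0.0, 0.0] for i in range(6)])
        assert end_to_end_length(Frame(coordinates=coords), np.arange(6)) == 5.0

    def test_closed_loop_is_zero(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        assert end_to_end_length(Frame(coordinates=coords), np.arange(3)) == 0.0

    def test_fjc_sample_matches_summed_steps(self):
        traj = gen_fjc(FjcSpec(n_bonds=30, bond_length=1.3, n_samples=1, seed=8))
        frame = traj.frames[0]
        steps = np.diff(frame.coordinates, axis=0)
        oracle = np.linalg.norm(steps.sum(axis=0))
        sel = select(traj.topology, "backbone")
        assert end_to_end_length(frame, sel) == pytest.approx(oracle, abs=1e-12)


class TestLmax:
    def test_fjc_sum_of_bonds(self):
        traj = gen_fjc(FjcSpec(n_bonds=100, bond_length=1.0, n_samples=1, seed=0))
        value = lmax(traj.topology, traj.frames[0], mode="sum_of_bonds")
        assert value == pytest.approx(100.0, abs=1e-9)

    def test_fjc_zigzag(self):
        traj = gen_fjc(FjcSpec(n_bonds=100, bond_length=1.0, n_samples=1, seed=0))
        value = lmax(traj.topology, traj.frames[0], mode="zigzag")
        assert round_half_up(value, 2) == 81.65
        assert value == pytest.approx(100.0 * ZIGZAG_FACTOR)

    def test_missing_bond_names_gap(self):
        traj = gen_fjc(FjcSpec(n_bonds=10, bond_length=1.0, n_samples=1, seed=0))
        topo = traj.topology
        broken = Topology(
            atoms=list(topo.atoms),
            bonds=topo.bonds - {(5, 6)},
            n_residues_polymer=topo.n_residues_polymer,
        )
        with pytest.raises(ValueError, match="disconnected"):
            lmax(broken, traj.frames[0])

    def test_unknown_mode(self):
        traj = gen_fjc(FjcSpec(n_bonds=2, bond_length=1.0, n_samples=1, seed=0))
        with pytest.raises(ValueError, match="mode"):
            lmax(traj.topology, traj.frames[0], mode="bogus")


class TestChainExtensionStats:
    def test_fjc_ensemble_rms_ratio(self):
        traj = gen_fjc(FjcSpec(n_bonds=100, bond_length=1.0, n_samples=20000, seed=3))
        stats = chain_extension_stats(traj)
        assert stats.rms_ratio == pytest.approx(0.100, abs=0.002)
        assert stats.ideal_ref == pytest.approx(0.1)
        assert stats.l_max == pytest.approx(100.0)

    def test_state_call(self):
        coords = np.array([[float(i) * 2.0, 0.0, 0.0] for i in range(5)])
        atoms = [Atom("C", "C", i, "FJC", frozenset({"backbone"})) for i in range(5)]
        topo = Topology(atoms=atoms, bonds={(i, i + 1) for i in range(4)},
                        n_residues_polymer=4)
        traj = Trajectory(topology=topo, frames=[Frame(coordinates=coords)] * 3)
        stats = chain_extension_stats(traj)
        # fully extended rod: ratio 1 > 1/sqrt(4)
        assert stats.ratio == pytest.approx(1.0)
        assert stats.state == "coil"
        assert stats.sd == 0.0

    def test_rigid_motion_invariance_of_length_series(self):
        rng = np.random.default_rng(13)
        traj = gen_fjc(FjcSpec(n_bonds=20, bond_length=1.0, n_samples=4, seed=9))
        ref = chain_extension_stats(traj)
        rot = random_rotation(rng)
        moved = Trajectory(
            topology=traj.topology,
            frames=[
                Frame(coordinates=f.coordinates @ rot.T + rng.uniform(-9, 9, 3))
                for f in traj.frames
            ],
        )
        assert chain_extension_stats(moved).ratio == pytest.approx(ref.ratio, abs=1e-9)


class TestTemperatureAverage:
    def test_printed_mege_row(self):
        result = temperature_average([0.14, 0.17, 0.21, 0.16, 0.15])
        assert round_half_up(result.mean, 2) == 0.17
        assert round_half_up(result.sd, 3) == 0.027

    def test_printed_meeo2ge_row(self):
        result = temperature_average([0.28, 0.27, 0.32, 0.27, 0.30])
        assert round_half_up(result.mean, 2) == 0.29

    def test_identical_ratios(self):
        result = temperature_average([0.2, 0.2, 0.2])
        assert result.sd == pytest.approx(0.0, abs=1e-12)
        assert result.cv == pytest.approx(0.0, abs=1e-12)


class TestSideChainLengths:
    @staticmethod
    def _rigid_trajectory(n_res=3, length=2.5, n_frames=4):
        atoms, bonds, coords = [], set(), []
        for r in range(n_res):
            base = 2 * r
            atoms += [
                Atom("C1", "C", r, "MON", frozenset({"backbone"})),
                Atom("CT", "C", r, "MON", frozenset({"sidechain", "terminal_carbon"})),
            ]
            coords += [[r * 4.0, 0.0, 0.0], [r * 4.0, length, 0.0]]
            bonds.add((base, base + 1))
            if r > 0:
                bonds.add((base - 2, base))
        topo = Topology(atoms=atoms, bonds=bonds, n_residues_polymer=n_res)
        frame = Frame(coordinates=np.array(coords))
        return Trajectory(topology=topo, frames=[frame] * n_frames)

    def test_rigid_side_chain_equals_static_distance(self):
        stats = side_chain_lengths(self._rigid_trajectory(length=2.5))
        np.testing.assert_allclose(stats.per_residue_mean, 2.5)
        assert stats.chain_mean == pytest.approx(2.5)

    def test_missing_terminal_is_error(self):
        traj = self._rigid_trajectory()
        atoms = [
            Atom(a.name, a.element, a.residue_index, a.residue_name,
                 a.roles - {"terminal_carbon"})
            for a in traj.topology.atoms
        ]
        topo = Topology(atoms=atoms, bonds=traj.topology.bonds, n_residues_polymer=3)
        with pytest.raises(ValueError, match="terminal"):
            side_chain_lengths(Trajectory(topology=topo, frames=traj.frames))

    def test_printed_side_chain_temperature_average(self):
        stats = side_chain_temperature_stats([3.70, 3.70, 3.69, 3.67, 3.66])
        assert round_half_up(stats.mean, 2) == 3.68
        assert round_half_up(stats.cv, 3) == 0.005

    def test_rg_series_on_fjc(self):
        traj = gen_fjc(FjcSpec(n_bonds=10, bond_length=1.0, n_samples=5, seed=2))
        series = rg_series(traj)
        assert len(series.values) == 5
        assert np.all(series.values > 0)
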