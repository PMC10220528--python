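import math

import numpy as np
import pytest

from polytraj.solvation_rdf import (
    PeakCurve,
    RDFResult,
    crossing_temperature,
    first_peak,
    peak_intensity_curve,
    rdf,
    tcrp,
)
from polytraj.synthetic_data import ShellSpec, gen_ideal_gas, gen_peak_curve, gen_shell_cloud
from polytraj.trajectory_io import Atom, Frame, Topology, Trajectory, select


def make_gas_trajectory(n_points=600, box=30.0, n_frames=40, seed=0):
    """One fixed reference atom at the box centre plus resampled gas frames."""
    atoms = [Atom("C", "C", 0, "REF", frozenset({"sidechain", "terminal_carbon"}))]
    atoms += [
        Atom("O", "O", 1 + j, "HOH", frozenset({"water_oxygen"}))
        for j in range(n_points)
    ]
    topo = Topology(atoms=atoms, bonds=set(), n_residues_polymer=1)
    frames = []
    for k in range(n_frames):
        gas = gen_ideal_gas(n_points, box, seed=seed * 10000 + k)
        centre = np.full((1, 3), box / 2.0)
        frames.append(
            Frame(coordinates=np.vstack([centre, gas.coordinates]), box=gas.box)
        )
    return Trajectory(topology=topo, frames=frames)


def brute_force_counts(trajectory, ref, target, dr, n_bins):
    """Independent all-pairs distance histogram (pure python loops)."""
    counts = [0] * n_bins
    for fr in trajectory.frames:
        box = fr.box
        for i in ref:
            for j in target:
                d2 = 0.0
                for k in range(3):
                    delta = fr.coordinates[i][k] - fr.coordinates[j][k]
                    delta -= box[k] * round(delta / box[k])
                    d2 += delta * delta
                b = int(math.sqrt(d2) / dr)
                if b < n_bins:
                    counts[b] += 1
    return np.array(counts)


class TestRdf:
    def test_ideal_gas_is_unity(self):
        traj = make_gas_trajectory()
        res = rdf(traj, select(traj.topology, "terminal_carbon"),
                  select(traj.topology, "water_oxygen"), dr=0.1)
        window = (res.r_centers >= 2.0) & (res.r_centers <= 30.0 / 4.0)
        assert np.mean(res.g[window]) == pytest.approx(1.0, abs=0.02)

    def test_two_fixed_atoms_single_bin(self):
        d = 3.57  # interior to bin 35 -> centre 3.55
        atoms = [
            Atom("C", "C", 0, "REF", frozenset({"sidechain", "terminal_carbon"})),
            Atom("O", "O", 1, "HOH", frozenset({"water_oxygen"})),
        ]
        topo = Topology(atoms=atoms, bonds=set(), n_residues_polymer=1)
        frame = Frame(
            coordinates=np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0 + d]]),
            box=[20.0, 20.0, 20.0],
        )
        res = rdf(Trajectory(topology=topo, frames=[frame]), [0], [1], dr=0.1)
        hot = np.flatnonzero(res.raw_counts)
        assert list(hot) == [35]
        # hand oracle: one count over the shell volume at the bin centre
        r_c = res.r_centers[35]
        rho = 1.0 / 20.0**3
        expected = 1.0 / (4.0 * math.pi * r_c**2 * 0.1 * rho)
        assert res.g[35] == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        n_ref, n_tgt = 8, 150
        atoms = [Atom("C", "C", i, "REF", frozenset({"sidechain", "terminal_carbon"}))
                 for i in range(n_ref)]
        atoms += [Atom("O", "O", n_ref + j, "HOH", frozenset({"water_oxygen"}))
                  for j in range(n_tgt)]
        topo = Topology(atoms=atoms, bonds=set(), n_residues_polymer=n_ref)
        frames = [
            Frame(coordinates=rng.uniform(0, 18.0, (n_ref + n_tgt, 3)),
                  box=[18.0, 18.0, 18.0])
            for _ in range(3)
        ]
        traj = Trajectory(topology=topo, frames=frames)
        ref = select(topo, "terminal_carbon")
        tgt = select(topo, "water_oxygen")
        res = rdf(traj, ref, tgt, dr=0.25)
        oracle = brute_force_counts(traj, ref, tgt, 0.25, len(res.raw_counts))
        np.testing.assert_array_equal(res.raw_counts, oracle)

    def test_translation_and_relabel_invariance(self):
        traj = make_gas_trajectory(n_points=200, n_frames=3, seed=5)
        ref = select(traj.topology, "terminal_carbon")
        tgt = select(traj.topology, "water_oxygen")
        res = rdf(traj, ref, tgt, dr=0.2)
        shift = np.array([7.3, -2.1, 11.9])
        shifted = Trajectory(
            topology=traj.topology,
            frames=[Frame(coordinates=f.coordinates + shift, box=f.box)
                    for f in traj.frames],
        )
        res2 = rdf(shifted, ref, tgt, dr=0.2)
        np.testing.assert_array_equal(res.raw_counts, res2.raw_counts)
        res3 = rdf(traj, ref[::-1], tgt, dr=0.2)
        np.testing.assert_array_equal(res.raw_counts, res3.raw_counts)

    def test_count_conservation_when_doubling_dr(self):
        traj = make_gas_trajectory(n_points=300, n_frames=5, seed=6)
        ref = select(traj.topology, "terminal_carbon")
        tgt = select(traj.topology, "water_oxygen")
        fine = rdf(traj, ref, tgt, dr=0.1, r_max=8.0)
        coarse = rdf(traj, ref, tgt, dr=0.2, r_max=8.0)
        assert fine.raw_counts.sum() == coarse.raw_counts.sum()
        # integral of rho * g * 4 pi r^2 dr over the shared range is conserved
        integral_fine = np.sum(
            fine.bulk_density * fine.g * 4 * np.pi * fine.r_centers**2 * fine.dr
        )
        integral_coarse = np.sum(
            coarse.bulk_density * coarse.g * 4 * np.pi * coarse.r_centers**2 * coarse.dr
        )
        assert integral_fine == pytest.approx(integral_coarse, rel=0.01)

    def test_contract_errors(self):
        traj = make_gas_trajectory(n_points=50, n_frames=1)
        ref = select(traj.topology, "terminal_carbon")
        tgt = select(traj.topology, "water_oxygen")
        with pytest.raises(ValueError, match="half the smallest box edge"):
            rdf(traj, ref, tgt, r_max=16.0)
        with pytest.raises(ValueError, match="non-empty"):
            rdf(traj, np.array([], dtype=int), tgt)
        with pytest.raises(ValueError, match="disjoint"):
            rdf(traj, ref, np.concatenate([ref, tgt]))
        boxless = Trajectory(
            topology=traj.topology,
            frames=[Frame(coordinates=traj.frames[0].coordinates)],
        )
        with pytest.raises(ValueError, match="no periodic box"):
            rdf(boxless, ref, tgt)


def synthetic_rdf(g_values, dr=0.1):
    g = np.asarray(g_values, dtype=float)
    r = (np.arange(len(g)) + 0.5) * dr
    return RDFResult(r_centers=r, g=g, raw_counts=np.zeros(len(g), dtype=int),
                     n_ref=1, n_frames=1, bulk_density=1.0, dr=dr)


class TestFirstPeak:
    def test_monotone_decreasing_reports_none(self):
        res = synthetic_rdf(np.linspace(3.0, 0.1, 80))
        assert first_peak(res) is None

    def test_tie_breaks_to_smaller_r(self):
        g = np.ones(80) * 0.5
        g[30] = 2.0
        g[45] = 2.0
        res = synthetic_rdf(g)
        r_peak, _ = first_peak(res, smooth=False)
        assert r_peak == pytest.approx(res.r_centers[30])

    def test_planted_shell_location(self):
        sc = gen_shell_cloud(
            ShellSpec(r0=3.6, sigma=0.3, amplitude=2.0, bulk_density=0.0334,
                      box=30.0, n_ref=3, n_frames=150, seed=7)
        )
        res = rdf(sc, select(sc.topology, "terminal_carbon"),
                  select(sc.topology, "water_oxygen"), dr=0.1)
        r_peak, _ = first_peak(res)
        assert r_peak == pytest.approx(3.6, abs=0.1)


class TestPeakIntensityCurve:
    def test_planted_temperature_series(self):
        t_list = [278.0, 300.0, 323.0, 343.0, 368.0]
        a_list = [1.3, 1.2, 1.05, 0.95, 0.9]
        rdfs = {}
        for i, (t, a) in enumerate(zip(t_list, a_list)):
            sc = gen_shell_cloud(
                ShellSpec(r0=3.6, sigma=0.3, amplitude=a, bulk_density=0.05,
                          box=20.0, n_ref=5, n_frames=300, seed=100 + i,
                          temperature=t)
            )
            rdfs[t] = rdf(sc, select(sc.topology, "terminal_carbon"),
                          select(sc.topology, "water_oxygen"), dr=0.1)
        curve = peak_intensity_curve(rdfs)
        np.testing.assert_array_equal(curve.temperatures, t_list)
        for got, planted in zip(curve.first_peak_intensity, a_list):
            assert got == pytest.approx(planted, abs=0.1)
        assert np.all(np.diff(curve.first_peak_intensity) < 0.05)

    def test_single_temperature_curve(self):
        res = synthetic_rdf(np.concatenate([np.ones(30), [1.5, 2.0, 1.5], np.ones(30)]))
        curve = peak_intensity_curve({300.0: res})
        assert len(curve.temperatures) == 1
        assert crossing_temperature(curve).temperature is None

    def test_shuffled_input_sorted_ascending(self):
        res = synthetic_rdf(np.concatenate([np.ones(30), [1.5, 2.0, 1.5], np.ones(30)]))
        curve = peak_intensity_curve([(343.0, res), (278.0, res), (300.0, res)])
        np.testing.assert_array_equal(curve.temperatures, [278.0, 300.0, 343.0])


class TestCrossingTemperature:
    def test_two_point_midpoint(self):
        curve = gen_peak_curve([300.0, 350.0], [1.2, 0.8])
        res = crossing_temperature(curve)
        assert res.temperature == pytest.approx(325.0, abs=1e-12)
        assert res.bracket == (300.0, 350.0)
        assert tcrp is crossing_temperature

    def test_all_above_threshold(self):
        curve = gen_peak_curve([278.0, 368.0], [1.3, 1.05])
        res = crossing_temperature(curve)
        assert res.temperature is None and res.bracket is None

    def test_linear_curve_exact(self):
        curve = gen_peak_curve([278.0, 300.0, 323.0, 343.0, 368.0],
                               lambda t: 2.0 - t / 300.0)
        assert crossing_temperature(curve).temperature == pytest.approx(300.0, abs=1e-9)

    def test_non_finite_intensity_is_error(self):
        curve = PeakCurve(temperatures=np.array([300.0, 350.0]),
                          first_peak_r=np.array([np.nan, np.nan]),
                          first_peak_intensity=np.array([np.nan, 0.8]))
        with pytest.raises(ValueError, match="non-finite"):
            crossing_temperature(curve)

    def test_threshold_is_inclusive_on_the_left(self):
        curve = gen_peak_curve([300.0, 350.0], [1.0, 0.5])
        res = crossing_temperature(curve)
        assert res.temperature == pytest.approx(300.0)


class TestPeakCurveValidation:
    def test_strictly_increasing_temperatures(self):
        with pytest.raises(ValueError, match="increasing"):
            PeakCurve(temperatures=np.array([300.0, 300.0]),
                      first_peak_r=np.zeros(2),
                      first_peak_intensity=np.ones(2))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            PeakCurve(temperatures=np.array([300.0, 350.0]),
                      first_peak_r=np.zeros(2),
                      first_peak_intensity=np.array([1.0, -0.1]))
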