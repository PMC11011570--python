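import numpy as np
import pandas as pd
import pytest

from metallotraj import (rmsd, gyration_radius, rdf, ChargeGroups,
                         salt_bridges, compactness_ratio, is_compact,
                         rmsf_pca, fe_water_orientation, center_of_mass,
                         cluster_com_distance, classify_functional,
                         FUNCTIONAL_RANGE_NM, CVSample, WindowSpec,
                         DEFAULT_WINDOWS, window_stats, SelectionSpec,
                         gen_toy_protein, gen_harmonic_trajectory,
                         gen_hydration_shell, gen_cubane)
from metallotraj.model import AtomRecord, StructureModel, Trajectory


class TestRmsdRg:
    def test_translation_removed_only_with_fit(self, rng):
        a = rng.standard_normal((10, 3))
        b = a + np.array([3.0, 0.0, 0.0])
        assert rmsd(a, b) == pytest.approx(3.0)
        assert rmsd(a, b, fit=True) == pytest.approx(0.0, abs=1e-10)

    def test_mass_weighting(self):
        a = np.zeros((2, 3))
        b = np.array([[1.0, 0, 0], [0.0, 0, 0]])
        # displacement only on the heavy atom
        heavy_first = rmsd(a, b, masses=[3.0, 1.0])
        light_first = rmsd(a, b, masses=[1.0, 3.0])
        assert heavy_first == pytest.approx(np.sqrt(3.0 / 4.0))
        assert light_first == pytest.approx(np.sqrt(1.0 / 4.0))

    def test_rg_of_point_pair(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert gyration_radius(frame) == pytest.approx(1.0)
        # all mass on one atom: Rg -> 0
        assert gyration_radius(frame, masses=[1.0, 1e-12]) \
            == pytest.approx(0.0, abs=1e-5)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestRdf:
    @staticmethod
    def ideal_gas_traj(n_b, n_frames, box_edge, seed):
        rng = np.random.default_rng(seed)
        atoms = [AtomRecord.create(1, "FE", 1, "FES", "X", (0.0, 0, 0),
                                   element="Fe")]
        atoms += [AtomRecord.create(i + 2, "OW", i + 2, "HOH", "W",
                                    (0.0, 0, 0), element="O")
                  for i in range(n_b)]
        top = StructureModel(atoms)
        frames = rng.uniform(0.0, box_edge, size=(n_frames, n_b + 1, 3))
        box = np.full(3, box_edge)
        return Trajectory(top, frames, box=box)

    def test_ideal_gas_is_flat_at_one(self):
        traj = self.ideal_gas_traj(n_b=500, n_frames=30, box_edge=30.0,
                                   seed=5)
        out = rdf(traj, [0], np.arange(1, 501), bin_width=0.25, r_max=10.0)
        sel = (out.bin_centers > 3.0) & (out.bin_centers < 10.0)
        assert np.abs(out.g_values[sel] - 1.0).mean() < 0.1

    def test_delta_shell_lands_in_the_right_bin(self):
        # one b-atom always at exactly 5.0 A from the a-atom
        atoms = [AtomRecord.create(1, "FE", 1, "FES", "X", (0, 0, 0),
                                   element="Fe"),
                 AtomRecord.create(2, "OW", 2, "HOH", "W", (5.0, 0, 0),
                                   element="O")]
        top = StructureModel(atoms)
        frames = np.tile(top.coords, (4, 1, 1)) + 10.0
        traj = Trajectory(top, frames, box=np.full(3, 40.0))
        out = rdf(traj, [0], [1], bin_width=0.5, r_max=10.0)
        nz = np.nonzero(out.g_values)[0]
        assert len(nz) == 1
        lo, hi = out.bin_edges[nz[0]], out.bin_edges[nz[0] + 1]
        assert lo <= 5.0 < hi

    def test_minimum_image_wraps_distances(self):
        # neighbours across the periodic boundary: 1 A apart through the
        # wall, 19 A apart in raw coordinates
        atoms = [AtomRecord.create(1, "FE", 1, "FES", "X", (0.5, 10, 10),
                                   element="Fe"),
                 AtomRecord.create(2, "OW", 2, "HOH", "W", (19.5, 10, 10),
                                   element="O")]
        top = StructureModel(atoms)
        traj = Trajectory(top, top.coords[None], box=np.full(3, 20.0))
        out = rdf(traj, [0], [1], bin_width=0.5, r_max=9.0)
        nz = np.nonzero(out.g_values)[0]
        assert out.bin_edges[nz[0]] <= 1.0 < out.bin_edges[nz[0] + 1]

    def test_self_pairs_excluded(self):
        traj = self.ideal_gas_traj(n_b=10, n_frames=2, box_edge=25.0, seed=9)
        idx = np.arange(11)
        out = rdf(traj, idx, idx, bin_width=0.5, r_max=10.0)
        assert out.g_values[0] == 0.0  # no zero-distance self counts

    def test_r_max_beyond_half_box_rejected(self):
        traj = self.ideal_gas_traj(n_b=5, n_frames=1, box_edge=15.0, seed=1)
        with pytest.raises(ValueError, match="half"):
            rdf(traj, [0], [1, 2], r_max=8.0)

    def test_no_box_warns_and_uses_local_density(self):
        atoms = [AtomRecord.create(i + 1, "OW", i + 1, "HOH", "W",
                                   (0.0, 0, 0), element="O")
                 for i in range(4)]
        top = StructureModel(atoms)
        rng = np.random.default_rng(0)
        frames = rng.uniform(0, 8.0, size=(3, 4, 3))
        traj = Trajectory(top, frames)
        with pytest.warns(UserWarning, match="without a box"):
            out = rdf(traj, [0], [1, 2, 3], r_max=4.0)
        assert np.all(np.isfinite(out.g_values))

    def test_empty_groups_rejected(self):
        traj = self.ideal_gas_traj(n_b=3, n_frames=1, box_edge=20.0, seed=2)
        with pytest.raises(ValueError, match="non-empty"):
            rdf(traj, [], [1])


class TestSaltBridges:
    @staticmethod
    def charged_pair(distance):
        atoms = [
            AtomRecord.create(1, "N", 1, "GLU", "A", (0.0, 50, 0)),
            AtomRecord.create(2, "CD", 1, "GLU", "A", (0.0, 0, 0)),
            AtomRecord.create(3, "C", 1, "GLU", "A", (0.0, -50, 0)),
            AtomRecord.create(4, "NZ", 2, "LYS", "B", (distance, 0, 0)),
        ]
        return StructureModel(atoms)

    @pytest.mark.parametrize("d, expected", [(3.5, 1), (4.0, 1), (4.2, 0)])
    def test_cutoff_is_inclusive(self, d, expected):
        model = self.charged_pair(d)
        groups = ChargeGroups.from_model(model)
        assert salt_bridges(model.coords, groups) == expected

    def test_termini_included(self):
        model = self.charged_pair(100.0)
        groups = ChargeGroups.from_model(model)
        # chain A: N-terminal N (basic) and C-terminal C (acidic)
        assert 0 in groups.basic          # atom 1: chain A N-terminus
        assert 2 in groups.acidic         # atom 3: chain A C-terminus
        assert 1 in groups.acidic         # Glu CD
        assert 3 in groups.basic          # Lys NZ

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            ChargeGroups(acidic=[1, 2], basic=[2, 3])

    def test_empty_groups_count_zero(self):
        groups = ChargeGroups(acidic=[], basic=[])
        assert salt_bridges(np.zeros((3, 3)), groups) == 0


class TestCompactness:
    def test_separated_domains_ratio_one(self):
        model, domains, _ = gen_toy_protein(residues_per_domain=8,
                                            separation=120.0)
        result = compactness_ratio(model, domains)
        assert result.R == pytest.approx(1.0, abs=1e-6)
        assert not result.compact

    def test_interpenetrating_domains_compact(self):
        model, domains, _ = gen_toy_protein(residues_per_domain=8,
                                            separation=2.0)
        result = compactness_ratio(model, domains)
        assert result.R < 0.95
        assert result.compact

    def test_boundary_inclusive(self):
        assert is_compact(0.95)
        assert is_compact(0.94999)
        assert not is_compact(0.95001)

    def test_c_terminus_can_push_ratio_above_one(self):
        model, domains, _ = gen_toy_protein(residues_per_domain=8,
                                            separation=120.0,
                                            with_c_terminus=True)
        result = compactness_ratio(model, domains)
        assert result.R > 1.0

    def test_missing_domain_label(self):
        model, domains, _ = gen_toy_protein(n_domains=1,
                                            residues_per_domain=5)
        with pytest.raises(ValueError, match="'H'"):
            compactness_ratio(model, domains)


class TestRmsfPca:
    def test_full_spectrum_equals_direct_variance(self):
        model, _, _ = gen_toy_protein(residues_per_domain=6)
        traj, _ = gen_harmonic_trajectory(model, 0.3, n_frames=400, seed=4)
        n3 = 3 * model.n_atoms
        out = rmsf_pca(traj, n_eigenvectors=n3, fit=False)
        x = traj.frames - traj.frames.mean(axis=0)
        direct = np.sqrt((x ** 2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose(out.per_atom, direct, atol=1e-8)

    def test_truncation_only_lowers_rmsf(self):
        model, _, _ = gen_toy_protein(residues_per_domain=6)
        traj, _ = gen_harmonic_trajectory(model, 0.3, n_frames=200, seed=8)
        full = rmsf_pca(traj, n_eigenvectors=3 * model.n_atoms, fit=False)
        trunc = rmsf_pca(traj, n_eigenvectors=4, fit=False)
        assert np.all(trunc.per_atom <= full.per_atom + 1e-12)

    def test_single_mode_motion_captured_by_one_eigenvector(self):
        # all atoms move together along x: rank-1 covariance
        model, _, _ = gen_toy_protein(residues_per_domain=4)
        rng = np.random.default_rng(3)
        amp = rng.standard_normal(500)
        frames = np.tile(model.coords, (500, 1, 1))
        frames[:, :, 0] += amp[:, None]
        traj = Trajectory(model, frames)
        out = rmsf_pca(traj, n_eigenvectors=1, fit=False)
        expected = amp.std()
        np.testing.assert_allclose(out.per_atom, expected, rtol=1e-8)
        assert out.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_planted_fluctuation_recovered(self):
        model, _, _ = gen_toy_protein(residues_per_domain=10)
        traj, truth = gen_harmonic_trajectory(model, 0.4, n_frames=2000,
                                              seed=12)
        out = rmsf_pca(traj, n_eigenvectors=3 * model.n_atoms, fit=True)
        expected = truth.expected["per_atom_rmsf"]
        mid = model.n_atoms // 2
        assert out.per_atom[mid] == pytest.approx(expected[mid], rel=0.05)

    def test_per_residue_aggregation(self):
        model, _, _ = gen_toy_protein(n_domains=1, residues_per_domain=3)
        traj, _ = gen_harmonic_trajectory(model, 0.3, n_frames=300, seed=6)
        out = rmsf_pca(traj, n_eigenvectors=3 * model.n_atoms, fit=False)
        assert set(out.per_residue) == {1, 2, 3}
        manual = np.sqrt(np.mean(out.per_atom[:5] ** 2))
        assert out.per_residue[1] == pytest.approx(manual)

    def test_validation(self):
        model, _, _ = gen_toy_protein(n_domains=1, residues_per_domain=2)
        traj, _ = gen_harmonic_trajectory(model, 0.1, n_frames=5)
        with pytest.raises(ValueError, match="eigenvectors"):
            rmsf_pca(traj, n_eigenvectors=3 * model.n_atoms + 1)
        with pytest.raises(ValueError, match="no atoms"):
            rmsf_pca(traj, selection=SelectionSpec(chain="Z"))


class TestOrientation:
    def test_planted_fraction_recovered_exactly(self):
        traj, truth = gen_hydration_shell(n_events=2000,
                                          orientation_fraction=0.12, seed=3)
        out = fe_water_orientation(traj, truth.expected["fe_atom"],
                                   truth.expected["waters"])
        assert out.n_events == 2000
        assert out.probability == pytest.approx(
            truth.expected["planted_fraction"], abs=1e-12)

    def test_no_events_is_undefined_not_zero(self):
        traj, truth = gen_hydration_shell(n_events=50, r_O=9.0, r_H_in=8.0,
                                          seed=1)
        out = fe_water_orientation(traj, 0, truth.expected["waters"],
                                   shell_cutoff=4.0)
        assert out.probability is None
        assert not out.defined

    def test_all_inward(self):
        traj, truth = gen_hydration_shell(n_events=100,
                                          orientation_fraction=1.0, seed=2)
        out = fe_water_orientation(traj, 0, truth.expected["waters"])
        assert out.probability == 1.0

    def test_requires_waters(self):
        traj, _ = gen_hydration_shell(n_events=10, seed=0)
        with pytest.raises(ValueError, match="no waters"):
            fe_water_orientation(traj, 0, [])


class TestClusterDistance:
    def test_known_distance_reported_in_nm(self):
        a, _ = gen_cubane(center=(0.0, 0.0, 0.0), first_serial=1)
        b, _ = gen_cubane(center=(12.5, 0.0, 0.0), first_serial=9)
        model = StructureModel(a.atoms + b.atoms)
        d = cluster_com_distance(model.coords, np.arange(8),
                                 np.arange(8, 16), model.masses)
        assert d == pytest.approx(1.25, abs=1e-9)

    def test_functional_window_inclusive(self):
        assert classify_functional(1.1)
        assert classify_functional(1.4)
        assert classify_functional(1.25)
        assert not classify_functional(1.09)
        assert not classify_functional(1.41)
        assert FUNCTIONAL_RANGE_NM == (1.1, 1.4)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_functional(-0.1)

    def test_com_mass_weighting(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        com = center_of_mass(coords, [3.0, 1.0])
        assert com[0] == pytest.approx(2.5)


class TestWindowStats:
    @staticmethod
    def hand_fixture():
        """10 samples whose window statistics are countable by hand."""
        return [
            # w1 (0.75-1.25): three members, SASA 10/20/30, R 0.9/0.9/1.0
            CVSample(0.8, 10.0, 0.90),
            CVSample(1.0, 20.0, 0.90),
            CVSample(1.25, 30.0, 1.00),   # boundary: inside (inclusive)
            # w2 (1.75-2.25): two members, one compact
            CVSample(1.8, 40.0, 0.95),    # boundary R: compact (inclusive)
            CVSample(2.2, 60.0, 1.10),
            # between windows: never counted
            CVSample(1.5, 99.0, 0.50),
            CVSample(2.5, 99.0, 0.50),
            # w3 (2.75-3.25): three members, none compact
            CVSample(2.75, 70.0, 1.20),
            CVSample(3.0, 80.0, 1.30),
            CVSample(3.25, 90.0, 1.40),
        ]

    def test_hand_countable_fixture(self):
        df = window_stats(self.hand_fixture())
        assert df.loc["w1", "count"] == 3
        assert df.loc["w2", "count"] == 2
        assert df.loc["w3", "count"] == 3
        assert df.loc["w1", "sasa_mean"] == pytest.approx(20.0)
        assert df.loc["w1", "sasa_sd"] == pytest.approx(
            np.std([10.0, 20.0, 30.0]))
        # percent-compact over ALL 10 samples: w1 has 2 compact -> 20 %
        assert df.loc["w1", "compact_percent"] == pytest.approx(20.0)
        assert df.loc["w2", "compact_percent"] == pytest.approx(10.0)
        assert df.loc["w3", "compact_percent"] == pytest.approx(0.0)

    def test_per_window_denominator_option(self):
        df = window_stats(self.hand_fixture(), per_window_denominator=True)
        assert df.loc["w1", "compact_percent"] == pytest.approx(200.0 / 3.0)
        assert df.loc["w2", "compact_percent"] == pytest.approx(50.0)

    def test_empty_window_is_nan_not_zero(self):
        samples = [CVSample(1.0, 10.0, 0.9)]
        df = window_stats(samples)
        assert df.loc["w2", "count"] == 0
        assert np.isnan(df.loc["w2", "sasa_mean"])
        assert np.isnan(df.loc["w2", "compact_percent"])

    def test_window_validation(self):
        with pytest.raises(ValueError, match="d_min > d_max"):
            WindowSpec("bad", 2.0, 1.0)
        with pytest.raises(ValueError, match="no samples"):
            window_stats([])
        with pytest.raises(ValueError, match="non-negative"):
            CVSample(-0.1, 1.0, 1.0)

    def test_default_windows(self):
        assert [w.label for w in DEFAULT_WINDOWS] == ["w1", "w2", "w3"]
        assert DEFAULT_WINDOWS[0].contains(0.75)
        assert DEFAULT_WINDOWS[0].contains(1.25)
        assert not DEFAULT_WINDOWS[0].contains(1.2501)
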