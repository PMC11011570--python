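import json

import numpy as np
import pytest

from metallotraj import (gen_toy_protein, gen_cubane, gen_harmonic_trajectory,
                         gen_hydration_shell, gen_sequence, gen_double_well,
                         MotifDef, find_cys_positions)


class TestDeterminism:
    def test_same_seed_same_artifact(self):
        m1, _, _ = gen_toy_protein(seed=5)
        m2, _, _ = gen_toy_protein(seed=5)
        np.testing.assert_array_equal(m1.coords, m2.coords)
        s1, _ = gen_sequence(200, seed=5)
        s2, _ = gen_sequence(200, seed=5)
        assert s1 == s2
        t1, _ = gen_harmonic_trajectory(m1, 0.3, 10, seed=5)
        t2, _ = gen_harmonic_trajectory(m2, 0.3, 10, seed=5)
        np.testing.assert_array_equal(t1.frames, t2.frames)

    def test_different_seed_different_artifact(self):
        s1, _ = gen_sequence(200, seed=1)
        s2, _ = gen_sequence(200, seed=2)
        assert s1 != s2

    def test_truth_is_json_serializable(self):
        _, _, truth = gen_toy_protein(seed=3)
        parsed = json.loads(truth.to_json())
        assert parsed["generator"] == "gen_toy_protein"
        assert parsed["seed"] == 3
        _, truth2 = gen_harmonic_trajectory(gen_toy_protein(seed=3)[0],
                                            0.2, 5, seed=3)
        json.loads(truth2.to_json())


class TestToyProtein:
    def test_domain_map_covers_all_residues(self):
        model, domains, truth = gen_toy_protein(residues_per_domain=12)
        assert domains["F"] == (1, 12)
        assert domains["H"] == (13, 24)
        assert truth.expected["n_atoms"] == model.n_atoms == 24 * 5

    def test_c_terminus_is_far_from_both_domains(self):
        model, domains, _ = gen_toy_protein(with_c_terminus=True,
                                            separation=100.0)
        lo, hi = domains["C"]
        tail = np.array([a.position for a in model.atoms
                         if lo <= a.residue_number <= hi])
        body = np.array([a.position for a in model.atoms
                         if a.residue_number < lo])
        min_sep = np.min(np.linalg.norm(
            tail[:, None, :] - body[None, :, :], axis=2))
        assert min_sep > 20.0

    def test_domain_separation_controls_distance(self):
        near, dn, _ = gen_toy_protein(separation=30.0, residues_per_domain=5)
        far, df, _ = gen_toy_protein(separation=90.0, residues_per_domain=5)
        def com_dist(model, domains):
            f = np.array([a.position for a in model.atoms
                          if a.residue_number <= domains["F"][1]])
            h = np.array([a.position for a in model.atoms
                          if a.residue_number > domains["F"][1]])
            return np.linalg.norm(f.mean(axis=0) - h.mean(axis=0))
        assert com_dist(far, df) == pytest.approx(
            com_dist(near, dn) + 60.0, abs=1e-6)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            gen_toy_protein(n_domains=0)
        with pytest.raises(ValueError):
            gen_toy_protein(separation=-1.0)


class TestCubane:
    def test_composition_and_geometry(self):
        model, spec = gen_cubane(center=(1.0, 2.0, 3.0))
        assert model.n_atoms == 8
        elements = [a.element.upper() for a in model.atoms]
        assert elements.count("FE") == 4 and elements.count("S") == 4
        np.testing.assert_allclose(model.coords.mean(axis=0),
                                   [1.0, 2.0, 3.0], atol=1e-12)
        # every nearest neighbour along a cube edge is Fe-S, 2.7 A
        for i, a in enumerate(model.atoms):
            d = np.linalg.norm(model.coords - a.position, axis=1)
            for j in np.nonzero(np.isclose(d, 2.7))[0]:
                assert model.atoms[j].element != a.element

    def test_serial_offset(self):
        model, spec = gen_cubane(center=(0.0, 0.0, 0.0), first_serial=42)
        assert [a.atom_id for a in model.atoms] == list(range(42, 50))
        assert spec.member_atom_ids == tuple(range(42, 50))


class TestHarmonicTrajectory:
    def test_sample_std_matches_planted(self):
        model, _, _ = gen_toy_protein(residues_per_domain=4)
        traj, truth = gen_harmonic_trajectory(model, 0.5, n_frames=5000,
                                              seed=9)
        disp = traj.frames - model.coords[None]
        per_axis = disp.std(axis=0)
        np.testing.assert_allclose(per_axis.mean(), 0.5, rtol=0.02)
        np.testing.assert_allclose(truth.expected["per_atom_rmsf"],
                                   0.5 * np.sqrt(3.0))

    def test_axis_restriction(self):
        model, _, _ = gen_toy_protein(residues_per_domain=3)
        traj, truth = gen_harmonic_trajectory(model, 0.4, n_frames=200,
                                              seed=2, axis="y")
        disp = traj.frames - model.coords[None]
        assert np.all(disp[:, :, 0] == 0.0)
        assert np.all(disp[:, :, 2] == 0.0)
        assert disp[:, :, 1].std() > 0.3
        np.testing.assert_allclose(truth.expected["per_atom_rmsf"], 0.4)

    def test_per_atom_std_array(self):
        model, _, _ = gen_toy_protein(residues_per_domain=2)
        stds = np.linspace(0.1, 1.0, model.n_atoms)
        traj, truth = gen_harmonic_trajectory(model, stds, n_frames=3000,
                                              seed=4)
        disp = traj.frames - model.coords[None]
        measured = np.sqrt((disp ** 2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose(measured, stds * np.sqrt(3.0), rtol=0.1)

    def test_validation(self):
        model, _, _ = gen_toy_protein(residues_per_domain=2)
        with pytest.raises(ValueError):
            gen_harmonic_trajectory(model, 0.5, n_frames=1)
        with pytest.raises(ValueError):
            gen_harmonic_trajectory(model, -0.1, n_frames=5)


class TestHydrationShell:
    def test_geometry_of_planted_events(self):
        traj, truth = gen_hydration_shell(n_events=400,
                                          orientation_fraction=0.5, seed=6)
        fe = traj.frames[:, 0, :]
        d_o = np.linalg.norm(traj.frames[:, 1, :] - fe, axis=1)
        np.testing.assert_allclose(d_o, 3.5, atol=1e-9)
        d_h = np.minimum(
            np.linalg.norm(traj.frames[:, 2, :] - fe, axis=1),
            np.linalg.norm(traj.frames[:, 3, :] - fe, axis=1))
        inward = d_h < d_o
        assert inward.mean() == pytest.approx(
            truth.expected["planted_fraction"], abs=1e-12)
        # inward hydrogens sit exactly at the planted radius
        np.testing.assert_allclose(d_h[inward], 2.5, atol=1e-9)
        # outward waters keep both hydrogens beyond the oxygen
        assert np.all(d_h[~inward] > 3.5)

    def test_water_geometry_near_rigid(self):
        traj, _ = gen_hydration_shell(n_events=100, seed=3)
        o = traj.frames[:, 1, :]
        for h_col in (2, 3):
            bond = np.linalg.norm(traj.frames[:, h_col, :] - o, axis=1)
            np.testing.assert_allclose(bond, 0.957, atol=0.06)

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            gen_hydration_shell(r_O=2.0, r_H_in=3.5)
        with pytest.raises(ValueError):
            gen_hydration_shell(orientation_fraction=1.5)
        with pytest.raises(ValueError):
            gen_hydration_shell(n_events=0)


class TestSequence:
    def test_background_has_no_cysteine(self):
        seq, truth = gen_sequence(500, seed=8)
        assert "C" not in seq
        assert truth.expected["cys_positions"] == []

    def test_planted_cys_positions_exact(self):
        seq, truth = gen_sequence(100, planted_cys_positions=[21, 72, 75, 78],
                                  seed=8)
        assert find_cys_positions(seq) == [21, 72, 75, 78]
        assert truth.expected["cys_positions"] == [21, 72, 75, 78]

    def test_motif_cys_counted_in_truth(self):
        motif = MotifDef("P1", "TSCCPGW")
        seq, truth = gen_sequence(50, planted_motifs=[(motif, 10)], seed=1)
        assert seq[9:16] == "TSCCPGW"
        assert truth.expected["cys_positions"] == [12, 13]
        assert find_cys_positions(seq) == [12, 13]

    def test_collisions_rejected(self):
        motif = MotifDef("P1", "TSCCPGW")
        with pytest.raises(ValueError, match="collides"):
            gen_sequence(50, planted_motifs=[(motif, 10), (motif, 12)])
        with pytest.raises(ValueError, match="collides"):
            gen_sequence(50, planted_motifs=[(motif, 10)],
                         planted_cys_positions=[11])
        with pytest.raises(ValueError, match="fit"):
            gen_sequence(10, planted_motifs=[(motif, 8)])
        with pytest.raises(ValueError, match="outside"):
            gen_sequence(10, planted_cys_positions=[11])


class TestDoubleWell:
    def test_symmetric_well_truth_is_zero(self):
        _, truth = gen_double_well(4.0)
        assert truth.expected["delta_f_kbt"] == pytest.approx(0.0, abs=1e-9)
        assert truth.expected["barrier_top"] == pytest.approx(0.0, abs=1e-4)

    def test_asymmetry_penalizes_the_right_basin(self):
        _, truth = gen_double_well(5.0, asymmetry=2.0)
        # right basin higher by ~2 kBT -> Delta F close to +2
        assert truth.expected["delta_f_kbt"] == pytest.approx(2.0, abs=0.2)

    def test_force_is_minus_gradient(self):
        system, _ = gen_double_well(3.0, asymmetry=1.0)
        q = np.linspace(-1.5, 1.5, 7)[:, None]
        h = 1e-6
        numeric = -(system.potential(q + h) - system.potential(q - h)) / (2 * h)
        np.testing.assert_allclose(system.force(q)[:, 0], numeric, atol=1e-5)

    def test_barrier_must_be_positive(self):
        with pytest.raises(ValueError):
            gen_double_well(0.0)
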