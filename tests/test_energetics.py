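"""Nonbonded pair potentials, frame energies, and event scoring."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bindscout.energetics import (
    COULOMB_KE,
    EnergyBreakdown,
    NonbondedModel,
    coulomb_pair_energy,
    interaction_energy,
    lj_pair_energy,
    read_parameter_table,
    score_events,
    write_parameter_table,
)
from bindscout.event_detection import BindingEvent, ContactFingerprint
from bindscout.structures_io import AtomRecord, SelectionMask, Topology, Trajectory
from bindscout.validation import (
    _random_two_molecule_fixture,
    brute_force_interaction_energy,
)


def model(mode="plain_cutoff", n=1):
    return NonbondedModel(
        charge=np.zeros(n), sigma=np.full(n, 0.3), epsilon=np.ones(n), lj_mode=mode
    )


class TestPairPotentials:
    def test_lj_zero_at_sigma(self):
        assert lj_pair_energy(0.3, 0.3, 1.0, model()) == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_depth(self):
        r_min = 2 ** (1 / 6) * 0.3
        assert lj_pair_energy(r_min, 0.3, 1.0, model()) == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("mode", ["plain_cutoff", "switched"])
    def test_zero_beyond_cutoff(self, mode):
        m = model(mode)
        assert lj_pair_energy(1.3, 0.3, 1.0, m) == 0.0
        assert coulomb_pair_energy(1.25, 1.0, 1.0, m) == 0.0

    def test_coulomb_constant_at_1nm(self):
        assert coulomb_pair_energy(1.0, 1.0, 1.0, model()) == pytest.approx(138.935458)

    def test_coulomb_zero_charge(self):
        assert coulomb_pair_energy(0.7, 0.0, 1.0, model()) == 0.0

    @pytest.mark.parametrize("func", [lj_pair_energy, coulomb_pair_energy])
    def test_nonpositive_distance_rejected(self, func):
        with pytest.raises(ValueError):
            func(0.0, 0.3, 1.0, model())

    def test_switched_potential_continuous_with_continuous_force(self):
        m = model("switched")
        h = 1e-6
        for r0 in (m.r_switch, m.r_cut):
            v_lo = lj_pair_energy(r0 - h, 0.34, 0.5, m)
            v_hi = lj_pair_energy(r0 + h, 0.34, 0.5, m)
            assert v_hi == pytest.approx(v_lo, abs=1e-4)
            d_lo = (lj_pair_energy(r0 - h, 0.34, 0.5, m)
                    - lj_pair_energy(r0 - 2 * h, 0.34, 0.5, m)) / h
            d_hi = (lj_pair_energy(r0 + 2 * h, 0.34, 0.5, m)
                    - lj_pair_energy(r0 + h, 0.34, 0.5, m)) / h
            assert d_hi == pytest.approx(d_lo, abs=1e-3)
        # both value and force vanish at the cutoff
        assert lj_pair_energy(m.r_cut, 0.34, 0.5, m) == pytest.approx(0.0, abs=1e-12)
        slope = (lj_pair_energy(m.r_cut, 0.34, 0.5, m)
                 - lj_pair_energy(m.r_cut - h, 0.34, 0.5, m)) / h
        assert slope == pytest.approx(0.0, abs=1e-4)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            NonbondedModel(np.zeros(1), np.ones(1), np.ones(1), r_switch=1.3, r_cut=1.2)
        with pytest.raises(ValueError):
            NonbondedModel(np.zeros(1), np.ones(1), -np.ones(1))
        with pytest.raises(ValueError):
            NonbondedModel(np.zeros(1), np.ones(1), np.ones(1), lj_mode="pme")


def fixture_3v4(mode="switched"):
    """3-atom ligand vs 4-atom receptor with parameters printed in the test."""
    atoms = [AtomRecord(i + 1, f"C{i + 1}", "C", "RES", 1, "R") for i in range(4)]
    atoms += [AtomRecord(5 + i, f"C{i + 1}", "C", "LIG", 1, "L") for i in range(3)]
    coords = np.array(
        [[
            [0.00, 0.0, 0.0], [0.40, 0.0, 0.0], [0.00, 0.4, 0.0], [0.30, 0.3, 0.3],
            [0.60, 0.6, 0.6], [0.90, 0.6, 0.6], [0.60, 1.0, 0.6],
        ]]
    )
    traj = Trajectory(coords=coords, topology=Topology(atoms), aligned=True)
    charge = np.array([0.3, -0.3, 0.1, -0.1, 0.25, -0.25, 0.0])
    sigma = np.array([0.30, 0.32, 0.28, 0.31, 0.25, 0.27, 0.33])
    eps = np.array([0.5, 0.6, 0.4, 0.7, 0.3, 0.9, 0.2])
    m = NonbondedModel(charge, sigma, eps, lj_mode=mode)
    return traj, SelectionMask([4, 5, 6]), SelectionMask([0, 1, 2, 3]), m


class TestInteractionEnergy:
    @pytest.mark.parametrize("mode", ["plain_cutoff", "switched"])
    def test_matches_double_loop_oracle(self, mode):
        traj, lig, rec, m = fixture_3v4(mode)
        got = interaction_energy(traj, 0, lig, rec, m)
        lj, coul = brute_force_interaction_energy(
            traj, 0, lig.indices.tolist(), rec.indices.tolist(), m
        )
        assert got.lj_kj_mol == pytest.approx(lj, rel=1e-9)
        assert got.coulomb_kj_mol == pytest.approx(coul, rel=1e-9)
        assert got.total_kj_mol == got.lj_kj_mol + got.coulomb_kj_mol

    def test_distant_ligand_zero(self):
        traj, lig, rec, m = fixture_3v4()
        far = traj.coords.copy()
        far[0, 4:, :] += 5.0
        traj2 = Trajectory(coords=far, topology=traj.topology, aligned=True)
        assert interaction_energy(traj2, 0, lig, rec, m).total_kj_mol == 0.0

    def test_coulomb_bilinearity_in_charges(self):
        traj, lig, rec, m = fixture_3v4()
        base = interaction_energy(traj, 0, lig, rec, m)
        m2 = NonbondedModel(2 * m.charge, m.sigma, m.epsilon, lj_mode=m.lj_mode)
        doubled = interaction_energy(traj, 0, lig, rec, m2)
        assert doubled.coulomb_kj_mol == pytest.approx(4 * base.coulomb_kj_mol, rel=1e-12)
        assert doubled.lj_kj_mol == pytest.approx(base.lj_kj_mol, rel=1e-12)

    def test_neighbor_list_equals_all_pairs(self, rng):
        for _ in range(10):
            traj, lig, rec, m = _random_two_molecule_fixture(rng)
            f = int(rng.integers(0, traj.n_frames))
            e1 = interaction_energy(traj, f, lig, rec, m, method="neighbor")
            e2 = interaction_energy(traj, f, lig, rec, m, method="all_pairs")
            assert e1.lj_kj_mol == pytest.approx(e2.lj_kj_mol, rel=1e-12, abs=1e-12)
            assert e1.coulomb_kj_mol == pytest.approx(e2.coulomb_kj_mol, rel=1e-12, abs=1e-12)

    def test_invariant_under_global_rigid_motion(self, rng):
        traj, lig, rec, m = fixture_3v4()
        base = interaction_energy(traj, 0, lig, rec, m).total_kj_mol
        R = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
        moved = traj.coords[0] @ R.T + np.array([3.0, -2.0, 1.0])
        traj2 = Trajectory(coords=moved[None], topology=traj.topology, aligned=True)
        assert interaction_energy(traj2, 0, lig, rec, m).total_kj_mol == pytest.approx(
            base, abs=1e-6
        )

    def test_missing_parameters_error_names_atom(self):
        traj, lig, rec, m = fixture_3v4()
        charge = m.charge.copy()
        charge[5] = np.nan
        m2 = NonbondedModel(charge, m.sigma, m.epsilon)
        with pytest.raises(KeyError, match="serial 6"):
            interaction_energy(traj, 0, lig, rec, m2)


class TestScoreEvents:
    @staticmethod
    def _event(start, end):
        return BindingEvent(
            start_frame=start,
            end_frame=end,
            frame_spacing_ns=1.0,
            representative_frame=start,
            intra_block_rmsd_median_nm=0.0,
            contact_fingerprint=ContactFingerprint({}),
        )

    def _static_traj(self, n_frames=4):
        traj, lig, rec, m = fixture_3v4()
        coords = np.repeat(traj.coords, n_frames, axis=0)
        return Trajectory(coords=coords, topology=traj.topology, aligned=True), lig, rec, m

    def test_single_frame_event_mean_equals_frame_energy(self):
        traj, lig, rec, m = self._static_traj()
        ev = score_events([self._event(1, 1)], traj, lig, rec, m)[0]
        expect = interaction_energy(traj, 1, lig, rec, m).total_kj_mol
        assert ev.mean_energy_kj_mol == pytest.approx(expect, rel=1e-12)
        assert ev.min_energy_kj_mol == ev.max_energy_kj_mol == ev.mean_energy_kj_mol

    def test_stride_invariant_on_constant_pose(self):
        traj, lig, rec, m = self._static_traj(6)
        e1 = score_events([self._event(0, 5)], traj, lig, rec, m, stride=1)[0]
        e2 = score_events([self._event(0, 5)], traj, lig, rec, m, stride=2)[0]
        assert e1.mean_energy_kj_mol == pytest.approx(e2.mean_energy_kj_mol, abs=1e-9)

    def test_sorted_most_favourable_first(self):
        traj, lig, rec, m = self._static_traj(4)
        # flip ligand charges so the bound pose is net attractive, then push
        # the ligand out of range in frames 2-3 so the second event scores 0
        charge = m.charge.copy()
        charge[4:] *= -1
        m2 = NonbondedModel(charge, m.sigma, m.epsilon, lj_mode=m.lj_mode)
        coords = traj.coords.copy()
        coords[2:, 4:, :] += 5.0
        traj2 = Trajectory(coords=coords, topology=traj.topology, aligned=True)
        events = score_events(
            [self._event(2, 3), self._event(0, 1)], traj2, lig, rec, m2
        )
        assert events[0].start_frame == 0
        assert events[0].mean_energy_kj_mol < 0 == events[1].mean_energy_kj_mol


class TestParameterTable:
    def test_roundtrip_and_model_build(self, tmp_path):
        import pandas as pd

        traj, lig, rec, m = fixture_3v4()
        df = pd.DataFrame(
            {
                "serial": [a.serial for a in traj.topology.atoms],
                "charge": m.charge,
                "sigma_nm": m.sigma,
                "epsilon_kj_mol": m.epsilon,
            }
        )
        path = tmp_path / "nb.tsv"
        write_parameter_table(df, path)
        model2 = read_parameter_table(path, traj.topology)
        assert np.allclose(model2.charge, m.charge, atol=1e-6)
        assert np.allclose(model2.sigma, m.sigma, atol=1e-6)
        e1 = interaction_energy(traj, 0, lig, rec, m)
        e2 = interaction_energy(traj, 0, lig, rec, model2)
        assert e1.total_kj_mol == pytest.approx(e2.total_kj_mol, rel=1e-5)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("serial\tcharge\n1\t0.0\n")
        traj, *_ = fixture_3v4()
        with pytest.raises(ValueError, match="columns"):
            read_parameter_table(path, traj.topology)
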