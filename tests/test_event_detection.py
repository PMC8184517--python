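"""Diagonal-block detection, event filtering, fingerprints, and site grouping."""

import numpy as np
import pytest

from bindscout.event_detection import (
    BindingEvent,
    ContactFingerprint,
    contact_fingerprint,
    detect_diagonal_blocks,
    filter_events,
    group_events_into_sites,
)
from bindscout.rmsd_map import RMSDMatrix, ligand_rmsd_matrix
from bindscout.structures_io import AtomRecord, SelectionMask, Topology, Trajectory
from bindscout.validation import (
    brute_force_contacts,
    epoch_recovery_experiment,
    interval_jaccard,
    null_trajectory_experiment,
)
from conftest import two_molecule_trajectory


def matrix_from(values):
    return RMSDMatrix(
        values=np.asarray(values, dtype=float),
        frame_spacing_ns=1.0,
        ligand_mask=SelectionMask([0]),
    )


class TestDetectDiagonalBlocks:
    def test_zero_matrix_single_full_interval(self):
        m = matrix_from(np.zeros((50, 50)))
        assert detect_diagonal_blocks(m) == [(0, 49)]

    def test_two_planted_blocks(self):
        v = np.full((60, 60), 1.0)
        np.fill_diagonal(v, 0.0)
        for lo, hi in ((0, 19), (35, 59)):
            v[lo : hi + 1, lo : hi + 1] = 0.1
            np.fill_diagonal(v[lo : hi + 1, lo : hi + 1], 0.0)
        intervals = detect_diagonal_blocks(matrix_from(v))
        assert len(intervals) == 2
        for got, planted in zip(intervals, [(0, 19), (35, 59)]):
            assert interval_jaccard(got, planted) >= 0.95

    def test_boundary_frame_absorption_is_at_most_one(self):
        # the fill criterion lets a dense block of L >= 19 frames absorb a
        # single unrelated neighbour frame ((L-1)/(L+1) >= 0.9), never two
        v = np.full((40, 40), 1.0)
        np.fill_diagonal(v, 0.0)
        v[0:20, 0:20] = 0.1
        np.fill_diagonal(v, 0.0)
        assert detect_diagonal_blocks(matrix_from(v)) == [(0, 20)]

    def test_uniformly_high_matrix_gives_nothing(self):
        v = np.full((40, 40), 0.8)
        np.fill_diagonal(v, 0.0)
        assert detect_diagonal_blocks(matrix_from(v)) == []

    def test_short_blocks_dropped_by_min_frames(self):
        v = np.full((30, 30), 1.0)
        np.fill_diagonal(v, 0.0)
        v[5:15, 5:15] = 0.1  # 10 frames < min_frames=20
        np.fill_diagonal(v, 0.0)
        assert detect_diagonal_blocks(matrix_from(v)) == []
        assert detect_diagonal_blocks(matrix_from(v), min_frames=10) == [(5, 14)]

    def test_intervals_non_overlapping_and_right_maximal(self, rng):
        for _ in range(10):
            # random symmetric matrix with planted pockets of low values
            n = 60
            v = rng.uniform(0.4, 1.2, size=(n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0.0)
            m = matrix_from(v)
            B = m.below(0.5)
            intervals = detect_diagonal_blocks(m, min_frames=5)
            prev_end = -1
            for (i, j) in intervals:
                assert i > prev_end
                prev_end = j
                if j + 1 < n and not any(i2 == j + 1 for i2, _ in intervals):
                    sub = B[i : j + 2, i : j + 2]
                    L = j - i + 2
                    fill = (sub.sum() - L) / 2 / (L * (L - 1) / 2)
                    assert fill < 0.9  # one more frame would dilute the block


class TestFilterEvents:
    def test_bound_ligand_retained(self, masks_two_molecule):
        lig, rec = masks_two_molecule
        traj = two_molecule_trajectory([(0.3, 0.0, 0.0)] * 30)
        m = ligand_rmsd_matrix(traj, lig)
        events = filter_events([(0, 29)], traj, m, lig, rec)
        assert len(events) == 1
        ev = events[0]
        assert (ev.start_frame, ev.end_frame) == (0, 29)
        assert ev.duration_ns == pytest.approx(29.0)
        assert ev.intra_block_rmsd_median_nm == pytest.approx(0.0)

    def test_stationary_in_solvent_rejected(self, masks_two_molecule):
        lig, rec = masks_two_molecule
        traj = two_molecule_trajectory([(3.0, 0.0, 0.0)] * 30)
        m = ligand_rmsd_matrix(traj, lig)
        assert filter_events([(0, 29)], traj, m, lig, rec) == []

    def test_short_event_rejected_by_duration(self, masks_two_molecule):
        lig, rec = masks_two_molecule
        traj = two_molecule_trajectory([(0.3, 0.0, 0.0)] * 10)
        m = ligand_rmsd_matrix(traj, lig)
        assert filter_events([(0, 9)], traj, m, lig, rec, min_duration_ns=20.0) == []

    def test_frame_count_mismatch_guard(self, masks_two_molecule):
        lig, rec = masks_two_molecule
        traj = two_molecule_trajectory([(0.3, 0.0, 0.0)] * 5)
        m = matrix_from(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="mismatch"):
            filter_events([(0, 3)], traj, m, lig, rec)

    def test_representative_frame_is_medoid(self, masks_two_molecule):
        lig, rec = masks_two_molecule
        # ligand drifts 0->0.04 nm; middle frame minimises summed RMSD
        offsets = [(0.3, 0.0, 0.01 * k) for k in range(5)]
        traj = two_molecule_trajectory(offsets)
        m = ligand_rmsd_matrix(traj, lig)
        events = filter_events([(0, 4)], traj, m, lig, rec, min_duration_ns=1.0)
        assert events[0].representative_frame == 2


class TestContactFingerprint:
    @staticmethod
    def _fixture(dist):
        atoms = [
            AtomRecord(1, "C1", "C", "RES", 10, "R"),
            AtomRecord(2, "C1", "C", "RES", 11, "R"),
            AtomRecord(3, "C1", "C", "LIG", 1, "L"),
        ]
        frames = [[(0.0, 0, 0), (5.0, 0, 0), (dist, 0.0, 0.0)]] * 4
        traj = Trajectory(
            coords=np.asarray(frames, dtype=float), topology=Topology(atoms), aligned=True
        )
        return traj, SelectionMask([2])

    def test_just_inside_cutoff(self):
        traj, lig = self._fixture(0.44)
        fp = contact_fingerprint(traj, (0, 3), lig)
        assert fp.frequencies == {("R", 10, "RES"): 1.0}

    def test_just_outside_cutoff(self):
        traj, lig = self._fixture(0.46)
        fp = contact_fingerprint(traj, (0, 3), lig)
        assert fp.frequencies == {}

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            n_rec, n_lig = 9, 4
            atoms = [
                AtomRecord(i + 1, "C1", "C", "RES", 1 + i // 3, "R") for i in range(n_rec)
            ] + [AtomRecord(n_rec + i + 1, "C1", "C", "LIG", 1, "L") for i in range(n_lig)]
            coords = rng.uniform(0, 1.5, size=(5, n_rec + n_lig, 3))
            traj = Trajectory(coords=coords, topology=Topology(atoms), aligned=True)
            lig = SelectionMask(np.arange(n_rec, n_rec + n_lig))
            rec = SelectionMask(np.arange(n_rec))
            fp = contact_fingerprint(traj, (0, 4), lig, receptor_mask=rec)
            ref = brute_force_contacts(traj, (0, 4), lig.indices.tolist(),
                                       rec.indices.tolist(), 0.45)
            assert fp.frequencies == pytest.approx(ref)

    def test_frequency_range_enforced(self):
        with pytest.raises(ValueError):
            ContactFingerprint(frequencies={("A", 1, "RES"): 1.5})

    def test_empty_interval_rejected(self):
        traj, lig = self._fixture(0.3)
        with pytest.raises(ValueError, match="empty"):
            contact_fingerprint(traj, (3, 2), lig)


class TestGrouping:
    @staticmethod
    def _events_at(offsets, spacing_ns=1.0):
        """One event per offset; representative frames hold the given ligand poses."""
        frames = [[(off, 0.0, 0.0)] for off in offsets]
        atoms = [AtomRecord(1, "C1", "C", "LIG", 1, "L")]
        traj = Trajectory(
            coords=np.asarray(frames, dtype=float), topology=Topology(atoms), aligned=True
        )
        fp = ContactFingerprint(frequencies={("R", 1, "RES"): 1.0})
        events = [
            BindingEvent(
                start_frame=i,
                end_frame=i,
                frame_spacing_ns=spacing_ns,
                representative_frame=i,
                intra_block_rmsd_median_nm=0.0,
                contact_fingerprint=fp,
            )
            for i in range(len(offsets))
        ]
        return events, traj, SelectionMask([0])

    def test_nearby_events_share_a_site(self):
        events, traj, lig = self._events_at([0.0, 0.2])
        sites = group_events_into_sites(events, traj, lig)
        assert len(sites) == 1
        assert len(sites[0].events) == 2

    def test_distant_events_split(self):
        events, traj, lig = self._events_at([0.0, 3.0])
        sites = group_events_into_sites(events, traj, lig)
        assert len(sites) == 2

    def test_single_linkage_chains(self):
        # pairwise pose RMSDs 0.3, 0.3, 0.6: chained into one site
        events, traj, lig = self._events_at([0.0, 0.3, 0.6])
        sites = group_events_into_sites(events, traj, lig)
        assert len(sites) == 1

    def test_labels_follow_energy_rank(self):
        events, traj, lig = self._events_at([0.0, 3.0])
        events[0].mean_energy_kj_mol = -10.0
        events[1].mean_energy_kj_mol = -200.0
        sites = group_events_into_sites(events, traj, lig)
        assert [s.label for s in sites] == ["a", "b"]
        assert sites[0].best_energy_kj_mol == -200.0

    def test_consensus_residues_majority_rule(self):
        events, traj, lig = self._events_at([0.0, 0.1, 0.2])
        events[0].contact_fingerprint = ContactFingerprint({("R", 1, "RES"): 1.0})
        events[1].contact_fingerprint = ContactFingerprint(
            {("R", 1, "RES"): 1.0, ("R", 2, "RES"): 0.6}
        )
        events[2].contact_fingerprint = ContactFingerprint({("R", 3, "RES"): 1.0})
        sites = group_events_into_sites(events, traj, lig)
        assert sites[0].consensus_residues == {("R", 1, "RES")}

    def test_no_events_rejected(self):
        _, traj, lig = self._events_at([0.0])
        with pytest.raises(ValueError):
            group_events_into_sites([], traj, lig)


class TestGroundTruthRecovery:
    """Scaled-down planted-epoch recovery; the full-size experiment runs in acceptance."""

    def test_planted_epochs_recovered(self):
        out = epoch_recovery_experiment(n_runs=8, base_seed=42, n_frames=1000)
        assert out["recovered_pct"] == 100.0
        assert out["min_jaccard"] >= 0.8

    def test_no_events_in_pure_diffusion(self):
        assert null_trajectory_experiment(n_runs=10, base_seed=42, n_frames=500) == 0

    def test_interval_jaccard_definition(self):
        assert interval_jaccard((0, 9), (0, 9)) == 1.0
        assert interval_jaccard((0, 9), (5, 14)) == pytest.approx(5 / 15)
        assert interval_jaccard((0, 9), (20, 29)) == 0.0
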