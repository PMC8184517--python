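"""Independent brute-force oracles and ground-truth recovery experiments.

The oracles here are deliberately naive double-loop reimplementations of the
pipeline's vectorised computations (RMSD matrix, contact fingerprint,
interaction energy) and are used only to cross-check them.  The experiment
routines generate synthetic data with known ground truth, run the pipeline,
and measure recovery; they back both the test suite and the acceptance
script.
"""

from __future__ import annotations

import math

import numpy as np

from . import energetics, event_detection, probe_ms, rmsd_map, structures_io, synthetic_data

__all__ = [
    "interval_jaccard",
    "brute_force_rmsd",
    "brute_force_contacts",
    "brute_force_interaction_energy",
    "epoch_recovery_experiment",
    "null_trajectory_experiment",
    "rmsd_matrix_oracle_error",
    "contact_fingerprint_oracle_mismatches",
    "interaction_energy_oracle_error",
    "energy_ranking_experiment",
    "ms_recovery_experiment",
]


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard overlap of two inclusive frame intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union


# --- naive oracles ---------------------------------------------------------

def brute_force_rmsd(xi: np.ndarray, xj: np.ndarray) -> float:
    """Positional RMSD between two conformations, plain python loop."""
    total = 0.0
    for a in range(len(xi)):
        for d in range(3):
            total += (xi[a][d] - xj[a][d]) ** 2
    return math.sqrt(total / len(xi))


def brute_force_contacts(
    traj: structures_io.Trajectory,
    interval: tuple[int, int],
    ligand_indices: list[int],
    receptor_indices: list[int],
    cutoff_nm: float,
) -> dict[tuple[str, int, str], float]:
    """All-pairs per-frame contact frequencies, no spatial indexing."""
    res_of = {}
    for i in receptor_indices:
        a = traj.topology.atoms[i]
        res_of[i] = (a.chain, a.res_id, a.res_name)
    counts: dict[tuple[str, int, str], int] = {}
    start, end = interval
    for f in range(start, end + 1):
        touched = set()
        for i in receptor_indices:
            for j in ligand_indices:
                d = math.dist(traj.coords[f, i], traj.coords[f, j])
                if d <= cutoff_nm:
                    touched.add(res_of[i])
        for key in touched:
            counts[key] = counts.get(key, 0) + 1
    n = end - start + 1
    return {k: c / n for k, c in counts.items()}


def _oracle_pair_lj(r: float, sig: float, eps: float, model: energetics.NonbondedModel) -> float:
    """Pair LJ term written out independently (per inverse-power force switch)."""
    if r > model.r_cut:
        return 0.0
    c12 = 4.0 * eps * sig**12
    c6 = 4.0 * eps * sig**6
    if model.lj_mode == "plain_cutoff":
        return c12 / r**12 - c6 / r**6
    total = 0.0
    for coeff, p in ((c12, 12), (-c6, 6)):
        rs, rc = model.r_switch, model.r_cut
        A = -p * ((p + 4) * rc - (p + 1) * rs) / (rc ** (p + 2) * (rc - rs) ** 2)
        B = p * ((p + 3) * rc - (p + 1) * rs) / (rc ** (p + 2) * (rc - rs) ** 3)
        C = 1.0 / rc**p - A / 3.0 * (rc - rs) ** 3 - B / 4.0 * (rc - rs) ** 4
        if r <= rs:
            total += coeff * (1.0 / r**p - C)
        else:
            dr = r - rs
            total += coeff * (1.0 / r**p - A / 3.0 * dr**3 - B / 4.0 * dr**4 - C)
    return total


def brute_force_interaction_energy(
    traj: structures_io.Trajectory,
    frame: int,
    ligand_indices: list[int],
    receptor_indices: list[int],
    model: energetics.NonbondedModel,
) -> tuple[float, float]:
    """(LJ, Coulomb) over all inter-molecular pairs, plain python loops."""
    lj = 0.0
    coul = 0.0
    for i in ligand_indices:
        for j in receptor_indices:
            r = math.dist(traj.coords[frame, i], traj.coords[frame, j])
            sig = 0.5 * (model.sigma[i] + model.sigma[j])
            eps = math.sqrt(model.epsilon[i] * model.epsilon[j])
            lj += _oracle_pair_lj(r, sig, eps, model)
            if r <= model.r_cut:
                coul += energetics.COULOMB_KE * model.charge[i] * model.charge[j] / r
    return lj, coul


# --- shared setup ----------------------------------------------------------

def _standard_masks(traj: structures_io.Trajectory):
    ligand = structures_io.select_atoms(traj.topology, "resname LIG and heavy")
    lig_set = set(ligand.indices.tolist())
    receptor = structures_io.SelectionMask(
        [i for i in traj.topology.heavy_indices() if i not in lig_set]
    )
    return ligand, receptor


def _model_from_params(traj, params) -> energetics.NonbondedModel:
    by = params.set_index("serial")
    charge = np.array([by.loc[a.serial, "charge"] for a in traj.topology.atoms])
    sigma = np.array([by.loc[a.serial, "sigma_nm"] for a in traj.topology.atoms])
    eps = np.array([by.loc[a.serial, "epsilon_kj_mol"] for a in traj.topology.atoms])
    return energetics.NonbondedModel(charge, sigma, eps)


def _detect(traj, ligand, receptor):
    matrix = rmsd_map.ligand_rmsd_matrix(traj, ligand, assume_aligned=True)
    intervals = event_detection.detect_diagonal_blocks(matrix)
    return matrix, event_detection.filter_events(intervals, traj, matrix, ligand, receptor)


# --- experiments -----------------------------------------------------------

def epoch_recovery_experiment(
    n_runs: int = 100, base_seed: int = 0, n_frames: int = 1000
) -> dict:
    """Plant 1-3 epochs of 20-200 frames per trajectory; measure recovery.

    An epoch counts as recovered when some reported event overlaps it with
    interval Jaccard >= 0.8.
    """
    n_epochs = 0
    n_recovered = 0
    jaccards = []
    for k in range(n_runs):
        rng = np.random.default_rng(base_seed + k)
        plan = synthetic_data.sample_epoch_plan(n_frames, int(rng.integers(1, 4)), rng)
        cfg = synthetic_data.SyntheticTrajectoryConfig(
            n_frames=n_frames, planted_events=plan, seed=base_seed + k
        )
        traj, truth, _ = synthetic_data.generate_binding_trajectory(cfg)
        ligand, receptor = _standard_masks(traj)
        _, events = _detect(traj, ligand, receptor)
        got = [(e.start_frame, e.end_frame) for e in events]
        for t in truth:
            n_epochs += 1
            j = max(
                (interval_jaccard((t["start_frame"], t["end_frame"]), g) for g in got),
                default=0.0,
            )
            jaccards.append(j)
            if j >= 0.8:
                n_recovered += 1
    return {
        "n_epochs": n_epochs,
        "recovered_pct": 100.0 * n_recovered / n_epochs,
        "mean_jaccard": float(np.mean(jaccards)),
        "min_jaccard": float(np.min(jaccards)),
    }


def null_trajectory_experiment(
    n_runs: int = 100, base_seed: int = 0, n_frames: int = 1000
) -> int:
    """Total events reported across pure-diffusion trajectories (expect 0)."""
    total = 0
    for k in range(n_runs):
        cfg = synthetic_data.SyntheticTrajectoryConfig(
            n_frames=n_frames, planted_events=[], seed=base_seed + k
        )
        traj, _, _ = synthetic_data.generate_binding_trajectory(cfg)
        ligand, receptor = _standard_masks(traj)
        _, events = _detect(traj, ligand, receptor)
        total += len(events)
    return total


def rmsd_matrix_oracle_error(n_fixtures: int = 50, seed: int = 0) -> float:
    """Max relative deviation of the RMSD matrix from the double-loop oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        n_frames = int(rng.integers(3, 8))
        k = int(rng.integers(2, 9))
        coords = rng.uniform(0, 3, size=(n_frames, k, 3))
        atoms = [
            structures_io.AtomRecord(i + 1, f"C{i}", "C", "LIG", 1, "L") for i in range(k)
        ]
        traj = structures_io.Trajectory(
            coords=coords, topology=structures_io.Topology(atoms), aligned=True
        )
        mask = structures_io.SelectionMask(np.arange(k))
        values = rmsd_map.ligand_rmsd_matrix(traj, mask).values
        for i in range(n_frames):
            for j in range(n_frames):
                ref = brute_force_rmsd(coords[i], coords[j])
                worst = max(worst, abs(values[i, j] - ref) / max(1.0, ref))
    return worst


def _random_two_molecule_fixture(rng):
    """Small ligand + receptor with random coordinates and parameters."""
    n_lig = int(rng.integers(3, 7))
    n_rec = int(rng.integers(6, 15))
    n_res = max(2, n_rec // 3)
    atoms = []
    for i in range(n_rec):
        atoms.append(
            structures_io.AtomRecord(i + 1, f"C{i % 4 + 1}", "C", "RES", 1 + i % n_res, "R")
        )
    for i in range(n_lig):
        atoms.append(
            structures_io.AtomRecord(n_rec + i + 1, f"C{i + 1}", "C", "LIG", 1, "L")
        )
    n_frames = int(rng.integers(2, 6))
    coords = rng.uniform(0, 2.0, size=(n_frames, n_rec + n_lig, 3))
    # keep molecules from coinciding exactly (r = 0 is unphysical)
    coords[:, n_rec:, :] += 0.05
    traj = structures_io.Trajectory(
        coords=coords, topology=structures_io.Topology(atoms), aligned=True
    )
    ligand = structures_io.SelectionMask(np.arange(n_rec, n_rec + n_lig))
    receptor = structures_io.SelectionMask(np.arange(n_rec))
    n = n_rec + n_lig
    model = energetics.NonbondedModel(
        charge=rng.uniform(-0.5, 0.5, size=n),
        sigma=rng.uniform(0.2, 0.35, size=n),
        epsilon=rng.uniform(0.1, 1.0, size=n),
        lj_mode="switched" if rng.random() < 0.5 else "plain_cutoff",
    )
    return traj, ligand, receptor, model


def contact_fingerprint_oracle_mismatches(n_fixtures: int = 50, seed: int = 0) -> int:
    """Count fixtures where the fingerprint differs from the all-pairs oracle."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_fixtures):
        traj, ligand, receptor, _ = _random_two_molecule_fixture(rng)
        interval = (0, traj.n_frames - 1)
        fp = event_detection.contact_fingerprint(
            traj, interval, ligand, traj.topology, cutoff_nm=0.45, receptor_mask=receptor
        )
        ref = brute_force_contacts(
            traj, interval, ligand.indices.tolist(), receptor.indices.tolist(), 0.45
        )
        same = set(fp.frequencies) == set(ref) and all(
            abs(fp.frequencies[k] - ref[k]) < 1e-12 for k in ref
        )
        if not same:
            mismatches += 1
    return mismatches


def interaction_energy_oracle_error(n_fixtures: int = 50, seed: int = 0) -> float:
    """Max relative deviation of interaction_energy from the double-loop oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        traj, ligand, receptor, model = _random_two_molecule_fixture(rng)
        frame = int(rng.integers(0, traj.n_frames))
        got = energetics.interaction_energy(traj, frame, ligand, receptor, model)
        lj, coul = brute_force_interaction_energy(
            traj, frame, ligand.indices.tolist(), receptor.indices.tolist(), model
        )
        for a, b in ((got.lj_kj_mol, lj), (got.coulomb_kj_mol, coul)):
            worst = max(worst, abs(a - b) / max(1.0, abs(b)))
    return worst


def energy_ranking_experiment(n_runs: int = 100, base_seed: int = 0) -> int:
    """Trajectories with one charged-pocket and one neutral-pocket epoch.

    Returns how many runs rank the charged-pocket event most favourable.
    """
    n_correct = 0
    for k in range(n_runs):
        plan = [(0, 50, 120, 0.05), (1, 200, 270, 0.05)]  # pocket 0 charged, 1 neutral
        cfg = synthetic_data.SyntheticTrajectoryConfig(
            n_frames=400, planted_events=plan, seed=base_seed + k
        )
        traj, _, params = synthetic_data.generate_binding_trajectory(cfg)
        ligand, receptor = _standard_masks(traj)
        _, events = _detect(traj, ligand, receptor)
        if len(events) != 2:
            continue
        model = _model_from_params(traj, params)
        events = energetics.score_events(events, traj, ligand, receptor, model)
        if events[0].start_frame == 50:
            n_correct += 1
    return n_correct


def ms_recovery_experiment(n_runs: int = 20, base_seed: int = 0) -> dict:
    """Labelled-peptide recovery and decoy false positives on synthetic runs."""
    n_planted = 0
    n_recovered = 0
    n_decoys = 0
    n_false = 0
    for k in range(n_runs):
        rng = np.random.default_rng(base_seed + k)
        protein = synthetic_data.random_protein(300, rng)
        positions = sorted(int(p) for p in rng.choice(300, size=3, replace=False) + 1)
        cfg = synthetic_data.SyntheticMSConfig(
            protein_sequence=protein,
            labeled_positions=positions,
            precursor_noise_ppm=5.0,
            seed=base_seed + k,
        )
        spectra, truth = synthetic_data.generate_labeled_ms_run(cfg)
        peptides = probe_ms.tryptic_digest(protein, missed_cleavages=2)
        candidates = probe_ms.match_modified_precursors(peptides, spectra, tol_ppm=10.0)
        flagged = probe_ms.diagnostic_ion_screen(spectra, cfg.reporter_mzs)
        candidates = probe_ms.rank_candidates(candidates, flagged)
        got = {(c.scan_id, c.peptide.sequence) for c in candidates}
        for t in truth:
            n_planted += 1
            if (t["scan_id"], t["sequence"]) in got:
                n_recovered += 1
        n_decoys += sum(1 for s in spectra if s.scan_id.startswith("DECOY"))
        n_false += sum(1 for c in candidates if c.scan_id.startswith("DECOY"))
    return {
        "n_planted": n_planted,
        "recovered_pct": 100.0 * n_recovered / n_planted,
        "n_decoys": n_decoys,
        "false_positives": n_false,
    }
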