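"""Ground-truthed synthetic inputs for both pipeline arms.

Trajectory arm: a rigid toy receptor scaffold (three well-separated pseudo-
residue pockets with distinct charge patterns) plus a small rigid ligand
that performs a reflected Gaussian random walk through the box, interrupted
by planted "binding epochs" during which its pose is pinned to a pocket
anchor plus isotropic positional jitter.  This reproduces the statistical
structure the detector assumes — stationary low-RMSD diagonal blocks on a
diffusive background — without integrating any forces.

MS arm: the protein is digested in silico, peptides covering chosen labelled
positions receive the +416.1348 Da probe adduct, and MS2 spectra are emitted
with the theoretical precursor m/z (plus bounded ppm noise), backbone b/y
ions, reporter ions, and random noise peaks; decoy spectra come from
unlabelled peptides without adduct or reporters.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .probe_ms import (
    PROBE_ADDUCT,
    PROTON_MASS,
    RESIDUE_MASS,
    WATER_MONOISOTOPIC,
    Modification,
    Peptide,
    SpectrumMS2,
    modified_precursor_mz,
    peptide_monoisotopic_mass,
    tryptic_digest,
    write_mgf,
)
from .structures_io import AtomRecord, Topology, Trajectory

__all__ = [
    "SyntheticTrajectoryConfig",
    "SyntheticMSConfig",
    "ToyReceptor",
    "build_toy_receptor",
    "build_toy_ligand",
    "sample_epoch_plan",
    "generate_binding_trajectory",
    "random_protein",
    "generate_labeled_ms_run",
]


# --- toy receptor/ligand scaffold -----------------------------------------

@dataclass
class ToyReceptor:
    """Rigid pseudo-atom scaffold with pocket anchor points and parameters."""

    coords: np.ndarray  # (n_atoms, 3) nm
    atoms: list[AtomRecord]
    params: pd.DataFrame  # serial / charge / sigma_nm / epsilon_kj_mol
    pocket_anchors: np.ndarray  # (n_pockets, 3) nm


#: per-atom charge of each pocket: one strongly charged, one neutral, one weak
POCKET_CHARGES = (-0.25, 0.0, -0.05)
POCKET_ANCHORS = np.array(
    [[1.5, 1.5, 2.0], [4.5, 1.5, 2.0], [3.0, 4.5, 2.0]]
)
_LIG_SIGMA = 0.30  # nm
_LIG_EPS = 0.30  # kJ/mol


def build_toy_receptor() -> ToyReceptor:
    """Three 20-atom pockets (5 pseudo-residues of 4 atoms) around fixed anchors.

    Each pocket is two rings of 10 atoms (radius 0.5 nm, z offset +-0.25 nm)
    centred on its anchor, so a ligand parked at the anchor sits in heavy-atom
    contact range without steric clashes.  Pocket 1 carries a strong negative
    charge, pocket 2 is neutral, pocket 3 weakly charged.
    """
    coords = []
    atoms = []
    rows = []
    serial = 1
    res_id = 1
    for p, (anchor, q) in enumerate(zip(POCKET_ANCHORS, POCKET_CHARGES)):
        ring = []
        for z_off in (-0.25, 0.25):
            for k in range(10):
                ang = 2 * np.pi * k / 10 + (0.3 if z_off > 0 else 0.0)
                ring.append(anchor + [0.5 * np.cos(ang), 0.5 * np.sin(ang), z_off])
        for k, xyz in enumerate(ring):
            if k % 4 == 0 and k > 0:
                res_id += 1
            coords.append(xyz)
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=f"C{k % 4 + 1}",
                    element="C",
                    res_name=f"PK{p + 1}",
                    res_id=res_id,
                    chain="R",
                )
            )
            rows.append((serial, q, _LIG_SIGMA, _LIG_EPS))
            serial += 1
        res_id += 1
    params = pd.DataFrame(rows, columns=["serial", "charge", "sigma_nm", "epsilon_kj_mol"])
    return ToyReceptor(
        coords=np.asarray(coords), atoms=atoms, params=params, pocket_anchors=POCKET_ANCHORS.copy()
    )


def build_toy_ligand(first_serial: int) -> tuple[np.ndarray, list[AtomRecord], pd.DataFrame]:
    """A rigid 8-atom cross-shaped ligand (net charge +0.8 e), centred at origin."""
    template = np.array(
        [
            [0.2, 0.0, 0.0],
            [-0.2, 0.0, 0.0],
            [0.0, 0.2, 0.0],
            [0.0, -0.2, 0.0],
            [0.0, 0.0, 0.15],
            [0.0, 0.0, -0.15],
            [0.1, 0.1, 0.0],
            [-0.1, -0.1, 0.0],
        ]
    )
    atoms = [
        AtomRecord(
            serial=first_serial + k,
            name=f"C{k + 1}",
            element="C",
            res_name="LIG",
            res_id=1,
            chain="L",
        )
        for k in range(len(template))
    ]
    params = pd.DataFrame(
        [(first_serial + k, 0.1, _LIG_SIGMA, _LIG_EPS) for k in range(len(template))],
        columns=["serial", "charge", "sigma_nm", "epsilon_kj_mol"],
    )
    return template, atoms, params


# --- trajectory generation -------------------------------------------------

@dataclass
class SyntheticTrajectoryConfig:
    """Study conditions for a planted-epoch trajectory.

    Defaults mirror the analysis settings of the emulated experiment: 1 ns
    frame spacing and positional jitter well below the 0.5 nm detection
    threshold.  The free-ligand diffusion step is the per-axis displacement
    per frame; the default 1.0 nm corresponds to sqrt(2 D dt) for a
    drug-sized molecule in water (D ~ 0.5e-9 m^2/s) sampled every 1 ns, so
    an unbound ligand decorrelates from frame to frame.
    """

    n_frames: int = 1000
    frame_spacing_ns: float = 1.0
    planted_events: list[tuple[int, int, int, float]] = field(default_factory=list)
    #: each planted event is (site_index, start_frame, end_frame, jitter_sigma_nm)
    diffusion_step_nm: float = 1.0
    box_extent_nm: float = 6.0
    receptor_jitter_sigma_nm: float = 0.0
    #: free-walk steps keeping any ligand atom closer than this to a receptor
    #: atom are resampled, emulating steric exclusion (real frames never clash)
    steric_clearance_nm: float = 0.28
    seed: int = 0

    def __post_init__(self) -> None:
        last_end = None
        for site, start, end, sigma in sorted(self.planted_events, key=lambda e: e[1]):
            if not 0 <= start <= end < self.n_frames:
                raise ValueError(f"planted interval [{start}, {end}] out of range")
            if last_end is not None and start <= last_end:
                raise ValueError("planted intervals overlap")
            if sigma < 0:
                raise ValueError("jitter sigma must be >= 0")
            last_end = end


def sample_epoch_plan(
    n_frames: int,
    n_events: int,
    rng: np.random.Generator,
    min_len: int = 20,
    max_len: int = 200,
    n_sites: int = 3,
    jitter_sigma_nm: float = 0.05,
    gap: int = 30,
) -> list[tuple[int, int, int, float]]:
    """Draw non-overlapping epochs (with diffusive gaps) for a trajectory config."""
    lengths = rng.integers(min_len, max_len + 1, size=n_events)
    occupied = int(lengths.sum()) + gap * n_events
    if occupied > n_frames:
        raise ValueError("epochs do not fit in the trajectory")
    slack = n_frames - occupied
    offsets = np.sort(rng.integers(0, slack + 1, size=n_events))
    events = []
    cum_len = 0
    for k in range(n_events):
        start = int(offsets[k]) + gap * (k + 1) + cum_len
        end = start + int(lengths[k]) - 1
        site = int(rng.integers(0, n_sites))
        events.append((site, start, end, jitter_sigma_nm))
        cum_len += int(lengths[k])
    return events


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (single bounce is enough for small steps)."""
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    return np.clip(x, lo, hi)


def generate_binding_trajectory(
    config: SyntheticTrajectoryConfig,
) -> tuple[Trajectory, list[dict], pd.DataFrame]:
    """Generate a trajectory with planted binding epochs plus its ground truth.

    Returns the trajectory (receptor + ligand), the planted-event list as
    dicts, and the full nonbonded parameter table for both molecules.
    """
    rng = np.random.default_rng(config.seed)
    receptor = build_toy_receptor()
    n_rec = len(receptor.atoms)
    lig_template, lig_atoms, lig_params = build_toy_ligand(first_serial=n_rec + 1)

    epoch_of_frame = {}
    for site, start, end, sigma in config.planted_events:
        for f in range(start, end + 1):
            epoch_of_frame[f] = (site, sigma)

    margin = 0.4
    lo, hi = margin, config.box_extent_nm - margin
    coords = np.empty((config.n_frames, n_rec + len(lig_template), 3))
    free_pos = rng.uniform(lo, hi, size=3)

    from scipy.spatial import cKDTree

    rec_tree = cKDTree(receptor.coords)
    lig_radius = float(np.max(np.linalg.norm(lig_template, axis=1)))

    def clashes(centre: np.ndarray) -> bool:
        # cheap prefilter on the bounding sphere, exact check only near it
        if rec_tree.query(centre, k=1)[0] > lig_radius + config.steric_clearance_nm:
            return False
        d, _ = cKDTree(lig_template + centre).query(receptor.coords, k=1)
        return bool(np.min(d) < config.steric_clearance_nm)

    for f in range(config.n_frames):
        rec = receptor.coords
        if config.receptor_jitter_sigma_nm > 0:
            rec = rec + rng.normal(0.0, config.receptor_jitter_sigma_nm, size=rec.shape)
        coords[f, :n_rec] = rec

        if f in epoch_of_frame:
            site, sigma = epoch_of_frame[f]
            centre = receptor.pocket_anchors[site] + rng.normal(0.0, sigma, size=3)
            free_pos = receptor.pocket_anchors[site]  # walk resumes from the pocket
        else:
            for _ in range(50):  # resample clashing steps (excluded volume)
                trial = _reflect(
                    free_pos + rng.normal(0.0, config.diffusion_step_nm, size=3), lo, hi
                )
                if not clashes(trial):
                    free_pos = trial
                    break
            centre = free_pos
        coords[f, n_rec:] = lig_template + centre

    topology = Topology(receptor.atoms + lig_atoms)
    traj = Trajectory(
        coords=coords, topology=topology, frame_spacing_ns=config.frame_spacing_ns
    )
    params = pd.concat([receptor.params, lig_params], ignore_index=True)
    truth = [
        {"site_index": site, "start_frame": start, "end_frame": end, "jitter_sigma_nm": sigma}
        for site, start, end, sigma in sorted(config.planted_events, key=lambda e: e[1])
    ]
    return traj, truth, params


# --- MS generation ---------------------------------------------------------

@dataclass
class SyntheticMSConfig:
    """Study conditions for a labelled MS run."""

    protein_sequence: str
    labeled_positions: list[int] = field(default_factory=list)
    reporter_mzs: list[float] = field(default_factory=lambda: [239.0886, 353.1227, 417.1421])
    precursor_noise_ppm: float = 3.0
    n_decoy_spectra: int = 100
    n_noise_peaks: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.protein_sequence)
        for p in self.labeled_positions:
            if not 1 <= p <= n:
                raise ValueError(f"labelled position {p} outside sequence (1-{n})")
        if self.precursor_noise_ppm < 0:
            raise ValueError("precursor noise must be >= 0")


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Random protein with realistic K/R density so tryptic peptides are MS-sized."""
    alphabet = np.array(list("ACDEFGHILMNPQSTVWY"))
    seq = list(rng.choice(alphabet, size=length))
    # sprinkle cleavage sites roughly every 10 residues
    for i in range(5, length, 10):
        seq[i] = "K" if rng.random() < 0.5 else "R"
    return "".join(seq)


def _backbone_ions(sequence: str) -> list[float]:
    """Singly charged b- and y-ion m/z of the unmodified backbone."""
    masses = [RESIDUE_MASS[aa] for aa in sequence]
    prefix = np.cumsum(masses)
    ions = []
    for i in range(1, len(sequence)):
        ions.append(prefix[i - 1] + PROTON_MASS)  # b_i
        ions.append(prefix[-1] - prefix[i - 1] + WATER_MONOISOTOPIC + PROTON_MASS)  # y_{n-i}
    return ions


def generate_labeled_ms_run(
    config: SyntheticMSConfig,
    mod: Modification = PROBE_ADDUCT,
) -> tuple[list[SpectrumMS2], list[dict]]:
    """Emit MS2 spectra for probe-labelled peptides plus unlabelled decoys.

    Labelled peptides are the 0-missed-cleavage tryptic peptides covering the
    configured positions; their spectra carry the modified precursor m/z
    (bounded uniform ppm noise), the reporter ions, backbone b/y ions, and
    random noise peaks.  Decoy spectra use unmodified peptides whose
    precursor m/z is at least 50 ppm away from every labelled target, and
    contain no reporter ions.  Returns (spectra, ground_truth).
    """
    rng = np.random.default_rng(config.seed)
    peptides = tryptic_digest(config.protein_sequence, missed_cleavages=0)

    labelled: list[Peptide] = []
    seen = set()
    for pos in config.labeled_positions:
        cover = [p for p in peptides if p.start_res <= pos <= p.end_res]
        if not cover:
            import warnings

            warnings.warn(f"labelled position {pos} not covered by any tryptic peptide")
            continue
        for p in cover:
            if p.sequence not in seen:
                seen.add(p.sequence)
                labelled.append(p)

    target_mzs = [
        modified_precursor_mz(peptide_monoisotopic_mass(p.sequence), mod.monoisotopic_mass_da, z)
        for p in labelled
        for z in (2, 3, 4)
    ]

    spectra: list[SpectrumMS2] = []
    truth: list[dict] = []
    for k, pep in enumerate(labelled):
        z = int(rng.choice([2, 3, 4]))
        theo = modified_precursor_mz(
            peptide_monoisotopic_mass(pep.sequence), mod.monoisotopic_mass_da, z
        )
        noise = rng.uniform(-config.precursor_noise_ppm, config.precursor_noise_ppm)
        observed = theo * (1.0 + noise * 1e-6)
        peaks = [(mz, 1000.0) for mz in config.reporter_mzs]
        peaks += [(mz, 200.0) for mz in _backbone_ions(pep.sequence)]
        peaks += [
            (float(mz), 50.0) for mz in rng.uniform(100.0, 1500.0, size=config.n_noise_peaks)
        ]
        spectra.append(
            SpectrumMS2(
                precursor_mz=observed,
                precursor_charge=z,
                peaks=peaks,
                scan_id=f"MOD_{k:04d}",
            )
        )
        truth.append(
            {
                "sequence": pep.sequence,
                "start_res": pep.start_res,
                "end_res": pep.end_res,
                "charge": z,
                "scan_id": f"MOD_{k:04d}",
                "theoretical_mz": theo,
            }
        )

    # decoys: unlabelled, unmodified, far (>50 ppm at the spectrum's charge)
    # from every labelled target
    labelled_seqs = {p.sequence for p in labelled}
    decoy_pool = [p for p in peptides if p.sequence not in labelled_seqs and len(p.sequence) >= 5]
    n_emitted = 0
    attempt = 0
    while n_emitted < config.n_decoy_spectra and attempt < 20 * config.n_decoy_spectra:
        attempt += 1
        pep = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
        z = int(rng.choice([2, 3, 4]))
        mz = (peptide_monoisotopic_mass(pep.sequence) + z * PROTON_MASS) / z
        if any(abs(mz - t) / t * 1e6 < 50.0 for t in target_mzs):
            continue
        peaks = [(m, 200.0) for m in _backbone_ions(pep.sequence)]
        peaks += [
            (float(m), 50.0) for m in rng.uniform(100.0, 1500.0, size=config.n_noise_peaks)
        ]
        # keep noise peaks clear of the reporters so decoys are reporter-free
        peaks = [
            (m, i)
            for m, i in peaks
            if all(abs(m - rep) / rep * 1e6 > 50.0 for rep in config.reporter_mzs)
        ]
        spectra.append(
            SpectrumMS2(
                precursor_mz=mz,
                precursor_charge=z,
                peaks=peaks,
                scan_id=f"DECOY_{n_emitted:04d}",
            )
        )
        n_emitted += 1

    return spectra, truth


# --- file emission ---------------------------------------------------------

def write_ms_run(
    spectra: list[SpectrumMS2], truth: list[dict], mgf_path: str | Path, truth_path: str | Path
) -> None:
    write_mgf(spectra, mgf_path)
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def write_trajectory_run(
    traj: Trajectory,
    truth: list[dict],
    params: pd.DataFrame,
    pdb_path: str | Path,
    truth_path: str | Path,
    params_path: str | Path,
) -> None:
    from .energetics import write_parameter_table
    from .structures_io import write_multimodel_pdb

    write_multimodel_pdb(traj, pdb_path)
    write_parameter_table(params, params_path)
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
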