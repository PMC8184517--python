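"""Protein-ligand nonbonded interaction energies for ranking binding events.

The score is the sum over all inter-molecular atom pairs of a Lennard-Jones
term and a Coulomb term, with Lorentz-Berthelot combination rules:

    V_LJ(r)   = 4 eps_ij [ (sig_ij / r)^12 - (sig_ij / r)^6 ]
    V_C(r)    = k_e q_i q_j / r,   k_e = 138.935458 kJ mol^-1 nm e^-2

Two LJ truncation modes are supported.  ``plain_cutoff`` truncates the bare
potential at ``r_cut`` (useful for closed-form checks).  ``switched``
applies the standard force-switching construction to each inverse-power
term separately: the force of a term c/r^p is modified on (r_switch, r_cut]
by a cubic polynomial in (r - r_switch),

    F_sw(r) = p c / r^(p+1) + c A (r - r_switch)^2 + c B (r - r_switch)^3,
    A = -p [ (p+4) r_c - (p+1) r_s ] / [ r_c^(p+2) (r_c - r_s)^2 ],
    B =  p [ (p+3) r_c - (p+1) r_s ] / [ r_c^(p+2) (r_c - r_s)^3 ],

chosen so that force and potential are continuous and both vanish exactly at
``r_cut``; integrating gives the potential, with a constant shift applied
for r <= r_switch.  Electrostatics use a plain Coulomb cutoff at ``r_cut``:
for the purpose of ranking events by interaction energy the long-range
reciprocal-space contribution is deliberately omitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures_io import SelectionMask, Topology, Trajectory

COULOMB_KE = 138.935458  # kJ mol^-1 nm e^-2; 1/(4 pi eps0) in MD units

__all__ = [
    "COULOMB_KE",
    "NonbondedModel",
    "EnergyBreakdown",
    "read_parameter_table",
    "write_parameter_table",
    "lj_pair_energy",
    "coulomb_pair_energy",
    "interaction_energy",
    "score_events",
]


@dataclass
class NonbondedModel:
    """Per-atom nonbonded parameters plus truncation settings.

    Arrays are indexed by topology atom index; ``charge`` in elementary
    charges, ``sigma`` in nm, ``epsilon`` in kJ/mol.  Atoms with no entry in
    the source table carry NaN and trigger an error if ever used.
    """

    charge: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    r_switch: float = 1.0
    r_cut: float = 1.2
    lj_mode: str = "switched"

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if not 0 < self.r_switch <= self.r_cut:
            raise ValueError("need 0 < r_switch <= r_cut")
        if self.lj_mode not in ("switched", "plain_cutoff"):
            raise ValueError(f"unknown lj_mode {self.lj_mode!r}")
        with np.errstate(invalid="ignore"):
            if np.any(self.epsilon < 0):
                raise ValueError("epsilon must be >= 0")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be > 0")

    def check_coverage(self, topology: Topology, mask: SelectionMask) -> None:
        """Raise if any atom in ``mask`` lacks parameters, naming the atom."""
        for i in mask.indices:
            if np.isnan(self.charge[i]) or np.isnan(self.sigma[i]) or np.isnan(self.epsilon[i]):
                a = topology.atoms[i]
                raise KeyError(
                    f"no nonbonded parameters for atom serial {a.serial} "
                    f"({a.res_name}{a.res_id}:{a.name})"
                )


@dataclass(frozen=True)
class EnergyBreakdown:
    """LJ + Coulomb interaction energy of one frame, in kJ/mol."""

    lj_kj_mol: float
    coulomb_kj_mol: float

    @property
    def total_kj_mol(self) -> float:
        return self.lj_kj_mol + self.coulomb_kj_mol


def read_parameter_table(
    path: str | Path,
    topology: Topology,
    r_switch: float = 1.0,
    r_cut: float = 1.2,
    lj_mode: str = "switched",
) -> NonbondedModel:
    """Build a NonbondedModel from a TSV with columns serial/charge/sigma_nm/epsilon_kj_mol."""
    df = pd.read_csv(path, sep="\t")
    required = {"serial", "charge", "sigma_nm", "epsilon_kj_mol"}
    if not required.issubset(df.columns):
        raise ValueError(f"parameter table must have columns {sorted(required)}")
    by_serial = df.set_index("serial")
    n = topology.n_atoms
    charge = np.full(n, np.nan)
    sigma = np.full(n, np.nan)
    epsilon = np.full(n, np.nan)
    for i, atom in enumerate(topology.atoms):
        if atom.serial in by_serial.index:
            row = by_serial.loc[atom.serial]
            charge[i] = row["charge"]
            sigma[i] = row["sigma_nm"]
            epsilon[i] = row["epsilon_kj_mol"]
    return NonbondedModel(charge, sigma, epsilon, r_switch=r_switch, r_cut=r_cut, lj_mode=lj_mode)


def write_parameter_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a serial/charge/sigma_nm/epsilon_kj_mol table as TSV."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# --- pair potentials -------------------------------------------------------

def _force_switch_terms(p: int, r_s: float, r_c: float) -> tuple[float, float, float]:
    """Polynomial coefficients (A, B) and potential shift C for power p."""
    A = -p * ((p + 4) * r_c - (p + 1) * r_s) / (r_c ** (p + 2) * (r_c - r_s) ** 2)
    B = p * ((p + 3) * r_c - (p + 1) * r_s) / (r_c ** (p + 2) * (r_c - r_s) ** 3)
    C = 1.0 / r_c**p - A / 3.0 * (r_c - r_s) ** 3 - B / 4.0 * (r_c - r_s) ** 4
    return A, B, C


def _switched_power_term(r: np.ndarray, p: int, r_s: float, r_c: float) -> np.ndarray:
    """Force-switched potential of the unit-coefficient term 1/r^p, zero beyond r_c."""
    A, B, C = _force_switch_terms(p, r_s, r_c)
    out = np.zeros_like(r)
    inner = r <= r_s
    mid = (r > r_s) & (r <= r_c)
    out[inner] = 1.0 / r[inner] ** p - C
    dr = r[mid] - r_s
    out[mid] = 1.0 / r[mid] ** p - A / 3.0 * dr**3 - B / 4.0 * dr**4 - C
    return out


def lj_pair_energy(
    r: float | np.ndarray, sigma_ij: float | np.ndarray, eps_ij: float | np.ndarray,
    model: NonbondedModel,
) -> float | np.ndarray:
    """Lennard-Jones pair energy (kJ/mol) under the model's truncation mode."""
    scalar = np.isscalar(r)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    sigma_ij = np.broadcast_to(np.asarray(sigma_ij, dtype=float), r.shape)
    eps_ij = np.broadcast_to(np.asarray(eps_ij, dtype=float), r.shape)

    c12 = 4.0 * eps_ij * sigma_ij**12
    c6 = 4.0 * eps_ij * sigma_ij**6
    if model.lj_mode == "plain_cutoff":
        out = np.where(r <= model.r_cut, c12 / r**12 - c6 / r**6, 0.0)
    else:
        out = c12 * _switched_power_term(r, 12, model.r_switch, model.r_cut)
        out -= c6 * _switched_power_term(r, 6, model.r_switch, model.r_cut)
    return float(out[0]) if scalar else out


def coulomb_pair_energy(
    r: float | np.ndarray, q_i: float | np.ndarray, q_j: float | np.ndarray,
    model: NonbondedModel,
) -> float | np.ndarray:
    """Plain-cutoff Coulomb pair energy (kJ/mol)."""
    scalar = np.isscalar(r)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    q_i = np.broadcast_to(np.asarray(q_i, dtype=float), r.shape)
    q_j = np.broadcast_to(np.asarray(q_j, dtype=float), r.shape)
    out = np.where(r <= model.r_cut, COULOMB_KE * q_i * q_j / r, 0.0)
    return float(out[0]) if scalar else out


# --- frame and event scoring ----------------------------------------------

def interaction_energy(
    traj: Trajectory,
    frame: int,
    ligand_mask: SelectionMask,
    receptor_mask: SelectionMask,
    model: NonbondedModel,
    method: str = "neighbor",
) -> EnergyBreakdown:
    """Total ligand-receptor nonbonded energy of one frame.

    ``method='neighbor'`` restricts the pair sum to a KD-tree neighbour list
    at ``r_cut`` (both potentials vanish beyond it, so the result equals the
    all-pairs sum, available as ``method='all_pairs'``).
    """
    model.check_coverage(traj.topology, ligand_mask)
    model.check_coverage(traj.topology, receptor_mask)

    li = ligand_mask.indices
    ri = receptor_mask.indices
    L = traj.coords[frame, li]
    R = traj.coords[frame, ri]

    if method == "neighbor":
        pairs = cKDTree(L).query_ball_tree(cKDTree(R), r=model.r_cut)
        ii: list[int] = []
        jj: list[int] = []
        for a, neigh in enumerate(pairs):
            ii.extend([a] * len(neigh))
            jj.extend(neigh)
        if not ii:
            return EnergyBreakdown(0.0, 0.0)
        ia = np.asarray(ii)
        ja = np.asarray(jj)
        r = np.linalg.norm(L[ia] - R[ja], axis=1)
    elif method == "all_pairs":
        diff = L[:, None, :] - R[None, :, :]
        r = np.sqrt(np.sum(diff**2, axis=2)).ravel()
        ia, ja = np.meshgrid(np.arange(len(li)), np.arange(len(ri)), indexing="ij")
        ia = ia.ravel()
        ja = ja.ravel()
    else:
        raise ValueError(f"unknown method {method!r}")

    sig = 0.5 * (model.sigma[li][ia] + model.sigma[ri][ja])  # Lorentz
    eps = np.sqrt(model.epsilon[li][ia] * model.epsilon[ri][ja])  # Berthelot
    lj = float(np.sum(lj_pair_energy(r, sig, eps, model)))
    coul = float(np.sum(coulomb_pair_energy(r, model.charge[li][ia], model.charge[ri][ja], model)))
    return EnergyBreakdown(lj_kj_mol=lj, coulomb_kj_mol=coul)


def score_events(
    events: list,
    traj: Trajectory,
    ligand_mask: SelectionMask,
    receptor_mask: SelectionMask,
    model: NonbondedModel,
    stride: int = 1,
) -> list:
    """Attach mean (and extreme) frame energies to events; sort most favourable first."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    scored = []
    for ev in events:
        frames = range(ev.start_frame, ev.end_frame + 1, stride)
        totals = [
            interaction_energy(traj, f, ligand_mask, receptor_mask, model).total_kj_mol
            for f in frames
        ]
        ev.mean_energy_kj_mol = float(np.mean(totals))
        ev.min_energy_kj_mol = float(np.min(totals))
        ev.max_energy_kj_mol = float(np.max(totals))
        scored.append(ev)
    scored.sort(key=lambda e: e.mean_energy_kj_mol)
    return scored
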