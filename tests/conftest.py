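import numpy as np
import pytest

from bindscout.structures_io import AtomRecord, SelectionMask, Topology, Trajectory


def make_pdb_text(frames, atoms):
    """Render frames (list of (k,3) arrays, nm) + AtomRecords as multi-model PDB text."""
    lines = []
    for f, coords in enumerate(frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for a, xyz in zip(atoms, np.asarray(coords) * 10.0):
            lines.append(
                f"ATOM  {a.serial:5d}  {a.name:<3.3s} {a.res_name:<3.3s} "
                f"{a.chain:1.1s}{a.res_id:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
                f"{a.element:>2.2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tripeptide_topology():
    """Three residues, each with N/CA/C plus one hydrogen."""
    atoms = []
    serial = 1
    for res_id, res_name in ((1, "ALA"), (2, "GLY"), (3, "SER")):
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("HA", "H")):
            atoms.append(AtomRecord(serial, name, element, res_name, res_id, "A"))
            serial += 1
    return Topology(atoms)


def two_molecule_trajectory(lig_offsets, receptor_xyz=(0.0, 0.0, 0.0)):
    """One receptor atom fixed at receptor_xyz, one ligand atom at per-frame offsets."""
    atoms = [
        AtomRecord(1, "C1", "C", "REC", 1, "R"),
        AtomRecord(2, "C1", "C", "LIG", 1, "L"),
    ]
    frames = []
    for off in lig_offsets:
        frames.append([receptor_xyz, off])
    return Trajectory(
        coords=np.asarray(frames, dtype=float),
        topology=Topology(atoms),
        aligned=True,
    )


@pytest.fixture
def masks_two_molecule():
    return SelectionMask([1]), SelectionMask([0])  # ligand, receptor
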