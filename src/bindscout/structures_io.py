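"""Trajectory and topology I/O, atom selection, and rigid-body superposition.

The canonical on-disk trajectory format is multi-model PDB (one MODEL/ENDMDL
block per frame, identical atom order in every model).  Coordinates are
converted to nanometres on read and kept in nm internally; residue numbers
are preserved verbatim from the input.

Periodic boundary conditions are NOT handled: trajectories are assumed to be
pre-wrapped with molecules whole, as is typical of post-processed MD output.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

ANGSTROM_PER_NM = 10.0

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "SelectionMask",
    "SuperpositionResult",
    "SelectionError",
    "PDBFormatError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "load_binary_trajectory",
    "select_atoms",
    "kabsch_superpose",
    "align_trajectory",
]


class PDBFormatError(ValueError):
    """Raised for unparseable or internally inconsistent PDB input."""


class SelectionError(ValueError):
    """Raised for a syntax error in a selection expression."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology, as read from the source file."""

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Topology:
    """Ordered atom list plus a derived residue table."""

    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise PDBFormatError("duplicate atom serials in topology")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residues(self) -> dict[tuple[str, int, str], np.ndarray]:
        """Map (chain, res_id, res_name) -> array of atom indices, in file order."""
        table: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            table.setdefault((a.chain, a.res_id, a.res_name), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in table.items()}

    def heavy_indices(self) -> np.ndarray:
        return np.asarray([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)


@dataclass(frozen=True)
class SelectionMask:
    """Sorted, unique atom indices into a Topology."""

    indices: np.ndarray
    empty: bool = field(init=False)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("selection indices must be 1-D")
        if idx.size and (np.any(np.diff(np.sort(idx)) == 0)):
            raise ValueError("selection indices must be unique")
        object.__setattr__(self, "indices", np.sort(idx))
        object.__setattr__(self, "empty", idx.size == 0)

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class Trajectory:
    """Coordinates in nm, shape (frames, atoms, 3), with topology metadata.

    ``aligned`` records whether frames have been superposed onto a common
    receptor reference (see :func:`align_trajectory`); downstream RMSD-map
    code refuses unaligned input unless explicitly overridden.
    """

    coords: np.ndarray
    topology: Topology
    frame_spacing_ns: float = 1.0
    aligned: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate/topology atom count mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.frame_spacing_ns <= 0:
            raise ValueError("frame_spacing_ns must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform mapping a mobile point set onto a reference.

    ``transformed = mobile @ rotation.T + translation``; the rotation is
    proper (det = +1) and rmsd_nm is the residual after the fit.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_nm: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# --- PDB I/O ---------------------------------------------------------------

def _infer_element(name_field: str, element_field: str) -> str:
    """Element from columns 77-78 when present, else first alphabetic of the name."""
    el = element_field.strip()
    if el:
        return el.capitalize()
    for ch in name_field.strip():
        if ch.isalpha():
            return ch.upper()
    raise PDBFormatError(f"cannot infer element from atom name {name_field!r}")


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or " "
        res_id = int(line[22:26])
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
        element = _infer_element(line[12:16], line[76:78] if len(line) >= 78 else "")
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"unparseable ATOM/HETATM record at line {lineno}: {exc}") from exc
    return AtomRecord(serial, name, element, res_name, res_id, chain), xyz / ANGSTROM_PER_NM


def read_multimodel_pdb(path: str | Path, frame_spacing_ns: float = 1.0) -> Trajectory:
    """Read a multi-model PDB file into a Trajectory (coordinates in nm).

    Every MODEL block must contain the same atoms in the same order; a file
    with no MODEL records is read as a single frame.  The topology is taken
    from the first model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    frames: list[list[np.ndarray]] = []
    atoms: list[AtomRecord] = []
    current: list[np.ndarray] | None = None  # frame under construction inside MODEL
    implicit: list[np.ndarray] = []  # atoms of a MODEL-less single-frame file

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if current is not None:
                    raise PDBFormatError(f"nested MODEL at line {lineno}")
                if implicit:
                    raise PDBFormatError(f"MODEL after bare ATOM records at line {lineno}")
                current = []
            elif rec == "ENDMDL":
                if current is None:
                    raise PDBFormatError(f"ENDMDL without MODEL at line {lineno}")
                frames.append(current)
                current = None
            elif rec in ("ATOM", "HETATM"):
                atom, xyz = _parse_atom_line(line, lineno)
                if current is not None:
                    current.append(xyz)
                    if not frames:
                        atoms.append(atom)
                elif frames:
                    raise PDBFormatError(f"ATOM outside MODEL block at line {lineno}")
                else:
                    implicit.append(xyz)
                    atoms.append(atom)
    if current is not None:  # unterminated final MODEL: accept
        frames.append(current)
    if not frames and implicit:
        frames = [implicit]

    if not frames or not frames[0]:
        raise PDBFormatError(f"no ATOM/HETATM records in {path}")

    n_atoms = len(frames[0])
    for k, fr in enumerate(frames):
        if len(fr) != n_atoms:
            raise PDBFormatError(
                f"inconsistent atom count between models: model 1 has {n_atoms}, "
                f"model {k + 1} has {len(fr)}"
            )

    coords = np.asarray([np.vstack(fr) for fr in frames])
    return Trajectory(coords=coords, topology=Topology(atoms), frame_spacing_ns=frame_spacing_ns)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as multi-model PDB (coordinates back-converted to A)."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a, xyz in zip(traj.topology.atoms, traj.coords[f] * ANGSTROM_PER_NM):
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {a.serial:5d} {name:<4.4s} {a.res_name:<3.3s} "
                    f"{a.chain:1.1s}{a.res_id:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"  1.00  0.00          {a.element:>2.2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def load_binary_trajectory(
    traj_path: str | Path, top_path: str | Path, frame_spacing_ns: float = 1.0
) -> Trajectory:
    """Load XTC/DCD (+ topology file) via mdtraj behind the same Trajectory contract."""
    import mdtraj  # optional dependency; multi-model PDB needs no extra install

    mt = mdtraj.load(str(traj_path), top=str(top_path))
    atoms = [
        AtomRecord(
            serial=a.serial if a.serial is not None else a.index + 1,
            name=a.name,
            element=(a.element.symbol if a.element is not None else a.name[0]),
            res_name=a.residue.name,
            res_id=a.residue.resSeq,
            chain=str(a.residue.chain.chain_id or " "),
        )
        for a in mt.topology.atoms
    ]
    return Trajectory(
        coords=np.asarray(mt.xyz, dtype=float),
        topology=Topology(atoms),
        frame_spacing_ns=frame_spacing_ns,
    )


# --- selection mini-language ----------------------------------------------

_RESID_RE = re.compile(r"^(\d+)(?:-(\d+))?$")


def select_atoms(topology: Topology, expr: str) -> SelectionMask:
    """Evaluate a selection expression against a topology.

    Grammar: clauses joined by ``and``; each clause is one of
    ``ca`` (atom name CA), ``heavy`` (element != H), ``resname X``,
    ``chain X``, ``resid A-B`` (or a single ``resid A``).
    An empty result is legal; check ``mask.empty``.
    """
    tokens = expr.split()
    if not tokens:
        raise SelectionError("empty selection expression")

    clauses: list[list[str]] = [[]]
    for tok in tokens:
        if tok.lower() == "and":
            if not clauses[-1]:
                raise SelectionError(f"misplaced 'and' in {expr!r}")
            clauses.append([])
        else:
            clauses[-1].append(tok)
    if not clauses[-1]:
        raise SelectionError(f"trailing 'and' in {expr!r}")

    keep = np.ones(topology.n_atoms, dtype=bool)
    for clause in clauses:
        kw = clause[0].lower()
        if kw == "ca" and len(clause) == 1:
            m = np.asarray([a.name == "CA" for a in topology.atoms])
        elif kw == "heavy" and len(clause) == 1:
            m = np.asarray([a.is_heavy for a in topology.atoms])
        elif kw == "resname" and len(clause) == 2:
            m = np.asarray([a.res_name == clause[1] for a in topology.atoms])
        elif kw == "chain" and len(clause) == 2:
            m = np.asarray([a.chain == clause[1] for a in topology.atoms])
        elif kw == "resid" and len(clause) == 2:
            g = _RESID_RE.match(clause[1])
            if not g:
                raise SelectionError(f"bad resid range {clause[1]!r}")
            lo = int(g.group(1))
            hi = int(g.group(2)) if g.group(2) else lo
            m = np.asarray([lo <= a.res_id <= hi for a in topology.atoms])
        else:
            raise SelectionError(f"cannot parse clause {' '.join(clause)!r}")
        keep &= m

    return SelectionMask(np.flatnonzero(keep))


# --- superposition ---------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference`` (Kabsch).

    Returns the proper rotation and translation minimising the RMSD between
    the transformed mobile set and the reference.  Reflections are never
    returned; a near-degenerate (collinear) reference triggers a warning.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (k, 3)")
    k = mobile.shape[0]
    if k < 3:
        raise ValueError("need at least 3 atoms for superposition")

    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc

    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1e-300):
        warnings.warn("degenerate (collinear) reference geometry in superposition")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T

    transformed = P @ R.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((transformed - reference) ** 2, axis=1))))
    translation = rc - mc @ R.T
    return SuperpositionResult(rotation=R, translation=translation, rmsd_nm=rmsd)


def align_trajectory(traj: Trajectory, ref_mask: SelectionMask) -> Trajectory:
    """Superpose every frame onto frame 0 using the atoms in ``ref_mask``.

    Frame 0 is left untouched.  The returned trajectory is marked aligned.
    """
    if len(ref_mask) < 3:
        raise ValueError("alignment mask must select at least 3 atoms")
    idx = ref_mask.indices
    ref = traj.coords[0, idx]
    out = traj.coords.copy()
    for f in range(1, traj.n_frames):
        sup = kabsch_superpose(out[f, idx], ref)
        out[f] = sup.apply(out[f])
    return replace(traj, coords=out, aligned=True)
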