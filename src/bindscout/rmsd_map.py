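"""Time-time RMSD matrix of the ligand over a receptor-aligned trajectory.

Entry (i, j) is the positional RMSD of the ligand heavy atoms between frames
i and j, computed WITHOUT per-pair re-superposition: after the receptor has
been aligned onto a common reference, a translation of the whole ligand
registers as RMSD, so a contiguous low-RMSD block on the diagonal marks a
period in which the ligand is stationary relative to the receptor - a
candidate binding event.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structures_io import SelectionMask, Trajectory

__all__ = ["RMSDMatrix", "ligand_rmsd_matrix", "render_rmsd_map"]


@dataclass
class RMSDMatrix:
    """N x N symmetric matrix of inter-frame ligand RMSD values (nm)."""

    values: np.ndarray
    frame_spacing_ns: float
    ligand_mask: SelectionMask

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("RMSD matrix entries must be finite and non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("RMSD matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("RMSD matrix diagonal must be zero")
        self.values = v

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])

    def below(self, threshold_nm: float) -> np.ndarray:
        """Boolean matrix of entries strictly below ``threshold_nm``."""
        return self.values < threshold_nm

    def to_csv(self, path: str | Path) -> None:
        """Dense CSV; header row holds frame times in ns."""
        times = np.arange(self.n_frames) * self.frame_spacing_ns
        with open(path, "w") as fh:
            fh.write(",".join(f"{t:g}" for t in times) + "\n")
            for row in self.values:
                fh.write(",".join(f"{x:.6f}" for x in row) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, ligand_mask: SelectionMask | None = None) -> "RMSDMatrix":
        with open(path) as fh:
            times = np.asarray([float(x) for x in fh.readline().split(",")])
            values = np.loadtxt(fh, delimiter=",")
        values = np.atleast_2d(values)
        spacing = float(times[1] - times[0]) if times.size > 1 else 1.0
        if ligand_mask is None:
            ligand_mask = SelectionMask(np.arange(1))
        return cls(values=values, frame_spacing_ns=spacing, ligand_mask=ligand_mask)


def ligand_rmsd_matrix(
    traj: Trajectory, ligand_mask: SelectionMask, *, assume_aligned: bool = False
) -> RMSDMatrix:
    """All-against-all positional RMSD of the masked ligand atoms.

    The trajectory must have passed through :func:`align_trajectory`
    (receptor superposed onto frame 0); pass ``assume_aligned=True`` to
    override the guard for input aligned elsewhere.
    """
    if ligand_mask.empty:
        raise ValueError("ligand mask is empty")
    if not traj.aligned and not assume_aligned:
        raise ValueError(
            "trajectory is not marked aligned; run align_trajectory first or "
            "pass assume_aligned=True"
        )
    k = len(ligand_mask)
    X = traj.coords[:, ligand_mask.indices, :].reshape(traj.n_frames, 3 * k)
    sq = pdist(X, metric="sqeuclidean") / k
    values = np.sqrt(squareform(sq))
    return RMSDMatrix(
        values=values, frame_spacing_ns=traj.frame_spacing_ns, ligand_mask=ligand_mask
    )


def render_rmsd_map(
    matrix: RMSDMatrix, threshold_nm: float = 0.5, image_path: str | Path | None = None
) -> np.ndarray:
    """Threshold the matrix (strictly below ``threshold_nm``) and optionally plot it.

    Returns the boolean matrix; if ``image_path`` is given the map is rendered
    with frames on both axes, below-threshold entries dark on white.
    """
    if threshold_nm <= 0:
        raise ValueError("threshold must be positive")
    B = matrix.below(threshold_nm)
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        extent_ns = matrix.n_frames * matrix.frame_spacing_ns
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(
            B,
            cmap="Greys",
            origin="lower",
            interpolation="none",
            extent=(0, extent_ns, 0, extent_ns),
        )
        ax.set_xlabel("time (ns)")
        ax.set_ylabel("time (ns)")
        ax.set_title(f"ligand RMSD < {threshold_nm:g} nm")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return B
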