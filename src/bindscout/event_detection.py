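"""Binding-event detection, filtering, contact fingerprints, and site grouping.

A binding event is a maximal contiguous run of frames whose pairwise ligand
RMSD values form a dense low-RMSD block on the diagonal of the time-time
RMSD matrix.  Candidate blocks are then filtered: the ligand must actually
touch the receptor (heavy-atom contact within 0.45 nm in at least half of
the block's frames) and the event must last a minimum time, which removes
stationary-in-solvent clusters and brief encounters.  Retained events are
fingerprinted by contacted receptor residue and grouped into sites by
single-linkage clustering of their representative (medoid) ligand poses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .rmsd_map import RMSDMatrix
from .structures_io import SelectionMask, Topology, Trajectory

__all__ = [
    "ContactFingerprint",
    "BindingEvent",
    "BindingSite",
    "detect_diagonal_blocks",
    "contact_fingerprint",
    "filter_events",
    "group_events_into_sites",
    "events_to_table",
    "sites_to_table",
]


@dataclass
class ContactFingerprint:
    """Per-residue contact frequency over an event's frames.

    A receptor residue is in contact in a frame iff any of its heavy atoms
    lies within the cutoff of any ligand heavy atom; the frequency is the
    fraction of the event's frames with contact, in [0, 1].
    """

    frequencies: dict[tuple[str, int, str], float]

    def __post_init__(self) -> None:
        for key, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"contact frequency out of range for {key}: {f}")

    @property
    def residues(self) -> set[tuple[str, int, str]]:
        return set(self.frequencies)


@dataclass
class BindingEvent:
    """A contiguous stationary-ligand interval with its pose and contacts."""

    start_frame: int
    end_frame: int
    frame_spacing_ns: float
    representative_frame: int
    intra_block_rmsd_median_nm: float
    contact_fingerprint: ContactFingerprint
    mean_energy_kj_mol: float | None = None
    min_energy_kj_mol: float | None = None
    max_energy_kj_mol: float | None = None

    def __post_init__(self) -> None:
        if not self.start_frame <= self.representative_frame <= self.end_frame:
            raise ValueError("representative frame outside event interval")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    @property
    def duration_ns(self) -> float:
        return (self.end_frame - self.start_frame) * self.frame_spacing_ns


@dataclass
class BindingSite:
    """A cluster of binding events sharing a ligand pose."""

    label: str
    events: list[BindingEvent]
    consensus_residues: set[tuple[str, int, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("a site needs at least one event")

    @property
    def best_energy_kj_mol(self) -> float | None:
        energies = [e.mean_energy_kj_mol for e in self.events if e.mean_energy_kj_mol is not None]
        return min(energies) if energies else None

    @property
    def total_duration_ns(self) -> float:
        return sum(e.duration_ns for e in self.events)


def detect_diagonal_blocks(
    matrix: RMSDMatrix,
    threshold_nm: float = 0.5,
    fill_fraction: float = 0.9,
    min_frames: int = 20,
) -> list[tuple[int, int]]:
    """Greedy detection of dense low-RMSD diagonal blocks.

    Starting at each unconsumed frame, the block is grown forward one frame
    at a time for as long as the fraction of pairwise entries inside the
    block that are strictly below ``threshold_nm`` stays >= ``fill_fraction``.
    Blocks shorter than ``min_frames`` are discarded (their start frame is
    re-examined shifted by one).  Returned intervals are inclusive, sorted,
    and non-overlapping.
    """
    if not 0 < fill_fraction <= 1:
        raise ValueError("fill_fraction must be in (0, 1]")
    if min_frames < 2:
        raise ValueError("min_frames must be >= 2")

    B = matrix.below(threshold_nm)
    n = matrix.n_frames
    # 2-D prefix sums give O(1) below-threshold pair counts for any block
    S = np.zeros((n + 1, n + 1), dtype=np.int64)
    S[1:, 1:] = np.cumsum(np.cumsum(B.astype(np.int64), axis=0), axis=1)

    def fill(i: int, j: int) -> float:
        length = j - i + 1
        if length < 2:
            return 1.0
        inside = S[j + 1, j + 1] - S[i, j + 1] - S[j + 1, i] + S[i, i]
        below = (inside - length) // 2  # drop the (always-true) diagonal
        return below / (length * (length - 1) // 2)

    intervals: list[tuple[int, int]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and fill(i, j + 1) >= fill_fraction:
            j += 1
        if j - i + 1 >= min_frames:
            intervals.append((i, j))
            i = j + 1
        else:
            i += 1
    return intervals


def contact_fingerprint(
    traj: Trajectory,
    interval: tuple[int, int],
    ligand_mask: SelectionMask,
    topology: Topology | None = None,
    cutoff_nm: float = 0.45,
    receptor_mask: SelectionMask | None = None,
) -> ContactFingerprint:
    """Contact frequencies of receptor residues over the frames of ``interval``.

    Receptor atoms default to all heavy atoms outside the ligand mask.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    start, end = interval
    if end < start:
        raise ValueError("empty interval")
    topology = topology if topology is not None else traj.topology

    lig = set(ligand_mask.indices.tolist())
    if receptor_mask is None:
        rec_idx = np.asarray(
            [i for i in topology.heavy_indices() if i not in lig], dtype=int
        )
    else:
        rec_idx = receptor_mask.indices

    # residue membership for each receptor atom, in rec_idx order
    residues = topology.residues()
    keys = list(residues)
    atom_res = {}
    for ri, key in enumerate(keys):
        for ai in residues[key]:
            atom_res[ai] = ri
    rec_res = np.asarray([atom_res[i] for i in rec_idx], dtype=int)

    counts = np.zeros(len(keys), dtype=int)
    n_frames = end - start + 1
    for f in range(start, end + 1):
        tree = cKDTree(traj.coords[f, ligand_mask.indices])
        d, _ = tree.query(traj.coords[f, rec_idx], k=1)
        touched = np.unique(rec_res[d <= cutoff_nm])
        counts[touched] += 1

    freqs = {
        keys[ri]: counts[ri] / n_frames for ri in range(len(keys)) if counts[ri] > 0
    }
    return ContactFingerprint(frequencies=freqs)


def filter_events(
    intervals: list[tuple[int, int]],
    traj: Trajectory,
    matrix: RMSDMatrix,
    ligand_mask: SelectionMask,
    receptor_mask: SelectionMask,
    contact_cutoff_nm: float = 0.45,
    min_contact_fraction: float = 0.5,
    min_duration_ns: float = 20.0,
) -> list[BindingEvent]:
    """Drop non-binding and too-brief blocks; build BindingEvent records.

    An interval survives iff its time span >= ``min_duration_ns`` and, in at
    least ``min_contact_fraction`` of its frames, some ligand heavy atom lies
    within ``contact_cutoff_nm`` of a receptor heavy atom.  Survivors get a
    medoid representative frame, the median intra-block RMSD, and a contact
    fingerprint.
    """
    if traj.n_frames != matrix.n_frames:
        raise ValueError("trajectory/matrix frame count mismatch")
    if ligand_mask.empty or receptor_mask.empty:
        raise ValueError("ligand and receptor masks must be non-empty")

    events: list[BindingEvent] = []
    for start, end in intervals:
        span_ns = (end - start) * traj.frame_spacing_ns
        if span_ns < min_duration_ns:
            continue

        n_contact = 0
        for f in range(start, end + 1):
            tree = cKDTree(traj.coords[f, receptor_mask.indices])
            d, _ = tree.query(traj.coords[f, ligand_mask.indices], k=1)
            if np.min(d) <= contact_cutoff_nm:
                n_contact += 1
        if n_contact / (end - start + 1) < min_contact_fraction:
            continue

        block = matrix.values[start : end + 1, start : end + 1]
        representative = start + int(np.argmin(block.sum(axis=1)))
        off_diag = block[np.triu_indices(block.shape[0], k=1)]
        median_rmsd = float(np.median(off_diag)) if off_diag.size else 0.0

        fp = contact_fingerprint(
            traj,
            (start, end),
            ligand_mask,
            traj.topology,
            cutoff_nm=contact_cutoff_nm,
            receptor_mask=receptor_mask,
        )
        events.append(
            BindingEvent(
                start_frame=start,
                end_frame=end,
                frame_spacing_ns=traj.frame_spacing_ns,
                representative_frame=representative,
                intra_block_rmsd_median_nm=median_rmsd,
                contact_fingerprint=fp,
            )
        )
    return events


def group_events_into_sites(
    events: list[BindingEvent],
    traj: Trajectory,
    ligand_mask: SelectionMask,
    link_rmsd_nm: float = 0.5,
) -> list[BindingSite]:
    """Single-linkage clustering of events by representative-pose ligand RMSD.

    Site labels a, b, c, ... are assigned in ascending order of best (most
    negative) mean event energy when energies are present on every event,
    else in descending order of total event duration.
    """
    if not events:
        raise ValueError("no events to group")

    k = len(ligand_mask)
    poses = np.stack(
        [traj.coords[e.representative_frame, ligand_mask.indices].ravel() for e in events]
    )
    if len(events) == 1:
        clusters = np.asarray([1])
    else:
        diff = poses[:, None, :] - poses[None, :, :]
        rmsd = np.sqrt(np.sum(diff**2, axis=2) / k)
        Z = linkage(squareform(rmsd, checks=False), method="single")
        clusters = fcluster(Z, t=link_rmsd_nm, criterion="distance")

    groups: dict[int, list[BindingEvent]] = {}
    for ev, c in zip(events, clusters):
        groups.setdefault(int(c), []).append(ev)

    sites = [BindingSite(label="?", events=evs) for evs in groups.values()]
    have_energy = all(
        e.mean_energy_kj_mol is not None for s in sites for e in s.events
    )
    if have_energy:
        sites.sort(key=lambda s: s.best_energy_kj_mol)
    else:
        sites.sort(key=lambda s: -s.total_duration_ns)

    labelled: list[BindingSite] = []
    for rank, site in enumerate(sites):
        n_events = len(site.events)
        consensus = {
            res
            for res in set().union(*(e.contact_fingerprint.residues for e in site.events))
            if sum(res in e.contact_fingerprint.residues for e in site.events)
            >= 0.5 * n_events
        }
        labelled.append(
            BindingSite(label=_site_label(rank), events=site.events, consensus_residues=consensus)
        )
    return labelled


def _site_label(rank: int) -> str:
    """0 -> a, 25 -> z, 26 -> aa, ..."""
    label = ""
    rank += 1
    while rank:
        rank, rem = divmod(rank - 1, 26)
        label = chr(ord("a") + rem) + label
    return label


# --- tabular export --------------------------------------------------------

def events_to_table(sites: list[BindingSite]) -> list[dict]:
    """Flatten sites/events into records for TSV/JSON reports."""
    rows = []
    for site in sites:
        for k, ev in enumerate(
            sorted(
                site.events,
                key=lambda e: (
                    e.mean_energy_kj_mol is None,
                    e.mean_energy_kj_mol if e.mean_energy_kj_mol is not None else 0.0,
                    e.start_frame,
                ),
            )
        ):
            contacts = ";".join(
                f"{chain}:{res_name}{res_id}={freq:.2f}"
                for (chain, res_id, res_name), freq in sorted(
                    ev.contact_fingerprint.frequencies.items(), key=lambda kv: kv[0][1]
                )
            )
            rows.append(
                {
                    "site": site.label,
                    "event": k,
                    "start_ns": ev.start_frame * ev.frame_spacing_ns,
                    "end_ns": ev.end_frame * ev.frame_spacing_ns,
                    "duration_ns": ev.duration_ns,
                    "representative_frame": ev.representative_frame,
                    "median_rmsd_nm": round(ev.intra_block_rmsd_median_nm, 4),
                    "mean_energy_kj_mol": (
                        None
                        if ev.mean_energy_kj_mol is None
                        else round(ev.mean_energy_kj_mol, 3)
                    ),
                    "contacts": contacts,
                }
            )
    return rows


def sites_to_table(sites: list[BindingSite]) -> list[dict]:
    rows = []
    for site in sites:
        rows.append(
            {
                "site": site.label,
                "n_events": len(site.events),
                "total_duration_ns": site.total_duration_ns,
                "best_energy_kj_mol": (
                    None if site.best_energy_kj_mol is None else round(site.best_energy_kj_mol, 3)
                ),
                "consensus_residues": ";".join(
                    f"{chain}:{res_name}{res_id}"
                    for chain, res_id, res_name in sorted(site.consensus_residues,
                                                          key=lambda r: (r[0], r[1]))
                ),
            }
        )
    return rows
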