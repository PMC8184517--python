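"""End-to-end orchestration of the two analysis arms, with reproducible reports.

``run_site_discovery`` executes align -> RMSD map -> block detection ->
event filtering -> energy scoring -> site grouping on a trajectory, and
``run_probe_id`` executes digest -> precursor match -> reporter screen ->
region annotation on an MS run.  Both write deterministic TSV/JSON reports
that embed the fully resolved configuration and the package version, so two
runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from . import energetics, event_detection, probe_ms, rmsd_map, structures_io

logger = logging.getLogger("bindscout")

__all__ = ["RunConfig", "StageError", "run_site_discovery", "run_probe_id"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All pipeline thresholds with their analysis defaults.

    The defaults reproduce the emulated study's settings: 0.5 nm (5 A) RMSD
    detection threshold, 0.45 nm heavy-atom contact cutoff, LJ force switch
    1.0 -> 1.2 nm, precursor charges 2-4 at 10 ppm.
    """

    rmsd_threshold_nm: float = 0.5
    fill_fraction: float = 0.9
    min_frames: int = 20
    contact_cutoff_nm: float = 0.45
    min_contact_fraction: float = 0.5
    min_duration_ns: float = 20.0
    link_rmsd_nm: float = 0.5
    r_switch_nm: float = 1.0
    r_cut_nm: float = 1.2
    lj_mode: str = "switched"
    energy_stride: int = 1
    tol_ppm: float = 10.0
    charges: tuple[int, ...] = (2, 3, 4)
    missed_cleavages: int = 2
    min_reporter_hits: int = 1
    ligand_selection: str = "resname LIG and heavy"
    align_selection: str = "ca"
    frame_spacing_ns: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rmsd_threshold_nm",
            "fill_fraction",
            "contact_cutoff_nm",
            "min_contact_fraction",
            "r_switch_nm",
            "r_cut_nm",
            "tol_ppm",
            "frame_spacing_ns",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.charges = tuple(int(c) for c in self.charges)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["charges"] = list(self.charges)
        return d


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _write_tsv(path: Path, rows: list[dict]) -> None:
    with open(path, "w") as fh:
        if not rows:
            fh.write("\n")
            return
        cols = list(rows[0])
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join("" if row[c] is None else str(row[c]) for c in cols) + "\n")


def run_site_discovery(
    trajectory_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    params_path: str | Path | None = None,
) -> dict:
    """Trajectory arm: detect, score, and group ligand binding sites.

    Writes ``sites.tsv``, ``events.tsv``, ``report.json``, ``rmsd_map.csv``
    and ``rmsd_map.png`` into ``out_dir``; returns the report dict.  Energy
    scoring runs only when a nonbonded parameter table is supplied.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        traj = structures_io.read_multimodel_pdb(
            trajectory_path, frame_spacing_ns=config.frame_spacing_ns
        )
    except (OSError, structures_io.PDBFormatError) as exc:
        raise StageError("structures_io", str(exc)) from exc

    try:
        ligand = structures_io.select_atoms(traj.topology, config.ligand_selection)
        if ligand.empty:
            raise StageError("structures_io", "ligand selection is empty")
        align_mask = structures_io.select_atoms(traj.topology, config.align_selection)
        if len(align_mask) < 3:
            # pseudo-atom scaffolds have no CA atoms: fall back to receptor heavy
            logger.info("alignment selection too small; falling back to receptor heavy atoms")
            lig = set(ligand.indices.tolist())
            align_mask = structures_io.SelectionMask(
                [i for i in traj.topology.heavy_indices() if i not in lig]
            )
        receptor = structures_io.SelectionMask(
            [i for i in traj.topology.heavy_indices() if i not in set(ligand.indices.tolist())]
        )
        traj = structures_io.align_trajectory(traj, align_mask)
    except StageError:
        raise
    except (ValueError, structures_io.SelectionError) as exc:
        raise StageError("structures_io", str(exc)) from exc

    try:
        matrix = rmsd_map.ligand_rmsd_matrix(traj, ligand)
        matrix.to_csv(out_dir / "rmsd_map.csv")
        rmsd_map.render_rmsd_map(
            matrix, config.rmsd_threshold_nm, image_path=out_dir / "rmsd_map.png"
        )
    except ValueError as exc:
        raise StageError("rmsd_map", str(exc)) from exc

    try:
        intervals = event_detection.detect_diagonal_blocks(
            matrix,
            threshold_nm=config.rmsd_threshold_nm,
            fill_fraction=config.fill_fraction,
            min_frames=config.min_frames,
        )
        events = event_detection.filter_events(
            intervals,
            traj,
            matrix,
            ligand,
            receptor,
            contact_cutoff_nm=config.contact_cutoff_nm,
            min_contact_fraction=config.min_contact_fraction,
            min_duration_ns=config.min_duration_ns,
        )
    except ValueError as exc:
        raise StageError("event_detection", str(exc)) from exc

    if events and params_path is not None:
        try:
            model = energetics.read_parameter_table(
                params_path,
                traj.topology,
                r_switch=config.r_switch_nm,
                r_cut=config.r_cut_nm,
                lj_mode=config.lj_mode,
            )
            events = energetics.score_events(
                events, traj, ligand, receptor, model, stride=config.energy_stride
            )
        except (OSError, ValueError, KeyError) as exc:
            raise StageError("energetics", str(exc)) from exc
    elif events and params_path is None:
        logger.info("no parameter table supplied; skipping energy scoring")

    sites = (
        event_detection.group_events_into_sites(
            events, traj, ligand, link_rmsd_nm=config.link_rmsd_nm
        )
        if events
        else []
    )

    site_rows = event_detection.sites_to_table(sites)
    event_rows = event_detection.events_to_table(sites)
    _write_tsv(out_dir / "sites.tsv", site_rows)
    _write_tsv(out_dir / "events.tsv", event_rows)

    report = {
        "tool": "bindscout",
        "version": __version__,
        "arm": "site_discovery",
        "config": config.to_dict(),
        "n_frames": traj.n_frames,
        "n_intervals_detected": len(intervals),
        "n_events": len(events),
        "n_sites": len(sites),
        "sites": site_rows,
        "events": event_rows,
    }
    _write_json(out_dir / "report.json", report)
    logger.info("site discovery: %d events in %d sites", len(events), len(sites))
    return report


def run_probe_id(
    fasta_path: str | Path,
    mgf_path: str | Path,
    reporter_mzs: list[float],
    out_dir: str | Path,
    config: RunConfig | None = None,
    region_table: list[tuple[str, int, int]] | None = None,
    mod: probe_ms.Modification = probe_ms.PROBE_ADDUCT,
) -> dict:
    """MS arm: find probe-modified peptides and annotate their protein regions.

    Writes ``candidates.tsv`` and ``report.json``; returns the report dict.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        protein = probe_ms.read_fasta_sequence(fasta_path)
        spectra = probe_ms.read_mgf(mgf_path)
    except (OSError, StopIteration, ValueError) as exc:
        raise StageError("probe_ms", f"unreadable input: {exc}") from exc

    peptides = probe_ms.tryptic_digest(protein, missed_cleavages=config.missed_cleavages)
    candidates = probe_ms.match_modified_precursors(
        peptides,
        spectra,
        mod=mod,
        charges=set(config.charges),
        tol_ppm=config.tol_ppm,
    )
    flagged = probe_ms.diagnostic_ion_screen(
        spectra, reporter_mzs, tol_ppm=config.tol_ppm, min_hits=config.min_reporter_hits
    )
    candidates = probe_ms.rank_candidates(candidates, flagged)
    if region_table:
        candidates = probe_ms.map_peptides_to_regions(candidates, region_table)

    rows = [
        {
            "sequence": c.peptide.sequence,
            "start_res": c.peptide.start_res,
            "end_res": c.peptide.end_res,
            "charge": c.charge,
            "theoretical_mz": round(c.theoretical_mz, 6),
            "observed_mz": round(c.observed_mz, 6),
            "ppm_error": round(c.ppm_error, 3),
            "diagnostic_hits": ";".join(f"{mz:g}" for mz in c.diagnostic_ion_hits),
            "regions": ";".join(c.regions),
            "scan_id": c.scan_id,
        }
        for c in candidates
    ]
    _write_tsv(out_dir / "candidates.tsv", rows)

    report = {
        "tool": "bindscout",
        "version": __version__,
        "arm": "probe_id",
        "config": config.to_dict(),
        "adduct": {"formula": mod.formula, "mass_da": round(mod.monoisotopic_mass_da, 4)},
        "n_spectra": len(spectra),
        "n_peptides": len(peptides),
        "n_candidates": len(candidates),
        "n_flagged_spectra": len(flagged),
        "candidates": rows,
    }
    _write_json(out_dir / "report.json", report)
    logger.info(
        "probe id: %d candidates from %d spectra (%d reporter-flagged)",
        len(candidates),
        len(spectra),
        len(flagged),
    )
    return report
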