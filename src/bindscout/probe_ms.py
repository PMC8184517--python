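"""Identification of photoprobe-modified tryptic peptides from MS data.

The covalent photo-adduct shifts a labelled peptide's mass by a fixed offset
(for the trifluoromethyl-diazirine ivacaftor probe: C22H19F3N2O3, i.e.
+416.1348 Da).  Because the probe-peptide bond fragments preferentially in
MS2 — releasing characteristic reporter ions but destroying probe-bearing
b/y ions — identification proceeds in two steps: (1) precursor matching of
every tryptic peptide + adduct against MS1 precursor m/z at charges 2-4
within a ppm tolerance, and (2) screening the corresponding MS2 spectra for
the user-supplied diagnostic reporter m/z values.  The adduct is treated as
peptide-level (one adduct, position unknown within the peptide).
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "MONOISOTOPIC_ELEMENT_MASS",
    "RESIDUE_FORMULA",
    "WATER_MONOISOTOPIC",
    "PROTON_MASS",
    "Peptide",
    "Modification",
    "SpectrumMS2",
    "ModifiedPeptideCandidate",
    "formula_monoisotopic_mass",
    "tryptic_digest",
    "peptide_monoisotopic_mass",
    "match_modified_precursors",
    "diagnostic_ion_screen",
    "rank_candidates",
    "map_peptides_to_regions",
    "read_mgf",
    "write_mgf",
    "read_fasta_sequence",
]

# Most-abundant-isotope masses (Da), IUPAC/CODATA values.
MONOISOTOPIC_ELEMENT_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "P": 30.9737615120,
    "S": 31.9720706912,
    "Na": 22.9897692820,
    "K": 38.9637064864,
    "Cl": 34.9688526800,
    "Br": 78.9183375600,
    "I": 126.9044719000,
    "Se": 79.9165218000,
    "Fe": 55.9349375000,
}

# Amino-acid residue formulas (peptide-bonded residues, i.e. minus water).
RESIDUE_FORMULA: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

PROTON_MASS = 1.007276466622  # Da, mass of H+

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental composition string such as 'C22H19F3N2O3'.

    The empty composition has mass 0.  Unknown element symbols raise KeyError.
    """
    if not formula:
        return 0.0
    pos = 0
    total = 0.0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"unparseable formula near {formula[pos:]!r}")
        pos = m.end()
        symbol, count = m.group(1), int(m.group(2) or 1)
        if symbol not in MONOISOTOPIC_ELEMENT_MASS:
            raise KeyError(f"unknown element symbol {symbol!r} in {formula!r}")
        total += MONOISOTOPIC_ELEMENT_MASS[symbol] * count
    if pos != len(formula):
        raise ValueError(f"unparseable formula near {formula[pos:]!r}")
    return total


WATER_MONOISOTOPIC = formula_monoisotopic_mass("H2O")  # 18.010565 Da

RESIDUE_MASS: dict[str, float] = {
    aa: formula_monoisotopic_mass(f) for aa, f in RESIDUE_FORMULA.items()
}


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with 1-based inclusive positions in its parent protein."""

    sequence: str
    start_res: int
    end_res: int
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end_res - self.start_res + 1:
            raise ValueError("peptide length/position mismatch")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


@dataclass(frozen=True)
class Modification:
    """A fixed-mass covalent adduct given by its elemental composition."""

    formula: str
    monoisotopic_mass_da: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        computed = formula_monoisotopic_mass(self.formula)
        if self.monoisotopic_mass_da is None:
            object.__setattr__(self, "monoisotopic_mass_da", computed)
        elif abs(self.monoisotopic_mass_da - computed) > 1e-4:
            raise ValueError(
                f"stated mass {self.monoisotopic_mass_da} inconsistent with "
                f"formula {self.formula} ({computed:.4f})"
            )


#: The ivacaftor diazirine photoprobe adduct (+416.1348 Da).
PROBE_ADDUCT = Modification(formula="C22H19F3N2O3")


@dataclass
class SpectrumMS2:
    """One MS2 spectrum: precursor plus a peak list sorted by m/z."""

    precursor_mz: float
    precursor_charge: int
    peaks: list[tuple[float, float]]
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks)
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")

    def mz_values(self) -> list[float]:
        return [mz for mz, _ in self.peaks]


@dataclass
class ModifiedPeptideCandidate:
    peptide: Peptide
    charge: int
    theoretical_mz: float
    observed_mz: float
    ppm_error: float
    scan_id: str = ""
    diagnostic_ion_hits: list[float] = field(default_factory=list)
    regions: list[str] = field(default_factory=list)


# --- digestion and masses --------------------------------------------------

_STANDARD = set(RESIDUE_FORMULA)


def tryptic_digest(protein: str, missed_cleavages: int = 2) -> list[Peptide]:
    """In-silico trypsin digest: cleave after K/R except before P.

    Emits every peptide with 0..``missed_cleavages`` missed cleavage sites,
    with 1-based positions.  Peptides containing non-standard residues are
    skipped with a log message.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    protein = protein.upper()

    # cut points: index i means a cut between protein[i-1] and protein[i]
    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))

    peptides: list[Peptide] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavages, len(cuts))):
            seq = protein[cuts[a] : cuts[b]]
            if set(seq) - _STANDARD:
                logger.warning("skipping peptide with non-standard residues: %s", seq)
                continue
            peptides.append(
                Peptide(
                    sequence=seq,
                    start_res=cuts[a] + 1,
                    end_res=cuts[b],
                    missed_cleavages=b - a - 1,
                )
            )
    return peptides


def peptide_monoisotopic_mass(sequence: str) -> float:
    """Neutral monoisotopic peptide mass: residue masses plus one water."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    try:
        return sum(RESIDUE_MASS[aa] for aa in sequence.upper()) + WATER_MONOISOTOPIC
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in {sequence!r}") from exc


def modified_precursor_mz(peptide_mass: float, mod_mass: float, charge: int) -> float:
    return (peptide_mass + mod_mass + charge * PROTON_MASS) / charge


# --- searching -------------------------------------------------------------

def match_modified_precursors(
    peptides: list[Peptide],
    spectra: list[SpectrumMS2],
    mod: Modification = PROBE_ADDUCT,
    charges: frozenset[int] | set[int] = frozenset({2, 3, 4}),
    tol_ppm: float = 10.0,
) -> list[ModifiedPeptideCandidate]:
    """Fixed-offset precursor search: peptide + adduct vs observed precursor m/z.

    A candidate is produced for every (peptide, spectrum) pair whose
    theoretical m/z at the spectrum's charge lies within ``tol_ppm`` of the
    observed precursor; spectra with charges outside ``charges`` are ignored.
    """
    masses = [(peptide_monoisotopic_mass(p.sequence), p) for p in peptides]
    candidates: list[ModifiedPeptideCandidate] = []
    for spec in spectra:
        if spec.precursor_charge not in charges:
            continue
        for pmass, pep in masses:
            theo = modified_precursor_mz(pmass, mod.monoisotopic_mass_da, spec.precursor_charge)
            ppm = (spec.precursor_mz - theo) / theo * 1e6
            if abs(ppm) <= tol_ppm:
                candidates.append(
                    ModifiedPeptideCandidate(
                        peptide=pep,
                        charge=spec.precursor_charge,
                        theoretical_mz=theo,
                        observed_mz=spec.precursor_mz,
                        ppm_error=ppm,
                        scan_id=spec.scan_id,
                    )
                )
    return candidates


def diagnostic_ion_screen(
    spectra: list[SpectrumMS2],
    reporter_mzs: list[float],
    tol_ppm: float = 10.0,
    min_hits: int = 1,
) -> dict[str, list[float]]:
    """Flag spectra containing probe reporter ions.

    Returns scan_id -> list of matched reporter m/z for every spectrum with
    at least ``min_hits`` reporters matched within ``tol_ppm``.
    """
    if not reporter_mzs:
        raise ValueError("reporter m/z list must be non-empty")
    flagged: dict[str, list[float]] = {}
    for spec in spectra:
        mzs = spec.mz_values()
        hits = []
        for rep in reporter_mzs:
            tol = rep * tol_ppm * 1e-6
            lo = bisect.bisect_left(mzs, rep - tol)
            if lo < len(mzs) and mzs[lo] <= rep + tol:
                hits.append(rep)
        if len(hits) >= min_hits:
            flagged[spec.scan_id] = hits
    return flagged


def rank_candidates(
    candidates: list[ModifiedPeptideCandidate],
    flagged: dict[str, list[float]],
) -> list[ModifiedPeptideCandidate]:
    """Attach reporter hits and rank: flagged-spectrum matches first, then by |ppm|."""
    for c in candidates:
        c.diagnostic_ion_hits = list(flagged.get(c.scan_id, []))
    return sorted(
        candidates, key=lambda c: (0 if c.diagnostic_ion_hits else 1, abs(c.ppm_error))
    )


def map_peptides_to_regions(
    candidates: list[ModifiedPeptideCandidate],
    region_table: list[tuple[str, int, int]],
) -> list[ModifiedPeptideCandidate]:
    """Annotate each candidate with every protein region its peptide overlaps.

    ``region_table`` rows are (name, start, end) with 1-based inclusive
    ranges (e.g. ICL4 or tm8 of CFTR).
    """
    for name, start, end in region_table:
        if end < start:
            raise ValueError(f"malformed region {name!r}: {start}-{end}")
    for c in candidates:
        c.regions = [
            name
            for name, start, end in region_table
            if c.peptide.start_res <= end and c.peptide.end_res >= start
        ]
    return candidates


# --- file formats ----------------------------------------------------------

def read_mgf(path: str | Path) -> list[SpectrumMS2]:
    """Read an MGF peak-list file into SpectrumMS2 records (via pyteomics)."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            charge = int(params["charge"][0]) if "charge" in params else 0
            spectra.append(
                SpectrumMS2(
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    peaks=list(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())),
                    scan_id=str(params.get("title", f"scan_{i}")),
                )
            )
    return spectra


def write_mgf(spectra: list[SpectrumMS2], path: str | Path) -> None:
    """Write spectra as MGF with deterministic formatting."""
    with open(path, "w") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spec.scan_id}\n")
            fh.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={spec.precursor_charge}+\n")
            for mz, inten in spec.peaks:
                fh.write(f"{mz:.6f} {inten:.2f}\n")
            fh.write("END IONS\n")


def read_fasta_sequence(path: str | Path) -> str:
    """First protein sequence of a FASTA file (via Biopython)."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()
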