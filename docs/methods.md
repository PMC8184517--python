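# Methods

This note documents the models and procedures `bindscout` implements, the
parameters that matter, the assumptions baked into the synthetic-data
generators, and the numerical choices made where the design was open.

## Trajectory arm

### Coordinates, units, alignment

All internal lengths are nanometres; PDB Å are converted on read.  The
canonical trajectory format is multi-model PDB (one MODEL block per frame,
identical atom order); XTC/DCD is accepted through mdtraj behind the same
`Trajectory` contract.  Residue numbers are preserved verbatim from the
input so reported contacts map directly onto the source numbering (for
CFTR, the canonical 1480-residue sequence).

Frames are superposed onto a reference selection of frame 0 — by default
all receptor Cα atoms, configurable (the membrane-spanning-domain-only
alternative is a selection string away); pseudo-atom scaffolds without Cα
fall back to all receptor heavy atoms.  Superposition is the Kabsch SVD
solution with the reflection branch removed, and is cross-checked in the
tests against an independent quaternion-eigenvalue implementation.

The package assumes pre-wrapped, molecules-whole trajectories, as produced
by standard MD post-processing; there is **no minimum-image logic**.  A
ligand split across a periodic boundary would produce spurious RMSD and
contacts.

### Time-time RMSD matrix

Entry (i, j) is the positional RMSD of the ligand heavy atoms between
frames i and j, with **no per-pair re-superposition** and no mass
weighting: after receptor alignment, whole-ligand translation must register
as RMSD, because positional stationarity is the binding signal.
Conformational-only (re-fitted) RMSD would erase it.  The map is
thresholded strictly below 0.5 nm (5 Å); an entry exactly at threshold
does not count.

### Event detection and filtering

Blocks are grown greedily forward along the diagonal: starting from an
unconsumed frame, the block absorbs the next frame while the fraction of
pairwise entries inside the block that are below threshold stays at or
above `fill_fraction` (default 0.9); blocks shorter than `min_frames`
(default 20) are discarded.  Two consequences of this rule are intentional
and pinned by tests:

* intervals are non-overlapping and right-maximal (adding the next frame
  would dilute the block below `fill_fraction`);
* a dense block of L ≥ 19 frames can absorb at most one unrelated
  neighbouring frame, since (L−1)/(L+1) ≥ 0.9 — detected intervals may
  therefore overshoot a true binding epoch by one frame.

An event's `duration_ns` is the time spanned, (end − start) ×
frame spacing.  Candidate blocks are kept only if (a) the span is at least
`min_duration_ns` (default 20 ns — the operational meaning of "not a brief
encounter"), and (b) in at least half of the block's frames some ligand
heavy atom lies within the contact cutoff (0.45 nm, ties inclusive) of a
receptor heavy atom — the operational meaning of "actually bound" as
opposed to stationary in solvent.  Events are excluded only by duration
and contact, never by recurrence count; recurrence is rewarded at the site
level, where events from any number of trajectories aligned to a common
reference can be pooled.

Each event carries its medoid frame (minimising summed intra-block RMSD) as
a stable, deterministic representative pose, the median intra-block RMSD,
and a contact fingerprint: per receptor residue, the fraction of event
frames in which any of its heavy atoms is within 0.45 nm of any ligand
heavy atom.

### Energy scoring and site grouping

The interaction energy of a frame is the sum over all ligand×receptor atom
pairs (intra-molecular pairs never enter) of a Lennard-Jones and a Coulomb
term, with Lorentz–Berthelot combination.  Two LJ truncation modes exist:

* `switched` (default): the standard force-switching construction applied
  per inverse-power term between 1.0 and 1.2 nm, making energy and force
  continuous and both zero at the cutoff (the closed form is in the
  `energetics` module docstring and its continuity is checked numerically);
* `plain_cutoff`: bare 12-6 LJ truncated at 1.2 nm, kept because it has
  closed-form targets (zero at σ, −ε at 2^{1/6}σ).

Electrostatics use plain cutoff Coulomb at 1.2 nm with
k_e = 138.935458 kJ mol⁻¹ nm e⁻².  This is a deliberate approximation of
the real-space part of an Ewald treatment: the quantity used downstream is
the *ranking* of events, not absolute binding energies, and long-range
reciprocal-space corrections are nearly constant across poses of the same
ligand.  Absolute values should not be compared across force fields or to
experiment.

Parameters come from a plain TSV (`serial charge sigma_nm epsilon_kj_mol`)
rather than binary force-field files; exporting such a table is a one-liner
in most MD packages' topology tooling.  An event's score is the mean frame
energy over its interval (optionally strided); per-frame minima and maxima
are also stored since single-frame extremes can differ substantially from
means.  A missing parameter for any atom in use is a hard error naming the
atom.

Events are grouped into sites by single-linkage clustering of
representative-pose ligand RMSD at 0.5 nm linkage; single linkage is chosen
because binding poses of the same site drift and chain.  Sites are labelled
a, b, c, … by best (most negative) mean event energy when energies are
available, else by descending total duration; a site's consensus residues
are those contacted in at least half of its member events.

## Proteomics arm

Monoisotopic masses are computed from an embedded IUPAC element table
(proton: 1.007276466622 Da; water: 18.010565 Da); the tests cross-check
them against pyteomics.  Digestion follows the plain trypsin rule — cleave
C-terminal to K or R except before P — with up to 2 missed cleavages by
default (common search practice).  Note that this deliberately omits the
ExPASy WKP/MRP counter-exceptions.  Peptides containing non-standard
residues are skipped with a log message.

The probe adduct is treated as **peptide-level**: one adduct of composition
C22H19F3N2O3 (416.1348 Da) at an unknown position.  Position-level
localisation is impossible for this chemistry because the probe-peptide
bond cleaves preferentially in MS2, destroying probe-bearing b/y ions —
the same cleavage that makes the released reporter ions diagnostic.
Precursor matching considers charges 2-4 at 10 ppm; reporter screening
flags a spectrum when at least `min_hits` reporter m/z values (user
supplied — they depend on the probe chemistry and instrument) match a peak
within tolerance, and flagged matches rank first, then by |ppm error|.
There is no search-engine scoring or FDR estimation; the output is a
transparent candidate table meant for manual inspection, with optional
region annotation (e.g. ICL4, tm8) from a user-provided table of 1-based
inclusive ranges.

## Synthetic data: what it emulates, and what it does not

The trajectory generator plants the statistical structure the detector
assumes: a rigid 60-pseudo-atom receptor with three well-separated pockets
(rings of 20 atoms around an anchor; per-atom charges −0.25 / 0 / −0.05 e
so the pockets have distinct electrostatic signatures against the net
+0.8 e ligand), and a rigid 8-atom ligand that alternates between

* free diffusion: a reflected Gaussian walk with per-axis step 1.0 nm per
  1 ns frame — the scale of √(2DΔt) for a drug-sized solute in water
  (D ≈ 0.5×10⁻⁹ m²/s) — with steps resampled if any ligand atom would come
  within 0.28 nm of the receptor (excluded volume; real MD frames never
  interpenetrate), and
* planted epochs: pose pinned to a pocket anchor plus isotropic Gaussian
  jitter (σ per axis, default 0.05 nm, giving intra-epoch pairwise RMSD
  medians near 0.11 nm — comfortably below the 0.5 nm detection
  threshold).

Everything is deterministic given the seed.  The generator does **not**
integrate forces: there are no association/dissociation kinetics, no
ligand conformational changes, no receptor flexibility (unless a jitter is
requested), and transitions into and out of epochs are instantaneous.
Passing recovery tests therefore demonstrates that the detector finds
stationary, receptor-contacting epochs against a diffusive background at
realistic geometry and noise scales — not that it would segment slow,
partially bound, or conformationally complex real events correctly.

The MS generator digests a protein, emits spectra for the 0-missed-cleavage
peptides covering the chosen labelled positions (theoretical modified
precursor m/z with bounded uniform ppm noise, reporter ions, unmodified
backbone b/y ions, random noise peaks) and decoy spectra from unlabelled,
unmodified peptides kept ≥ 50 ppm from every target and free of reporter
peaks.  It does not model isotope envelopes, co-isolation, retention time,
or intensity realism; recovery results certify the matching arithmetic and
screening logic, not search sensitivity on real instrument data.

## Problem sizes and reproducibility

The shipped validation experiments use 100 trajectories of 1000 frames
(1-3 planted epochs of 20-200 frames each) plus 100 pure-diffusion
trajectories, 50 random fixtures per brute-force oracle comparison, 100
seeded ranking runs, and 20 synthetic MS runs (~57 planted peptides, 2000
decoys) — sizes chosen so the whole battery completes in well under a
minute on one CPU while keeping multi-hundred-event statistics.  All
randomness flows from explicit seeds; reports embed the resolved
configuration and package version, and identical config + seed produces
byte-identical TSV/JSON output.

## Known limitations

* No periodic-boundary handling (pre-wrapped input is required).
* Interaction energies are truncated-potential scores for ranking, not
  binding free energies; entropy, solvation and reciprocal-space
  electrostatics are absent by design.
* The greedy detector can overshoot an epoch boundary by one frame, and
  "maximality" is guaranteed in the forward direction only.
* Peptide candidates are unscored beyond ppm error and reporter hits; a
  match is a hypothesis, not an identification with an error rate.
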