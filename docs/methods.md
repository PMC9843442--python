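# Methods

## Scope and model

`chlassign` decides, per chlorophyll site in an atomic model, whether the
substituent at ring position C2, C3 or C7 is a formyl group (Chl *f*, *d*,
*b* respectively) or the methyl/vinyl group of Chl *a*.  Two independent
evidence channels are implemented; both operate on standard inputs (mmCIF
or PDB coordinates; MRC/CCP4 maps) and neither modifies the model.

### Coordinate language

Deposited chlorophyll components (CLA, CHL, CL7, F6C, …) name their atoms
in a dialect whose ring lettering is rotated one quadrant against IUPAC
numbering (the ring carrying the C2 methyl and C3 vinyl is the dialect's
"B" ring).  `structure_io` maps every site onto IUPAC labels (`C1`–`C20`,
`NA`–`ND`, `MG`, substituent carbons `C21`/`C31`/`C71`/`C81`, formyl
oxygens `O21`/`O31`/`O71`) once at parse time; all geometry downstream
speaks IUPAC.  The table covers the four standard component codes and is
user-extensible (JSON/TOML) because Chl *d*/*f* codes vary between
depositions.  Author chain/residue numbering identifies sites ("f:605"),
since that is how sites are discussed in the field.  Alternate conformers
collapse to the highest-occupancy one (ties: first altloc letter).

### Cone scan

For probe position CX¹ the idealized formyl-oxygen locus is generated from
internal coordinates: bond length C=O **1.22 Å**, angle C–C=O **120°**
(standard sp² carbonyl stereochemistry; both configurable), dihedral swept
in **5°** steps (72 samples).  The dihedral origin is a fixed in-ring
reference atom (C1 for C2¹, C2 for C3¹, C8 for C7¹); the choice is
arbitrary and does not affect the physically meaningful output, the peak
direction relative to the protein.  Map values are trilinearly
interpolated at the 72 points — out-of-bounds points are an error, never
padded.

Scaling (`ScaleModel`): the default `macrocycle_mean` divides each site's
samples by the mean map density at its 24 macrocycle atom centers, a
per-site occupancy/contrast proxy that makes profiles comparable across
sites, which the pooled null requires.  `zscore_local` (subtract that mean,
divide by the SD at the same atoms) is exactly invariant under positive
affine transforms of the map; `none` disables scaling.  Whether a sharpened
or unsharpened map is used is the caller's choice.

The null distribution pools **all values of all C7 scans** (the C7
substituent is a methyl in every chlorophyll) and uses the sample SD
(ddof = 1).  A site is formyl-positive when its scan **peak** strictly
exceeds **μ + 3σ**.  Every circular local maximum above the threshold is
reported, because a formyl group can plausibly occupy two orientations and
produce a double peak.  Sites with incomplete macrocycles are excluded
from scans (and the null) with a logged warning.

One step of the original protocol — maps "inverted" after alignment to a
reference chlorin — is ambiguous in the available description (hand
inversion vs density inversion) and is **not** implemented; scans here
sample the deposited map directly at each site, which is equivalent up to
that unresolved step.

### H-bond donor search

All-pairs distance scan (no spatial index; N·M is trivial and the output
is auditable): report every donor-class atom within **4.1 Å inclusive** of
the probe carbon, excluding atoms of the probed chlorophyll itself.
Default donor classes: nitrogen atoms of polymer residues (backbone and
sidechain) and Ser OG / Thr OG1 / Tyr OH hydroxyl oxygens.  Waters are
parsed but excluded by default (flag to include).  A site is
formyl-positive iff ≥ 1 hit.  The optional `exclude_engaged` filter drops
donors that already have another O/N acceptor (outside their own residue
and the probed site) within 3.5 Å — the mechanism behind Chl *d*
false positives — but is off by default to reproduce the plain benchmark.

Aromatic contacts: Phe/Tyr/Trp rings whose nearest ring atom is ≤ 3.8 Å
from the probe are classified by the probe's elevation over the
least-squares ring plane: ≤ 30° → CH–O, ≥ 60° → CHO–π, intermediate
geometries unreported.  All thresholds configurable; this channel is
reported as evidence only and enters no benchmark.

### Combined rule

Logical OR of the channels, each also reported separately.  No weighted
score is invented: the evidence types are incommensurable (map contrast vs
modeled geometry), and OR is the rule that rescues scan-negative sites in
poorly resolved regions with clearly modeled donors.

### Superposition

Kabsch (SVD) least-squares rigid superposition over the shared macrocycle
atoms (20 C + 4 N; ≥ 4 required), with proper-rotation correction and
degeneracy detection on the singular spectrum.  Tested against an
independent quaternion-eigenvalue (Horn) oracle to 1e-9.

## Synthetic fixtures

The generator emulates exactly the motifs the detectors key on:

* **Macrocycle**: an idealized planar, fourfold-symmetric chlorin solved
  once by least squares against standard bond lengths (N–Cα 1.38, Cα–Cβ
  1.44, Cβ–Cβ 1.36, Cα–meso 1.39 Å; N and meso radii 2.05 / 3.45 Å).  All
  ring bonds land in [1.3, 1.6] Å.  Substituent carbons point radially
  outward; a formyl oxygen is placed at a requested dihedral using the
  same internal-coordinate convention the scanner uses.
* **Environment**: hydroxyl (Thr OG1), sidechain N (Asn ND2), backbone N
  (Gly N), water O, or a Phe ring placed at exact probe distances, with a
  2.0 Å clash guard.  Ring orientation `in_plane` realizes CH–O geometry,
  `axial` realizes CHO–π.
* **Maps**: sums of atom-centered Gaussians; weight = atomic number,
  variance = B/(8π²) + (voxel/2)² in quadrature, so each atom's voxel
  integral is independent of B.  Defaults: B = 20 Å², voxel 0.5 Å, 5 Å
  margin.  Optional noise is white per-voxel Gaussian with SD `noise_sd`,
  seeded; the seed fully determines every output.  "SNR" in tests and the
  acceptance script means (formyl-oxygen peak density) / `noise_sd`.

What the fixtures do **not** emulate: CTF, solvent, anisotropy, local
resolution variation, or spatially correlated noise.  Passing tests
therefore demonstrate the correctness and calibration of the statistics on
idealized maps, not performance on real reconstructions; the deposited
benchmarks (run when the user supplies the files under `data/`) cover the
latter.

## Numerical choices and edge cases

* Cutoff comparisons are inclusive (≤ 4.1 Å), so boundary behavior is
  deterministic and testable (4.09 in, 4.11 out).
* Profile peak ties resolve to the smallest angle.
* Strict exceedance: peak = threshold is negative.
* Trilinear sampling errors out outside the voxel-center bounding box.
* Zero variance or zero mean in scaling raises instead of propagating NaN.
* Map axis order is canonicalized to X,Y,Z on load; origins combine the
  MRC2014 ORIGIN record with CCP4 start indices.  Non-orthogonal cells go
  through the full fractional↔Cartesian matrix.

## Calibration note on the cone-scan statistic

The classifier compares the *maximum* of 72 angular samples against
μ + 3σ of pooled *individual* values.  Under white voxel noise the
trilinear samples have position-dependent variance (pooled σ ≈ 0.63× the
voxel noise SD, samples near voxel centers at 1.0×), so the methyl
false-positive rate at strong noise is irreducibly a few percent per site
— at oxygen-peak SNR 3 the 40-site suite classifies at ≈ 94–95% over 100
noise seeds (false positives dominate; false negatives ≈ 1–2%).  This
mirrors the behavior of the statistic on real maps, where a small number
of methyl sites exceed the null in poorly resolved regions.  Noise-free
classification is error-free, and specificity in well-resolved conditions
(SNR ≳ 10) is ≥ 95% per the test suite.

## Problem sizes

Default test and acceptance runs use 40-site suites (20 formyl / 20
methyl), 100 noise seeds for the SNR experiment, 100 seeded fixtures for
the brute-force donor comparison, and ~30×30×30-voxel maps per site —
sizes at which every experiment is exact or Monte-Carlo-stable while the
whole battery completes in about a minute on one CPU.
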