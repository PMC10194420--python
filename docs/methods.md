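# Methods

This note documents the models, conventions and numerical choices behind
neuromap3d, and what the synthetic phantom does and does not establish.

## Prohormone cleavage model

Mature neuropeptides are excised from precursors by a greedy
left-to-right scan for dibasic motifs {KR, RR, KK, RK}, cutting after
the second basic residue; non-overlapping motifs are consumed as
encountered. Flanking K/R left on a fragment are trimmed
(carboxypeptidase step) and fragments outside [min_len, max_len]
(defaults 3 and 50 residues) are dropped. Monobasic cleavage exists in
insects but produces many false positives, so it is off by default and
available as a flag. Signal-peptide removal is not modelled: the
N-terminal fragment of a precursor is returned like any other candidate
and can be blacklisted by the user. PTM enumeration emits *all* variants
(unmodified, amide, pyroglutamate, both) rather than guessing one,
because real detected-peptide tables contain modified and unmodified
termini side by side; curated catalogs loaded from CSV bypass the rule
engine entirely. The rule engine is a reconstruction of standard
prohormone-convertase convention, not any specific lab's manual
procedure.

## Mass arithmetic

Residues are modelled as elemental compositions over C/H/N/O/S, which
covers the 20 canonical amino acids; isotopic fine structure, adducts
other than [M+H]+, and average masses are out of scope. Monoisotopic
element masses are CODATA/IUPAC values; residue masses and the PTM
deltas (water 18.010565; amidation −0.984016; pyroglutamate −17.026549
from Q, −18.010565 from E) are derived *exactly* from the element
masses so that the two independent mass routes — residue-mass summation
and elemental-composition summation — agree to better than 1e-9 Da (a
permanent cross-check in the test suite, plus an external comparison
against pyteomics). A useful identity follows: for a peptide that is
both Q-cyclised and amidated, water + Δamide + ΔpyroQ = 0 exactly, so
[M+H]+ is simply the residue sum plus the proton.

Protonation uses the proton mass 1.007276 Da, not the hydrogen atom:
online peptide calculators are inconsistent at the 4th decimal between
the two conventions, which is why reported masses are rounded to 3
decimals by default and external agreement is only ever claimed to
±0.001 Da. ppm errors are stored signed and ranked by magnitude;
annotation ties break toward higher peak intensity, then lower m/z.
Default matching tolerance is 5 ppm, matching magnetic-resonance MS
accuracy where all credible peptide hits fall below ~4.5 ppm. Isobar
detection groups peptides with identical elemental formulas always, and
peptides within a caller-chosen ppm gap optionally; annotation hits
carry these groups so downstream tables can mark MS1-ambiguous calls.

## MSI processing

Sections hold sparse centroided spectra per pixel; pixels that were
never acquired, or acquired empty, are carried as an explicit missing
mask and never imputed (empty spectra are also recorded as missing on
imzML round trips, since the format cannot hold zero-length arrays).
TIC normalisation scales every spectrum to the *section median* TIC,
computed over spectra with positive TIC; zero-TIC spectra are left
untouched and flagged. The median convention makes normalisation
idempotent and keeps the intensity scale interpretable. Ion images sum
intensity in a window of ±tol ppm (or Da) around the target m/z, so
total extracted intensity is monotone in the tolerance.

Spatial segmentation is k-means over channel images: spectra are binned
at 0.01 Da, the ~300 most intense bins dataset-wide become channel
images, each is smoothed with a 3×3 spatial median filter, and pixels
are clustered on the resulting vectors with a fixed seed. The channel
cap exists because dense 0.01 Da binning over 300–3,000 Da would mean
270,000 mostly-empty channels; the most-intense-bins reduction keeps
exactly the peaks that drive tissue-type separation. This segmentation
is a documented stand-in for unpublished commercial implementations and
is validated only on phantoms.

## 3D stacking and coregistration

Stacks are anisotropic: in-plane pixel size is set by the MSI raster
(tens of µm) and plane spacing by the microtome (10 µm here). Plane
placement uses documented physical z positions from a required sidecar
table — never guessed — and sections that were cut but not measured
become zero planes with `plane_mask = False`, distinguishing "not
measured" from "measured zero"; stacking never interpolates.
Coordinates are right-handed (x = columns, y = rows, z = sectioning
order), voxel-center, in µm.

The similarity transform (det +1 rotation, single positive scale,
translation) is estimated from ≥ 3 non-collinear landmark pairs by the
closed-form SVD least-squares solution with a reflection guard. Only
proportional scaling is permitted; anisotropic scaling is rejected by
construction. The fit is equivariant under rotations of either frame
and its RMS residual is invariant to pair order. Resampling is
pull-back: each target voxel samples the moving volume at the inverse-
transformed physical position, trilinear for intensities and nearest
for labels. Under trilinear interpolation, corners on gap planes or
outside the stack carry zero weight and the remaining weights are
renormalised; a voxel with no measured support (e.g. exactly on a gap
plane) is marked unmeasured rather than given an invented value. The
transform fitted on the optical stack is transferred unchanged to every
ion volume after verifying grid identity, and travels in the output
metadata as provenance.

## Anatomy and presence calls

CT volumes must have isotropic voxels. Segmentation is threshold-based
(user value, or Otsu's method as fallback) followed by removal of
26-connected components below a voxel-count floor. Volumes are voxel
count × voxel³, reported in mm³; ratios are plain percentages. Region
label volumes are consumed, not discovered — parcellation quality is
the supplier's responsibility.

The presence rule is explicit and recorded with every table: a peptide
is present in a region iff at least `min_voxels` (default 5) measured
voxels of the region exceed `frac` (default 0.2) of the ion volume's
global maximum. Published presence/absence tables of this kind are
expert visual judgments; this rule is the package's deterministic,
monotone replacement (raising either threshold can only remove calls).

## The phantom

The phantom emulates the study conditions: an ellipsoidal "head"
containing a brighter "brain" (phosphotungstic-acid-like contrast, with
Gaussian noise) holding five disjoint ellipsoidal regions (AL, OL, MB,
CX, SEG); 12 serial sections at 10 µm with two unmeasured dropouts, a
24 µm raster on a 22×22 grid; a mass range of 300–3,000 Da; and a true
pose of 10° rotation about the sectioning axis with proportional scale
1.25. Default problem size — a 60×72×72 CT at 6 µm voxels and ~4,800
spectra — was chosen so a full end-to-end run takes on the order of a
second while every region still spans several MSI pixels and dozens of
CT voxels, the regime in which presence calls are well posed.

Peptide peaks are seeded with Gaussian m/z jitter (s.d. 0.001 Da,
truncated at 3 s.d. so every seeded peak stays inside the default
matching window) only at pixels whose CT-space position falls inside
the peptide's target regions; intensities are uniform at a
signal-to-background ratio ≥ 10. Background species are a fixed set of
uniformly drawn m/z values with per-pixel uniform intensities — two
pools, one everywhere and one confined to the brain so that chemistry-
based clustering has something to find. Background draws avoid a
±0.05 Da guard band around catalog masses so that ground-truth presence
is unambiguous; the resulting density (~60 species over 2,700 Da) stays
far below one per 0.5 Da. Landmarks are exact corresponding features
under the true pose (an optional noise s.d. exists for robustness
studies). All randomness flows through one seeded generator; a fixed
config reproduces identical spectra, volumes and ground-truth tables,
and outputs carry the config hash. (Byte-identity of written imzML is
not claimed: the imzML standard embeds a fresh UUID per file.)

What phantom recovery shows: the algebra and bookkeeping of the whole
chain — windowed annotation, stacking with gaps, similarity recovery,
mask-aware resampling, presence thresholds — are correct under known
ground truth. What it does not show: performance on real tissue, where
sections distort and rupture, ion suppression varies across the
section, landmark placement carries expert error, and MSI and CT come
from different individuals. Real printed head/brain volumetrics and
region tables from any particular study therefore cannot be regenerated
from this package alone; they require the corresponding deposited
datasets and landmark files.

## Known limitations

- No MS/MS, ion mobility, adducts beyond [M+H]+, or isotopic fine
  structure; MS1 isobars are flagged, not resolved.
- No peak picking from profile data and no recalibration; inputs are
  centroided.
- No elastic or intensity-based registration; one stack-level
  similarity transform, with expert knowledge entering via the landmark
  file.
- No shrinkage correction for dehydration/critical-point-drying
  artifacts in CT specimens.
- The cleavage engine is a convention, not a learned model; unusual
  processing (e.g. non-canonical monobasic sites) needs explicit rule
  configuration.
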