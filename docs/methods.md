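# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a methods section: what is computed, under
which assumptions, which knobs matter, and what the synthetic studies do
and do not demonstrate.

## Coordinate and unit conventions

Voxel grids are numpy arrays indexed `[z, y, x]`; physical coordinates
are `[x, y, z]` vectors in nanometres, with the voxel (0,0,0) centre at
`origin`. The electron beam runs along z, the tilt axis along y, and the
support plane is a constant-z plane; heights are measured normal to it.
All tables are in nm; Ångström appears only where the field
conventionally uses it (helical rise, FSC resolutions), converted at the
boundary. MRC files store the pixel size in Å in the cell header.

## The synthetic scene generator

The generator emulates the statistical structure of pseudopodium
tomograms, not their optics. One scene is:

* **Geometry** — a bilayer tube (two Gaussian-profile leaflets, centres
  5 nm apart, σ = 0.9 nm) of radius 50 nm resting 3 nm above the support
  plane, capped by a hemisphere at the +x end (the protrusion tip) and
  open at the x = 0 volume face (the protrusion continues into the cell
  body outside the field of view — this also anchors the membrane to the
  volume boundary so the enclosed volume is well defined for normal
  estimation). Desk-scale default: 256×256×128 voxels at 1.1 nm.
* **Actin** — 15–30 near-straight filaments, 60–170 nm long, roughly
  parallel to the tube axis (4° angular jitter), packed with a 9 nm
  minimum axis separation (bundled, non-interpenetrating). Each filament
  is a 1-start helix with rise 27.6 Å and twist −166.7° per subunit
  (left-handed, the actin convention; sign configurable). The barbed end
  points tip-ward with probability `tip_fraction` (default 0.74), drawn
  independently per filament; the stored point order of each trace is
  randomized independently of polarity so nothing downstream can read
  the answer off the table.
* **Subunit shape** — each subunit is *two* Gaussian lobes: a main lobe
  (σ = 0.9 nm) 2.2 nm off-axis and a smaller lobe (amplitude 0.9,
  σ = 0.7 nm) 3.0 nm off-axis, displaced 1.4 nm toward the barbed end
  and −60° in azimuth. This matters more than it looks: a helix of
  single isotropic blobs has an exact 2-fold axis perpendicular to the
  filament — flipping it end-over-end reproduces the same helix at
  another phase — so its polarity would be undetectable *in principle*,
  at any signal-to-noise. The two-lobe subunit breaks that dyad the same
  way the two-domain actin monomer does in reality, producing the
  arrowhead appearance polarity reading rests on. Single-lobe geometry
  remains available through `HelicalParams`.
* **Receptors** — bent chains of four Gaussian lobes anchored on the
  outer leaflet, calibrated numerically so the half-peak extent along
  the normal equals the `height` parameter (default 12 nm) — the same
  convention the downstream measurement uses. Placements are uniform on
  the membrane within a configurable height band above the support
  (default 50–70 nm) with 9 nm minimum separation.
* **Imaging model** — a single-axis missing wedge (Fourier coefficients
  with |k_z| > tan(tilt_range)·|k_x| zeroed; ±60° default) followed by
  additive white Gaussian noise with SD = `noise_sigma` × the noise-free
  volume peak. No CTF, no per-tilt dose or alignment errors: the model
  captures anisotropic information loss and shot-to-shot noise, which is
  what the analyses are sensitive to, and nothing else.

**Noise level.** `noise_sigma = 0.4` was chosen so the polarity
pipeline's confidence criterion operates in the regime the method is
designed for: at 0.4, roughly three quarters of the synthetic filaments
pass the default confidence test (at 0.3 nearly all do, at 0.5 about
half). The selection criterion is the resolved *fraction*; the recovered
tip-ward composition among resolved filaments is unbiased across this
whole range, so this choice calibrates difficulty, not the answer.

## Actin polarity determination

1. **Segments** — traces are resampled at 8 nm arc length (first centre
   at arc length 0; floor(L/8)+1 segments; tangents by central
   differences, one-sided at the ends). Cubic 32-voxel boxes (35 nm at
   desk scale; the acquisition-scale equivalent is 168 voxels at 0.22 nm
   = 37 nm) are cut at the nearest voxel, the sub-voxel residual stored
   and compensated during alignment. Out-of-bounds boxes are rejected,
   never padded.
2. **Projections** — each box is masked with a soft raised-cosine
   cylinder (radius 6 nm, 2 nm taper) around its expected axis — the
   8-to-10-nm filament fits inside, bundle neighbours at ≥9 nm are
   suppressed — then the central 11-nm z-slab is summed and the image
   rotated so the in-plane tangent maps onto +x (cubic interpolation).
   Tangents within 5° of the beam axis are unusable in projection and
   flagged.
3. **2D classification** — reference-free alternation of alignment
   (translation + 180° in-plane rotation) and reassignment, with two
   numerical details that decide whether it works at all: references are
   bootstrapped from *single images* (the average of a random partition
   is a structureless fixed point of align-and-average), and images are
   Fourier-upsampled 4× along the filament axis so the translational
   search locks the helical phase (one desk-scale voxel is 0.4 of a
   rise; integer-voxel alignment smears the arrowhead out of the class
   averages). Empty classes are reseeded from the worst-fitting member.
   Deterministic given the seed.
4. **Polarity scoring** — class averages are scored by maximum NCC
   against projections of the noise-free helical model in both axial
   orientations, maximized over a 12-phase model bank (the screw
   symmetry ties phase to axial shift, but shift steps sample phase too
   coarsely at desk scale). Classes are retained when the score margin
   is ≥ 0.05 and membership ≥ 10; members inherit the class label (times
   −1 if they aligned through the 180° rotation). Members of discarded
   classes are scored individually against the same bank and abstain
   below a 0.01 margin. The individual fallback is deliberate: at
   desk-scale voxels the orientation discriminant is a few percent of
   image energy, and image-to-image similarity — all any unsupervised
   grouping can see — is dominated by nuisance structure (measured
   pairwise polarity-relation accuracy is near chance even noise-free,
   while image-to-model matching is near perfect). Polarity information
   enters through the model comparison either way, exactly as reading
   class averages against a resolved actin structure does; the class
   route is kept wherever the averages support it.
5. **Calls and fractions** — exact binomial confidence as in the README;
   ties are unresolved; the stringent criterion (α = 0.01) can only
   unresolve, never flip, a default call. The tip axis is the principal
   axis of the membrane mask, oriented toward the capped end (detected
   as the axial end whose terminal slab contains membrane voxels near
   the axis; an override is accepted and required for degenerate masks).
   A resolved filament counts tip-ward when its barbed-end direction has
   positive dot product with the tip axis; an exactly zero dot product
   counts cell-ward (conservative). Fractions are over resolved
   filaments per tomogram (they sum to 100%; unresolved counts are
   reported separately), aggregated as mean ± SD across tomograms.

## Receptor pipeline

Normals come from the gradient of a smoothed solid indicator (membrane
mask plus its hole-filled interior; volume faces the mask touches are
capped first so boundary-open tubes still enclose a volume). Sheets with
no enclosable interior fall back to Hessian ridge normals with a
consistent but globally arbitrary sign. Candidates are local maxima of
the lightly smoothed tomogram 2–12 nm outside the outer leaflet, above
mean + 3.5 SD of that band; each inherits the nearest surface point and
its normal. Filters: height above support within 50–70 nm, normal tilt
from the image plane ≤ 20° (the membrane must be roughly parallel to the
beam; the threshold is a configurable default, as no canonical value
exists), then an 8-nm proximity dedup among filter-passing picks
(highest density wins) — dedup competes only among survivors, so filter
and dedup order commute. Every rejection carries exactly one reason.

Boxes are centred on the surface foot point inset 1 nm along the inward
normal (the nearest-mask-voxel foot sits on the outer *edge* of the
segmented leaflet, about half the segmentation thickness outside its
density centre), rotated normal-to-z by the minimal rotation (in-plane
angle left free and marginalized by averaging — the initial model is
cylindrically smeared by construction), averaged, and classified by an
alignment-free cosine k-partition (references bootstrapped from single
boxes, for the same fixed-point reason as in 2D). The selected class is
the most self-consistent one above a member floor. Height is the extent
of supra-threshold extracellular density along +z from the outer
leaflet, read from a lightly smoothed lateral-max profile at 0.5 of the
extracellular peak, with linear interpolation at the crossing; a class
with no peak distinguishable from the box-top background (or below 10%
of the volume maximum) reports 0 nm, flagged.

Rigid fitting renders pseudo-atoms as Gaussians (FWHM = stated
resolution), scans a ≤15° rotation grid with FFT translations, and
refines all six parameters with Powell; it reports the fitted rotation
and centroid plus the global NCC. The spatial-randomness test compares
the observed mean nearest-neighbour distance of picks against uniform
draws from the surface point set, with the +1-corrected two-sided
Monte-Carlo p-value.

## Averaging and FSC

Pre-oriented boxes are mapped to a common frame (residual shift, then
in-plane rotation about z, then the polarity flip — a 180° rotation
about y) and voxel-averaged; helical symmetrization applies the screw
operators j·(rise, twist), j = −n..n, and re-averages. The FSC uses
one-voxel shells after a soft spherical mask (raised cosine at 0.9 ×
box/2) to limit mask-correlation bias; resolutions are read at 0.143 and
0.5 by linear interpolation, and a curve that never crosses a threshold
reports "beyond Nyquist" (None), flagged. No phase randomization is
applied; desk-scale boxes are small enough that residual mask bias is
visible in the curves and the numbers should be read accordingly.

## What the synthetic studies show — and what they don't

Passing recovery tests shows the chain is *internally consistent*: given
data whose structure matches its assumptions (known helical lattice with
an asymmetric subunit, membrane-attached blobs of defined height,
white noise plus a wedge), the pipeline recovers the generating
parameters without systematic bias. Real tomograms add everything the
generator omits — CTF, dose-dependent damage, alignment errors, crowded
cytoplasm, curved filaments, receptor conformational heterogeneity, and
segmentation errors in the input traces and membranes — so desk-scale
recovery is a necessary, not sufficient, condition for correctness on
real data. Quantities tied to acquisition-scale resolution (the ~14 Å
filament average, the ~26 Å receptor class) are out of reach at 1.1 nm
voxels by construction; the FSC read-outs here characterize the
synthetic averages only.

## Problem sizes and determinism

The shipped studies run 28 polarity scenes (256×256×128 voxels, ~650
filaments, ~9000 segments, a few minutes on one CPU) and 5 receptor
scenes (~200 picked boxes, under a minute): sizes chosen so the full
recovery experiments are routine to rerun. Every random choice flows
from explicit seeds (scene seeds offset per tomogram; classification
seeds derived from the config seed), and reruns are bit-identical,
including the file-based pipeline artifacts.
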