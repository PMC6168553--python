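# Methods

This note documents the models, defaults and numerical choices behind
helifil, and what the synthetic-data tests do and do not establish about
real data.

## Helical symmetry and its parameterizations

Subunit *k* of a 1-start helix is generated from subunit 0 by rotation about
+z by *k·twist* (right-hand rule) plus translation *k·rise* along +z.
Left-handed filaments carry negative twist; the `handedness` field is
validated against the sign rather than stored independently.  The
(pitch, units-per-turn) parameterization converts exactly:
|twist| = 360/(u/t), rise = pitch/(u/t); round-trips are exact to 1e-9
relative tolerance (property-tested).

Rational repeats are found by minimizing |u/t − x| over coprime pairs with
t ≤ max_turns.  Continued-fraction convergents seed the candidate set and an
exhaustive sweep over all denominators guarantees optimality; ties resolve
toward smaller t.  The value 3.56 rationalizes to 32/9 at t ≤ 10 and to
89/25 at larger t — both describe the same helix at different precision, and
both appear in the package's outputs (the indexer reports 89/25 because the
synthetic generator realizes 3.56 exactly).

Segment bookkeeping uses floor(step/rise) unique subunits per refinement
segment.  The formula is reverse-engineered from the published totals
(135,254 / 9,661 = 14 = floor(70/4.848)); no authoritative statement of the
formula exists, so it is a documented inference.

## Synthetic data

The generator realizes the study conditions: 1.21 Å/px sampling, 420 px
boxes, 400 Å filament length, segment stacks with independently seeded
additive white Gaussian noise, and a default single scatterer per
asymmetric unit at radius 25 Å — the midpoint of the filament wall (channel
radius ~12.5 Å, outer radius ~37.5 Å) and the same radius the analytic
refinement model uses, so the two simulators describe the same object.
Scatterers render as isotropic Gaussians of σ = 2 px, chosen for analytic
transformability.  No CTF, ice background or atomic B-factors are simulated.
Consequences to keep in mind:

- The σ = 2 px envelope attenuates the meridional (1/4.85 Å⁻¹) line by
  ~4 orders of magnitude; under noise it is often undetectable, which real
  protein density (with fine internal structure) does not suffer from to the
  same degree.  The indexing chain compensates (below).
- Passing tests show the chain's correctness on an idealized single-radius
  helix with white noise; they do not show robustness to CTF rings,
  out-of-plane tilt, or flexible filaments, all of which are out of scope.

Shift tables carry per-residue Cα/Cβ values built from standard per-type
base shifts plus planted perturbations plus Gaussian noise; glycines carry
no Cβ row.  The bundled deterministic 108-residue test sequence (numbered
433–540) contains 14 Leu, 6 Thr, 7 Val and 4 Pro placed so that masking the
disordered tail (512+) leaves 9/14, 6/6, 5/7 and 1/4 visible — the
composition pattern used for residue-type signal accounting.  Gold-particle
tables label each particle off/on_body/on_end with configurable off-filament
rate and end preference.

All generators are seeded and bit-reproducible.

## Power spectra and layer-line indexing

Averaged power spectra are mean squared Fourier magnitudes, origin-centred.
Images are zero-padded two-fold along the filament axis before the FFT:
finite-length layer lines are narrower than one unpadded Fourier pixel, and
the finer sampling roughly halves peak-localization error at negligible
cost.

Detection works on the radially integrated axial profile (meridian band of
±2 px excluded), symmetrized across Friedel mates.  The background is a
rolling median (window 31 rows), which tracks the reciprocal-space envelope;
peaks must exceed the robust scatter (median absolute deviation) of the
background-subtracted profile by `min_snr` (default 5), are separated by at
least 3 rows (suppressing finite-length sinc sidelobes), are ranked by local
contrast (peak/background) rather than raw power — this is what keeps
envelope-crushed high-resolution lines in the list — and are refined to
sub-row precision by parabolic interpolation.

Repeat fitting considers every candidate c = l/h over detected heights h and
indices l ≤ max_l, refits c by least squares for each integer assignment,
and must choose among aliases: a repeat of length c can index *arbitrary*
heights to within its own line spacing (rms 1/(√12·c)), so candidates are
scored by residual × c — the residual relative to that null — with exact
ties resolved toward the smallest repeat, and candidates whose line spacing
falls below two spectral rows rejected as unresolvable.  This score is the
package's answer to an ambiguity the classical workflow resolves by eye.

Bessel orders are assigned by the single-radius first-maximum heuristic: on
a line carrying order n, the first intensity maximum sits at
2πRr = x\_n (the first maximum of J\_n; 0 for n = 0).  The radial position is
measured as the argmax of the line's symmetrized, lightly smoothed profile
(±1 row band, Friedel-averaged), valid because the decaying envelope makes
the first maximum the global one.  Orders beyond n_max report n_max with a
low-confidence flag.

The full chain then solves the strongest meridional (n = 0) line for the
rise and the lowest n = 1 line for the pitch.  When no meridional line
survives the envelope, the two lowest n = 1 lines are used instead: they are
n = +1 (height 1/P) and n = −1 (height 1/rise − 1/P), so their heights sum
to 1/rise and their indices to the meridional index.  Handedness cannot be
read from a projection power spectrum and is an explicit input (default
left, the established hand for CARD filaments).

## Amplitude-correlation grid refinement

Candidate spectra come from the single-radius helix transform: layer line l
at height l/c carries the coherent sum of J\_n(2πRr) over selection-rule
orders (|n| ≤ 36), axially broadened by sinc² of width 1/length, optionally
multiplied by the Gaussian-scatterer envelope so that model and rendered
projection share line shapes.  The score is the Pearson correlation of
square-root amplitudes over a mask that excludes the equator and a 3 px
origin disc (both dominated by low-frequency background).  Grids are
inclusive of both endpoints with node counts round((max−min)/step)+1 — the
published spans reproduce 11×11.  Ties in the argmax resolve toward the grid
centre.  `GridRefiner` precomputes the node spectra once so repeated trials
reduce to one matrix product each.

Recovery, not the correlation value, is the tested contract: noiseless
self-consistent input recovers the generating node exactly, and at SNR 1
(noise σ equal to the signal's real-space standard deviation, 10 segments
averaged) the node stays within one grid step in ≥95/100 seeded trials.

## Assemblies, RMSD and interfaces

`build_filament` applies the helical operator exactly (closed-form rotation
matrices); subunit-to-subunit mapping is exact to ≤1e-9 Å fixed-frame RMSD.
Chain ids run A–Z, a–z, 0–9, then two-character ids; PDB output refuses
multi-character ids (use mmCIF).  Superposition is plain Kabsch (SVD with a
determinant correction so the rotation is always proper); degenerate
(collinear) point sets are rejected because the optimum is not unique.
Pairing for RMSD is by residue number and atom-name intersection (default
Cα), with unpaired residues reported.  Published RMSDs computed with
secondary-structure-matching pair selection may differ at the second decimal
from plain Kabsch over a stated residue range; comparisons against deposited
models are therefore optional integration checks, not unit tests.

Contacts are heavy-atom pairs within 4.0 Å (configurable), extracted per
subunit-index offset with a k-d tree and verified against an all-pairs
oracle in the tests.  Which offset realizes which death-domain interface
type is established data-driven: contacting residue sets are matched against
the bundled annotation file (transcribed surface residue lists and pairs for
types I/II/III) by orientation-symmetric mean Jaccard overlap, and the
mapping is reported as a result, not assumed.  Salt-bridge candidates are
opposite-charge charged-group N/O pairs within 4.0 Å.  Hydrogens are
ignored.

## Chemical shifts

Secondary shifts use Δδ = δ_obs − δ_random-coil (positive ΔδCα ⇒ helical);
the sign convention is a documented switch because the opposite convention
is also in circulation.  The bundled random-coil table carries standard
published Cα/Cβ values; tests use synthetic tables and assert no specific
random-coil numbers.  State perturbations sum |ΔCα| + |ΔCβ| over atoms
present in both states (a missing atom omits that term and is recorded);
residues absent from either table are returned unassessed.  The 1.2 ppm
flag threshold is absolute by default, with a mean-deviation mode offered
because the published wording admits both readings.  Flags are monotone in
the threshold, and the random-coil terms cancel exactly when differencing
two secondary-shift profiles (both property-tested).

## Polarity statistics

`gold_summary` reports the on-filament fraction, the end fraction among
on-filament particles, and (when filament ids exist) the number of filaments
carrying two or more end-bound particles — a conservative stand-in for
"both ends" when end identity is not annotated.  The end-preference test is
the exact one-sided binomial tail P[X ≥ n_end] under a caller-supplied
uniform-binding end fraction rho0; rho0 has no default because it depends on
what the annotator counts as an end (e.g. 2×window/filament length).  The
test is one-sided because the hypothesis (nucleation at one end) is
directional.

## Pipeline and formats

The pipeline runs any contiguous subset of simulate→index→refine→build→
interfaces from a validated config (unknown keys rejected; lossless
serialization round-trip) and writes JSON reports keyed with units
(`rise_ang`, `twist_deg`).  Identical config + seed gives identical reports.
Structure I/O (PDB/mmCIF) is backed by gemmi; MRC modes 0/1/2 are read and
mode 2 written by a compact built-in codec (fixed 1024-byte header; pixel
size from cell/grid fields); shift and gold tables are TSV, with a
simplified NMR-STAR chemical-shift loop reader.

## Problem sizes

The default test geometry is a 420 px box at 1.21 Å/px with a 400 Å
filament, 10-segment stacks, an 11×11 refinement grid, and 100 trials for
the stochastic recovery check; the whole suite runs in about two minutes on
one CPU.

## Known limitations

- Single-radius diffraction model: adequate for parameter recovery, not for
  map fidelity; no Fourier–Bessel decomposition.
- No CTF, tilt, or flexibility in the simulator; no 2D classification or
  segment alignment (inputs are assumed vertical).
- Interface typing depends on the curated annotation lists; on toy
  monomers it reports which offsets touch but cannot reproduce biological
  surface assignments.
- The published gold-particle percentages rest on raw counts that were not
  printed, so they anchor the API (fractions, both-ends count) rather than
  numeric tests.
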