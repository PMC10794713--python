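# Methods

This note records the models, conventions and design choices behind each
module, what the synthetic generators do and do not emulate, and the
problem sizes the test suite uses.

## Helical geometry

A filament class is `(Δz, Δφ, Cn)`: rise per asymmetric unit (Å), twist
per asymmetric unit (degrees, negative = left-handed), and cyclic
symmetry of the cross-section.  Derived quantities are elementary:
units per turn `u = 360/|Δφ|` (zero twist is rejected — no helix),
pitch `Δz·u`, and the lattice recurrence placing repeat `j` at
`z = j·Δz`, azimuth `(φ₀ + j·Δφ) mod 360`, with `Cn` symmetry mates
spaced `360/Cn` within each ring.  For Cn > 1 the `(Δz, Δφ)` step is
interpreted ring-to-ring, consistent with the symmetry annotation of
stacked-ring reconstructions.

**Theoretical filament length.**  A filament that exactly encapsidates
an RNA of `N` nt at `k` nt per subunit contains `N/k` subunits and spans
`(N/k)·Δz` Å.  Default `k = 5`, the RNA register of the potyviral
subunit; default rise 4.01 Å (the RNA-encapsidating helical class).
Printed comparisons round half away from zero to the printed precision
(65 nm, 3.9 Å), matching how such values are reported.

**Architecture classification.**  `stacked_ring` iff `Cn > 1` and the
per-ring rise is at least `subunit_axial_extent`; otherwise
`one_start_helix`.  The extent is a heuristic no reconstruction table
states; the default is 30 Å — deliberately below the ~40 Å ring height,
because engineered interfaces can pull stacked rings several Å closer
(39.3 Å in the truncated double ring) without changing the architecture.
It is an exposed parameter, not a claim about the data.

## Ring-packing order parameter

For each frame of a rigid-ring trajectory a contact graph is built:
edge `(i, j)` iff the center–center distance is ≤ `threshold`.  The
underlying experiments never state a numerical contact criterion, so the
default (12 nm ≈ 1.1 ring diameters) is a package choice: it is the
simplest reproducible criterion consistent with the 16 nm initial
spacing producing no initial contacts.  Triangles of the graph are the
ring triplets; each is scored with `p = |n₁·(n₂×n₃)|` over the unit
normals.  `p` lies in [0, 1] by Hadamard's inequality, and is invariant
under triplet permutation (the determinant changes sign only), under
flipping any normal (ring normals have no intrinsic sign), and under
global proper rotations.  Non-unit normals are rejected rather than
silently normalized (an opt-in `normalize=True` exists).  If poses lack
normals, a least-squares plane fit of ring subunit positions supplies
one (sign arbitrary — immaterial for `p`).  Classification bands default
to planar ≤ 0.2 < intermediate < 0.8 ≤ orthogonal.

## Filament morphometry

Length distributions are summarized by median and 25th/75th percentiles
(linear interpolation, the numpy default) as on violin plots.  Mixtures
are fitted by EM on the raw length values, not on histogram counts:
histogram least squares is bin-width dependent, while EM on raw data is
the statistically standard equivalent.  A histogram-fit mode
(`fit_histogram_gaussians`, user-chosen bin width) exists for
comparability with GUI curve fitting.  EM details: random-data-point
initialization, best of `n_restarts` (default 5) by log-likelihood,
convergence when the improvement drops below 1e-8 or at 500 iterations,
per-iteration log-likelihood trace exposed (and asserted non-decreasing
in tests).  A component sd collapsing below 0.1 nm aborts that restart;
all restarts degenerate is an error.  `K` is user-specified — four
apparent peaks in the motivating data — with BIC available as an
optional report only, not automatic selection.  Zero-truncation of the
length distribution is ignored in fitting (lengths ≫ 0 in practice).

**Peak multiples.**  Component `k` is "approximately an integer
multiple" of the first when `|r − round(r)| ≤ rel_tol·round(r)` for
`r = mean_k/mean_1`.  Default `rel_tol = 0.12`, chosen so the observed
quartet 61/134/199/267 nm (ratios 2.20/3.26/4.38) passes; configurable.

## Thermal stability and mass

Tm is the temperature of the first-derivative extremum of fluorescence,
central differences on the uniform grid (one-sided at the ends), no
spline fitting — the plainest reading of "first derivative of the
measured data".  The default mode takes the derivative **minimum**;
SYPRO-Orange unfolding classically yields a maximum, but instrument and
export sign conventions vary, so `mode` accepts `min`, `max` and `auto`
(larger-magnitude extremum).  Optional moving-mean smoothing (default
off) precedes differentiation.  A derivative range at or below the
noise floor (plus a relative floor `1e-9·max|f'|` that catches flat and
purely linear curves) raises a "no transition" error; an extremum on
the grid boundary is flagged, not silently trusted.

Masses are kept in kDa (MDa converted at ingestion).  Expected assembly
mass is `n·m`; cargo mass is the measured particle mass minus that
shell mass, reported as the plain subtraction: 1.3 MDa − 48×22.3 kDa =
229.6 kDa.  Published descriptions of the same arithmetic quote "about
245 kDa" and a 250–350 kDa range, which presumably reflect the exact
peak position and monomer mass used; the package does not force
agreement.  Histogram peak calling fits a Gaussian over a ±3-bin window
around the modal bin; secondary local maxima ≥ 50% of the mode height
outside the window set a multimodality flag, and the tallest peak is
returned.

## RNA-packaging quantification

Coordinates are 0-based half-open internally; SAM (1-based) is converted
by pysam at ingestion.  One primary alignment per read is enforced
(duplicate read ids error).  MAPQ retention is equality with 60 — the
aligner's maximum, and the plain reading of "MAPQ 60 retained" — not
`≥`; the cutoff is configurable.  The 3′ filter keeps alignments with
`ref_length − end ≤ window` (default 50 nt), operationalizing the
filter on the alignment end coordinate; whether upstream tools measure
from the alignment end or the post-clipping read end is not recoverable,
so the end-coordinate reading is documented as the package's choice.

TPM is the standard length-normalized composition
(`rate_i = count_i/length_i`, scaled to 10⁶).  Adjusted TPM retains
transcripts with TPM > 0 in **both** replicates, renormalizes each
replicate's survivors to 10⁶, and averages.  Whether the original
procedure renormalized after discarding or averaged surviving raw TPMs
is not stated; renormalization is the default because it preserves the
sum-to-10⁶ invariant per replicate, and `renormalize=False` provides
the other reading.  Coverage is computed from the MAPQ-retained
alignments (the 3′ window is a counting sensor for full-length
transcripts, not a coverage mask), normalized by the grand total over
all references × 10⁶, and smoothed by a centered 40-base moving mean
truncated at track edges (output length preserved; constants pass
through).  Class bp% sums aligned spans per RNA class (CP, p97, rRNA,
other) over the same retained alignments.

## Synthetic data

The generators define the study conditions the tests run under:

- **Trajectories**: 8 rings in a 50 nm cubic box, initial pairwise
  spacing ≥ 16 nm by rejection sampling (bounded attempts, explicit
  error naming the constraint when the box cannot hold the rings), ring
  diameter 16/1.5 ≈ 10.67 nm (spacing stated as 1.5 ring diameters —
  the only size cue available).  Dynamics are a reflecting-wall random
  walk (0.5 nm/frame positional, 0.05 rad/frame orientational) — the
  analysis contract needs kinematically plausible rigid-body motion,
  not force-field physics, which is explicitly not emulated.  Periodic
  boundaries are not emulated either; rings reflect at walls, avoiding
  ambiguous minimum-image contacts.  In `orthogonal`/`planar` mode,
  rings 0–2 snap from the onset fraction onward to a mutually
  contacting equilateral cluster (side ≈ 11 nm) with orthonormal or
  coplanar normals plus 0.01 orientation noise; free rings are kept
  ≥ 19 nm from the cluster center so chance contacts cannot contaminate
  the persistent triplet.  The trajectory's persistent triplet is the
  generator's guarantee; other triplets may transiently form among free
  rings.
- **Length mixtures**: multinomial component assignment, Gaussian draws
  truncated at zero by resampling.
- **Melt curves**: decreasing logistic `A/(1+e^{s(T−Tm)})` on the
  25–95 °C, 1 °C grid, so the derivative extremum is a minimum at the
  true Tm, matching the extraction convention; Gaussian noise added
  after.
- **Alignments**: per-read reference choice by the composition vector,
  Gaussian read lengths clipped to the reference, 3′-anchored ends
  within 50 nt of the reference end for the biased fraction (uniform
  starts otherwise), MAPQ 60 with the stated high fraction (uniform
  0–59 otherwise).  Two replicates by default, seeded `seed + replicate
  index`.

All generators are deterministic given the spec and seed (byte-identical
TSV outputs).  None of them emulate real-data features such as basecall
errors, chimeric reads, stage drift in micrographs, or buffer-dependent
melt-curve baselines — passing tests demonstrate that the *analysis*
recovers what the generators inject under clean statistical conditions,
not that the pipeline is robust to every real-data artifact.

## Problem sizes and tolerances in the test suite

Statistical recoveries use n = 10⁴ observations (mixture fits within
2% at ≥ 4 sd separation; medians/means within ~3 SEM; MAPQ and
composition fractions within 2%), 50 seeds for Tm recovery (mean within
0.5 °C at 1% noise with a 5-point smoothing window), 100 seeds for the
placement constraint, 10⁴ random unit triples for order-parameter
invariances (1e-12 absolute for permutation/sign, 1e-9 under rotation
against scipy rotation matrices), and graphs up to n = 12 against the
brute-force C(n,3) triangle oracle.  Trajectory round trips run 40
frames of 8 rings.  These sizes keep the whole suite in seconds while
leaving the statistical assertions comfortably inside their tolerances.

## Known limitations

- The contact criterion and trajectory kinematics are package choices;
  quantitative contact statistics from real simulations would need the
  original trajectories and cutoffs.
- The EM fit assumes Gaussian components and a known K; heavily
  overlapping or skewed length populations will bias means.
- `classify_architecture` is a two-way heuristic; exotic symmetries
  (e.g. point-group cubes/spheres) are out of its domain.
- The alignment data model is single-end, primary-only, ungapped spans;
  spliced or supplementary alignments are rejected, not interpreted.
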