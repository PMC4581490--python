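# Methods

## Coordinate system and symmetry assumption

All quantification assumes cylindrically symmetric staining: expression is
a function of position along the oral–aboral (primary) axis only.  Profiles
are parameterized by normalized arc length *t* ∈ [0, 1] along a
half-meridian of the cell-layer midline, with *t* = 0 at the animal/oral
pole and *t* = 1 at the vegetal/aboral pole.  Genes flagged noncylindrical
in a domain table are carried through the transition statistics but are
excluded from 1D profile quantification; quantifying them would require a
2D/3D template and is out of scope.

## Profile extraction

A morphology is a pair of index-paired boundary polylines (inner and outer
edge of the cell layer) with at least three point pairs.  Segment *k* is
the quadrilateral `(inner_k, inner_{k+1}, outer_{k+1}, outer_k)`; its
position is the normalized cumulative arc length of the midline (the
pointwise average of the two polylines) at the segment midpoint.  When a
different segment count is requested, each polyline is resampled
independently at arc-length-uniform spacing.

Pixel membership uses the pixel-center-in-polygon test (even-odd rule, x =
column, y = row), which makes segment means deterministic; a pixel center
exactly on a shared edge is a measure-zero event for generic geometry.
Segments capturing no pixel center are dropped with a warning; degenerate
(zero-area) quads are an error naming the segment index.

Artifact editing replaces intensities at masked positions by linear
interpolation between the nearest unmasked neighbors (masked runs touching
an end take the nearest unmasked value).  When masking an artifact whose
true extent is known, the mask should be padded by about one segment width:
a segment whose midpoint lies just outside the artifact interval can still
contain contaminated pixels.

Standardization interpolates the edited profile at 100 equidistant points
spanning [0, 1] inclusive (step 1/99) and divides by the maximum, so every
stored profile has max = 1.  All-zero profiles cannot be scaled and are
rejected, as are constant profiles at the distance-matrix stage (Pearson
correlation is undefined at zero variance).  Standardized profiles are
invariant under positive rescaling of the input image — bit-exactly for
power-of-two factors, to one ulp otherwise.

Input polarity is configurable: the pipeline works on signal-positive
intensities; grayscale images of dark stain on light background are
inverted with a flag, and RGB images are collapsed to luminance (or a
chosen channel) and inverted by default.

## Clustering

The distance between two profiles is 1 − *r* (Pearson), kept on the full
[0, 2] scale — anti-correlated profiles are maximally distant, and
stage cutoffs above 1 are meaningful, so distances are never clamped.

UPGMA is implemented directly with Lance–Williams size-weighted updates,
which reproduce the unweighted pair-group mean exactly.  Tie-breaking is
part of the contract: among equally close pairs, the lexicographically
smallest `(node_a, node_b)` pair (creation-ordered ids) merges first, so
merge sequences are bit-reproducible and testable against a brute-force
oracle that recomputes all inter-leaf means at every step.

Two cluster readouts are provided, since neither subsumes the other: cutting
at the stage-specific threshold (0.7, 1.3, 1.1, 0.6, 0.9, 0.9, 0.9;
mean 0.9), and the main-cluster rule — split the root into two branches,
and also split the larger branch when it contains the second-highest merge.
Because UPGMA heights are monotone, that second-highest merge is always the
top merge of one root branch; the rule fires only when that branch is
strictly larger by leaf count.  Display leaf order is deterministic: at each
merge the branch containing the smallest leaf index goes left.  Subcluster
("block") identification inside a main cluster is exposed as cutting the
subtree at a secondary threshold; its default is a convenience, not a
calibrated value.

## Major regions and transition statistics

The three major regions are R1 (central domain / endoderm lineage), R2
(central ring + external ring / oral ectoderm lineage) and R3 (vegetal
hemisphere / aboral ectoderm lineage).  The default name→region map assigns
each germ-layer descendant accordingly and deliberately leaves pan-regional
or uncertain names (`AnHe`, `Ec`, `BwEc`, `TeEc`, …) unmapped — in
particular the body-wall ectoderm lineage, whose regional origin is
uncertain.  The map is a plain lookup and is user-overridable.

A transition between consecutive *available* stages (stages a gene actually
has images for; they need not be globally adjacent) is classified from the
endpoint region sets: `none` (both empty), `appeared`, `vanished`, `minor`
(equal nonempty sets) or `major` (unequal nonempty sets).  "Minor" demands
set equality, the strictest reading of "remained within the same major
region"; for the single-region-filtered tables this reduces to "still
exactly that region".  Genes whose initial expression spans several regions
appear only in the all-regions table.  A stage described solely by unmapped
domain names is ambiguous (expressed, but nowhere attributable), so such
pairs are skipped with a warning; a genuinely empty domain set means "not
expressed".

Aggregation credits a pair observed between stages *i* and *f* to every
consecutive-stage period (*s*, *s*+1) with *i* ≤ *s* < *f*: the change
could have occurred in any period the observation spans, and the total
credit of a cell across periods equals its count × (*f* − *i*).
Percentages are integers, rounded half away from zero; a zero total yields
zero percentages.

Fisher's exact test (two-tail) enumerates all 2×2 tables with the observed
margins and sums the probabilities not exceeding the observed table's.
With fixed margins every probability shares the denominator C(N, n), so the
comparison is done on exact integer numerators (`math.comb`) — no floating
tolerance enters.  Any zero margin gives p = 1.  The published claim that
change rates peak during gastrulation rests on one specific 2×2 table whose
composition is not recoverable from the published count matrices, so no
p-value for it is asserted anywhere in this package; the test itself is
verified against exhaustive enumeration via an independent implementation.

## Synthetic data generator

The generator defines the conditions under which the pipeline is tested.

**Images.**  The embryo is an elliptical annulus (default outer radius 52
px, aspect 1.0, layer thickness 14 px, on a 128×128 raster); gastrula-like
scenes dent both boundaries inward around the oral pole with a Gaussian
bump (depth in px, width in radians).  Staining inside the layer is an
archetype's window function of *t*; the arc-position of each pixel is
computed from the same midline arc-length parameterization the extractor
uses.  The emitted morphology has 257 boundary point pairs (256 segments)
over the half-meridian.  Noise is additive Gaussian truncated at zero —
the simplest model that exercises robustness; its magnitude is
configurable.  Artifacts are bright or dark intensity blobs over recorded
arc intervals, giving editing tests exact ground truth.  Background
defaults to 0 (a background-subtracted intensity scale); a uniform nonzero
background is supported and becomes a documented offset in standardized
profiles.

**Archetype windows** have a raised-cosine edge taper, default 0.05 arc
units.  Real expression domains have graded boundaries, and a step edge is
not representable by segment means at any finite segment count, so sharp
boxes (taper 0) are reserved for pixel-level oracle tests.  With the
default taper and 256 segments, the noise-free extraction round trip is
accurate to ≈ 0.04 maximum absolute deviation (the 0.05 invariant the
tests assert).

**Profile sets** sample the window function at the 100 standard positions,
apply per-window multiplicative amplitude jitter and truncated additive
noise, and rescale to unit maximum, retaining the generating archetype
label for recovery tests.

**Domain tables** evolve a major-region state per gene across its available
stages under a transition kernel (probabilities over the five categories,
renormalized over the categories feasible from the current state), writing
the state as the region's representative domain name at each stage and
recording every true category.  Availability is the per-stage probability
of having an image; genes are redrawn until at least two stages are
available, matching the inclusion criterion of the transition analysis.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: photorealistic staining texture, probe chemistry,
3D embryos, noncylindrical patterns, segmentation error from manual
boundary placement, and the correlated inter-individual variability of real
embryos.  The synthetic benchmarks validate the computational pipeline, not
the biology.

## Problem sizes and numerical checks

The test suite and the acceptance script use 128-px images with 256
segments, profile sets of 8–40 samples, 200 random matrices (n ≤ 12) for
the UPGMA oracle, 2000 genes for kernel recovery (12 000 transitions;
binomial sampling error well under the 3-point check), and exhaustive
Fisher enumeration for small margins plus 1000 randomized tables with
margins up to 30.  These sizes are the package's own defaults for fast,
deterministic verification; all are parameters.

## Known limitations

- Boundary polylines must be supplied; there is no automatic cell-layer
  segmentation from images.
- The 1D representation cannot express secondary-axis asymmetry.
- The default domain→region map is an inference; analyses sensitive to the
  body-wall ectoderm assignment should override it.
- Cluster counts from threshold cutting and from the 2-vs-3 main-cluster
  rule can disagree; both are reported and neither takes precedence.
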