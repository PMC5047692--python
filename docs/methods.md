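# Methods

This note documents the models and procedures implemented in `flymotor`,
the design choices made where the underlying experimental procedure leaves
the computation under-specified, and what the synthetic-data tests do and
do not demonstrate about real data.

## Fragmentation scoring

**Procedure.** Scoring operates on 2D maximum projections of multi-channel
confocal stacks (axial flattening matches how these preparations are scored
in practice; 3D scoring is out of scope).  A branch is represented by an
arc-length-parameterized centerline trace.  The trace is divided into
consecutive half-open segments [k·s, (k+1)·s) of length s = 1 µm starting
at the trace origin; the trailing remainder shorter than one segment is
discarded so that all segments are identical in length and the percentage
is well defined.  The grid phase is fixed at the trace start and treated as
arbitrary — no anatomical landmark anchors it.

**Centerline tracing.** The projection is binarized (Otsu by default), gaps
up to a bridging distance (default 1.5 µm) are closed morphologically so
that beaded-but-aligned fragments are traced as one branch, the largest
component is skeletonized, and the longest geodesic path through the
skeleton (double Dijkstra sweep over the 8-connected pixel graph, weighted
by Euclidean step length) becomes the centerline.  Skeletonization stops
roughly one tube radius short of a rounded end, so each endpoint is
extended along its local direction until the local half-thickness (mask
distance transform) falls below 80% of its value at the skeleton endpoint —
recovering the cap without overshooting.  The path is smoothed with a
0.3 µm moving average to remove pixel staircase and resampled at half-pixel
arc steps.  Orientation runs from the endpoint nearer the image border
inward, with a lexicographic tie-break, so tracing is deterministic.
Branches fragmented beyond the bridging distance cannot be traced as one
object; the trace then covers the largest fragment, and cohort-scale
scoring of heavily fragmented branches should supply an external trace
(the simulator ground-truth centerline, or a user CSV of points).

**Continuity.** Signal presence along the trace is the local maximum within
a sampling disc (default radius 0.3 µm) compared against a robust
threshold: the larger of (background median + 5·MAD, computed on the raw
projection) and the half-way level between background and the bright
plateau (99.5th percentile of the disc-maximum image).  The 50% level
localizes the blurred edge of a gap without bias, because a Gaussian PSF
crosses half its plateau exactly at the underlying edge.  Two corrections
keep measured run lengths faithful: a 3-sample median filter removes
single-sample noise flips, and — since a disc maximum-filter of radius ρ
widens every presence run by ρ on each side — absence runs are re-expanded
by ρ before the threshold rule is applied (the exact morphological
inverse for a centered trace).  An uncompensated tube-radius disc would
shorten every measured gap by two radii and systematically misread gaps
near the 0.5 µm decision boundary; the small disc plus compensation removes
that bias while still tolerating ~0.3 µm of trace jitter.

**Discontinuity rule.** A maximal absence run is measured as a whole: if
its total length exceeds the gap threshold (default 0.5 µm) it invalidates
*every* segment it overlaps, including a segment containing only a
sub-threshold portion of a straddling run.  This reading avoids the
pathology of a 0.9 µm gap split across a boundary counting nowhere.  The
alternative — a segment is invalidated only when the run's portion inside
it exceeds the threshold — is available via
`straddle_rule="within-segment"`.  Percent continuous is 100 × the mean of
the per-segment flags; group summaries report mean ± s.e.m. (sd/√n) over
branches, with the standard design of ten most-central branches × three
preparations giving n = 30.

## Puncta classification and colocalization

Puncta detection: light Gaussian smoothing, robust threshold (median +
5·MAD with a floor at 25% of the bright range, so noise-free renders do not
degenerate), connected components, watershed splitting of components
containing multiple intensity peaks (minimum peak separation 0.8 µm), and
an area gate (defaults 0.1–20 µm²).  Two puncta closer than the PSF merge
into one component; this is a known failure mode bounded by the ≥0.9
recall/precision property at ≥2 µm spacing.  Nuclei: Otsu threshold, hole
filling, distance-transform watershed to split touching nuclei, equivalent
radius gate (1–8 µm), and an optional eccentricity filter for tracheal
autofluorescence, which shares the DAPI channel in these preparations.

Classification is purely geometric: the signed distance from the punctum
centroid to the nearest nucleus boundary.  Negative → `nuclear_interior`
(reported separately; intranuclear ubiquitin signal must not contaminate
the perinuclear class), within d_max (default 2.0 µm) → `perinuclear`, else
`non_perinuclear`.  The threshold is a design choice — the underlying
distinction is visual ("ring-like" vs dispersed) — so it is exposed on the
CLI and shared verbatim with the generator, enabling the closed-loop test
in which classifier labels must equal generator labels exactly on clean
renders.  Punctum size is recorded but deliberately not used for class
assignment, as no size boundary between the classes is established.

Colocalization is object-based (a punctum is positive iff ≥ `overlap_frac`
of its pixels exceed the other channel's robust threshold) because the
statements of interest are about puncta being P62-positive or -negative;
pixel-correlation measures (Manders, Pearson) are a non-goal.  A class with
zero puncta reports a missing fraction, never zero.  Clearance between
timepoints compares per-class counts; a ratio below 0.25 flags the class as
cleared.

## Behavioral indices and statistics

The experimental unit is the *test* — a group of six flies assayed together
— so n equals the number of independent groups (typically 10), not the
number of flies.  FI is the mean over tests of the per-test mean adhesion
height; heights are integers in [0, 17] cm (19 cm cylinder, zero line 2 cm
above the bottom).  CI is the inverse of the grand mean of per-test mean
climb times (three repeats per test), in s⁻¹, so larger is faster; its
s.e.m. uses the delta method (sem/T²), as does the uncertainty of a
normalized index (ratio of means of independent groups) — the original
reports do not state how normalized error bars were computed, so the
first-order propagation is this package's choice.

The t-test is the classic pooled-variance two-sample test (t from the
pooled variance, df = n_a + n_b − 2, two-tailed p from the t distribution),
implemented in-package and cross-checked in the tests against an
independent reference implementation; Welch's unequal-variance form is an
option.  Zero pooled variance with equal means returns t = 0, p = 1.  No
multiple-testing correction is applied by default (matching the reporting
convention of the assays modeled); a Bonferroni-style adjustment can be
applied by the caller.

## Synthetic data

**Branches.** The centerline is a sinusoid reparameterized by arc length
(length 40 µm, curvature amplitude 2 µm by default), rendered as a tube of
radius 0.5 µm; the glial sheath is a parallel offset curve at 1.2 µm with
the same radius, covering a configurable proximal fraction of the branch.
Fragmentation is a marked Poisson process on arc length: gap starts arrive
at `gap_rate_per_um` on a window extended below zero by the maximum
plausible gap length (stationary coverage, no edge artifact at the branch
origin), lengths are Gaussian (mean 1.5 µm, sd 0.5 µm, truncated at zero),
overlapping gaps are merged.  Expected coverage is the Boolean-model value
1 − exp(−λµ), verified by a law-of-large-numbers test.  Axon and glia gap
processes are independent by default, with an optional coupling probability
that copies axon gaps into the glia channel.  Rendering assigns each voxel
the arc position of its nearest centerline point (Euclidean distance
transform with physical sampling), zeroes intensity inside gap intervals,
convolves with an isotropic Gaussian PSF (σ = 0.15 µm), and adds mixed
Poisson–Gaussian noise with peak amplitude snr² photons plus unit read
noise; `snr=inf` renders noise-free.  Voxel sizes default to 0.1 µm
in-plane (an assumption, recorded in the sidecar — acquisition pixel sizes
of the modeled 60×/1.4 NA setups are not standardized) and 0.2 µm z-step
(the standard acquisition step for these preparations).

**Muscle fields.** Nuclei (radius 3 µm) are placed by rejection sampling
with margins; perinuclear puncta (radius 0.4 µm) are placed in an annulus
0.3–1.4 µm outside a nucleus boundary — safely inside the 2 µm classifier
threshold even after pixelization — and non-perinuclear puncta (radius
0.8 µm) farther than d_max + 1 µm + punctum radius from every boundary.
A P62 punctum is co-placed at a ubiquitin punctum's centroid with the
per-class colocalization probability.  Same-channel puncta keep a minimum
spacing (default 2 µm) so that detection failure modes are controlled
explicitly rather than entangled with placement density; geometrically
impossible requests fail with a placement error after a bounded number of
attempts.

**Cohorts.** Flight: each fly is flightless (height 0) with probability
`p_flightless`, otherwise its height is Gaussian, rounded to the nearest
integer and clipped to [0, 17].  Climbing: per-test repeat times are
truncated-Gaussian.  All randomness flows from one integer seed through a
named generator stream per object category, so adding puncta does not
perturb nucleus placement and identical seeds reproduce ground truth
bit for bit.

**What the simulator does not emulate.** Real myofibril/mitochondrial
texture and autofluorescent structures, anisotropic PSFs, depth-dependent
attenuation, chromatic offsets between channels, biologically clustered
(non-Poisson) fragmentation, and curved/branched axon topology beyond a
single sinusoidal branch.  Passing the closed-loop tests therefore shows
that the scoring procedures are correct implementations of their rules and
robust at the simulated noise levels — not that they are validated against
manual expert scoring of real micrographs.

## Problem sizes and numerical choices

The validation suites run at deliberately compact sizes chosen to exercise
the full pipelines while keeping the suite quick on a single CPU: 50
noise-free branches (gap rates 0–0.2 µm⁻¹) for the image-vs-geometry
equivalence check (≥95% segment agreement), 100 rendered branches at
snr = 10 for parameter recovery (Spearman ρ > 0.9 between realized gap
coverage and 100 − percent continuous), and 100 replicate two-condition
experiments (gap rates 0.01 vs 0.15 µm⁻¹, 30 branches each) for the
degeneration-contrast power check.  The replicate experiments score
branches geometrically from simulated gap intervals through the same
`score_continuity` machinery — the stochastic component under test is the
gap process and the statistics, and image-path fidelity is established
separately by the equivalence and recovery suites.  Floating-point
conventions: half-open intervals throughout; strict inequality at the gap
threshold (a run of exactly 0.5 µm does not invalidate); segment counts use
floor with a 1e-9 guard; ties in tracing and branch selection break
lexicographically; degenerate inputs (blank images, empty classes,
zero-variance groups) return defined values or named errors, never silent
zeros.
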