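# Methods

`fibmorph` measures cross-sectional cortical bone morphometry from binary
bone and marrow masks, and validates the whole measurement-and-analysis
chain on synthetic data with known ground truth. This note records the
models, the defaults and why they were chosen, and the limits of what the
synthetic validation demonstrates.

## The ring model and the measured quantities

A long-bone shaft cross-section is idealized as a deformed annulus: a
compact-bone wall between an inner (endosteal) contour enclosing marrow and
an outer (periosteal) contour bordered by muscle. Per slice:

- **BA** (bone area, mm²) — foreground pixel count of the bone mask times
  the pixel area.
- **CL** (centerline length, mm) — the physical length of the wall's
  mid-line loop (see below).
- **BT** (wall thickness, mm) — `BA / CL`: the mean thickness of a ribbon
  of length CL and area BA. Per subject, BT is the arithmetic mean of the
  per-slice `BA/CL` over the seven central slices.
- **g-ratio** — with the centerline diameter `d = CL / π`, the ring model
  gives an outer diameter `D_out = d + BT` and inner diameter
  `D_in = d − BT`, and `g = D_in / D_out`. A thinner wall relative to the
  enclosed marrow gives a larger g, exactly as in the axon/myelin g-ratio.
  A "literal" convention `g = (CL − BT)/(CL + BT)`, which treats the loop
  length itself as a diameter, is selectable for comparison; on realistic
  geometry it saturates near 0.8–0.9 and is not the default because it is
  inconsistent with the diameter definition of g: for the average geometry
  (D_out 10.9 mm, BT 2.7 mm) the diameter convention yields
  g = 5.5/10.9 ≈ 0.50, matching the definition exactly.
- **MPI** (mean pixel intensity) — mean normalized intensity over the bone
  mask. Each slice is normalized by its own 99th-percentile intensity and
  clipped to [0, 1], which makes MPI invariant to global intensity rescaling
  (scanner gain) and bounded. In T2-weighted contrast, compact bone is
  nearly signal-free; water/lipid infiltration into resorbed bone raises
  MPI, so it serves as a bone-density-loss index.
- **BMA** (marrow area, mm²) — marrow mask pixel count times pixel area.

Per-slice identity `BA = BT · CL` holds by construction. Subject-level
values average the central seven slices (configurable); g is averaged per
slice rather than recomputed from subject-mean CL and BT — the difference
is second order, and the per-slice form parallels the BT averaging.

## Centerline extraction and length

The bone mask is thinned to a unit-width, topology-preserving skeleton
(`skimage.morphology.skeletonize`) after removing connected components
below 5 pixels (stray pixels from manual tracing; far below any plausible
bone area at 0.7 mm). The skeleton's 8-neighbor pixel graph is pruned of
spur branches (iterative removal of degree-1 pixels), and the longest
remaining simple cycle is the centerline loop. Diagonal edges that shortcut
an L-corner are removed so the cycle passes through every skeleton pixel.
If pruning empties the graph — a broken ("open") ring, which occurs in
thin-walled concave bones — the longest simple path over the unpruned
skeleton is used instead and the slice is flagged `open_ring`; these bones
are clinically the interesting ones, so the measurement is reported rather
than discarded.

Measuring the *physical length* of a digital path is the numerically
delicate step. Three estimators are provided:

- `chain` — 1 per edge step, √2 per diagonal step. Exact for axis-aligned
  paths, but it overestimates smooth digitized curves by ≈5.5% averaged
  over orientations; this bias does not vanish with resolution.
- `corrected` — Kulpa's weights (0.948 / 1.340), unbiased for straight
  segments averaged over orientations and within ≈0.1% on digitized
  circles of moderate radius. Used for open-ring paths.
- `equidistant` (pipeline default for closed rings) — the centerline is
  extracted directly as the zero level set of
  `dist(x, marrow cavity) − dist(x, outside)` via marching squares, i.e.
  the locus equidistant from the endosteal and periosteal boundaries, with
  subpixel interpolation. This avoids pixel-path orientation bias entirely
  and remains accurate when the cavity is only a pixel wide, where thinning
  skeletons collapse onto the cavity.

The equidistant default is what makes the measurement *consistent*: on
undeformed annuli spanning D_out 8–14 mm and BT 1.5–3.5 mm, the maximum BT
error is 0.26 mm at 0.7 mm pixels (below half a pixel), 0.15 mm at 0.35 mm,
and 0.08 mm at 0.175 mm; g errors are 0.076 / 0.026 / 0.019. Pixel-path
estimators plateau instead of converging.

## Phantoms

The outer contour is `r(θ) = (D_out/2)(1 + Σ aₖ cos(kθ + φₖ))` with
harmonic orders k ≥ 2 and amplitudes < 0.3 (keeping the contour simple and
star-shaped); the inner contour follows at a constant radial wall
thickness. A k = 3 harmonic emulates the largely triangular periosteal
contour of real fibulae. Ground truth (BA, CL of the mid-wall contour, BT =
BA/CL, ring-model g, BMA) is computed from the continuous contours by dense
polygonal integration (7200 vertices), never from pixels, so truth is
resolution-independent.

Rendering supersamples each pixel (default 8×8 subsamples), assigns tissue
intensities (bone 0.108, marrow 0.90, muscle 0.45, background 0.05 by
default — hypointense wall, hyperintense marrow, intermediate muscle), and
block-averages, emulating partial volume, the dominant error source when
the pixel size (0.7 mm) is a sizeable fraction of the wall (2–3 mm). Truth
masks use majority occupancy (≥ 50% of subsamples), the rounding a careful
manual tracer applies. Additive Gaussian noise (default σ 0.02 in image
mode) is applied at the target resolution. The grid is sized odd so the
ring center falls on a pixel center; with an even grid a near-pixel-sized
marrow cavity straddles four pixels and can disappear under the majority
rule, silently breaking ring topology.

What the phantoms do *not* emulate: anatomically realistic muscle
compartments, MR physics (T2 weighting, coil sensitivity profiles), motion,
chemical shift, or true proximal-to-distal shape progression — slice stacks
replicate one geometry with ≤ 2% scale jitter, because it is the averaging
behavior, not anatomy, that the pipeline needs to exercise. Passing the
phantom oracle therefore demonstrates geometric correctness of the
measurement chain, not robustness to every artifact of real scans.

## Synthetic cohorts

The cohort simulator draws per-subject BT, BA, g and MPI from a four-cell
model (sex × age group, split at 50 years inclusive on the younger side)
with per-sex linear age slopes centered on each group's age midpoint, plus
covariates: BMI (normal per sex), subcutaneous fat thickness (normal), and
a muscle-fat-infiltration class (categorical per group). Defaults are
packaged in `data/default_cohort.yaml`: group sizes (17/13/26/51), means
and SDs, and age ranges are study-derived values for a 107-subject 7T MRI
fibula cohort; they define the population being emulated, not targets any
analysis is graded against. Values not available per group — the age
slopes (BT −0.015 mm/yr and MPI +0.001/yr in women, 0 in men, matching the
qualitative female-specific age decline), the SFT distribution (5 ± 2 mm)
and the MFI class mix — are the package's own realistic choices, fixed
once.

Sampled values are truncated to physical ranges; g is truncated to the
study population's observed range (0.14–0.80), because below ≈0.14 the
marrow cavity falls under the 0.7 mm pixel size and the geometry is not
measurable at study resolution (and D_out = 2·BT/(1−g) diverges as g → 1).

*Table mode* emits the sampled values directly (used for replicate sweeps
and null calibration). *Image mode* renders a 9-slice phantom stack per
subject realizing the sampled BT and g — BA and CL are then implied by the
ring geometry and the recorded truth is updated accordingly — so the entire
mask-based measurement chain runs end to end. Generation is bit-reproducible
under a fixed seed.

## Statistics

Group comparisons use the pooled-variance Student's t-test (two-sided,
df = n₁ + n₂ − 2), matching the default of the common two-sample t-test
routines; Welch is available by option. Correlations are Pearson's r with
the two-sided p from the t transform with n − 2 df, plus the least-squares
line for display. Zero-variance samples yield p = 1 when means are equal
(no evidence) and an error otherwise. No multiple-testing correction is
applied by default — every test is reported at its raw p against α = 0.05;
Holm adjustment is available as a post-hoc helper. Both tests were checked
against brute-force permutation nulls (10⁵ permutations; agreement within
0.002 on the fixtures used).

Reproducibility of repeated segmentations is summarized as the coefficient
of variation (sample SD / mean). The noise-propagation analysis multiplies
each measurement by (1 + ε), ε ~ N(0, CV + leeway), default CV 1.3–1.5%
with a +2% leeway, re-computes the correlation p ten times, and reports
whether the significance classification at α ever changes. The leeway is
applied as an additive increment to the CV; its exact application is a
design choice fixed by config.

## Numerical and design notes

- Coordinate convention: row = y, col = x, pixel centers at integer
  coordinates, 0-based; all physical quantities in mm via the pixel
  spacing. Anisotropic in-plane spacing is accepted by I/O but rejected by
  morphometry, whose length arithmetic assumes isotropy.
- Central-slice selection is by index centering; with an even surplus the
  tie breaks toward the proximal (lower-index) side. 9 acquired → 7 central
  drops the first and last slice.
- Longest-cycle ties in loop extraction break by deterministic scan order;
  skeletons retaining junction pixels after pruning fall back to the
  longest cycle-basis cycle.
- `D_in ≤ 0` (wall thicker than the ring model allows) is reported as a
  negative value with a flag, never clamped.
- Problem sizes in the validation suite — 9 phantom geometries × 3
  resolutions, 100 table-mode and 3 image-mode cohort replicates, 200 null
  seeds, 10⁵ permutations — were chosen so the whole battery runs in a few
  minutes on one CPU while keeping Monte-Carlo error well below the margins
  being tested.

## Known limitations

- The method measures a single global wall thickness per slice; no
  per-angle thickness maps, no 3D continuity across slices, no porosity or
  trabecular measures.
- MPI normalization is a pragmatic convention; absolute MPI values are
  comparable only within a fixed normalization rule.
- The equidistant centerline requires an enclosed cavity; broken rings use
  the (slightly biased) skeleton-path length and are flagged.
- The cohort simulator samples BT, BA and g independently in table mode,
  although they are geometrically coupled; image mode enforces the
  coupling. Table-mode nulls are therefore calibration checks of the test
  battery, not of the geometry.
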