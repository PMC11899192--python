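# fibmorph

Cross-sectional cortical bone morphometry from segmentation masks, with a
fully synthetic validation harness.

Quantitative MRI studies of long-bone aging measure, on each axial slice, a
small set of geometric and intensity indices of the compact-bone wall:
bone area **BA** (mask pixels × pixel area), the medial-axis centerline
length **CL** of the wall, wall thickness **BT = BA / CL**, the
inner-to-outer-diameter ratio (**g-ratio**) of the equivalent ring

```
d = CL / π,   D_out = d + BT,   D_in = d − BT,   g = D_in / D_out,
```

a mean-pixel-intensity density-loss index **MPI**, and the enclosed marrow
area **BMA**. Per subject, BT is the mean of per-slice BA/CL over the seven
central slices. Cohort analysis then asks how these indices differ by sex
and age group (pooled-variance t-tests) and how they co-vary with age, BMI,
marrow area, subcutaneous fat and muscle fat infiltration (Pearson
correlations), and whether the conclusions survive segmentation-scale
measurement noise.

Real cohorts of this kind are not publicly deposited, so `fibmorph` ships a
first-class synthetic layer: deformed-annulus phantoms whose ground truth
(area, centerline length, thickness, g) comes from the continuous contours
by polygonal integration, and whole simulated cohorts with configurable
age/sex structure that can be rendered as image stacks and pushed through
the identical measurement path as real data. It is intended for method
developers who need a tested, reproducible reference implementation of the
ring-model morphometry, and for anyone who wants to know how much of a
cohort effect survives 0.7 mm pixels.

## Worked example

```python
import fibmorph as fm

# an annulus phantom with the cohort-average geometry
spec = fm.PhantomSpec(outer_diameter=10.9, wall_thickness=2.7)   # mm
image, bone, marrow, truth = fm.make_annulus_phantom(spec, rng=0)
sm = fm.slice_morphometry(image, bone, marrow)
print(f"true BT {truth.true_BT:.2f} mm   measured BT {sm.BT:.2f} mm")
print(f"true g  {truth.true_g:.3f}     measured g  {sm.g:.3f}")
```

prints

```
true BT 2.70 mm   measured BT 2.71 mm
true g  0.505     measured g  0.495
```

i.e. at the study resolution (0.7 mm pixels) the wall thickness is
recovered well within half a pixel and the g-ratio within 0.01 of the
closed-form truth for this geometry. An end-to-end synthetic study —
generate a 107-subject image-mode cohort, measure every subject through the
mask pipeline, run the full comparison/correlation battery:

```python
report = fm.run_synthetic_study(fm.RunConfig(seed=1))
print(report.summary())
```

reports, among other fields, `mean_abs_bt_error_mm: 0.037` — the mean
absolute truth-vs-measured wall-thickness error across all 107 rendered
subjects — and the sex-by-age-group t-test table in `report.comparisons`.

The same operations are available from the shell:

```sh
fibmorph phantom single --out phantom.png
fibmorph phantom cohort --mode table --seed 3 --out cohort/
fibmorph measure --input stacks/ --covariates cov.csv --out measured.csv
fibmorph stats --measurements measured.csv --out stats/
fibmorph study --seed 1 --out run1/
```

## Layout

| module | contents |
| --- | --- |
| `fibmorph.phantom` | annulus phantom spec, renderer, analytic truth |
| `fibmorph.cohort` | cohort simulator (table and image modes) |
| `fibmorph.mask_io` | NIfTI / PNG+sidecar / CSV readers and writers |
| `fibmorph.morphometry` | skeletonization, centerline loop, BA/BT/g/MPI/BMA |
| `fibmorph.stats` | t-tests, correlations, MFI contrasts, CV, noise propagation |
| `fibmorph.pipeline` | run configs and the end-to-end synthetic study |
| `fibmorph.cli` | `fibmorph` command-line entry point |

See `docs/methods.md` for the model assumptions, estimator choices (in
particular how the centerline length is made resolution-consistent), and
known limitations.
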