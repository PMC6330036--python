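# vertmorph

Density-weighted cross-sectional moment morphometry for vertebral
micro-CT, with a synthetic longitudinal phantom study generator.

## The problem

Bone strength depends on bone mass (how much mineral there is) and bone
quality (how that mineral is arranged). Volumetric bone mineral density
(BMD) captures only the first. Two cross-sectional indices capture the
second directly from calibrated CT density maps of a vertebral body:

* the **minimum cross-sectional moment of inertia** — the density-weighted
  second moment about the centroidal axis that minimizes it, an index of
  flexural (bending) strength, in mg·cm:

  I(θ) = ΣΣ r′² · BMD(x, y) dx dy,   r′ = |−sinθ·(x−X_g) + cosθ·(y−Y_g)|,
  I_min = min over θ of I(θ)

* the **polar moment of inertia** — the density-weighted second moment
  about the centroid itself, an index of torsional strength, in mg·cm:

  J = ΣΣ r² · BMD(x, y) dx dy,   r² = (x−X_g)² + (y−Y_g)²

with (X_g, Y_g) the density-weighted center of gravity of the bone pixels.
I(θ) is a quadratic form of the 2×2 second-moment tensor, so I_min is its
smaller eigenvalue and J its trace (the perpendicular-axis relation
J = I(θ) + I(θ+π/2) holds for every θ). Alongside the moments the package
computes volumetric BMD = mineral content / (d·ΣS(i)) over the L2–L4
analysis window (S(i) the bone area of slice i, d the inter-slice
interval), mean cortical thickness (medial-axis local thickness), and
vertebral body height/width by the superior/inferior intermediate-value
convention, each averaged over L2–L4.

These indices matter because mass and quality can dissociate: after a
growth insult such as a several-day fast, BMD can catch back up while the
moments — which are sensitive to where the mineral sits — do not. The
package ships a phantom generator that emulates exactly this study design
(control n=5 vs fasting n=6 rat cohorts, 14 days, 4-day fast, imaging
every other day, 1 mm slices) with closed-form ground truth, plus the
per-day two-group pooled-variance Student's t analysis used to read out
the time course.

It is intended for people building or validating bone-morphometry
measurement chains: every stage (stack I/O, segmentation, moments,
statistics) is importable on its own, and the phantom makes the whole
chain testable without animal data.

## Worked example

```python
import numpy as np
from vertmorph import phantom, pipeline, stats

params = phantom.PhantomParams(seed=1)
design = phantom.StudyDesign()

# one subject, one day: render and measure a full L2-L4 stack
state = phantom.subject_states(params, design, "control", 0)[0]
stack = phantom.generate_stack(params, state, np.random.default_rng(0))
m = pipeline.measure_stack(stack)
print(f"BMD {m['bmd']:.1f} mg/cm^3 | I_min {m['min_moment']:.2f} mg*cm | "
      f"J {m['polar_moment']:.2f} mg*cm | Ct.Th {m['cortical_thickness']:.2f} mm")

# the longitudinal two-group comparison (measurement model, no rendering)
table = phantom.simulate_measurements(params, design)
report = stats.timecourse_report(table, ["bmd", "min_moment"])
print(report[report.day.isin([2, 8, 14])].to_string(index=False))
```

prints

```
BMD 415.2 mg/cm^3 | I_min 3.55 mg*cm | J 8.84 mg*cm | Ct.Th 0.62 mm
  variable  day  mean_control  sd_control  mean_fasting  sd_fasting        t      p tier
       bmd    2    441.916793   15.475701    386.246795    7.888775 7.741939 0.0000  ***
       bmd    8    478.262881   17.411517    465.171807    9.205042 1.603350 0.1433   ns
       bmd   14    518.095225   18.336276    503.140820    9.903037 1.729457 0.1178   ns
min_moment    2      3.786538    0.249950      3.002512    0.126688 6.760221 0.0001  ***
min_moment    8      4.806906    0.314536      3.849094    0.154313 6.613764 0.0001  ***
min_moment   14      6.142817    0.427331      4.934900    0.215834 6.097148 0.0002  ***
```

The first line is the morphometry of one measured stack. The report shows
the dissociation the fasting phantom is built to exhibit: the BMD deficit
is large during the fast (day 2, ***) and gone by day 8 (ns), while the
minimum cross-sectional moment deficit persists at *** through day 14.

The same pipeline runs from the shell:

```
vertmorph all --seed 1 --out study_out        # simulate -> measure -> compare
```

which writes the TIFF+JSON slice stacks, `ground_truth.csv`,
`measurements.csv` (one row per subject × imaging day) and `report.csv`
(one pooled-t comparison per variable × day) under `study_out/`.

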