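# Methods

## Measurement model

All quantities are computed from calibrated per-pixel density maps
(mg/cm³) with isotropic in-plane pixel spacing (cm) and a fixed
inter-slice interval d (cm, default 0.1 = 1 mm, the in-vivo protocol's
value). Integrals are discretized as point masses at pixel centers
carrying their pixel area; the brute-force oracles in the test suite use
the identical rule, so implementation-vs-oracle agreement is limited only
by the linear algebra, not by quadrature differences.

**Centroid.** The center of gravity (X_g, Y_g) is density-weighted (not
area-weighted): X_g = Σ x·BMD / Σ BMD over all bone pixels. With this
choice I_min is the true minimum of I(θ) over all lines, since the moment
about any line through the density-weighted centroid is minimal among
parallel lines.

**Moments.** The distance from a pixel to the axis at angle θ through the
centroid is taken in the singularity-free form
|−sinθ·(x−X_g) + cosθ·(y−Y_g)|, which is finite at θ = π/2 and equals the
usual tanθ form with its √(tan²θ+1) normalization at all non-degenerate
angles. I(θ) is then a quadratic form of the 2×2 density-weighted
second-moment tensor about the centroid; I_min is its smaller eigenvalue
(computed in closed form), the principal angle θ* is reported in [0, π),
and the polar moment J is the trace. An isotropic tensor (circular
symmetry) is a genuine tie; θ* = 0 is reported for determinism. Moments
are computed over all bone pixels (cortical + cancellous), with no
compartment restriction, and the per-animal value is the mean over the
L2–L4 slice set (~18 slices at the default geometry). The mg·cm unit
marks a per-cross-section quantity; a slice sum would scale with slice
count, whereas the slice average matches the L2–L4 averaging convention
used for every other per-animal value.

**BMD bookkeeping.** S(i) is the bone-pixel area of slice i; bone volume
is d·ΣS(i); mineral content integrates BMD × pixel area × d over bone
pixels; volumetric BMD is their ratio, so BMD × volume = mineral content
holds identically. BMD is computed over the configured vertebra set
(default L2–L4).

**Segmentation.** Bone is density ≥ bone_threshold (default 160 mg/cm³, a
conventional in-vivo soft-tissue/bone cutoff; configurable), keeping the
largest connected component. The cortical compartment is the
boundary-connected shell: bone pixels of density ≥ cortical_threshold
(default 450 mg/cm³) reachable from the outer bone boundary, no deeper
than max_shell_depth_cm (default 0.2 cm). Partial-volume blur leaves a
thin sub-threshold bone halo outside the shell; bone pixels that can
reach the exterior without crossing the shell are merged into the cortex
when they form less than halo_fraction (default 0.25) of all bone pixels
— a larger exterior-reachable set means the ring is genuinely broken, and
the slice is flagged (ring_ok = False) and skipped by the thickness
measurement. Manual corrections are replayable JSON edit records
(polygon + forced label, later edits win) rather than an interactive UI,
so corrected analyses are reproducible.

**Cortical thickness.** Per-slice local thickness is twice the
medial-axis distance-transform value averaged over the skeleton
(skeletonization ties are broken with a fixed rng for determinism). On
curved rings two or more pixels wide the pixel-center boundary offset and
the skeleton's own off-center offset cancel on average, making the
estimator empirically unbiased (0.3% on the default shell at 0.005 cm
spacing); a one-pixel ring reads about one pixel high. Per-vertebra means
over intact-ring slices are averaged over L2–L4.

**Dimensions.** Body height is labeled-slice-count × d. Body width
follows the intermediate-value convention: the mean of the transverse
bone extents at the superior and inferior labeled slices. Both are
averaged over L2, L3, L4; a missing vertebra label is an error, not a
silent average of fewer values.

**Statistics.** Per (variable, imaging day): classical pooled-variance
two-sample Student's t (not Welch — the original analysis used a
spreadsheet t-test), two-sided, α = 0.05, df = n1+n2−2, sample (n−1) SDs,
tiers * <0.05, ** <0.01, *** <0.001, no multiple-testing correction
across days or variables. Zero pooled variance with equal means gives
t = 0, p = 1; with unequal means the comparison is flagged degenerate.

## The phantom generator

Each subject carries three elliptical vertebral bodies (L2/L3/L4 scale
factors 0.97/1.00/1.03, within-vertebra linear taper 6% so the superior
and inferior diameters straddle the mid value). A cross-section is a
cortical shell (default 850 mg/cm³, 0.05 cm thick) around a cancellous
interior (250 ± 30 mg/cm³ smoothed Gaussian texture), rendered by
pixel-center classification, blurred (σ = 0.8 px, partial volume) with
additive noise (15 mg/cm³). The texture is a smoothed Gaussian density
fluctuation, not resolved trabeculae: the moments depend only on the
macroscopic density distribution, and a 1 mm in-vivo protocol does not
resolve trabeculae either.

**Growth** is multiplicative per day (semiaxes and shell thickness
+0.7%/day — isometric cross-sectional growth, so the shell area fraction
and hence composite BMD stay unbiased; height +1%/day; cortical density
+1.2%/day; cancellous density +1.5%/day), giving the roughly linear
14-day rises expected in 6-week-old rats without claiming a specific
growth law.

**The fasting intervention** (days 0–4 by default) multiplies density
growth by −3 (net resorption: a marked BMD fall, matching the reported
markedly lower density during the fast) and geometry growth by 0 (growth
halt, no gross morphological change). After refeeding the relative
density and height deficits decay geometrically by 0.3/day (rapid
catch-up: the BMD deficit is negligible from day 8 = fast end + 4, the
configured recovery day), while the width deficit persists (decay 1.0).

**The quality perturbation** is an inward shift of cortical mineral: per
fast day the shell thickness multiplier grows by 0.2 (q = 0.8 after a
4-day fast, persisting afterwards), and the thickened shell's density is
scaled so that it carries the nominal shell mineral plus the cancellous
mineral of the annexed interior band. Total slice mineral — and therefore
BMD — is unchanged exactly, while the mass distribution moves toward the
centroid, lowering I_min and J by ~15% at matched BMD. This is the
simplest mechanism exhibiting the mass-recovery / quality-non-recovery
dissociation; it is a phantom device, not a biological claim. A known
side effect: the fasting phantom's measured cortical shell is thicker,
whereas the animal study this design emulates found no thickness
difference — the perturbation trades thickness fidelity for the moment
dissociation.

**Variability.** Per-subject size and density scale factors (CV 1% and
3%: an inbred young male cohort is anthropometrically tight, densities
vary more) come from independent random substreams derived from the
master seed via spawn keys (group, subject, tag), so regeneration is
bit-identical and independent of iteration order. Effect magnitudes were
chosen so the simulated significance tiers mirror the tiers the emulated
study printed (BMD **/*** during the fast, ns from day 8; moment
differences **/*** persisting to day 14).

**Measurement model.** `simulate_measurements` multiplies the analytic
per-subject ground truth by an independent Gaussian error of CV 0.2% per
value (repeat-scan precision of a stable in-vivo protocol). Replicated
statistical experiments (the 200-study type-I calibration, the 100-study
dissociation fraction) run on this model; the imaging chain itself is
validated separately by noiseless parameter recovery (every quantity
within 2% of ground truth at 0.005 cm spacing, thickness within half a
pixel), whose residual discretization bias is common to both cohorts and
cancels in the group comparison. Problem sizes throughout (200 × 200
grids at 0.005 cm, 100–200 replicates) were chosen as the smallest at
which the discretization and Monte-Carlo errors are comfortably inside
the tolerances being checked.

What passing these tests shows — and does not show — about real data:
the pipeline provably recovers known geometry/density truth through
rendering, blur, noise, segmentation and the full statistical readout,
and its t-test is correctly calibrated under the null. It does not show
that real vertebrae satisfy the elliptical-shell model, that real fasting
produces the assumed inward redistribution, or anything about trabecular
microarchitecture, which the phantom deliberately does not model.

## Numerical choices and degenerate inputs

* Eigen tie (isotropic tensor): θ* = 0, detected at relative scale 1e−12.
* Empty bone mask: centroid/moments raise; the slice is excluded upstream
  and the per-animal value uses the remaining slices (all-excluded is an
  error).
* Out-of-body slice indices render as all-zero maps.
* 16-bit stack quantization: density = 0.05·v − 200 by default, so
  round-trips are exact to 0.05 mg/cm³ and moderately negative noise
  excursions survive.
* Anisotropic pixel spacing is rejected at read time (the discretization
  assumes square pixels).
* Unknown config keys are rejected with the offending dotted path named.

## Known limitations

* No trabecular micro-architecture (connectivity, Tb.N), no projection
  physics, beam hardening or contrast-agent modeling; the phantom
  emulates calibrated density maps directly.
* The cortical/cancellous split is an explicit stand-in for the scanner
  vendor's unpublished rule; on real data the thresholds and the manual
  edit files are the control points.
* Body height is quantized to the slice interval (slice count × d), so at
  d = 1 mm the phantom's height resolution is coarse; group comparisons
  of height on rendered stacks can be degenerate at small n and are
  flagged rather than hidden.
* The one-pixel-wide ring reads about one pixel thick (documented bias of
  the medial-axis estimator at its resolution limit).
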