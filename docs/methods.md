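# Methods

## Density calibration

Raw scanner units are mapped to relative physical density by the two-point
linear rule `ρ(v) = 1050 · (v − μ_air)/(μ_blood − μ_air)` mg/cc, with
`μ_air`/`μ_blood` the mean raw intensity of an exterior-air ROI and a
descending-aorta blood ROI drawn on the *same* image.  Because anchors are
refit per image, any affine drift of scanner output cancels exactly
(`calibrate(a·raw + b)` with refit anchors ≡ `calibrate(raw)`), which is
the purpose of the step.  Negative calibrated values (noise below air) are
retained: clamping would bias ROI means and mass sums.  Each time point is
calibrated with its own anchors; reference ROIs are therefore required per
image rather than propagated.

## Analysis masks

Lobe contours inevitably include extra-pleural tissue.  The five lobe
masks (tumor removed first) are combined into one lung mask, eroded twice
by one voxel with the full 3×3×3 (26-neighbourhood) structuring element —
"one voxel in all dimensions" is read to include diagonals, with the
6-connected cross exposed as an option — and each lobe is **intersected**
with the eroded combined lung.  The intersection realizes erosion *from
the exterior of the lung only*: voxels on an interlobar fissure deep
inside the lung survive, the pleural shell does not.  Outside-image voxels
count as background.  Tumor removal defaults to preceding erosion (the
exposed cavity wall is then also eroded); the order is configurable, and a
test demonstrates when it matters.

## Measures and classification

Per ROI: mass = Σ density·voxel-volume (mg), density = mean (mg/cc),
volume = count·voxel-volume (ml); `mass = density · volume` is an identity
up to rounding and is asserted to 1e-9 relative.  Percent changes require
a positive baseline; empty ROIs are errors, not zeros.

Resolution labels derive from atelectasis volumes: fractional reduction
f > 0.80 → full, 0.20 ≤ f ≤ 0.80 → partial, f < 0.20 *or* absolute
decrease < 15 ml → none.  Boundary decisions are frozen as: f exactly
0.80 → partial, f exactly 0.20 → partial, decrease exactly 15 ml → not
floored.  When the floor conflicts with the fraction (tiny baselines) the
floor wins — it exists to guard against delineation noise, which dominates
small volumes.

## Rigid plan transfer

Bone alignment is the closed-form orthogonal-Procrustes/Kabsch fit (via
`scipy.spatial.transform.Rotation.align_vectors`) on corresponding bone
landmarks restricted to a sternum/spine box; it is exact for noiseless
rigid motion and reports the residual RMS.  Carina alignment matches the
carina-mask centroids and is translation-only by construction.  Followup
volumes are resampled onto the baseline grid (trilinear for scalars,
nearest-neighbour for labels, air/background fill outside the field).
Manual/intensity-based fusion of the clinical workflow is deliberately
replaced by these deterministic schemes for reproducibility.

The dose engine is a **toy** and is documented as not clinically valid:
each beam deposits `weight · MU · exp(−μ_eff · d_rad)` inside the
divergent projection of its aperture polygon from a virtual source
(SAD 1000 mm), where `d_rad` is the density-weighted path length
(density/1000 per mm) integrated along the beam axis in a beam-aligned
frame (parallel-ray approximation for depth; in-plane spacing must be
isotropic for the rotation resampling).  Defaults: μ_eff = 0.005/mm
water-equivalent.  No scatter, inverse-square or fraction-weighted
accumulation: dose is computed once per geometry, representing the
worst case in which the anatomical change is present from the first
fraction.  Only *relative* dose changes are meaningful.  Plans are
normalized once, on the planning image, so the isocenter receives the
prescription; the engine itself is linear in beam weight.

## DVH constraints

D_max/D_mean/D_min are extrema/volume-weighted mean over the structure;
V_x is the percent of structure volume with dose ≥ x (closed lower bound);
V_Rx is V_x at the prescription dose on the GTV (reported both in Gy-based
and %-prescription form upstream to avoid committing to one convention).
A constraint is met when value ≤ limit (limits are maxima; equality is
met).  Defaults: spinal cord D_max 50.5 Gy, esophagus D_mean 34 Gy, heart
V40 ≤ 50 % and V60 ≤ 30 %, and D_mean ≤ 20 Gy, V20 ≤ 30 %, V30 ≤ 20 % for
each of three lung definitions — lungs (union of the five lobes, which
includes atelectasis), lungs−GTV, lungs−CTV.  GTV is delineated per time
point; CTV is rigidly carried from the planning anatomy.  A constraint has
*improved* when unmet at baseline and met at followup, *worsened*
conversely.  The cohort change table reports mean/stdev/min/max per
metric and alignment, the fraction of changes exceeding 1/2/5/10 Gy-or-%,
and the number of patients with at least one |change| ≥ 5.

## Statistics

Wilcoxon rank-sum (two-sided, unpaired): exact when min(n) ≤ 10 and the
pooled sample is tie-free, via the classic counting recurrence for the
Mann–Whitney U null distribution (cached per group-size pair — cohort
group sizes of 4/5/9 demand exact handling, and caching keeps 10⁴-replicate
null calibrations cheap); otherwise the normal approximation with tie and
continuity correction.  The F-test uses `F = s_x²/s_y²` against the F
distribution, two-sided.  α = 0.05 throughout; no multiple-testing
correction is applied (none is applied in the analysis this mirrors), so
p-values are per-comparison.  For sessions with repeat scans, pairings are
enumerated matched-index-first and the intra-patient SD across pairings is
reported.

## Synthetic cohort generator

The phantom is a 240 mm world cube: elliptic-cylinder body (1000 mg/cc),
five axis-aligned ellipsoid lobes (healthy parenchyma 260 mg/cc), heart,
esophagus, spinal cord, spine + sternum bone with seven alignment
landmarks, a carina ball, an aortic blood ROI and an exterior-air ROI.
All shapes have closed-form volumes, so truth records come from geometry,
never voxel sums.  The default grid is 96³ at 2.5 mm; cohorts use 64³ at
3.75 mm, the coarsest grid at which lobe-boundary discretization keeps
class-mean density-change error well inside the generator's ±2
percentage-point contract.

Atelectasis is a consolidated core (1050 mg/cc, default 85 % of the
right lower lobe, tumor nested inside) of which a fraction `r` re-aerates
by followup: the resolved tissue reappears as an aerated shell at density
ρ_a with volume set by mass conservation, while an edema excess-mass
fraction `e` disappears on resolution (resolved mass is divided by 1+e) —
the mechanism hypothesized for net mass loss.  The lobe boundary moves
outward correspondingly; axial expansion is capped (×1.25, top face
anchored) so a fully re-aerating lobe stays inside the thorax, with the
remainder taken in-plane.  Tumor regression shrinks the nested tumor; the
lobe-minus-tumor truth is invariant to it by construction.  Healthy lobes
get small fractional density/volume jitters (SD 2 %/3 %).  Noise is
additive Gaussian in raw units, default equivalent to 20 mg/cc — the
visible parenchyma noise scale — and the raw map is affine
(density ↦ slope·density + intercept, default slope 1, intercept −1000, so
air ≈ −1000 and water ≈ 0 raw units).  The followup anatomy is displaced
by a known rigid translation (default a few mm), which both alignment
schemes must recover; rotational setup error is exercised on landmark sets
directly rather than through the voxel phantom, whose shapes are
axis-aligned.

Cohorts assign patients to full/partial/none in 22/50/28 % proportions by
largest-remainder rounding (18 patients → 4/9/5).  Per class, the
programmed per-patient density-change targets (defaults −66 / −25.6 /
−17 %, SD 5 points) are drawn by stratified inverse-CDF normal sampling:
marginals are exactly N(mean, sd) while class means track the programmed
targets far more tightly than sd/√n, which the generator's contract
(class-mean within ±2 points at class sizes near 10) requires.  The
resolution fraction is drawn per class (full 0.85–0.98, partial 0.30–0.70,
none 0.02–0.12, consistent with the volume classifier), and the aerated
density ρ_a is then solved in closed form so the lobe-minus-tumor density
change hits its target (clamped to [60 mg/cc, consolidated density];
truth records always reflect the achieved values).  Per-class edema
fractions (0.10 / 0.35 / 0.15) produce qualitatively negative mass
changes; mass is not an independently programmable target because mass,
density and volume changes are linked by `1+m = (1+d)(1+v)` and a pure
resolution-linked edema mechanism cannot produce a large mass loss in a
lobe whose volume barely changes.

Phantom truth records are defined on whole (tumor-free) lobe regions, and
the phantom/cohort drivers therefore measure on un-eroded lobes by
default.  At phantom resolution the two-voxel erosion shell is a large and
*time-point-dependent* fraction of the lobe (the lobe grows, so the shell
fraction shrinks), which makes eroded-mask mass changes of a
mass-conserving phantom systematically positive; the erosion stage is
validated separately against brute-force morphology oracles, and eroded
measurement remains the default for the CLI/clinical path.  What passing
phantom tests show is that the measurement chain is unbiased on geometry
whose truth is known; they do not certify behaviour on real anatomy with
partial-volume boundaries, motion artifacts or delineation error, none of
which the generator emulates.

## Numerical choices

- Grid congruence tolerance 1e-6 mm; downstream stages refuse mismatched
  grids.
- Voxel membership of analytic shapes is centre-inclusion; voxelized
  volumes agree with analytic truth within one voxel shell of the surface
  area (tested with the Thomsen area approximation).
- Exact Wilcoxon two-sided p = min(1, 2·min tail) including the observed
  statistic; verified against full enumeration and scipy.
- Bisection sweeps for classifier boundaries run to 1e-3 precision in
  percent or ml.
- Degenerate inputs are explicit failures: empty ROIs, zero baselines,
  collinear landmarks, zero denominator variance, blood anchor not above
  air anchor.

## Known limitations

Axis-aligned analytic shapes (no realistic airways, fissure curvature or
oblique scans); translation-only voxel-level setup error; toy dose with no
scatter/inverse-square; no deformable registration or dose accumulation
across fractions; no 4-D/motion modelling; lungs are modelled with uniform
compartment densities, so intra-lobe texture effects on erosion bias are
not represented.
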