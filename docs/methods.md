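# Methods

This note documents the models, numerical choices and defaults behind
`vesselwarp`, and what the synthetic phantoms do and do not establish
about clinical data.

## Coordinate conventions and units

Right-handed world coordinates in millimetres; image voxel indices are
0-based with world position `origin + index * spacing` at voxel
centers. Pullback frame 0 is the **distal** end of the region of
interest (the imaging catheter starts distal and is pulled back
proximally). The internal unit system for hemodynamics is mm–s–MPa, so
Windkessel resistance is MPa·s/mm³ and capacitance mm³/MPa; mmHg, cm/s
and ml/min are converted at every interface (1 mmHg = 133.322387415 Pa).

## Phantoms

A phantom is a tube swept along an analytic centerline (straight,
circular arc, helix, or interpolating spline) with a radius profile
`r(s)`. A stenosis is a compact cosine bump: at the throat the radius
is `r₀(1 − severity)`, so a severity of 0.5 on a 2 mm lumen gives the
closed-form minimum slice area π mm². A dissection is modeled as a
circumferential shell: the false lumen occupies the annular sector
`r + m ≤ ρ ≤ r + m + g` over a given angular extent and arc-length
window, where `m` (default 0.15 mm) is the membrane (flap) thickness
keeping the two lumens disjoint and `g` the radial gap. This is the
simplest geometry with a quantifiable false-lumen area: the channel
wall area per unit length is `θ(2r + 2m + g) + 2g`.

Projections use an ideal pinhole (cone-beam) model with configurable
source and detector distances (defaults 1000/1500 mm, 0.2 mm detector
pixels, magnification 1.5 at the target). Fiducials default to a
12-point non-coplanar cage — sufficient for DLT calibration; no
specific physical calibration phantom is reproduced. Silhouette
boundaries are computed per centerline sample as the projection of
`c ± r·ê`, with `ê ⟂` both the viewing ray and the local tangent; for
clinical-scale geometry (r ≈ 2 mm, source distance ≈ 1 m) this
approximation of the true perspective silhouette is accurate to
O(r²/D) ≈ 5 µm. Fiducial detections carry i.i.d. Gaussian pixel noise;
contour noise perturbs the OCT contour radius per point. The same seed
reproduces every phantom product bit for bit.

Deliberately **not** emulated: OCT speckle and texture, X-ray
attenuation physics, calcification, catheter-induced vessel
straightening, and cardiac/respiratory motion. Tests passing on
phantoms therefore establish the geometric and numerical correctness
of the operators — not robustness to the full noise structure of
clinical images, which enters through the operator-traced contours and
splines this package consumes as inputs.

## Biplane reconstruction

Calibration is the normalized DLT: ≥ 6 non-coplanar correspondences,
homogeneous least squares via SVD, RMS reprojection error reported.
Triangulation returns the midpoint of the common perpendicular of the
two back-projected rays and rejects rays within 1° of parallel. The
acquisition-protocol rule that views be separated by more than 45° is
enforced as a warning (the geometry still triangulates); coincident
axes are an error.

The two lumen boundaries per view correspond across views by
**normalized arc length** — a choice, since nothing in biplane
geometry fixes the correspondence; it is exact for silhouettes of
near-uniform tubes and degrades gracefully with taper. The centerline
is the per-parameter midpoint of the left/right 3D boundary curves,
fitted with a smoothing spline (default residual budget 0.1 mm²
summed over samples — small enough that a straight phantom stays
straight to well under 0.01 mm). The midpoint locus is a deliberate
assumption (an inscribed-sphere center would differ for asymmetric
lumens); on phantoms it recovers centerlines to ≈ 0.006 mm (straight)
and ≈ r²/2R_bend (arcs). Frames are rotation-minimizing
(double-reflection transport), not Frenet, because Frenet normals are
undefined at the inflection points of near-straight arteries.

## OCT label volumes

Contours are rasterized by point-in-polygon tests at voxel centers
(scikit-image `polygon2mask`); false-lumen contours are rasterized
after the true lumen so the false-lumen label wins on overlap —
dissection membranes are thin and the false-lumen tag drives the
downstream area attribution. "Basic" inter-slice interpolation is
per-label **signed-distance interpolation**: the SDFs of the two
bracketing annotated slices are blended linearly by slice position and
thresholded at zero, which interpolates shape rather than copying
pixels; stack ends are nearest-slice copies; annotation gaps above 10
slices are an error. Resampling to the isotropic working grid (default
0.075 mm in the single-volume tools, 0.12–0.15 mm in the end-to-end
pipeline, where three stages multiply the voxel count) is
nearest-neighbor only — labels are categorical.

## Straight-to-anatomical warping

The OCT-based centerline of the straightened volume is the per-slice
centroid of lumen voxels. Terminal slices whose voxel count falls
below 95% of the median of the next 20 slices inward are trimmed: on
*warped* volumes these are partial oblique end cuts whose centroids
sit off-axis, and the same rule is harmless on straight volumes.

The slice map assigns each pullback slice a rigid pose:

- **Arc-length correspondence** is piecewise linear through landmark
  pairs, defaulting to matched endpoints (normalized arc length) when
  no side-branch landmarks exist. The arc length used is that of the
  *smoothed anchor curve* (below), not of the raw centroid polyline,
  whose lateral jumps at dissection onsets would otherwise advance the
  mapped position discontinuously between adjacent slices.
- **Source frames are the grid triad** (ex, ey, ez). Slices of a
  straightened pullback volume are orthogonal to the grid axis by
  construction; per-slice centroid tangents would tilt slices
  spuriously wherever the centroid jumps (dissection onset) and make
  the forward field non-Lipschitz. The centroid centerline contributes
  only the arc-length parameterization and the in-plane anchor points.
- **Anchors are Gaussian-smoothed** over 2 mm of arc length so that
  rigid per-slice motions do not chase high-frequency centroid jumps;
  the anchor is where the slice attaches to the target centerline.
- **Target frames** are the X-ray centerline's rotation-minimizing
  frames, globally rolled so the proximal slice's pose is rotation
  minimal with respect to the source axes (an arbitrary RMF seed can
  otherwise introduce a constant large roll whose displacement
  gradient breaks the fixed-point inversion); an optional global roll
  parameter remains for landmark-based roll registration. Bends with
  radius below 5× the lumen radius are rejected — the slice slabs
  would self-intersect.

The forward field is evaluated **densely on every slice** (the rigid
transform is globally defined), which keeps it smooth across label
discontinuities; the lumen-dilated band (3 voxels) defines its
meaningful support. The inverse is computed by fixed-point iteration
`v ← −u(y + v)` on target voxels near the mapped lumen, initialized by
splatting the negated forward vectors at their target voxels,
with tolerance 0.01 voxel and a 50-iteration cap; convergence is
judged on the core support (images of band voxels), the dilated fringe
serving only as an interpolation buffer. The composition residual
`|u(y+v) + v|` is reported on the field. Labels are pulled back by
nearest-neighbor lookup at `y + v(y)`; the target grid is auto-sized
from the forward-mapped bounding box padded by 2 voxels.

One physical subtlety: per-slice rigid bending has Jacobian `1 − κx`
across the bend, so voxel *counts* in the bent configuration
under-represent structures on the inner side of the bend by ≈ κ·x̄ —
about 4% for a false lumen 2.4 mm inside a 60 mm bend. This is a
property of the geometry, not an artifact; cross-section areas
measured orthogonal to the centerline are conserved (within 2% at the
working resolution).

## Surface meshing

Marching cubes at the 0.5 level of the zero-padded binary mask;
false-lumen wall faces are those whose centroids are nearer to
false-lumen than to true-lumen voxels (distance-transform lookup).
Smoothing is uniform-weight Laplacian, defaults 20 iterations at
λ = 0.5 (no reference values exist; both are recorded in run
provenance as assumed). Laplacian smoothing shrinks — the relative
volume change is reported and > 5% warns. Clipping uses planar cuts
orthogonal to the centerline tangent at the two clip stations; the
open boundary rings are capped by centroid fans (tagged inlet at the
proximal end, outlet at the distal end, cap cross-section areas
recorded), optionally after straight prismatic extensions along the
end tangents. Extension faces carry a dedicated `extension` tag so the
wall-area metrics can exclude them; the default extension length in
CFD practice is ~3 local diameters, but the pipeline default is 0 (the
Poiseuille oracle needs no entrance length). The export bundle for an
external solver records the volumetric-meshing and fluid parameters
verbatim (growth scale 1.8; boundary layer 6 × 0.15 mm; ρ = 1050
kg/m³, µ = 3.5·10⁻³ Pa·s; Δt = 2·10⁻³ s, 3 cardiac cycles) without
ever executing a volumetric mesh or flow solve here.

## Hemodynamics

Duplex ultrasound provides only waveform extrema, so inlet waveforms
are piecewise-sinusoid templates scaled to PSV/MDV exactly:

- **triphasic** (healthy FP pattern): forward systolic lobe (30% of
  the period), reverse early-diastolic lobe (15%), forward
  late-diastolic lobe (25%, amplitude 0.2·PSV), zero rest;
- **monophasic** (post-stenotic): forward lobe (35%) plus a low
  secondary lobe (amplitude 0.05·PSV) filling the remainder.

Phase fractions and secondary amplitudes are template parameters with
the above defaults; the cardiac period defaults to 1 s (not fixed by
any measurement used here). The template's time average is positive
for every PSV/MDV pair in the reference velocimetry table. Flow is
`Q(t) = v(t)·A_inlet` with the velocity treated as the spatial mean;
the parabolic inlet profile `v(r) = 2v̄(1 − (r/R_eff)²)` is evaluated
per cap vertex and rescaled so the face-integrated flux equals
`v̄·A` exactly (R_eff is the maximal centroid distance, so non-circular
caps are handled by the same radial law plus rescaling).

The two-element Windkessel `C dP/dt = Q − P/R` is integrated with
classical RK4 at the solver's fixed step 2·10⁻³ s, repeating cardiac
cycles until the cycle-to-cycle maximum difference falls below
0.1 mmHg (≤ 20 cycles) and returning the last cycle. Calibration
solves `{max P = 120, min P = 80}` mmHg by damped Newton in
log-parameters with a finite-difference Jacobian, seeded by the exact
mean-pressure balance `mean(P) = R·mean(Q)` and the sinusoidal
amplitude relation; a constant flow leaves C unidentifiable and is
rejected. The calibration targets are only the idealized 120/80
extrema — no published per-patient R/C values are targeted, as the
procedure that produced them is not fully specified. Note the stopping
rule bounds the *cycle-to-cycle* change; comparing against closed
forms requires converging tighter (the tests use 10⁻⁵ mmHg).

The desk-scale WSS oracle is fully developed Poiseuille flow,
`τ = 4µQ/(πr³)` (0.0557 Pa at Q = 100 mm³/s, r = 2 mm,
µ = 3.5·10⁻³ Pa·s). On a mesh, wall faces are binned by arc length
(50 bins), each bin's effective radius is the median radial distance
of its true-lumen faces, and false-lumen faces are attenuated by 0.05
— a stand-in for the near-stagnant flow CFD predicts inside dissection
channels, chosen so that false-lumen faces fall below the 0.5 Pa
threshold whenever the main lumen is below 10 Pa. This oracle
reproduces scaling (r⁻³, linearity in Q) and threshold logic, not the
secondary flows, entrance effects or skewed profiles of a 3D solver —
which is why clinical TAWSS area magnitudes are out of scope and only
pattern-level statements (dissections strictly increase low-TAWSS
area; false-lumen surfaces are overwhelmingly low-TAWSS) are made.

## TAWSS reporting

TAWSS is the trapezoidal period average of per-face WSS magnitude.
Classification is strict (`< 0.5`, `> 7` Pa): boundary-equal faces are
normal. Caps and extensions are excluded; the low/high/normal areas
partition the wall area to floating-point accuracy. Group summaries
report mean, sample (n−1) SD and pooled-variance Student t-tests
(Welch by flag); significance at p < 0.05.

## Defaults that are assumptions

| Parameter | Default | Status |
| --- | --- | --- |
| smoothing iterations / λ | 20 / 0.5 | assumed, recorded in provenance |
| extension length | 0 (pipeline), 3 diameters (practice) | assumed |
| cardiac period | 1 s | assumed |
| triphasic phase fractions | 0.30 / 0.15 / 0.25 | assumed template |
| late-forward, plateau amplitudes | 0.20·PSV, 0.05·PSV | assumed template |
| false-lumen attenuation | 0.05 | assumed oracle parameter |
| anchor smoothing | 2 mm | numerical regularity choice |
| inverse-field tolerance / cap | 0.01 voxel / 50 iterations | numerical choice |
| annotation gap limit | 10 slices | numerical choice |

## Known limitations

- The in-plane roll of the warped lumen about the centerline is fixed
  by proximal anchoring (plus an optional global roll); true per-slice
  roll registration would need circumferential landmarks.
- Centroid-based OCT centerlines are biased by large false lumens;
  anchor smoothing bounds, but does not remove, the effect.
- The per-slice rigid warp cannot represent catheter-induced
  straightening or non-rigid wall deformation.
- Surface areas inherit marching-cubes stair-stepping at coarse
  working resolutions; the cylinder-area convergence tests quantify
  the effect (error ≈ first order in voxel size after smoothing).
- The Poiseuille field is an oracle, not a CFD surrogate, as discussed
  above.

## Problem sizes

Default test and acceptance runs use 30–50 mm phantoms with 2 mm lumen
radius at 0.05 mm OCT pixels, 0.2 mm frame spacing and 0.12–0.15 mm
isotropic warping grids (≈ 0.4–5 M voxels per stage); these sizes were
chosen so the complete suite and the acceptance script each finish in
about a minute while keeping discretization errors well inside every
stated tolerance.
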