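# Methods

## Geometry

The vitreous cavity of a pseudophakic eye is a sphere of axial diameter
24/25/26/31 mm with the anterior 2.5 mm cap removed; the flat face stands in
for the IOL plane and its rim circle for the limbus.  The truncation depth
and the landmark arc distances are anatomical constants held fixed in mm as
the diameter changes; only the sphere scales.  Landmarks are placed by arc
length along great-circle meridians (`s = R Δθ`): the ora serrata of the
superior/nasal/temporal/inferior quadrant lies 7.4/5.5/6.9/6.7 mm posterior
to the limbus, the equator a further 6.5 mm.  The measured "quadrant" is the
band between ora serrata and equator — retinal tears almost always lie
anterior to the equator, and the published 0 % sitting/inferior cells are
geometrically consistent only with the band, not with a full quadrant
reaching the posterior pole.

Frame: origin at the sphere centre, +z anterior, +y superior, +x nasal
(right eye; left eyes mirror x).  Azimuth runs from the superior meridian
with nasal at +90°; the quadrant boundaries at 1:30/4:30/7:30/10:30 are the
±45° meridians about the four cardinal directions.  Band areas are exact
spherical zone sectors, `(90/360) · 2πR² (cos θ_ora − cos θ_eq)`; the cavity
volume is the sphere minus the removed cap, 7019.0 mm³ at 24 mm.

A triangulated boundary mesh (UV sphere + truncation disc, ring latitudes
snapped to every band boundary so face tagging is exact) backs the area
oracle and OBJ/PLY/STL export; at the default azimuthal resolution 256 the
tagged-area discretisation error is below 0.01 %.

## Positions

Each posture fixes the "up" unit vector in the eye frame: supine +z, sitting
+y, prone −z, lower temporal/nasal ±x (nasal axis).  "Prone with closed
eyes" models the residual elevation of the globe measured in patients who
superficially hold a strict prone position: up = (0, sin α, −cos α) with
α = 16.1° by default, a rotation about the nasal–temporal axis only (the
source measurement quantifies no torsion or adduction, so none is modelled).
The published "lateral" rows, which appear only for the superior and
inferior bands, are evaluated as the lower-temporal decubitus; for those
bands the two decubitus variants differ only through the small nasal/temporal
ora asymmetry.

## Interface model

With σ = 0.072 N/m, Δρ ≈ 997 kg/m³ and g = 9.81 m/s², the capillary length
is ℓ_c = 2.713 mm and the Bond number at R = 12 mm is ≈ 20: gravity
dominates, so the bulk interface is a horizontal plane and capillarity acts
only in a boundary layer at the wall.  A full constant-mean-curvature solve
of the 3-D interface is deliberately out of scope.

*Fill level.*  Cross-sections of the cavity perpendicular to "up" are discs
cut by the half-space behind the truncation plane; their areas are analytic
(circular segments).  The volume profile is their cumulative trapezoidal
quadrature on 2000 uniform slices, and the fill level is obtained by
bisection to a relative volume tolerance of 1e-9 against that profile.  The
profile total agrees with the closed-form cavity volume to ~1e-6 relative.

*Meniscus.*  In the default "meniscus" mode the contact line is lifted above
the flat level by the planar-wall first integral of the 2-D Young–Laplace
equation, `rise = ℓ_c sqrt(2 (1 − sin θ_eff))` with
`θ_eff = clamp(θ_c + α, 0°, 90°)`; α is the wall tilt from vertical at the
flat-level wall intersection (positive where the wall opens upward like a
bowl, which suppresses the climb; overhangs amplify it up to the clamp at
√2 ℓ_c).  The contact angle θ_c = 38.8° is applied so that water climbs —
the direction that reduces gas coverage.  An independent numerical
integration of the meniscus profile (tangent-angle parametrisation, RK45)
agrees with the closed form to well under 5 % across |α| ≤ 30° and backs it
in the test suite.  On a sphere the flat-level intersection has a single
inclination, so the contact line is azimuth-uniform except where the level
meets the truncation plane; there the plane's own tilt is used and the
stored threshold is equivalent to clipping at the plane's rim for any
retinal-band query.  Optional refinements (off by default): a ≤ 5-iteration
fixed point that re-evaluates the tilt at the lifted contact height, and a
re-balance of the flat level for the water held in the meniscus ring
(estimated as perimeter · ℓ_c² · cos θ_eff).  The ring holds up to ~5 % of
the cavity volume at mid fills, more than a naive estimate suggests, but the
re-balance is kept opt-in: it shifts different reference cells in opposite
directions and the uncorrected budget is the cleaner baseline.

*Coverage.*  A wall point is gas-covered iff strictly above the contact line
at its azimuth about the up axis.  Bands whose analytic height extremes
clear the whole contact line resolve exactly to 0 or 100 %; otherwise the
covered patch is integrated on a 1024-azimuth × adaptive-polar (≈ 8 samples
per degree, 64–512) midpoint grid, normalised by the same quadrature of the
full band so discretisation cancels.  Percentages are reported rounded
half-away-from-zero to integers, matching the all-integer reference tables;
raw floats are retained in the CSV output.

## Reference data and oracles

The packaged CSV transcribes all 968 published table cells (4 eye sizes ×
positions × 11 gas levels, per band); load-time validation enforces
integer range, monotonicity in gas fraction and 100 % at full fill.  Two
independent oracles check the simulator: the tagged surface mesh (areas) and
a voxel brute force (coverage) that voxelises the cavity on a cell-centred
grid, fills it from the bottom by voxel count (voxel layers tied at the
fill level are split fractionally) and classifies exposed wall voxels by
band.  Exposed faces are weighted by the inverse L1 norm of the analytic
surface normal, which removes the staircase anisotropy of voxel surface
areas; at 200³ the worst disagreement with the analytic flat-mode coverage
across 72 spot cells is 0.65 percentage points.

## Agreement with the published CFD tables, and known limitations

On the full grid the meniscus mode matches the published tables with a mean
absolute difference of 4.4 points (85 % of cells within 10); flat mode gives
5.4 points (80 %).  The structural cells are robust: bands entirely inside
the bubble or entirely submerged reproduce the published 100 %/0 % cells
exactly, in particular the flooded nasal band in lower-nasal and the flooded
inferior band in sitting from 90 % gas down.  Position rankings (supine for
inferior or multi-quadrant breaks; sitting / lower temporal / lower nasal
for superior / nasal / temporal breaks) reproduce the published
recommendations in both modes.

The main systematic deviation is the size of the meniscus climb.  Planar-wall
theory with the stated σ and θ_c predicts climbs of 2–4 mm where the wall is
near-vertical or overhanging; the published tables are consistent with an
effective climb of ≲ 1 mm in those configurations (e.g. supine mid fills, or
the sitting superior band at low gas, where the predicted climb would end
the printed 100 % run two columns early).  Where the wall is bowl-like and
the predicted climb is sub-millimetre — e.g. prone-with-closed-eyes at 90 %
gas, the configuration in which the reference work illustrates the meniscus —
the meniscus mode lands within a few points of the printed values while the
flat mode overshoots by ~20.  The likely cause is the finite mesh resolution
of the reference CFD, which cannot resolve a boundary layer much thinner
than its cells; a static model faithful to the stated physical constants
cannot reproduce both behaviours at once.  Both modes are first-class and
reported side by side by `scripts/acceptance.py`.

Other limitations, by design: no transient dynamics, shear stress or bubble
break-up; no gas expansion/absorption kinetics (air properties only, volumes
given as fractions); a single bubble; rigid spherical globes (no high-myopia
irregularity); no eye movements; the IOL face wets like the retina.
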