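# gastamp

Static capillary-equilibrium simulation of intraocular gas tamponade
coverage in model eyes.

After pars plana vitrectomy for a rhegmatogenous retinal detachment, a gas
bubble is left in the vitreous cavity to press against the retinal breaks
while laser adhesion matures.  The bubble shrinks over days, and how much of
each retinal quadrant it still covers depends on the gas volume and on the
patient's body position.  `gastamp` answers, for surgeons and modellers, the
question: *given an eye size, a body position and a gas fill fraction, what
percentage of each anterior retinal quadrant is covered by gas?*

## Model

The pseudophakic vitreous cavity is a sphere of axial diameter `D`
(24/25/26/31 mm) with the anterior 2.5 mm cap removed (the IOL plane).  The
measured retina in each quadrant is the band between the ora serrata
(7.4/5.5/6.9/6.7 mm posterior to the limbus for the superior/nasal/temporal/
inferior quadrants) and the equator (a further 6.5 mm posterior), with
quadrants split at the 1:30/4:30/7:30/10:30 clock meridians.

At eye scale the Bond number `Bo = Δρ g R² / σ ≈ 20`, so gravity dominates
capillarity and the equilibrium interface is solved in two parts:

1. **flat level** `h`: root of `V_below(h) = (1 − f_gas) · V_cavity`, with the
   cavity volume profile computed by 1-D quadrature of analytic
   circle/segment cross-sections of the truncated sphere;
2. **meniscus climb** (default mode): the contact line on the wall rises above
   the flat level by the planar-wall Young–Laplace height

   `rise = ℓ_c · sqrt(2 (1 − sin(θ_c + α)))`,   `ℓ_c = sqrt(σ / (Δρ g)) ≈ 2.71 mm`,

   where `θ_c = 38.8°` is the gas–water–retina contact angle and `α` the local
   wall tilt from vertical.  Water wets the retina, so the climb can only
   reduce gas coverage.

The gas cover rate of a band is `covered area / band area × 100 %`, integrated
exactly (spherical zone sectors) or by azimuth × polar quadrature against the
per-azimuth contact line.  Six positions are supported: supine, sitting,
prone, prone with closed eyes (16.1° residual supraduction), lower temporal
and lower nasal decubitus.

## Worked example

Prone with closed eyes, 24-mm eye, 90 % gas fill:

```sh
$ gastamp run --diameter 24 --position prone_closed_eyes --gas 0.9
fill level -6.642 mm, contact line [-5.812, -5.812] mm, gas volume 6317.1 mm3
diameter,position,quadrant,gas_percent,coverage_percent,coverage_raw
24,prone_closed_eyes,superior,90,100,100.0000
24,prone_closed_eyes,nasal,90,96,95.6618
24,prone_closed_eyes,inferior,90,82,82.1458
24,prone_closed_eyes,temporal,90,100,99.8655
```

Even with 90 % of the cavity filled, the residual 16.1° supraduction of a
"prone" patient leaves almost a fifth of the inferior band uncovered: the
water pools against the tilted IOL face and the meniscus climbs a further
0.83 mm up the wall (flat level −6.64 mm, contact line −5.81 mm).  The
published CFD table prints 75 % for this cell.

Other entry points:

```sh
gastamp grid --out grid.csv --wide      # full 1056-cell experiment
gastamp compare grid.csv --tolerance 10 # against the published tables
gastamp recommend --breaks inferior     # rank positions for break locations
gastamp info --diameter 31              # model landmarks and volumes as JSON
gastamp mesh --diameter 24 --out eye.obj
```

`gastamp recommend` ranks positions by the smallest gas fraction at which
every break quadrant still shows 100 % cover — e.g. breaks confined to the
inferior quadrant (or spread over several quadrants) rank **supine** first,
superior breaks rank **sitting** first, nasal breaks **lower temporal**, and
temporal breaks **lower nasal**.

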