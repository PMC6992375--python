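# irmkit

Analysis toolkit for **confocal multiwavelength interference reflection
microscopy (IRM)** of specimens near a cover glass — in particular
label-free 3D readout of the basal surface of gliding bacteria
(*Myxococcus xanthus*-like rods) and of calibration lenses, together with a
physics-based synthetic-image generator so that every analysis stage can be
verified against known ground truth without microscope data.

## The model

IRM treats the sample as a three-layer stack — cover glass (g), aqueous
medium (m), cell (c) — where the medium forms a thin film of variable
thickness *z*, the gap between glass and the basal cell surface. Light
reflected at the two interfaces interferes; at normal incidence

```
I(z) = I_gm + I_mc + 2 √(I_gm · I_mc) · cos(4π n_m z / λ + δ),
I_gm = I₀ ((n_g − n_m)/(n_g + n_m))²       (Fresnel, normal incidence)
```

with δ = π because the cell is optically denser than the medium. Destructive
fringes therefore sit at *z* = *N*·λ/(2*n_m*) and constructive fringes at
*z* = (*N* + ½)·λ/(2*n_m*), *N* = 0, 1, 2, … Consecutive same-kind fringes
are spaced λ/(2*n*) apart in height — 244 nm for 488-nm light in air.

Two wavelengths turn this into a direction sensor: along a **rising** basal
surface the 488-nm maximum (91.7 nm above the glass in *n* = 1.33 medium)
appears before the 635-nm maximum (119.3 nm); along a **falling** surface
the order reverses. `irmkit` uses this "color ordering" to classify slope
direction along a cell body, pin absolute height anchors at each detected
fringe, and reconstruct the basal profile; repeated per frame it quantifies
the aperiodic adhesion fluctuations of gliding cells, and centroid tracks
give per-strain velocity statistics (Welch comparison).

## Worked example

Simulate a lens-on-glass calibration image (radius of curvature 20 mm, air
gap, 0.84 μm/pixel, 30% background inhomogeneity, 2% noise), flat-field it
and analyse the fringes:

```python
from irmkit.simulate import (LensGeometry, lens_height_map, render_irm,
                             lens_optical_config, LENS_PIXEL_SIZE, LENS_NA)
from irmkit.frames import write_stack

geom = LensGeometry(20.0)
hm = lens_height_map(geom, 1030 * LENS_PIXEL_SIZE, LENS_PIXEL_SIZE)
frame = render_irm(hm, lens_optical_config((488.0, 543.0)),
                   background_amplitude=0.3, noise_sd=0.02, seed=4, na=LENS_NA)
write_stack([frame], "lens.tif")
```

```sh
$ irmkit correct --k 1001 lens.tif lens_corr.tif
$ irmkit lens --radius-mm 20 lens_corr.tif lens_peaks.csv
488 nm: spacing 244.1 ± 1.0 nm (theory 244.0 nm)
543 nm: spacing 271.5 ± 0.7 nm (theory 271.5 nm)
```

The recovered axial spacings are the λ/2*n* fringe periods of the two laser
lines: the full inverse pipeline (correction → radial profile → peak
detection → neighbour-fringe subtraction through the lens sag
*z*(*x*) = *R* − √(*R*² − *x*²)) reproduces theory to a fraction of a
percent on a simulated image.

The same machinery applied to a simulated gliding cell (attached at the
leading pole, body rising to 180 nm):

```sh
$ irmkit run --config pipe.json        # simulate → correct → profile → track
$ irmkit cell --line 2,3:7,3 --width 3 demo_out/corrected.tif cell_profile.csv
2 segment(s): adhered [0.00,0.60] μm, incline [2.60,3.40] μm
```

The cell is adhered near its leading pole and inclines where the 488-nm
fringe (anchor 91.7 nm) precedes the 635-nm fringe (anchor 119.4 nm); the
pipeline's `stats.json` reports each simulated cell's mean velocity (e.g.
15.76 and 9.26 μm/min for the two demo cells) recovered from its
ground-truth centroid track.

## Layout

| module | role |
| --- | --- |
| `irmkit.optics` | three-layer interference law; order ↔ height ladder |
| `irmkit.simulate` | ground-truth height maps (lens, cells, movies) and rendering |
| `irmkit.correct` | moving-average (k×k) flat-field division |
| `irmkit.fringes` | radial profiling, peak detection, spacing, 3D lens reconstruction |
| `irmkit.topography` | line profiles, color-ordering classification, basal reconstruction |
| `irmkit.tracking` | path length, mean velocity, linearity screen, strain comparison |
| `irmkit.pipeline`, `irmkit.cli` | config, stack IO glue and the `irmkit` subcommand CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
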