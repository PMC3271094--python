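# tjmesh

Quantitative morphometry of tight-junction (TJ) strand networks from
single-molecule localization microscopy (SMLM/SPDM) point clouds.

Tight junctions seal the space between epithelial and endothelial cells.
Their backbone is a polymeric network of claudin strands that encloses
loop-shaped *meshes*; mesh size, shape and molecular density set the
paracellular barrier. Localization microscopy detects individual
claudin-fluorophore fusions with ~20 nm accuracy, and with an on-strand
density of thousands of molecules per µm² the strand network is resolved
at ~50 nm structural resolution — good enough to measure hundreds of
meshes per network. `tjmesh` implements the full analysis chain for this
kind of data, plus a ground-truth simulator so every stage is testable
without microscope data. It is aimed at microscopists and image analysts
working with SMLM tables of membrane protein networks.

## What it computes

For each mesh, seeded by an approximate centre:

- mean radius r̄ from the first maximum of the radial intensity profile
  of the rendered image;
- a closed contour from a Canny edge filter (thresholds 0.04/0.1,
  Gaussian σ 10 nm) on the normalized region of interest, corrected onto
  the molecule positions via the signed point-to-contour offset
  distribution (the edge filter systematically misses the strand
  centreline);
- circumference C and diameter d = C/π (circular-shape convention),
  mesh area, Feret ratio (min caliper / perpendicular caliper ∈ (0,1]),
  and the extent ratio along vs. across the network's principal axis
  (meshes > 200 nm);
- molecule densities in the strand band (half-width = localization
  accuracy σ_loc) and in the eroded interior.

Population level: normalized diameter histograms fitted with a sum of
two Gaussians, A₁·exp(−(d−µ₁)²/2σ₁²) + A₂·exp(−(d−µ₂)²/2σ₂²), with
FWHM = 2√(2 ln 2)·σ and standard errors; Kolmogorov–Smirnov comparison
of diameter distributions; the strand/off-strand density ratio with the
apparent-width correction (raw ratio × apparent/physical strand width,
e.g. 3700/780 × 50/10 ≈ 24). A detection/localization engine for raw
camera stacks (running-mean background, thresholded detection,
background-subtracted centre of mass) and an adaptive-blur renderer
(per-molecule kernel = mean distance to the 4 nearest neighbours, photon
weighted, 2 nm pixels; 50 nm-radius local-density maps) complete the
chain.

See `docs/methods.md` for the algorithms, parameter defaults and known
limitations.

## Worked example

Simulate a claudin-3-like network (two mesh-diameter populations,
elliptical meshes elongated along the network axis, 20 nm scatter,
blinking re-detections, 400 µm⁻² background), measure every mesh and
refit the populations:

```python
from tjmesh import (SceneParams, make_scene, measure_all,
                    diameter_histogram, fit_two_gaussians)
from tjmesh.stats import feret_and_orientation_summary

scene = make_scene(SceneParams(n_meshes=40, seed=7))
print(f"{len(scene.table)} localizations from {len(scene.meshes)} meshes")

df = measure_all(scene.table, scene.seeds())
d = df["diameter_nm"].dropna()
big = df[df["diameter_nm"] > 400]
print(f"measured {len(d)}/{len(df)} meshes")
print(f"on-strand density (d>400nm): {big['on_strand_density_um2'].mean():.0f} /um^2")
print(f"interior density  (d>400nm): {big['interior_density_um2'].mean():.0f} /um^2")

c, h, _ = diameter_histogram(d, bin_width=25.0)
fit = fit_two_gaussians(c, h, n_total=len(d))
print(f"small component: mean {fit.small.mean:.0f} nm, FWHM {fit.small.fwhm:.0f} nm")
print(f"large component: mean {fit.large.mean:.0f} nm, FWHM {fit.large.fwhm:.0f} nm")
s = feret_and_orientation_summary(df)
print(f"feret mode {s['feret_mode']:.2f}; orientation mean {s['orientation_mean']:.2f}")
```

Output:

```
16307 localizations from 40 meshes
measured 37/40 meshes
on-strand density (d>400nm): 3567 /um^2
interior density  (d>400nm): 737 /um^2
small component: mean 117 nm, FWHM 81 nm
large component: mean 354 nm, FWHM 517 nm
feret mode 0.75; orientation mean 1.23
```

The generator placed detections at 3700 µm⁻² on the strand band and
780 µm⁻² in the interiors; the densitometry recovers both on the large
meshes. The diameter mixture (105/364 nm) is recovered by the refit,
with the small component reading high: meshes below ~80 nm are smaller
than the structural resolution allows to measure, so the small
population is left-censored (quantified in `docs/methods.md`). Three of
the forty meshes were too small to close a contour and are reported as
flagged failures, not numbers.

The same workflow is available from the shell:

```sh
tjmesh simulate --seed 7 --n-meshes 40 --out locs.csv --seeds-out seeds.csv
tjmesh measure --locs locs.csv --seeds seeds.csv --out meshes.csv
tjmesh fit --meshes meshes.csv --out fit.json
tjmesh render --locs locs.csv --pixel-size 2 --out img.tif
tjmesh densitymap --locs locs.csv --radius 50 --vmax 3700 --out dens.tif
tjmesh localize --stack stack.tif --pixel-size 100 --out locs.csv
```

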