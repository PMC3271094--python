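# Methods

`tjmesh` quantifies the morphology of reconstituted tight-junction (TJ)
strand networks from single-molecule localization microscopy (SMLM/SPDM)
data. Its unit of analysis is the *mesh*: a closed loop enclosed by
claudin strands. This note describes the models and algorithms, the
choices made where the design was open, and what the synthetic ground
truth does and does not establish about real data.

## Data model and conventions

A localization table holds one record per detected molecule: position
(x, y) in nm, camera frame, photon count Q, and localization accuracy
σ_loc (nm). All geometry is continuous, in nm, origin at the lower-left,
y up; pixels exist only in rendered rasters (pixel (i, j) centre at
`pixel_size·(j+0.5, i+0.5)` plus the origin). Re-detections of one
molecule in different frames are separate records: with the long-lived
dark states of YFP-type fluorophores, ~88% of molecules appear exactly
once, and linking would create artificial clusters.

## Rendering

The visualization renderer blurs every record with an isotropic Gaussian
whose standard deviation is the mean distance to its 4 nearest
neighbouring records (floored at 1 nm so coincident re-detections stay
finite), weighted by the photon count, rasterized at 2 nm/px. Kernels
are truncated at 4σ and renormalized on their support, so the raster
total equals the photon sum exactly except for mass clipped at the
border, which is accumulated and reported. Local-density maps count
records (self included) within a 50 nm radius and divide by the disk
area; the export clamps the color scale at 0–3700 µm⁻² by default.

The *analysis* raster used by the mesh morphometry is a point-density
variant of the same renderer: unit mass per record, kernel floor at half
the mean σ_loc. Photon weighting is a visualization device; for
measurement it lets a single bright re-detection hot spot dominate the
intensity normalization, and the extra photon variance carries no
positional information.

## Per-mesh measurement

Given a seed point near a mesh centre (seeds are inputs; centres are
chosen manually in practice):

1. **Radial profile.** Annulus-averaged intensity in 4 nm bins out to
   800 nm. The mean radius r̄ is the first maximum: first +→− zero
   crossing of the derivative of the Gaussian-smoothed profile (σ = 2
   bins), refined sub-bin. Maxima below 0.6 of the global peak are
   skipped — sparse off-strand molecules inside large meshes otherwise
   produce spurious early maxima at 0.3–0.45 of the strand brightness; a
   genuine inner ring of comparable brightness still wins.
2. **Edge contour.** A Canny filter (thresholds 0.04/0.1, Gaussian σ
   10 nm = 5 px) runs on the ROI (square of side 4r̄, at least
   2r̄+200 nm) normalized between its 5th-percentile intensity floor and
   the radial-profile peak, i.e. the thresholds refer to fractions of
   the typical strand brightness. The raw contour is the outline of the
   connected non-edge region holding the seed. Two robustness layers
   handle broken edge chains at realistic point densities: escalating
   morphological closing with removal of small trapping loops, then a
   polar edge trace (per bearing, the edge pixel radially closest to a
   smoothed reference radius; outliers rejected against a circular
   median filter; gaps interpolated periodically). A contour that still
   cannot be closed is an error ("open mesh"), never a guess.
3. **Contour correction.** The edge filter settles on a flank of the
   strand's intensity ridge, not on the molecule positions. Signed
   distances (positive outside) from the in-ROI records to the contour
   are collected per angular sector (~30 nm of arc per sector, at least
   12); each sector's median, minus the convexity bias σ_loc²/(2R) of
   points scattered from a curved arc, moves the contour radially; three
   passes converge well below σ_loc. The mean applied offset is reported
   as the correction offset δ. Fewer than 20 usable records: the mesh is
   flagged uncorrected; |δ| > r̄/2 is flagged suspect. Finally the
   radius-versus-angle profile is Fourier low-passed, keeping harmonics
   down to ~250 nm of arc (at least k = 3): radial wiggle below the
   structural resolution is sampling noise, and the circumference grows
   quadratically in its amplitude without carrying shape.
4. **Scalars.** Circumference C of the corrected polygon; diameter
   d = C/π (circular-shape convention); mesh area from the polygon. The
   strand band is the morphological band of half-width equal to the mean
   in-ROI σ_loc around the contour; the interior is the erosion by the
   same amount (absent when erosion empties — common for small meshes,
   which then carry no interior density). Band/interior/exterior counts
   partition the in-ROI records exactly. The Feret ratio is the minimum
   over a 1° caliper grid of width(θ)/width(θ+90°) on the convex hull
   (minor/major ratio for an ellipse). The orientation ratio — caliper
   extent along the network's first principal direction over the
   perpendicular extent — is only reported for d > 200 nm, where shape
   is measured reliably; the network axis is the leading PCA direction
   of all records, flagged unreliable below an eigenvalue ratio of 1.05.

Per-mesh failures never abort a batch run; they become flagged rows.

## Population statistics

Diameter histograms are normalized by the number of analyzed meshes
(50 nm bins by default). The two-population structure is summarized by a
sum-of-two-Gaussians fit to the histogram, components ordered by mean,
FWHM = 2√(2 ln 2)·σ. Several initializations are tried (two tallest
smoothed peaks, plus quantile seedings) and the best kept; by default the
fit is the unweighted least squares of the bin heights, and when the
total mesh count is supplied the implied bin counts are fitted by
Poisson maximum likelihood instead — markedly more stable when one
component is sparse, with standard errors from the numerical Hessian.
Distributions are compared with the two-sample Kolmogorov–Smirnov test
(exact statistic, asymptotic p).

The strand/off-strand density comparison corrects for apparent strand
width: the localization scatter spreads on-strand molecules over a band
(~50 nm) much wider than the ~10 nm physical strand, so the corrected
ratio is the raw band/interior ratio times apparent/physical width.
With the reported band and interior densities (3700 and 780 µm⁻²) this
yields ≈4.7 raw and ≈24 corrected.

## Localization engine

Camera frames are photon-calibrated. Background follows a temporal
running mean B_k = (1−s)·B_{k−1} + s·I_k (B_0 = I_0) with Poisson noise
width √max(B, 1); detection for frame k uses the state before folding in
frame k, so a molecule does not subtract itself (frame 0 is burn-in).
Pixels above B + nσ (default 4) seed candidates in fixed 7×7 windows
centred on the local maximum; any two candidates whose windows overlap
are both discarded (the centre-of-mass estimator requires optical
isolation), as are border windows. Localization is background-subtracted
centre of mass with an additional corner floor of one noise width
(clipped at zero) that suppresses noisy window corners; the accuracy is
the two-axis mean of √(second moment)/√Q computed on the un-floored
signal (the floor biases the measured spot width low). This estimator
tracks the Cramér–Rao-like 1/√Q scaling; its absolute error is roughly
twice that bound at realistic backgrounds, which is the known efficiency
cost of centre-of-mass versus full PSF fitting.

## Synthetic ground truth

The generator builds a quasi-linear belt of non-overlapping elliptical
meshes — the geometry of strand networks at cell–cell contacts — with:

- diameters (perimeter/π, the pipeline's convention) from a
  two-component Gaussian mixture; defaults are the claudin-3 populations
  (means 105/364 nm, FWHM 132/444 nm), claudin-5 (61/482, 174/442)
  provided as a constant. Components carry equal mass: the published
  histograms resolve both populations well enough to fit both, which a
  vanishing small component would not allow. Diameters are truncated at
  50 nm (below the structural resolution no mesh can be said to exist);
- axis ratios peaked at 0.7 (truncated normal, SD 0.08, range
  0.45–0.95); major axes oriented so the along-axis/perpendicular extent
  ratio realizes a normal draw with mean 1.21 and SD 0.38, the draw mean
  being adjusted in closed form for clipping into each mesh's attainable
  range [q, 1/q] (or uniformly random orientations for isotropy
  studies);
- 10 nm-wide strands along each boundary, optionally interrupted by
  10–100 nm gaps (strand-continuity studies; the morphometry population
  uses closed meshes);
- molecules as homogeneous Poisson processes on strands, in interiors
  and in the surrounding field; each molecule emits one detection with
  probability 0.88, otherwise 2 + geometric extra events (mean 2.5 among
  re-detected molecules); detections are displaced by an isotropic 20 nm
  Gaussian; photons are log-normal (median 800); the recorded accuracy
  equals the scatter.

Density parameters (defaults 3700 / 780 / 400 µm⁻² for band, interior
and far field) are *expected detected densities in the regions the
pipeline measures*. Because the 20 nm scatter moves roughly a third of
the strand detections outside the ±σ_loc band and spills band, interior
and background into one another, placement intensities are calibrated
analytically (capture fraction of a uniform strip convolved with a
Gaussian; half-plane spill integrals; strand-to-interior leakage, solved
by a short fixed point per mesh). Without this calibration the generator
would systematically contradict its own declared ground truth. The
number of *molecules* is the detected count divided by the mean
detections per molecule, so blinking leaves densities invariant in
expectation.

What the simulator does not emulate: shared strands between adjacent
meshes (meshes are spaced ~100 nm apart), spatially varying background,
drift, z-defocus, photophysics kinetics, or irregular (non-elliptical)
mesh shapes. Passing recovery tests therefore demonstrates the
correctness of the measurement chain under the stated statistical
conditions, not robustness to every property of real specimens.

## Accuracy, calibration and known limitations

- On noise-free circular meshes (points exactly on a 10 nm annulus) the
  corrected diameter matches truth to ~2 nm, well within one render
  pixel plus one correction bin.
- Under realistic conditions the diameter bias is ≈ +1–3% for meshes of
  200–800 nm, growing toward the resolution limit; the measured-vs-true
  relation is strictly monotone (Spearman ρ > 0.99 on a diameter
  ladder).
- Meshes below ~80 nm diameter are usually unmeasurable: their interior
  (diameter minus the ~50 nm apparent strand width) falls below the
  structural resolution and no closed edge contour exists. This
  *left-censors* the small-diameter population. Refitting a plain
  two-Gaussian sum to the censored histogram therefore overestimates the
  small component's mean by ~20–25% (≈125–135 nm recovered for a 105 nm
  component; verified by idealized censoring simulations across bin
  widths and generator floors). The same physics is why the smallest
  reported population (61 nm) can only be fitted vaguely on real data.
  No censoring correction is applied: the published procedure is
  measure-then-fit, and the bias is reported rather than hidden.
- The Feret ratio reads ~0.03–0.08 high (rounder) near the resolution
  limit because counting noise limits how much elongation the sector
  correction can recover; at 300 nm and above the bias is within ~0.03.
- The orientation-ratio mean is recovered within ~5% for the d > 200 nm
  population; clipping losses in the generator are pre-compensated, so
  residual deviation is measurement smoothing.
- Densities are recovered within a few percent on ≥400 nm meshes; for
  small meshes the interior is frequently absent and the band density
  noisier.

## Problem sizes

The test suite measures 100-mesh scenes for each claudin parameter set,
60 meshes for the Feret-mode study, 24 large meshes for density
recovery, and a 20-mesh ladder for monotonicity. The reproduction script
(`scripts/acceptance.py`) generates 400-mesh scenes for the population
refits (the large component's sample mean then scatters by ~1 SE =
14 nm) and 200 meshes for the Feret mode, and fits the population
histograms (50 nm bins) by Poisson likelihood with the measured mesh
count — on censored measured data this estimator recovered the large
component with the smallest spread across replicate scenes.
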