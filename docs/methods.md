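# Methods

`cortexpen` implements the quantitative machinery for asking how far
nonmuscle myosin II penetrates the cortical actin network of a rounded
cell, and what that penetration does to cortical tension.  Every stage
can be exercised end-to-end on synthetic data with recorded ground
truth; this note documents the models, the conventions, the defaults
and their rationale, and what the synthetic benchmarks do and do not
establish about real data.

## Coordinate and sign conventions

Continuous coordinates are in nanometres with the origin at the corner
of image pixel (0, 0); pixel indices are 0-based and a pixel centre
sits at `(i + 0.5) * pixel_size`.  The signed transverse axis across
the cortex is positive toward the cytoplasm, so for an equatorial
(circular) cortex "deeper" means smaller radius.  All intervals on
this axis are closed.

## SMLM post-processing (`smlm_core`)

Input is a per-molecule localization table (frame, x/y in nm,
localization uncertainty in nm, photon count, channel), the output of
any standard single-molecule fitting package; the CSV dialect uses
ThunderSTORM column names.  The synthetic scenes draw per-molecule
uncertainties from a truncated normal with mean 20 nm and SD 10 nm,
the typical per-localization precision of cortical dSTORM data.

**Drift.**  Two estimators are provided.  (1) Fiducial-bead tracking:
per frame, the localization nearest each bead seed within a search
radius; gaps linearly interpolated; beads visible in fewer than half
the frames dropped; per-frame drift is the mean bead displacement from
the first frame, smoothed with a 50-frame moving average.  The mean
(not an SD-weighted combination) is the default because bead jitter is
homogeneous in the scenes we generate; a weighted option would only
matter with beads of very different brightness.  (2) Redundant
cross-correlation (RCC) for single-colour data: the acquisition is cut
into 2000-frame windows, each window's localizations are binned into a
2D histogram with 20-nm sub-pixels (blurred by one sub-pixel, which
stabilizes the correlation peak of sparse histograms), successive
windows are cross-correlated, the peak is refined with a 3-point
parabolic fit per axis, cumulative shifts are anchored at window
midpoints, and a cubic spline (clamped at the ends) interpolates to
every frame.  An all-pairs least-squares mode (`mode="allpairs"`)
implements the fully redundant variant.  Drift is defined only up to
an additive constant; the estimate is anchored at the first window, so
trajectory comparisons in the tests remove the common offset first.
Windows with fewer than 100 localizations are merged with their left
neighbour.

**Chromatic registration.**  A 2D affine transform (scaling, rotation,
shear, translation) is fitted by linear least squares to matched
multicolour bead positions; matching across channels is by mutual
nearest neighbour within 300 nm.  Three non-collinear pairs are the
hard minimum; the residual RMS is reported on the fitted transform.

**Rendering.**  Each molecule contributes a unit-mass isotropic
Gaussian whose sigma is its own localization uncertainty, integrated
exactly over pixels (error-function differences) and truncated at
4 sigma (relative mass error ~1.3e-4 per molecule); the map is then
multiplied by 100 so that downstream digitization cannot quantize away
faint density.  Rendering is linear and mass-preserving up to
truncation: the image sum is 100x the molecule count.

## Cortex profiles and the cytoplasmic overhang (`cortex_profile`)

The cortex is detected on the rendered actin channel: seed points
(auto-seeded from a circle fit for synthetic equatorial cells, or user
polylines for real data) are refined to the transverse intensity
maximum along the local normal, averaging profiles over a +-40 nm
tangential window and smoothing before the parabolic peak refinement —
without this, localization shot noise puts ~50 nm of jitter on the
ridge position and the straightened profiles broaden accordingly.  A
periodic cubic spline is fitted through the refined points (after a
light circular smoothing of the ridge radii); normals point toward the
cytoplasm (the interior for a closed contour, else the side brighter
at a 400-nm offset).

All channels are sampled along the normals by bilinear interpolation
(rows = arc position at the rendering pixel pitch, columns = signed
transverse axis), rows whose normal exits the image are flagged, and
profiles are averaged in 200-nm bins along the cortex (20 rendering
pixels); bins containing flagged rows and the incomplete trailing bin
are dropped.

Per bin and channel: background is the mean of the medians of the
outer 20% of samples on each side (robust, parameter-light); the peak
is the background-subtracted maximum with parabolic sub-sample
refinement; the FWHM interval is bounded by the innermost half-maximum
crossings bracketing the peak, located by linear interpolation.
Profiles without an interior peak or with a missing crossing are
rejected with a reason code.

The comparison statistics per bin are the signed peak-to-peak distance
(target peak minus actin peak; positive = deeper in the cytoplasm) and
the signed cytoplasmic overhang

    overhang = 100 * (t_hi - a_hi) / (t_hi - t_lo)   [%]

where `[a_lo, a_hi]` and `[t_lo, t_hi]` are the actin and target FWHM
intervals and `hi` is the cytoplasmic edge.  This single-edge signed
form is the minimal definition that yields both a positive
percentage-of-FWHM overhang for a layer protruding into the cytoplasm
and negative values for a membrane-hugging protein (moesin-like); a
symmetric two-sided non-overlap (`overhang_symmetric`) is available
but off by default.  Per-cell values average the accepted bins
(median available by configuration); cells with fewer than three
accepted bins are excluded.  Bin-then-average is the default rather
than pooling profiles first, because pooled mean profiles are wider
than the individual ones whenever the cortex position jitters.

`curvature_broadening_bound(R, slab)` returns
`2 * (R - sqrt(R^2 - (slab/2)^2))` — the worst-case FWHM inflation
from out-of-focus parts of a spherical shell of radius R seen in a
focal slab, assuming the worst case on both profile edges.  For
R = 5 um and a 200-nm slab this is 2.0 nm, negligible against
~200-nm cortical widths.

## Minifilament geometry and the cosine tension model (`minifil_sim`)

Two-channel SIM images of labelled myosin II show a minifilament as
two head spots flanking one tail spot.  Detection: subtract the
large-radius Gaussian blur of the image (default 500 px ~ 10 um;
smaller for small synthetic frames), Richardson-Lucy deconvolution
with a Gaussian PSF (reflect-padded to avoid boundary blow-up; default
20 iterations; a divergence guard stops early if the estimate norm
explodes), zero everything below 3x the SD of a cell-free background
area, erode the binary support with a 3x3 element to kill isolated
noise pixels, detect strict 8-neighbour local maxima, and refine each
to the intensity centroid of its 5x5-pixel ROI (plateaus of exactly
equal pixels are resolved once, in scan order).  Analysis is
restricted to the image interior (margin = the 400-nm pairing bound).

Pairing is all-pairs: every head pair separated by 200–400 nm is a
candidate, validated if a tail peak lies within 50 nm of the pair
midpoint.  A head may serve several candidates, matching the all-pairs
rule; an optional greedy resolution by tail distance is off by
default.  A property test pins the implementation to brute-force
enumeration on random scenes.

A minifilament of reference length `L_ref` tilted out of the imaging
plane by theta projects to `L_proj = L_ref * cos(theta)`, so
`theta = arccos(L_proj / L_ref)`.  The default `L_ref` is 317 nm (the
mean projected length of stress-fiber minifilaments, which lie
parallel to the membrane); 330 nm, the electron-microscopy filament
length, is the documented alternative.  Under the simplest model in
which each minifilament contributes tension proportionally to
`cos(theta)`, a change of mean angle changes tension by
`100 * (cos(theta_after)/cos(theta_before) - 1)` percent — identically
`100 * (L_proj,after / L_proj,before - 1)` at fixed `L_ref`.  Angles
are aggregated as the arccos of the per-cell mean length ratio
(mean-of-angles is available), matching arithmetic done on mean
projected lengths.

The generator's out-of-plane angle distribution is uniform on
[0, 30 deg] by default — the cortex constrains minifilament
orientation, so an isotropic distribution would be unrealistic — and
is exposed as a parameter because no measured distribution exists to
copy.

## Confocal quantification (`confocal_quant`)

**Cortical intensity.**  Rolling-ball background subtraction (50-px
ball; the cortex is ~8 px wide, so the ball cannot descend into it),
then two independent segmentations: (a) threshold at mean + SD of a
user-chosen cell-free region, fill holes; (b) Sobel gradient
magnitude (after a 1.5-px Gaussian pre-smoothing), Otsu threshold,
morphological closing, hole filling, small-object removal, opening, a
2-px boundary-refinement erosion (the filled edge band otherwise
overshoots the gradient ridge by about half its width), and a
distance-transform watershed to split touching cells; candidates whose
interior is not brighter than the surroundings are discarded as noise
artifacts.  Candidates from both routes are grouped by centroid
proximity (20 px) and, per group, the candidate whose contour has the
highest mean intensity on a lightly smoothed image wins (a raw total
would reward long ragged contours).  Cortex band edges come from
dilating (5 px) and eroding (3 px) the winning mask; cortical
intensity is the mean within an 8-px band centred on the outline.
Unspecific staining is corrected by subtracting the mean of a
secondary-antibody-only control.

**Thickness and penetration.**  A transverse linescan is modelled as a
piecewise-constant density — extracellular level `i_out`, cortical
level `i_cort` over `[X_m, X_m + h_actin)`, cytoplasmic level `i_in`
— convolved with a Gaussian PSF (`sigma_psf`, a calibration input,
default 170 nm).  The convolution is evaluated analytically with
normal CDFs, and the generator uses the same functions, so the
round-trip at zero noise is exact by construction.  The actin fit
frees `X_m`, `h_actin`, `i_cort`, `i_in` (with `i_out` estimated from
the extracellular tail), multistarts over h in {50, …, 400} nm and
keeps the best residual; h is bounded to [10, 500] nm because at
`sigma_psf = 170 nm` the likelihood surface has a flat (h, i_cort)
trade-off ridge along which unbounded fits can escape.  Myosin is a
slab of width `h_myo` whose cytoplasmic edge is pinned to
`X_m + h_actin` (it can fail to reach the membrane but not overshoot
the actin cortex into the cytoplasm); `h_actin - h_myo` is the
myosin-free cortex length.  A fitted `h_myo > h_actin` is clipped
with a warning (full penetration).

The same flat ridge limits what a single noisy linescan can say about
h: at 5%-of-peak noise, single-scan estimates of a 200-nm cortex
scatter by >50 nm and are biased low.  The Monte-Carlo benchmarks
therefore fit the average of 50 linescans per cell — the standard
practice of averaging radial linescans around a cell contour — at
which point the bias is within a few nanometres.

## AFM cortical tension (`afm_tension`)

A rounded cell compressed between dish and tipless cantilever relaxes
to a force plateau F.  Neglecting the small cantilever tilt and
adhesion, the force balance at the contact line gives

    T = F * (r_mid^2 / r_c^2 - 1) / (2 * pi * r_mid)   [nN/um = mN/m]

with `r_mid` the equatorial cross-section radius and `r_c` the
cell-cantilever contact radius, computed from the equatorial area and
the compressed cell height as `A_c = A_mid - (pi/4) h_cell^2`,
`r_c = sqrt(A_c / pi)`.  The contact relation is sometimes quoted with
`A_c` equated to a perimeter (`2 pi r_c`), which is dimensionally
inconsistent; this package reads it as an area and derives `r_c`
accordingly.  `h_cell` is the difference between the cantilever z on
the compressed cell and on the glass.  The plateau is the mean force
from 30 s after the compression peak to drug addition (or curve end),
flagged non-stationary if the linear drift across the window exceeds
2% of the plateau.  Drug responses are computed on a Savitzky-Golay
smoothed trace (window 21 samples, order 3 — unstated in the usual
protocols; polynomials up to the order are preserved exactly): the
baseline is the mean force in the 20 s before addition and the outputs
are the mean and maximum in the 300 s after, normalized to it.

## Statistics (`stats_report`)

Each pairwise comparison tests both groups for normality
(D'Agostino-Pearson); if both pass at alpha = 0.05 the means are
compared by Welch's two-tailed t-test, otherwise by the two-tailed
Mann-Whitney U (exact enumeration for group sizes up to 8, tie-corrected
normal approximation above).  The normality test needs n >= 8; smaller
groups go nonparametric by construction.  Box summaries report
type-7 (linear interpolation) quartiles, the median, and min-max
whiskers.

## Synthetic data: what it does and does not emulate

The generators (`synthgen`) are deterministic given (spec, seed) and
record full ground truth.  They emulate: annular two-channel
localization scenes with radially offset Gaussian bands, per-molecule
localization noise, cumulative stage drift, a one-channel affine
chromatic distortion, and always-on fiducial beads; dumbbell
minifilament images over a smooth background with Poisson and read
noise; step-convolution linescans (sharing the fitter's forward
model); ring-cell confocal images whose cortical band peaks at a
sharp membrane edge with a raised-cosine inner flank; and AFM force
curves with a compression peak, exponential relaxation, and
parameterized drug transients.

They deliberately do not model: multi-frame blinking (each molecule
appears in exactly one frame — adequate for drift and rendering tests,
useless for kinetic analyses), 3D cortex structure (the z-curvature
effect is handled analytically by the broadening bound instead),
microvilli or bead aggregates on the cortex, sample-dependent
backgrounds in SMLM, or cell-to-cell biological variability.  Passing
the recovery benchmarks therefore establishes that the estimators are
unbiased and precise under the stated noise models, not that real
cortices satisfy those models.

## Benchmark problem sizes

The recovery studies use cells of 2.5-um radius with 15,000
localizations per channel rendered at 10 nm/px (overhang grid:
5 conditions spanning roughly -28% to +38% true overhang, 20 seeds
each), 150,000 localizations for RCC drift scenes, 25 filaments per
256-px SIM frame over 20 seeds, 50 Monte-Carlo cells for the linescan
fits, and 10 seeds for segmentation at SNR 5.  These sizes put the
standard error of each aggregate statistic comfortably below its
acceptance band while keeping the full suite fast.

## Known limitations

- RCC assumes the cortical structure itself is stationary; real
  cortices remodel over minutes, which biases long-window estimates.
- The overhang statistic inherits any differential chromatic or
  drift-correction residual between channels; the same-band control
  scenes quantify the floor (~2 percentage points SD per cell).
- The single-edge overhang definition is one of two readings
  consistent with negative moesin-like values; the symmetric variant
  is provided for sensitivity analyses.
- Thickness fitting at confocal resolution is ill-conditioned for
  cortices much thinner than ~150 nm even with scan averaging; results
  below that scale should be treated as bounded, not estimated.
- The cosine tension model treats every minifilament as an equal,
  independent tension generator; it is a bound-style argument, not a
  mechanical model of the network.
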