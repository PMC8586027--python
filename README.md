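# cortexpen

Quantitative analysis of how far myosin II penetrates the actin cortex
of a rounded cell — and what that penetration means for cortical
tension.

The actomyosin cortex is a thin (~150–200 nm) actin network under the
plasma membrane whose myosin-generated tension sets cell shape.
Super-resolution imaging shows that myosin does not always overlap the
actin layer: in low-tension cells the myosin layer can be displaced
toward the cytoplasm, leaving a myosin-free zone at the membrane.
`cortexpen` implements the complete measurement chain for this
question, for researchers analysing two-colour dSTORM/SMLM
localization data, SIM images of myosin minifilaments, confocal stacks
of cortical linescans, and parallel-plate AFM force curves — plus
synthetic generators with recorded ground truth so that every stage is
testable without microscope data.

## What it computes

- **SMLM post-processing** (`smlm_core`) — lateral drift correction by
  fiducial-bead tracking or redundant cross-correlation (2000-frame
  windows, 20-nm sub-pixel histograms, spline interpolation),
  chromatic correction by an affine fit to multicolour beads, and
  rendering of localization tables as Gaussian density maps
  (per-molecule sigma = localization uncertainty, unit mass, ×100).
- **Cortex profile statistics** (`cortex_profile`) — spline-based
  cortex straightening, 200-nm binned transverse profiles, per-bin
  peak and FWHM, signed peak-to-peak distance between channels, and
  the headline *cytoplasmic overhang*: the signed percentage of the
  target protein's FWHM that extends beyond the actin FWHM on the
  cytoplasm side,

  `overhang = 100 · (t_hi − a_hi) / (t_hi − t_lo)`.

- **Minifilament geometry** (`minifil_sim`) — detection of bipolar
  minifilaments in two-channel SIM images (two head spots 200–400 nm
  apart validated by a tail spot within 50 nm of their midpoint),
  projected-length statistics, the implied membrane angle
  `θ = arccos(L_proj / L_ref)` with `L_ref = 317 nm`, and the
  equal-contribution cosine tension model
  `ΔT = 100 · (cos θ_after / cos θ_before − 1) %`.
- **Confocal quantification** (`confocal_quant`) — rolling-ball
  background subtraction, dual-route cell segmentation with per-cell
  candidate selection, cortical-band intensity, and step-convolution
  fitting of linescans for the cortex thickness `h_actin`, the myosin
  penetration depth `h_myo` (cytoplasmic edges aligned), and the
  myosin-free cortex length `h_actin − h_myo`.
- **AFM cortical tension** (`afm_tension`) — plateau force extraction
  and the parallel-plate force balance
  `T = F (r_mid²/r_c² − 1) / (2π r_mid)` with
  `r_c = sqrt((A_mid − (π/4) h_cell²)/π)`, and Savitzky–Golay-smoothed
  drug-transient analysis (mean/max force 300 s post-addition
  normalized to the 20 s pre-addition baseline).
- **Statistics** (`stats_report`) — D'Agostino–Pearson-gated Welch t /
  Mann–Whitney U comparisons and box-plot summaries.
- **Synthetic data** (`synthgen`) — seed-deterministic generators for
  every input above, with ground truth recorded alongside.

See `docs/methods.md` for models, conventions, parameter defaults and
limitations.

## Worked example

Simulate a two-colour equatorial cortex whose target band sits 40 nm
deeper than the actin band (true overhang 22.7%), then run the profile
pipeline:

```sh
$ cortexpen simulate --preset cortex --seed 1 --out sim
wrote actin.csv, target.csv, groundtruth.json to sim
$ cortexpen profile sim/actin.csv sim/target.csv --out prof
overhang +20.5% over 52 bins
```

The `+20.5%` is the per-cell mean cytoplasmic overhang over 52
accepted 200-nm bins — the target layer's FWHM extends past the actin
layer's cytoplasmic edge by about a fifth of its width, recovering the
generative truth of 22.7% to within the per-cell noise floor
(~2 percentage points SD).  `prof/overhang.csv` holds the per-cell
summary (mean FWHMs, peak-to-peak, overhang) and `prof/bins.csv` the
per-bin table.

Minifilament orientation from a synthetic SIM frame:

```sh
$ cortexpen simulate --preset minifil --seed 2 --out simm
$ cortexpen minifil simm/minifil.tif --out mf
23 minifilaments, mean projected length 303.0 nm, angle 17.1 deg
```

A mean projected length of 303 nm against the 317-nm stress-fiber
reference implies a mean out-of-plane angle of ~17°; scenes are drawn
with angles uniform on [0°, 30°].

Cortical tension from a synthetic AFM curve (equatorial area
314.2 µm², cantilever z 12 µm on the cell vs 4 µm on glass):

```sh
$ cortexpen simulate --preset afm --seed 3 --out sima
$ cortexpen afm sima/force.csv --a-mid 314.159 --z-cell 12 \
      --z-glass 4 --drug-time 60 --out afmo
T = 0.037 mN/m (plateau 12.14 nN)
```

The plateau force of ~12 nN with a 10-µm equatorial radius and 8-µm
compressed height gives a contact radius of 9.17 µm and a cortical
tension of 0.037 mN/m; `afmo/tension.csv` adds the drug-response
ratios.

All subcommands accept `--config <yaml>` and write a JSON run manifest
(configuration, seed, versions) next to their outputs.

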