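# acrqa

Automated image-quality assurance for CT and cone-beam CT (CBCT) using
the ACR CT accreditation phantom (Gammex model 464), written for
radiotherapy physics groups that run one phantom across a CT simulator
and several linac CBCT systems.

The phantom is a 20 cm cylinder of four 4 cm modules: (1) density plugs
(air, polyethylene, water, acrylic, bone) plus wire ramps for slice
width, (2) low-contrast rods, (3) a uniform section with two BBs
machined 100.0 mm apart, (4) high-contrast bar patterns. `acrqa` reads
an axial DICOM series of the phantom, localizes it (body threshold,
BB detection, roll estimation, per-module analysis-slice selection),
measures the full eight-test panel, and tracks the results
longitudinally against baselines with statistically derived tolerances.
Commercial analysis software is known to fail on noisy CBCT volumes at
the localization step; that step is the part this package automates
most carefully, with explicit fallbacks and flags.

## Measurements

For each analysis slice, circular ROIs at the ACR sizes (≈200 mm² for
HU plugs, ≈100 mm² for low contrast, ≈400 mm² for uniformity) give
mean and SD in Hounsfield units. On top of these:

- **CNR** (polyethylene and acrylic vs the water plug in the same
  slice): `CNR = |ROI_mean − BG_mean| / BG_SD`
- **Noise (%)**: `100 × ROI_SD / (ROI_mean + 1000 HU)` — the +1000 HU
  rescale keeps the denominator away from zero for water-like plugs
- **Uniformity**: max over the four edge ROIs of |edge − center| mean HU
- **In-plane distance**: sub-pixel distance between the two BB
  centroids (nominal 100.0 mm)
- **Slice thickness**: wire-ramp count method (0.5 mm z-pitch per wire)
- **Low contrast**: CNR of the 25 mm cylinder and visibility of the
  four 6 mm rods (contrast > k × background SD, default k = 1)
- **High contrast**: best bar pattern whose modulation exceeds a
  fraction of the coarsest pattern's, scanned coarse→fine (lp/cm)

The statistical layer sets the tolerance for each metric at **twice the
maximum standard deviation** over all machines and protocols between
baseline resets, rounded at the metric's reporting precision (nearest
HU; one decimal for CNR; two for noise %). Under normality a result
lands outside such a band about 5% of the time, so an out-of-tolerance
result is a prompt to investigate, not a clinical failure. Baselines
are reset after maintenance, recalibration or tube replacement.

A synthetic phantom renderer (`acrqa.synthetic`) stands in for scanner
data: it draws the full four-module geometry with configurable plug
HUs, Gaussian noise, Gaussian PSF, parabolic cupping and crescent
artifacts, and session-to-session drift, and writes standard DICOM so
synthetic data takes the same path as scanner exports.

## Worked example

```sh
acrqa simulate --preset ct-sim --seed 17 --out /tmp/series
acrqa analyze /tmp/series --out /tmp/qa --history /tmp/history.csv
```

prints (CT-simulator-like conditions: σ = 3.5 HU, 0.45 mm PSF):

```
16 metrics evaluated; 0 not evaluable
  cnr_acrylic                      32.40
  cnr_polyethylene                 25.63
  distance_mm                     100.01
  high_contrast_lp_cm               6.00
  hu_acrylic                      119.87
  hu_air                         -999.93
  hu_bone                         955.50
  hu_polyethylene                 -94.99
  hu_water                         -0.08
  low_contrast_cnr                  1.59
  low_contrast_rods_visible         4.00
  noise_acrylic                     0.31
  noise_polyethylene                0.40
  slice_thickness_mm                2.50
  uniformity_center_hu             -0.02
  uniformity_hu                     0.19
```

Every plug mean sits inside its accepted range, all four 6 mm rods are
visible with low-contrast CNR above the 1.0 minimum, the distance test
is within ±1.0 mm of 100.0 mm, the slice width matches the 2.5 mm
nominal, and the resolution is 6 lp/cm — a panel a CT simulator should
pass. The CBCT-like preset (`--preset cbct-head`: σ = 30 HU plus a
20 HU cupping artifact) instead reports uniformity ≈ 20 HU, plug CNR
≈ 3, noise ≈ 3%, and zero visible rods — low-contrast scoring is not
usable on linac CBCT, which is why the plug-CNR and noise tests exist.

Tolerances are derived from measurement history, e.g.

```sh
acrqa derive-tolerances --history history.csv --out tolerances.yaml
acrqa baseline --history history.csv --out baseline.json
acrqa evaluate --session /tmp/qa/session.json \
    --baseline baseline.json --tolerances tolerances.yaml
acrqa trend --history history.csv --out trend/
```

`acrqa.qa_program.reference_tolerances("CT"|"CBCT")` returns the
tolerance set derived from the two-year reference program tables
shipped with the package (e.g. water HU ±16 HU, CBCT uniformity
±22 HU, CBCT polyethylene CNR ±3.6).

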