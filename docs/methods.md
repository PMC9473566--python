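# Methods

This note documents the models implemented in `nightshift`, the defaults
and why they were chosen, what the synthetic scenes do and do not
emulate, and the numerical decisions a user should know before trusting
the outputs.

## Synthetic photometry

A light source is a spectral power distribution (SPD) `P(λ)` sampled on a
1-nm grid over 380–780 nm (fine enough to resolve gas-discharge lines,
which are modeled as Gaussians of 2–8 nm width).  A sensor channel with
peak-normalized sensitivity `R_c(λ)` records the band signal
`S_c = ∫ P R_c dλ` (trapezoidal rule on the union of the two sample
grids, restricted to the overlap of their supports; disjoint supports are
an error, not a zero).  Color ratios `B/G`, `G/R`, `R/G` and all
action-spectrum indices are ratios of such integrals and therefore
invariant to the overall radiometric scale of `P` — this is the property
that makes color ratios robust to the absolute-calibration uncertainties
(window transmittance, oblique viewing) that plague band intensities.

Biological indices are photopically normalized and anchored to a broad
reference illuminant:

    index(P) = ( ∫P·A / ∫P·V ) / ( ∫Ref·A / ∫Ref·V )

so that `index(Ref) = 1` by construction.  `A` is the action spectrum
(melatonin suppression, blue-weighted scotopic for star visibility, or
insect phototaxis), `V` the photopic curve, `Ref` a 6500 K Planckian
("D65-like") spectrum.  The shipped action spectra are analytic Gaussian
approximations of the published curves (melatonin 460/40 nm, photopic
555/45 nm, scotopic 507/45 nm, phototaxis 400/60 nm); measured curves can
be substituted from two-column CSV.  Because indices are ratios of broad
integrals, their ordering across lamp classes is insensitive to the exact
curve shapes; the absolute values shift with the curves and should not be
compared against indices computed with other curve tabulations.

### Camera model

Default channel sensitivities are Gaussians: B 460/30 nm, G 530/30 nm,
R 600/40 nm.  The green width matters for one qualitative anchor: with
σ_G = 30 nm a pure 589-nm sodium spectrum lands at R/G ≈ 6.8 — inside the
R/G > 6 outlier region that the masking rule attributes to low-S/N or
non-streetlight pixels — and at B/G ≈ 0.001.  Wider green curves
(σ ≳ 31 nm) would pull pure LPS below the R/G = 6 line and break that
interpretation.  Measured DSLR curves are loadable from CSV; all
downstream math is curve-agnostic.

### Lamp library

Seven classes (LPS, HPS, mercury vapor, metal halide, triphosphor
fluorescent, LED 3000 K, LED 4000 K), each a parametric line list plus
Gaussian continua (parameters in `data/lamp_library.json`), normalized to
unit bolometric power so that a pixel's emission scale multiplies a
convex class mixture.  These are synthetic stand-ins, not measured
spectra: adequate for ratio/index *structure* (sodium red-heavy, LEDs
blue-pumped, mercury line-dominated), not for matching any published
coefficient derived from measured-spectrum libraries.

## Ratio–index and ratio–intensity regressions

Indices and satellite-correction factors are fitted as functions of one
color ratio over the library (7 pure classes + 21 pairwise mixtures):
quadratic `c0 + c1x + c2x²` for B/G predictors, exponential `a·bˣ` for
G/R predictors — the same functional families as the published
satellite-correction equations.  Exponential fits are solved by
`scipy.optimize.curve_fit` seeded from a log-linear fit.

Coefficient uncertainty: a seeded **leverage-adjusted residual
bootstrap** with expanded percentile intervals (percentile levels widened
by the small-sample t adjustment), 1000 replicates by default.  Residual
resampling is used because the library design is fixed across fits; case
resampling of library members was tried first and its percentile
intervals undercover the intercept at this sample size (n = 28), which
the coverage test would flag.  With the shipped scheme, per-coefficient
coverage of the generating truth measures ≈ 0.95 (the acceptance script
recomputes a 100-replicate coverage check).

### Published intensity coefficients vs. refits

The closed-form models

    G/VIIRS = 0.21 · 1.5^(G/R)        (a: +0.21/−0.06, b: +0.09/−0.30)
    B/VIIRS = −0.03 + 0.6·(B/G) + 1.3·(B/G)²
    P/VIIRS = 0.23 · 0.21^(G/R)       (p1 CI reaches 0.0 at its lower end)

are shipped verbatim as the canonical defaults (`RegressionCoefficients`)
and are what the CLI and CI propagation use unless told otherwise.  They
encode a *different* spectral library and camera than this package's
synthetic ones, so the synthetic pipeline refits the same three
relationships from its own library (same procedure, `RatioIndexModel`
objects) and uses the refits for its internally consistent intensity
grids.  The published values are never overwritten; equation-fidelity
checks test them exactly as printed.  Negative quadratic outputs (the
B model dips to −0.03 at B/G = 0) are clamped to zero in intensity grids
with a counter recorded, never in the raw model evaluation.  Coefficient
CIs are propagated by evaluating the model at every CI corner and taking
the envelope — exact for these monotone-in-parameter forms and cheaper
than re-bootstrapping per pixel.

## Synthetic scenes: what they emulate

`make_lamp_maps` draws Gaussian-decay city blobs (σ 12–20 px of 500 m,
log-normal amplitudes around 8 nW cm⁻² sr⁻¹-equivalent bolometric) with a
per-city epoch-1 technology mix dominated by HPS (55–75 %) plus minority
LPS, mercury, fluorescent and metal halide; pixels below 2.0 units are
unlit.  Epoch 2 reassigns the sodium weight of a seeded Bernoulli
(`epoch_shift`) subset of lit pixels to LED (70 % 4000 K / 30 % 3000 K).
The satellite raster is the 480–920 nm in-band integral of the same
ground truth — deliberately blind to the LED blue pump.

`render_frame` applies, in physical order: cloud occlusion (smoothed
thresholded noise field; transmission 0.05 plus a faint broad-spectrum
glow of 0.3 units — occluding rather than purely bright, because the
cloud-detection heuristic compares camera darkness against the
multi-date satellite composite), per-band atmospheric extinction
`t^airmass` (t = 0.93/0.88/0.82 for R/G/B, airmass = 1/cosθ capped at 5),
radial vignetting `1 − 0.35u² − 0.15u⁴`, exposure/ISO/lens scaling with
instrumental constants ≈ 5×10⁻⁵ radiance units per count, reference point
sources, 3×3 channel crosstalk, a rational high-count roll-off above 80 %
of a 65535 full well, and Gaussian noise with variance `15² + 2·counts`.
Ground truth for every corruption is attached to the frame.
Georeferencing error is modeled as Gaussian jitter (σ = 4 px) on the
*reported* map coordinates of the control points while the true frame
placement is exact — so the fitted warp, not the scene, carries the
error, and the control-point residual RMSE reproduces the ~4 px figure.

Not emulated: urban morphology and road networks, astronaut pointing and
window-transmittance variation (a single per-frame gray factor stands in),
PSF/chromatic aberration, real star fields (replaced by synthetic
point sources of known flux), and real weather.  Consequently, passing
round-trip tests demonstrates the *correction chain's* fidelity against
its own forward model, not performance on real raw files.

## Calibration chain

Fixed order: decode → linearity inversion → flat-field → crosstalk
inversion → photometric calibration → settings (radiometric) correction →
atmospheric correction → cloud mask.  A test verifies that permuting
linearity and flat-field measurably worsens the round trip (they do not
commute above the knee).  Saturation is flagged where the inverted count
exceeds the full well (i.e., beyond the roll-off midpoint); masked pixels
never re-enter statistics.  Instrumental constants are estimated per
acquisition from dedicated dark star-field calibration frames — aperture
photometry (radius 3 px, annulus 5–8 px, median background) of ≥ 3
unsaturated reference sources, median ratio of known flux to
background-subtracted counts normalized to reference settings.
Calibrating against sources embedded in bright focal scenes is supported
as a fallback but is biased by the scene background gradient; the
star-field route is the supported one.  The cloud heuristic masks pixels
whose G radiance falls below 0.2 of the co-located satellite radiance.

## Mosaicking

Map→frame coordinate mappings are fitted from control points (affine
least squares, or thin-plate splines via `RBFInterpolator` with optional
smoothing for ≥ 6 points); fitting the inverse direction directly makes
resampling a lookup.  Nearest-neighbor resampling is the default so that
no mosaic pixel blends spectra from different frame pixels (bilinear is
available).  The synthetic pipeline defaults to the affine fit because
its frames are affinely placed and exact TPS interpolation of jittered
control points would warp locally; TPS is exercised against smooth
nonlinear warps in tests.  Compositing is winner-takes-all with the
lexicographic precedence (observation angle, focal length, offset from
frame center, recency under the post-epoch policy, frame ID as the
deterministic tie-break) — the published preference list states no
combination rule, and a lexicographic order with angle dominant is
reproducible and order-free.  Per-pixel provenance is recorded;
permuting the input frame list changes nothing.

## Masks

Outliers: strictly greater than 1.2 (B/G), 1.2 (G/R) or 6 (R/G), OR'd —
"exceeded" is read as strict, so boundary values survive; a conjunctive
reading (requiring the R/G violation jointly) is available by flag.
Satellite floor: strictly below 0.5 nW cm⁻² sr⁻¹ masked.  Masking never
alters surviving values, and the two filters commute.

## Change analysis

Per-epoch medians and IQRs use linear-interpolation (type-7) quantiles —
IQR values depend on this choice.  Two-epoch comparison uses the
two-group Kruskal-Wallis rank test with midrank tie correction (χ²
approximation, df = 1), matching the form of the published statistics; an
all-identical pooled sample short-circuits to H = 0, p = 1 with a
warning.  Pixels are treated as independent samples, as the published
analysis implicitly does; spatial autocorrelation makes p-values
anti-conservative, and every report footer says so.  Zonal summaries use
the pixel-center-in-polygon rule; regions with no valid pixels are
flagged, never dropped.

### The matched-conditions null

With `epoch_shift = 0` and fully independent acquisitions per epoch, the
Europe-wide medians still shift by a few percent: the two epochs have
different random cloud fields and per-frame calibration draws, so their
*valid pixel sets* differ, and at n ≈ 20 000 the rank test detects any
frame-level systematic.  This is a property of the scenario, not a
pipeline defect (on the common valid pixels the shift collapses toward
zero).  The null question "does the pipeline inject a spurious epoch
shift?" is therefore posed with `paired_epochs = True`: identical scene,
acquisition geometries, clouds and control-point jitter in both epochs,
with only the sensor-noise streams independent.  Under that
configuration all shifts sit within pixel noise (≲ 0.5 %) and the rank
test does not reject.

## Numerical and scale choices

* Analysis grid 500 m in EPSG:3035; demo scenes 300 × 300 px with 12
  overlapping 120 × 120 acquisitions per epoch — sized so the full
  two-epoch pipeline runs in tens of seconds while every pathway
  (overlap precedence, clouds, saturation, masking) is exercised.
* Statistics in float64; rasters stored float32 with geospatial metadata
  embedded as JSON in the TIFF description tag; regions as GeoJSON.
* All randomness descends from one seed via `numpy` `SeedSequence`
  spawning; reruns are bit-identical, and every output raster embeds the
  config hash and seed (`verify` checks the chain).
* Round-trip accuracy under the default distortions (recomputed by the
  acceptance script): median per-pixel radiance error ≈ 4 % (dominated by
  nearest-neighbor resampling under ~4 px georeferencing error at city
  edges); the median per-pixel recovered/true ratio sits within a few
  tenths of a percent of 1, i.e. the chain introduces no systematic ratio
  distortion (the noiseless pipeline recovers ratios exactly).  Per-pixel
  ratio scatter is noise-dominated (B/G ≈ 2.7 % median, the blue band
  being the weakest), and that symmetric scatter smears the pooled ratio
  distribution enough to move its raw median by ~2 % — an observation
  effect any noisy survey of a skewed distribution shares, not a
  calibration bias.

## Known limitations

* Lamp spectra, camera curves and action spectra are parametric
  approximations; absolute index values and refit coefficients are
  internally consistent but not anchored to published tables derived
  from measured libraries.
* The intensity estimators are approximate by design (a one-ratio
  correction of a panchromatic measurement); per-pixel relative errors
  of 10–15 % against ground truth are expected even with a perfect fit.
* Rank-test p-values ignore spatial autocorrelation.
* Real raw-file decoding (demosaicing), star-catalog astrometry and
  radiative-transfer atmospheric correction are out of scope; their
  synthetic stand-ins are exact inverses of the forward model, which
  real data would not be.
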