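# Methods notes

This note documents the modeling choices, numerical conventions, and the
reasoning behind the parts of the design that were genuinely open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Steerable pyramid and energy responses

The filter bank is constructed directly in the frequency domain. Radial
windows are raised cosines in log2 spatial frequency,
`cos(pi/2 * log2(r/r_c) / b)` on `|log2(r/r_c)| < b`, with centers spaced by
the bandwidth `b` octaves so that squared magnitudes tile the spectrum
exactly between the coarsest and finest centers. Angular windows are
`cos^(K-1)` lobes restricted to a half plane, normalized so the squared
lobes of all `K` orientations (both half planes) sum to a constant; this
makes each subband an analytic filter whose real/imaginary spatial parts are
the even/odd quadrature pair and whose squared modulus is the
phase-invariant energy. The exact transition shape of the radial window is
not prescribed by the model definition; the raised-cosine choice is the
standard one and satisfies the tiling requirement (verified to ~1e-13 in the
tests, far inside the 1 % requirement).

Center frequencies start at `image_size/4` cycles per image (half of
Nyquist) and halve per octave while they remain above one cycle per image:
for a 512-px image and 1-octave bandwidth this yields exactly 7 levels at
128, 64, 32, 16, 8, 4, 2 cycles/image. The residual high- and low-pass bands
are discarded: only the 7 bandpass levels enter the models. All energy maps
are kept at full image resolution (no subband downsampling) so pRF sampling
uses one common pixel grid.

**Cycles/degree conversion.** Dividing the center frequencies by the
12.0471° field of view gives 10.62, 5.31, 2.66, 1.33, 0.66, 0.33,
0.17 cpd. An alternative published listing of the same levels reports
21.85 … 0.34 cpd — exactly a factor 2.057 higher, which is not consistent
with any plain cycles-per-image / degrees conversion for this geometry.
This package implements the straightforward division and surfaces it in
`center_frequencies`; the discrepancy is noted here rather than guessed
around.

**Orientation convention** (global): angles in radians on `[0, pi)`,
counterclockwise from the positive horizontal axis of visual space,
referring to a grating's *stripe* orientation (0 = horizontal stripes,
pi/2 = vertical). A grating with stripe orientation theta has frequency
power along theta + pi/2, which is where the corresponding angular window
sits. Visual y points up while array row indices grow downward; the pixel
grid helpers handle the sign flip once, and everything else goes through
them.

## Stimulus chain

The display-emulation chain (upsample 425→714, pad with mid-gray to 1024,
fixation disk, channel-average grayscale, anti-aliased downsample to 512)
fixes the working geometry: field of view 8.4° × 1024/714 = 12.0471°
(displayed as 12.05°), Nyquist (512/2)/12.0471 = 21.25 cpd. Unstated
details were resolved as: anti-aliased area-style resampling (protects the
coarse SF channels), a 0.1°-radius fixation disk at a gray level midway
between background and black drawn before grayscale conversion (the few
central pixels are immaterial to the channels), and a linear intensity
mapping with gratings at mean 0.5 and amplitude 0.5 at full contrast.

## pRF sampling

The pRF Gaussian is evaluated at pixel centers, unnormalized (peak 1), and
truncated at the image border without renormalization — the sampled feature
is a plain dot product over the image domain. The published "size" of a
pRF is used directly as the Gaussian SD; no compressive-summation exponent
is applied (for datasets fit with a CSS-style model the size parameter
already accounts for it). Constrained features are exact orientation-group
sums of full features (one code path, asserted in tests), which is what
makes the two model forms exactly nested.

## Encoding fits

OLS is solved with an SVD-based least-squares routine rather than the
normal-equations inverse; rank deficiency falls back to the minimum-norm
solution with a warning. No regularization anywhere. Cross-validation uses
a random split into two near-equal halves with a recorded seed;
coefficients and out-of-sample R² are averaged across the two partitions.
Both control analyses use the same partition for the first-stage constrained
fit and for extracting its residuals/predictions, and the second-stage full
fit is in-partition by design.

## Tuning inference

Probe gratings (30 SFs exponentially spaced from one cycle/image to
Nyquist × 30 orientations uniform on `[0, pi)`) are summed over space per
channel with no pRF weighting; the probe channel sums are computed
spectrally (Parseval) rather than via inverse transforms, which is
bit-for-bit equivalent (tested) and ~50× faster. Preferred orientation is
the amplitude-weighted circular mean on doubled angles after subtracting the
profile minimum; a flat profile (zero resultant) yields NaN — an undefined
preference, flagged, never a crash. "Mean frequency" is computed in log2
domain (geometric mean) because the probes are exponentially spaced and the
channels octave-spaced; a linear-domain alternative sits behind the
`domain` flag. The constant regression term is included in the probe
response but cannot affect either estimate after min-subtraction (tested as
an affine-invariance property).

## Map quantification

Ideal maps: radial = pRF polar angle mod pi; vertical = pi/2 everywhere;
cardinal = vertical for pRFs nearer the vertical meridian, horizontal
otherwise, with the measure-zero 45° tie assigned to vertical. Deviations
are axial angular distances in [0°, 90°]. Binning uses 20 bins — geometric
edges from 0.1° for eccentricity (the first bin extended down to 0),
uniform circular bins for polar angle, uniform [0, 1] for pRF R² — with
voxels of negative pRF R² excluded. Group comparisons are one-sample
t-tests on per-subject paired differences (df = n_subjects − 1,
uncorrected), equivalent to the paired-sample t-test; zero-variance
differences are flagged degenerate instead of propagating NaN. The
deviation-vs-meridian-distance analysis reports the Pearson correlation and
the first-order partial correlation controlling pRF R². Circular
association between two orientation maps uses the Fisher–Lee coefficient on
doubled angles with a seeded permutation test.

## Synthetic data: what it emulates, and what it does not

Image ensembles emulate the broadband second-order statistics of natural
scenes (1/f amplitude noise), optionally with a random per-image
orientation anisotropy (amplitude envelope `1 + 0.8 cos 2(phi - phi_0)`) so
that the orientation channels receive informative variance — without this,
orientation weights are poorly identified no matter the fit. Planted
orientation tuning is a peak-normalized von Mises profile on doubled angles
(kappa = 0 reduces exactly to the orientation-pooled generative case);
SF tuning is Gaussian in log2 frequency across the octave-spaced levels;
noise is additive Gaussian, homoscedastic per voxel, matching the OLS noise
model. Simulated "subjects" are independent voxel populations sharing the
planted map, enabling the df = 7 group tests.

What the generator does **not** emulate: actual natural photographs
(higher-order structure, phase alignments), hemodynamics or time-series
noise structure, voxel-to-voxel noise correlations, pRF-estimation error
(planted pRFs are the true ones), or cortical geometry. Passing recovery
tests therefore validate the *estimator chain*, not robustness to every
real-data pathology.

**Noise calibration.** The group simulation calibrates each voxel's noise
so the explainable variance fraction is 0.15 at 600 images, which puts the
measured cross-validated R² in the low single percents — the regime of
single-trial fMRI betas, where out-of-sample R² is dragged well below the
explainable fraction by estimating 41 weights from ~300 training images.
The calibration matches the observable (cv R²), not the unobservable
explainable variance.

## Problem sizes

The structural and filter-bank checks run at the full 512-px configuration.
The simulation studies (recovery, group map, controls, vignetting) run at a
128-px working grid spanning the same 12.05° field of view, which gives 5
levels / 40 channels; this preserves every geometric relation (channel
spacing, probe grid, pRF scales in degrees) while keeping the pyramid
transform cheap enough that the whole acceptance script completes in about
a minute. Scaled-down sizes — 150–600 images, 30–320 voxels — were chosen
as the smallest at which the estimator chain is comfortably identified
(images ≫ parameters in each partition).

## Vignetting demonstration: design choice

The demonstration plants orientation-pooled (kappa = 0) voxels, drives them
with aperture-masked gratings, and reads apparent preference **directly off
the response profile over stimulus orientation** — the readout of a classic
orientation-mapping experiment. A route through the full-model fit plus
unapertured grating probes cannot exhibit the artifact here, for an
algebraic reason: noiseless orientation-pooled responses lie exactly in the
span of the constrained design columns, so a full-rank full-model OLS fit
reproduces them with orientation-equal weights and the probe profile is
exactly flat. The direct readout is the faithful rendering of the
phenomenon: at the aperture edge the windowed grating has excess energy at
the radial orientation, so untuned edge voxels appear radially tuned, while
voxels whose pRFs see only the grating interior show an order of magnitude
weaker orientation modulation. The edge/interior contrast (rings at the
aperture radius and well inside it) makes the spatial specificity of the
artifact explicit.

## Known limitations

- The frequency-domain bank assumes square, power-of-two-friendly images;
  non-square input is rejected rather than padded.
- Probe features ignore the pRF by design (whole-image energy sums); for
  very eccentric pRFs the probe therefore reflects the planted channel
  weights, not a local stimulus.
- The Fisher–Lee permutation test is O(n² · permutations); it is meant for
  the few-hundred-voxel analyses here, not whole-brain maps.
- `preferred_sf` inherits a small truncation bias (~0.1 octave median in
  the noiseless tests) from averaging a broad profile over a bounded probe
  range; preferences near the range edges are biased inward.
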