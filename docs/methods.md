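# Methods

## Geometry and calibration

All coordinates are 0-based `(row, col)` pixels; pixel `i` occupies
`[i, i+1)` with its center at `i + 0.5`, and every distance (disc
membership, arc sample placement) is computed between continuous points
under this convention, so fractional region centers are well defined.
Angles are degrees from the +col axis toward the +row axis.

Default calibration matches spinning-disc imaging of one-cell *C. elegans*
embryos: 0.151 µm/pixel, 500 ms per frame, 61 frames per 30-s movie.
Because 61 frames span 30 s, a window of `w` seconds contains
`round(w / Δt) + 1` frames with both endpoints included; the standard 5-s
analysis window is therefore 11 kymograph rows. Intensities are converted
on load to a floating 0–255 working scale (integer TIFFs are rescaled by
`255 / dtype_max`), which is the scale on which the comet-counting
threshold of 40 is defined.

## Measurement procedures

**Disc quantification.** Centrosomal signal is the mean over the pixels
whose centers fall within a 25-px-diameter disc (489 pixels when centered
on a pixel center); centriolar signal uses a 5-px disc (21 pixels). The
disc mean is evaluated on every z-plane and the brightest plane reported,
ties breaking toward the lowest index. Background is a same-size disc
outside the embryo, measured by default on the paired signal's chosen
plane. Fold change is the ratio of background-subtracted group means; its
dispersion is the SD of per-sample net values over the control mean, and
it is invariant under any global additive offset and any global rescaling.

**Arc kymographs.** An arc of radius r spanning 355° (a 5° wedge excluded,
pointing along +col by default — the sources never orient it) or 180° is
sampled at uniform arc-length steps; each sample is the mean of bilinear
interpolations at `width_px` radial offsets centered on r. Bilinear
interpolation is used because sub-pixel arcs at radii 25–60 px alias
badly under nearest-pixel sampling; a brute-force nearest-pixel oracle
exists only in the tests. The default column step is 0.5 px so that
diffraction-limited (sub-pixel) comet spots are not aliased across
columns. Counting arcs use `width_px = 1`: the 5-px sampling width is
documented only for the nucleation linescan, and radial averaging over
5 px would dilute a comet's peak to ~42 on the 0–255 scale, making the
threshold-40 count unstable, so single-pixel lines are the only
self-consistent reading for counting.

**Comet events.** Kymograph pixels strictly above threshold (default 40)
are comet signal. Both statistics are always reported: the raw
suprathreshold pixel count, and the number of connected components, which
is the render-scale-invariant "number of growing MTs". Components use
4-connectivity by default: at 0.88 µm/s a comet traverses the sampled arc
in well under one frame, so a suprathreshold blob spans ~1 row, and
diagonal-only contact between consecutive rows almost always joins two
*distinct* crossings; 8-connectivity is available as an argument.

**Cortex crossings.** The ring 1.5 µm (10 px at default calibration)
inside the cortex polygon is sampled as a closed path (computed by inward
polygon buffering); events are local maxima above threshold, greedily
deduplicated with a minimum separation (default 3 px) in
(row, arc-length) space — an automated stand-in for the manual dot
counting used on real recordings.

**Nucleation intensity.** The mean of a 5-px-wide semicircular linescan
(25-px radius) around the centrosome on a 5-s maximum-intensity
projection, minus the same-shape linescan at a user-given cytoplasmic
location. The statistic is approximately linear in the nucleation rate
until crossings begin to overlap on the projection.

**Growth velocity.** A 4.5-µm line (warn if the drawn line deviates more
than 10%) along a single comet track gives a line kymograph; per time row
the comet position is the intensity-weighted centroid of suprathreshold
samples. Rows whose suprathreshold set touches either end of the line are
excluded — a truncated blob would bias its centroid inward. Velocity is
the least-squares slope of position (µm) against time (s), requiring at
least 3 usable rows. On noise-free renders the estimator is accurate to
well under 2% across sub-pixel phase offsets; with default read noise it
recovers 0.3–1.2 µm/s within 5%.

**Colocalization.** Directional Manders-style fractions: within each
60-px-diameter cytoplasmic disc, `100·|M1∩M2|/|M1|` and symmetrically,
where `Mi` is the suprathreshold mask of channel i. Both directions are
reported per region and pooled over the union of regions; an empty source
mask yields 0% with a flag. Unstated thresholds default to the 0.95
within-region quantile and are always recorded.

**Statistics.** The group comparison is the two-sample equal-variance
(pooled-SD) Student t-test with a two-tailed p on n1+n2−2 degrees of
freedom (scipy's implementation, cross-checked in the tests against the
textbook formula to 1e-10). p-values are reported to 3 significant
figures; no multiple-testing correction is applied.

## Simulator

The synthetic embryo is an ellipse with 25 × 15 µm semi-axes; one or two
centrosomes sit on the long axis. Comet births per centrosome follow a
homogeneous Poisson process at rate λ; directions are uniform in a
configurable sector; comets start `birth_radius_px` (default 5 px) from
the centrosome center and move radially at constant v until per-frame
Bernoulli catastrophe (probability p_cat, chosen over continuous-time
exponential to match the frame-quantized analysis and keep crossing
survival in closed form) or cortex contact. With p_cat = 0 every comet
crosses each concentric arc beyond its birth radius exactly once, so the
expected event count of a w-second kymograph window at steady state is
λ·w·(sector fraction facing the arc) — the identity all counting tests
and benchmarks rest on.

Rendering: frame = background (20) + pericentriolar Gaussian blobs
(amplitude 60, σ 4 px) + one isotropic Gaussian per live comet (amplitude
120, σ 0.7 px), then optional Poisson resampling, additive Gaussian read
noise (σ 5), and clipping to [0, 255]. The comet width is the Gaussian
approximation of a diffraction-limited PSF for GFP emission at high NA
(σ ≈ 0.106 µm ≈ 0.7 px at 0.151 µm/px); comets are rendered without
tails because the analyses use point-like plus-end signal only. Amplitude
120 over background 20 with σ-5 noise places comets safely above the
count threshold of 40 and the noise floor (P(background pixel > 40) ≈
3×10⁻⁵) far below it. Fixed immunofluorescence-style z-stacks place each
blob at a focal plane with Gaussian axial attenuation (σ 1.5 planes).
Movies are single-plane, matching center-plane time-lapse acquisition;
there is no photobleaching, z-drift, spindle or chromosome model. λ, v
and p_cat are simulator parameters calibrated to produce realistic
observables (the wild-type benchmark uses λ = 1.26/s and v = 0.88 µm/s),
not measured biological constants.

What passing tests show — and don't: the synthetic movies share the real
data's geometry, sampling and noise scale, but real recordings add
photobleaching, motion of the whole spindle, out-of-focus light, comet
brightness variation and non-radial trajectories. Recovery results here
certify the measurement code, not performance on arbitrary real movies.

## Benchmark conditions and known limitations

The benchmark experiments (`cometkymo.experiments`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use 21-frame
movies with a steady-state window starting at 5 s — by then the earliest
comets have long passed the 25-px arc (crossing takes ~3.4 s from birth).
The wild-type condition (λ = 1.26/s into the semicircle facing the arc,
17 movies) recovers ~5.9–6.9 events against the expected 6.3. Fold-change
benchmarks use control amplitudes (40, 20) so a 3× sample stays within
the 0–255 scale, and the nucleation benchmark compares λ = 1.26/s against
2.52/s, averaging the linescan statistic over the five disjoint 5-s
windows of a full 61-frame recording to tame Poisson noise in the
per-embryo value.

**Crossing merging at high density.** At λ = 5.786/s, ~29 comets cross
the 78.5-px semicircular arc per 5-s window; the mean nearest-neighbor
spacing (~2.7 px) is comparable to a suprathreshold blob's footprint
(~3 px), so distinct crossings occasionally fuse into one component.
Faithful end-to-end simulation puts this merge loss at ~15–25%, partially
offset by blob capture at the window edges; the recovered mean is
~24–25 events rather than 28.93. This is an intrinsic resolution limit of
threshold-component counting at 500-ms sampling, not an adjustable bias:
sharpening the PSF below ~0.7 px makes sub-frame crossings fall between
frames and lose detections faster than it separates neighbors. Studies
needing exact counts at such densities would require shorter frame
intervals or a tracking-based counter, both outside this package's scope.

Other limitations: no automatic centrosome detection (annotations are
inputs); no deconvolution, flat-field, drift correction or proprietary
microscope formats; no full particle tracking/linking; no Pearson/Costes
colocalization statistics; midpoint arcs default to the same semicircular
span as proximal arcs (the span there is a convention, not a measured
choice); whether MetaMorph disc regions include boundary pixels is
unknowable from the sources, so the pixel-center rule above is this
package's convention.
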