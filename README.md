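# cometkymo

Quantification of centrosome signal and microtubule (MT) dynamics in
fluorescence time-lapse movies of one-cell *C. elegans* embryos, plus a
synthetic-embryo simulator that provides ground truth for every measurement
stage.

The package is aimed at cell biologists analyzing movies of an EB-family
plus-end marker (EBP-2::GFP), where each growing MT tip appears as a moving
"comet", and at anyone who wants a tested, scriptable replacement for the
interactive region/kymograph workflows usually done in MetaMorph or ImageJ:

* **Region-based intensity quantification** — mean intensity in a
  25-pixel-diameter disc centered on the centrosome (5-pixel disc for
  centriolar signal), evaluated on every focal plane with the brightest
  plane selected, background-subtracted with a same-size disc outside the
  embryo, and expressed as fold change versus a control group.
* **Arc kymographs** — each movie frame is resampled along a 355° circle
  (35-px radius) or semicircle around the centrosome; a kymograph row per
  frame, a column per arc position. Linescan profiles are per-column means.
* **Comet counting** — kymograph pixels above an intensity threshold of 40
  (0–255 working scale) mark comet crossings; connected components of the
  suprathreshold mask count growing MTs at proximal (25 px) and midpoint
  (60 px) arcs, and separated local maxima count comets crossing a ring
  1.5 µm (10 px) inside the cell cortex.
* **Growth velocity** — a 4.5-µm line drawn along one comet track yields a
  line kymograph; the comet position per time row is the intensity-weighted
  centroid of suprathreshold samples, and velocity is the least-squares
  slope of position (µm) versus time (s).
* **Colocalization** — Manders-style directional overlap: within 60-px
  cytoplasmic discs, the percentage of suprathreshold pixels of one channel
  that are also suprathreshold in the other.
* **Statistics** — per-group n / mean / SD / SEM, fold versus control, and
  the equal-variance two-tailed two-sample Student t-test.

The simulator renders an elliptical embryo (50 × 30 µm at 0.151 µm/px) with
Gaussian pericentriolar blobs and comets born at each centrosome as a
Poisson process (rate λ per second), moving radially outward at constant
speed v (wild-type calibration 0.88 µm/s) until per-frame catastrophe with
probability p_cat or cortex contact. Frames are 500 ms apart, with additive
background, optional Poisson resampling and Gaussian read noise. Every
random step takes an explicit seed and reruns bit-identically.

## Worked example

Simulate a wild-type-like movie, build the proximal semicircular kymograph
over a steady-state 5-s window, and count comet events:

```python
from cometkymo import (ImagingConfig, CometSimParams, RenderModel,
                       EmbryoGeometry, RegionSpec, simulate_comets,
                       render_movie, build_kymograph, count_comet_events)

config = ImagingConfig()                      # 0.151 um/px, 500 ms/frame
geometry = EmbryoGeometry.default(config)     # one centrosome, elliptical cortex
params = CometSimParams(nucleation_rate_per_s=1.26, velocity_um_per_s=0.88,
                        angular_sector_deg=180.0, sector_center_deg=180.0)
tracks = simulate_comets(params, geometry, duration_s=10.5, seed=1, config=config)
stack, truth = render_movie(tracks, RenderModel(), config, seed=101, n_frames=21)

arc = RegionSpec.arc(geometry.centrosomes[0], radius_px=25, span_deg=180,
                     gap_center_deg=0, width_px=1)
kym = build_kymograph(stack, arc, window_s=5.0, t_start_s=5.0, step=0.5)
res = count_comet_events(kym)
print(f"simulated comets: {len(tracks)}")
print(f"kymograph shape: {kym.data.shape}")
print(f"events: {res.count}   suprathreshold pixels: {res.suprathreshold_pixels}")
print(f"true crossings in window: "
      f"{truth.tracks.expected_arc_crossings(25.0, 5.0, 10.0, config)}")
```

prints

```
simulated comets: 11
kymograph shape: (11, 157)
events: 6   suprathreshold pixels: 25
true crossings in window: 6
```

Eleven comets were nucleated over 10.5 s into the semicircle facing the
arc; six of them crossed the 25-px arc during the 5-s analysis window
(11 kymograph rows × 157 half-pixel arc columns), and the pipeline counted
exactly those six as connected suprathreshold events. At a mean nucleation
rate of 1.26/s the expected count per 5-s window is λ·w = 6.3.

The same workflow is available from the shell:

```
cometkymo simulate --seed 1 --out run/
cometkymo kymo --stack run/movie.tif --regions run/regions.json \
    --mode count --threshold 40 --out run/counts.csv
cometkymo report --in run/counts.csv --control proximal --out run/report.csv
```

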