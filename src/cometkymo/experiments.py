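"""Reference synthetic experiments exercising the full pipeline.

Each function builds ground-truth movies with the simulator, runs the same
measurement code a user would, and returns the recovered statistic. They
define the package's benchmark conditions:

* comet counting at the proximal semicircular arc for wild-type-like
  (1.26 comets/s) and elevated (5.786 comets/s) nucleation,
* growth-velocity recovery for comets advancing a stated number of pixels
  per frame,
* fold-change recovery for centrosomal amplitude ratios and nucleation-rate
  ratios.

Movies use the default calibration (0.151 um/px, 500 ms/frame) and render
constants (comet amplitude 120 over background 20, read noise sigma 5)
unless an experiment states otherwise; counting windows are 5-s steady-state
windows that start once the earliest-born comets have passed the arc.
"""

from __future__ import annotations

import numpy as np

from .core import ImagingConfig, RegionSpec
from .intensity import fold_change, measure_background, measure_region
from .kymo import (build_kymograph, count_comet_events, nucleation_intensity,
                   polymerization_rate)
from .simulate import (CometSimParams, CometTrack, CometTrackSet,
                       EmbryoGeometry, RenderModel, render_movie,
                       simulate_comets)

#: px/frame displacements equivalent to 0.88 and 0.70 um/s at defaults
WT_PX_PER_FRAME = 2.914
MUT_PX_PER_FRAME = 2.318

PROXIMAL_RADIUS_PX = 25.0
STEADY_STATE_START_S = 5.0
WINDOW_S = 5.0


def _movie(lam: float, seed: int, config: ImagingConfig, n_frames: int = 21,
           model: RenderModel | None = None, sector_deg: float = 180.0,
           sector_center_deg: float = 180.0):
    geometry = EmbryoGeometry.default(config)
    params = CometSimParams(
        nucleation_rate_per_s=lam,
        velocity_um_per_s=0.88,
        catastrophe_per_frame=0.0,
        angular_sector_deg=sector_deg,
        sector_center_deg=sector_center_deg,
    )
    duration = n_frames * config.frame_interval_s
    tracks = simulate_comets(params, geometry, duration, seed, config)
    stack, truth = render_movie(tracks, model or RenderModel(), config,
                                seed + 500_000, n_frames=n_frames)
    return geometry, stack, truth


def proximal_comet_count(lam: float, n_movies: int, base_seed: int,
                         config: ImagingConfig | None = None) -> tuple[float, list[int]]:
    """Mean comet-event count per 5-s proximal-arc kymograph.

    Comets nucleate into the semicircle facing a 25-px-radius semicircular
    arc; the kymograph covers a steady-state 5-s window and events are
    connected suprathreshold (>40) components.
    """
    config = config or ImagingConfig()
    counts = []
    for i in range(n_movies):
        geometry, stack, _ = _movie(lam, base_seed + i, config)
        region = RegionSpec.arc(geometry.centrosomes[0], PROXIMAL_RADIUS_PX,
                                span_deg=180.0, gap_center_deg=0.0, width_px=1)
        kym = build_kymograph(stack, region, WINDOW_S,
                              t_start_s=STEADY_STATE_START_S, step=0.5)
        counts.append(count_comet_events(kym).count)
    return float(np.mean(counts)), counts


def velocity_recovery(px_per_frame: float,
                      config: ImagingConfig | None = None) -> float:
    """Growth velocity (um/s) recovered from a noise-free single-comet render.

    A 4.5-um line is drawn along the track and the velocity estimated from
    the least-squares slope of per-row intensity-weighted centroids.
    """
    config = config or ImagingConfig()
    geometry = EmbryoGeometry.default(config)
    v_um = px_per_frame * config.pixel_size_um / config.frame_interval_s
    birth_radius = 5.0
    cen = geometry.centrosomes[0]
    origin = (cen[0], cen[1] + birth_radius)
    track = CometTrack(0.0, origin, 0.0, v_um, np.inf)
    params = CometSimParams(nucleation_rate_per_s=0.0, velocity_um_per_s=v_um,
                            birth_radius_px=birth_radius)
    tracks = CometTrackSet([track], params, geometry, 10.5, 0)
    model = RenderModel(gaussian_noise_sigma=0.0, pcm_amplitude=0.0)
    stack, _ = render_movie(tracks, model, config, seed=0, n_frames=21)
    length = 4.5 / config.pixel_size_um
    p0 = (cen[0], cen[1] + birth_radius + 1.0)
    line = RegionSpec.line(p0, (p0[0], p0[1] + length), width_px=1)
    return polymerization_rate(stack, line).velocity_um_per_s


def centrosomal_fold_change(n_seeds: int, base_seed: int, ratio: float = 3.0,
                            config: ImagingConfig | None = None) -> float:
    """Recovered 25-px-disc fold change for a generative amplitude ratio.

    Control movies use comet/PCM amplitudes (40, 20); the sample group
    scales both by ``ratio`` (kept within the 0-255 working scale so the
    render stays linear). Backgrounds are same-size discs outside the
    embryo on the same frame.
    """
    config = config or ImagingConfig()
    groups = {"control": [], "sample": []}
    for i in range(n_seeds):
        for name, scale in (("control", 1.0), ("sample", ratio)):
            model = RenderModel(comet_amplitude=40.0 * scale,
                                pcm_amplitude=20.0 * scale)
            seed = base_seed + i + (0 if name == "control" else 100_000)
            geometry, stack, _ = _movie(1.26, seed, config, model=model,
                                        sector_deg=360.0)
            t_mid = stack.n_frames // 2
            sig = measure_region(stack, RegionSpec.disc(geometry.centrosomes[0], 25),
                                 t=t_mid)
            bg = measure_background(stack, RegionSpec.disc((14.0, 14.0), 25),
                                    t=t_mid, plane=sig.chosen_plane)
            groups[name].append((sig, bg))
    return fold_change(groups["sample"], groups["control"]).ratio


def nucleation_fold_change(n_seeds: int, base_seed: int,
                           lam_control: float = 1.26, rate_ratio: float = 2.0,
                           config: ImagingConfig | None = None) -> float:
    """Recovered semicircle-linescan fold change for a nucleation-rate ratio.

    The statistic is the background-subtracted mean of a 5-px-wide
    semicircular linescan (25-px radius) on a 5-s time projection; comets
    nucleate isotropically at the wild-type rate in the control group. Each
    movie spans the full 61-frame recording and the statistic is averaged
    over its five disjoint steady-state windows, as a measurement on a real
    30-s recording would be.
    """
    config = config or ImagingConfig()
    vals = {"control": [], "sample": []}
    for i in range(n_seeds):
        for name, lam in (("control", lam_control),
                          ("sample", lam_control * rate_ratio)):
            seed = base_seed + i + (0 if name == "control" else 100_000)
            geometry, stack, _ = _movie(lam, seed, config, sector_deg=360.0,
                                        n_frames=61)
            cen = geometry.centrosomes[0]
            bgc = (cen[0], cen[1] + geometry.semi_axes_px[1] * 0.58)
            per_window = [
                nucleation_intensity(stack, cen, bgc, t_start_s=t0)
                for t0 in (5.0, 10.0, 15.0, 20.0, 25.0)
            ]
            vals[name].append(float(np.mean(per_window)))
    return float(np.mean(vals["sample"]) / np.mean(vals["control"]))


def cortex_offset_px(config: ImagingConfig | None = None) -> int:
    """The 1.5-um inward cortex offset expressed in whole pixels."""
    config = config or ImagingConfig()
    return int(round(config.um_to_px(1.5)))
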