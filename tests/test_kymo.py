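"""Kymographs, comet counting, nucleation intensity, growth velocity."""

import numpy as np
import pytest
from conftest import make_single_comet_movie

from cometkymo import (CometSimParams, CometTrack, CometTrackSet,
                       ImagingConfig, RegionSpec, RenderModel,
                       build_kymograph, count_comet_events,
                       count_cortex_crossings, linescan_profile,
                       nucleation_intensity, polymerization_rate,
                       render_movie, simulate_comets, time_projection)
from cometkymo.core import ImageStack

V_PX_WT = 2.914  # px/frame corresponding to 0.88 um/s at defaults


def multi_comet_movie(config, geometry, directions_deg, births_s, px_per_frame=V_PX_WT,
                      n_frames=21, model=None, birth_radius_px=5.0):
    v_um = px_per_frame * config.pixel_size_um / config.frame_interval_s
    params = CometSimParams(nucleation_rate_per_s=0.0, velocity_um_per_s=v_um,
                            birth_radius_px=birth_radius_px)
    cen = geometry.centrosomes[0]
    tracks = []
    for d, b in zip(directions_deg, births_s):
        th = np.radians(d)
        origin = (cen[0] + birth_radius_px * np.sin(th),
                  cen[1] + birth_radius_px * np.cos(th))
        tracks.append(CometTrack(b, origin, d, v_um, np.inf))
    ts = CometTrackSet(tracks, params, geometry, n_frames * 0.5, 0)
    model = model or RenderModel(gaussian_noise_sigma=0.0, pcm_amplitude=0.0)
    return render_movie(ts, model, config, seed=0, n_frames=n_frames)


class TestTimeProjection:
    def test_static_movie_projects_to_itself(self, config):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 200, (32, 32))
        stack = ImageStack(np.repeat(frame[None], 11, axis=0)[:, None, None], config)
        np.testing.assert_array_equal(time_projection(stack, 5.0), frame)

    def test_projection_dominates_every_frame(self, config, geometry):
        tr = simulate_comets(CometSimParams(), geometry, 10.0, 1, config)
        stack, _ = render_movie(tr, RenderModel(), config, 2, n_frames=11)
        proj = time_projection(stack, 5.0)
        for k in range(11):
            assert (proj >= stack.frame(k) - 1e-12).all()

    def test_moving_comet_leaves_a_track_of_loci(self, config, geometry):
        stack, _ = make_single_comet_movie(config, geometry, V_PX_WT, n_frames=11)
        proj = time_projection(stack, 5.0)
        # one suprathreshold locus per frame spaced ~2.9 px along the path
        row = int(geometry.centrosomes[0][0])
        band = proj[row - 2:row + 3]
        cols = np.nonzero((band > 40).any(axis=0))[0]
        assert np.ptp(cols) >= 10 * V_PX_WT - 3

    def test_empty_window_rejected(self, config):
        stack = ImageStack(np.zeros((3, 1, 1, 8, 8)), config)
        with pytest.raises(ValueError):
            time_projection(stack, 5.0, t_start_s=10.0)


class TestBuildKymograph:
    def test_uniform_movie_constant_kymograph(self, config):
        stack = ImageStack(np.full((11, 1, 1, 80, 80), 33.0), config)
        region = RegionSpec.arc((40.0, 40.0), 25, span_deg=180, width_px=1)
        k = build_kymograph(stack, region, 5.0)
        np.testing.assert_allclose(k.data, 33.0)
        assert k.n_rows == 11

    def test_column_count_closed_form(self, config):
        stack = ImageStack(np.zeros((11, 1, 1, 220, 220)), config)
        region = RegionSpec.arc((110.0, 110.0), 35, span_deg=355, width_px=1)
        k = build_kymograph(stack, region, 5.0, step=1.0)
        assert k.n_cols == 216

    def test_crossing_lands_in_predicted_row(self, config, geometry):
        stack, truth = make_single_comet_movie(config, geometry, V_PX_WT, n_frames=21)
        region = RegionSpec.arc(geometry.centrosomes[0], 25, span_deg=180,
                                gap_center_deg=180.0, width_px=1)
        k = build_kymograph(stack, region, 5.0, t_start_s=0.0, step=0.5)
        # crossing time: (25 - 5) px at 2.914 px/frame = 6.86 frames -> row 7
        rows = np.nonzero((k.data > 40).any(axis=1))[0]
        assert len(rows) > 0 and {int(r) for r in rows} <= {6, 7, 8}

    def test_commutes_with_time_cropping(self, config, geometry):
        tr = simulate_comets(CometSimParams(), geometry, 10.0, 3, config)
        stack, _ = render_movie(tr, RenderModel(), config, 4, n_frames=21)
        region = RegionSpec.arc(geometry.centrosomes[0], 25, span_deg=180, width_px=1)
        full = build_kymograph(stack, region, 5.0, t_start_s=2.0)
        cropped = build_kymograph(stack.crop_time(4, 21), region, 5.0, t_start_s=0.0)
        np.testing.assert_allclose(full.data, cropped.data)


class TestLinescanProfile:
    def test_constant_kymograph(self, config):
        stack = ImageStack(np.full((11, 1, 1, 80, 80), 12.0), config)
        region = RegionSpec.arc((40.0, 40.0), 25, span_deg=355, width_px=1)
        prof = linescan_profile(build_kymograph(stack, region, 5.0))
        np.testing.assert_allclose(prof.values, 12.0)
        assert prof.values.size == prof.angles_deg.size

    def test_single_crossing_gives_single_bump(self, config, geometry):
        stack, _ = make_single_comet_movie(config, geometry, V_PX_WT, n_frames=11)
        region = RegionSpec.arc(geometry.centrosomes[0], 25, span_deg=180,
                                gap_center_deg=180.0, width_px=1)
        prof = linescan_profile(build_kymograph(stack, region, 5.0, step=0.5))
        above = prof.values > 25.0  # background is 20
        runs = np.diff(np.r_[0, above.astype(int), 0])
        assert (runs == 1).sum() == 1

    def test_profile_level_scales_with_comet_rate(self, config, geometry):
        """Mean background-subtracted profile roughly doubles with rate."""
        region = RegionSpec.arc(geometry.centrosomes[0], 25, span_deg=180, width_px=1)
        levels = {}
        for lam in (0.6, 1.2):
            vals = []
            for seed in range(12):
                p = CometSimParams(nucleation_rate_per_s=lam,
                                   angular_sector_deg=180.0, sector_center_deg=180.0)
                tr = simulate_comets(p, geometry, 10.0, 100 + seed, config)
                stack, _ = render_movie(tr, RenderModel(), config, 200 + seed,
                                        n_frames=21)
                prof = linescan_profile(build_kymograph(stack, region, 5.0,
                                                        t_start_s=5.0))
                vals.append(prof.values.mean() - 20.0)
            levels[lam] = np.mean(vals)
        assert levels[1.2] / levels[0.6] == pytest.approx(2.0, rel=0.25)


class TestCountCometEvents:
    def test_background_only_counts_zero(self, config):
        stack = ImageStack(np.full((11, 1, 1, 80, 80), 20.0), config)
        region = RegionSpec.arc((40.0, 40.0), 25, span_deg=180, width_px=1)
        res = count_comet_events(build_kymograph(stack, region, 5.0))
        assert res.count == 0 and res.suprathreshold_pixels == 0

    def test_single_crossing_is_one_event(self, config, geometry):
        stack, _ = make_single_comet_movie(config, geometry, V_PX_WT, n_frames=11)
        region = RegionSpec.arc(geometry.centrosomes[0], 25, span_deg=180,
                                gap_center_deg=180.0, width_px=1)
        res = count_comet_events(build_kymograph(stack, region, 5.0, step=0.5))
        assert res.count == 1
        assert res.suprathreshold_pixels >= 1

    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_well_separated_crossings_count_exactly(self, config, geometry, k):
        directions = 180.0 + np.linspace(-70, 70, k)
        births = np.linspace(0.0, 1.5, k)
        stack, _ = multi_comet_movie(config, geometry, directions, births)
        region = RegionSpec.arc(geometry.centrosomes[0], 25, span_deg=180,
                                gap_center_deg=0.0, width_px=1)
        res = count_comet_events(build_kymograph(stack, region, 5.0, step=0.5))
        assert res.count == k

    def test_components_match_brute_force_labeling(self, config, geometry):
        """4-connected components equal an independent flood-fill count."""
        directions = 180.0 + np.linspace(-60, 60, 5)
        stack, _ = multi_comet_movie(config, geometry, directions, np.linspace(0, 2, 5))
        region = RegionSpec.arc(geometry.centrosomes[0], 25, span_deg=180, width_px=1)
        kym = build_kymograph(stack, region, 5.0, step=0.5)
        res = count_comet_events(kym)
        mask = kym.data > 40.0
        seen = np.zeros_like(mask)
        n = 0
        for i in range(mask.shape[0]):
            for j in range(mask.shape[1]):
                if mask[i, j] and not seen[i, j]:
                    n += 1
                    stackq = [(i, j)]
                    while stackq:
                        a, b = stackq.pop()
                        if not (0 <= a < mask.shape[0] and 0 <= b < mask.shape[1]):
                            continue
                        if not mask[a, b] or seen[a, b]:
                            continue
                        seen[a, b] = True
                        stackq += [(a + 1, b), (a - 1, b), (a, b + 1), (a, b - 1)]
        assert res.count == n

    def test_crossing_conservation_poisson_mean(self, config, geometry):
        """With p_cat = 0, mean events at a steady-state semicircular arc
        approach lambda * window within 3 SE over 50 seeds."""
        lam = 0.8
        counts = []
        region = RegionSpec.arc(geometry.centrosomes[0], 25, span_deg=180,
                                gap_center_deg=0.0, width_px=1)
        for seed in range(50):
            p = CometSimParams(nucleation_rate_per_s=lam, angular_sector_deg=180.0,
                               sector_center_deg=180.0)
            tr = simulate_comets(p, geometry, 10.5, seed, config)
            stack, _ = render_movie(tr, RenderModel(), config, 1000 + seed,
                                    n_frames=21)
            k = build_kymograph(stack, region, 5.0, t_start_s=5.0, step=0.5)
            counts.append(count_comet_events(k).count)
        expect = lam * 5.0
        se = np.sqrt(expect / 50)
        # window-edge capture adds ~lam * blob-duration of extra events
        assert abs(np.mean(counts) - expect) < 3 * se + lam * 0.6


class TestCortexCrossings:
    def _cortex_region(self, geometry, config):
        return RegionSpec.polygon_offset(geometry.cortex_polygon(),
                                         round(config.um_to_px(1.5)))

    def test_no_comet_reaches_cortex(self, config, geometry):
        p = CometSimParams(nucleation_rate_per_s=1.0, catastrophe_per_frame=0.9)
        tr = simulate_comets(p, geometry, 10.0, 2, config)
        stack, _ = render_movie(tr, RenderModel(), config, 3, n_frames=11)
        res = count_cortex_crossings(stack, self._cortex_region(geometry, config), 5.0)
        assert res.count == 0

    def test_single_comet_crosses_once(self, config, geometry):
        # aim along the short axis; the ring at r ~89 px is reached at ~14.9 s
        stack, _ = make_single_comet_movie(config, geometry, V_PX_WT,
                                           direction_deg=90.0, n_frames=36)
        region = self._cortex_region(geometry, config)
        res = count_cortex_crossings(stack, region, 5.0, t_start_s=12.5)
        assert res.count == 1

    def test_counts_decrease_with_catastrophe(self, config, geometry):
        region = self._cortex_region(geometry, config)
        means = []
        for p_cat in (0.0, 0.25):
            counts = []
            for seed in range(8):
                p = CometSimParams(nucleation_rate_per_s=1.5,
                                   catastrophe_per_frame=p_cat)
                tr = simulate_comets(p, geometry, 25.0, seed, config)
                stack, _ = render_movie(tr, RenderModel(), config, 50 + seed,
                                        n_frames=51)
                counts.append(count_cortex_crossings(stack, region, 5.0,
                                                     t_start_s=18.0).count)
            means.append(np.mean(counts))
        assert means[1] < means[0]

    def test_degenerate_polygon_rejected(self, config, geometry):
        region = RegionSpec.polygon_offset([(0, 0), (0, 4), (4, 4), (4, 0)], 10)
        stack, _ = make_single_comet_movie(config, geometry, V_PX_WT, n_frames=11)
        with pytest.raises(ValueError, match="degenerate"):
            count_cortex_crossings(stack, region, 5.0)


class TestRadialMonotonicity:
    def test_counts_fall_with_radius_under_catastrophe(self, config, geometry):
        """Per arc length, mean counts at 25 px >= 60 px when p_cat > 0."""
        per_radius = {25: [], 60: []}
        for seed in range(8):
            p = CometSimParams(nucleation_rate_per_s=3.0, catastrophe_per_frame=0.15,
                               angular_sector_deg=180.0, sector_center_deg=180.0)
            tr = simulate_comets(p, geometry, 18.0, seed, config)
            stack, _ = render_movie(tr, RenderModel(), config, 300 + seed,
                                    n_frames=37)
            for radius in (25, 60):
                region = RegionSpec.arc(geometry.centrosomes[0], radius,
                                        span_deg=180, gap_center_deg=0.0, width_px=1)
                k = build_kymograph(stack, region, 5.0, t_start_s=12.0, step=0.5)
                per_radius[radius].append(count_comet_events(k).count / radius)
        assert np.mean(per_radius[25]) >= np.mean(per_radius[60])


class TestNucleationIntensity:
    def test_zero_comets_zero_signal(self, config, geometry):
        p = CometSimParams(nucleation_rate_per_s=0.0)
        tr = simulate_comets(p, geometry, 10.0, 1, config)
        stack, _ = render_movie(tr, RenderModel(pcm_amplitude=0.0), config, 2,
                                n_frames=11)
        cen = geometry.centrosomes[0]
        bgc = (cen[0], cen[1] + 90.0)
        val = nucleation_intensity(stack, cen, bgc)
        # pure noise: the statistic should sit near zero
        assert abs(val) < 3.0

    def test_missing_background_region_rejected(self, config, geometry):
        stack, _ = make_single_comet_movie(config, geometry, V_PX_WT, n_frames=11)
        with pytest.raises(ValueError, match="background"):
            nucleation_intensity(stack, geometry.centrosomes[0], None)

    def test_orientation_insensitive_for_isotropic_nucleation(self, config, geometry):
        cen = geometry.centrosomes[0]
        bgc = (cen[0], cen[1] + 95.0)
        a_vals, b_vals = [], []
        for seed in range(10):
            p = CometSimParams(nucleation_rate_per_s=2.0)
            tr = simulate_comets(p, geometry, 10.0, seed, config)
            stack, _ = render_movie(tr, RenderModel(), config, 700 + seed,
                                    n_frames=21)
            a_vals.append(nucleation_intensity(stack, cen, bgc, t_start_s=5.0,
                                               gap_center_deg=270.0))
            b_vals.append(nucleation_intensity(stack, cen, bgc, t_start_s=5.0,
                                               gap_center_deg=90.0))
        diff = np.mean(a_vals) - np.mean(b_vals)
        se = np.sqrt(np.var(a_vals, ddof=1) / 10 + np.var(b_vals, ddof=1) / 10)
        assert abs(diff) < max(3 * se, 1.0)


class TestPolymerizationRate:
    def _track_line(self, geometry, config, direction_deg=0.0, start_radius=6.0):
        cen = geometry.centrosomes[0]
        th = np.radians(direction_deg)
        length = 4.5 / config.pixel_size_um  # 29.8 px
        p0 = (cen[0] + start_radius * np.sin(th), cen[1] + start_radius * np.cos(th))
        p1 = (p0[0] + length * np.sin(th), p0[1] + length * np.cos(th))
        return RegionSpec.line(p0, p1, width_px=1)

    @pytest.mark.parametrize("px_per_frame,expected", [(2.914, 0.88), (2.318, 0.70)])
    def test_recovers_known_rates(self, config, geometry, px_per_frame, expected):
        stack, _ = make_single_comet_movie(config, geometry, px_per_frame, n_frames=21)
        est = polymerization_rate(stack, self._track_line(geometry, config))
        assert est.velocity_um_per_s == pytest.approx(expected, abs=0.02)
        assert est.n_time_points >= 3

    def test_stationary_spot_zero_velocity(self, config, geometry):
        frame = np.full((219, 352), 20.0)
        cen = geometry.centrosomes[0]
        yy, xx = np.mgrid[0:219, 0:352]
        frame += 120 * np.exp(-(((yy + 0.5) - cen[0]) ** 2
                                + ((xx + 0.5) - (cen[1] + 15)) ** 2) / (2 * 0.7**2))
        stack = ImageStack(np.repeat(frame[None], 11, axis=0)[:, None, None], config)
        est = polymerization_rate(stack, self._track_line(geometry, config))
        assert est.velocity_um_per_s == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_track_rejected(self, config, geometry):
        stack, _ = make_single_comet_movie(config, geometry, 2.914, n_frames=3)
        line = self._track_line(geometry, config, start_radius=20.0)
        with pytest.raises(ValueError, match="fewer than 3"):
            polymerization_rate(stack, line)

    @pytest.mark.parametrize("v_um", [0.3, 0.6, 0.9, 1.2])
    def test_velocity_sweep_with_noise(self, config, geometry, v_um):
        px_per_frame = v_um / config.pixel_size_um * config.frame_interval_s
        model = RenderModel(pcm_amplitude=0.0)  # default read noise sigma 5
        stack, _ = make_single_comet_movie(config, geometry, px_per_frame,
                                           n_frames=31, model=model, seed=42)
        est = polymerization_rate(stack, self._track_line(geometry, config))
        assert est.velocity_um_per_s == pytest.approx(v_um, rel=0.05)

    def test_subpixel_phase_offsets_unbiased(self, config, geometry):
        """Noise-free slope recovery within 2% across fractional start offsets."""
        for offset in (0.0, 0.25, 0.5, 0.75):
            stack, _ = make_single_comet_movie(config, geometry, 2.914,
                                               birth_radius_px=5.0 + offset,
                                               n_frames=21)
            est = polymerization_rate(stack, self._track_line(geometry, config))
            assert est.velocity_um_per_s == pytest.approx(0.88, rel=0.02)
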