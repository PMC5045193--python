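import numpy as np
import pytest

from cometkymo import (CometSimParams, CometTrack, CometTrackSet,
                       EmbryoGeometry, ImagingConfig, RenderModel,
                       render_movie)


@pytest.fixture
def config():
    return ImagingConfig()


@pytest.fixture
def geometry(config):
    return EmbryoGeometry.default(config)


@pytest.fixture
def quiet_model():
    """Noise-free render model without a pericentriolar blob."""
    return RenderModel(gaussian_noise_sigma=0.0, pcm_amplitude=0.0)


def make_single_comet_movie(config, geometry, px_per_frame, direction_deg=0.0,
                            n_frames=21, model=None, birth_radius_px=5.0,
                            seed=0):
    """Render one comet advancing ``px_per_frame`` radially per frame."""
    v_um = px_per_frame * config.pixel_size_um / config.frame_interval_s
    params = CometSimParams(nucleation_rate_per_s=0.0, velocity_um_per_s=v_um,
                            birth_radius_px=birth_radius_px)
    th = np.radians(direction_deg)
    cen = geometry.centrosomes[0]
    origin = (cen[0] + birth_radius_px * np.sin(th),
              cen[1] + birth_radius_px * np.cos(th))
    track = CometTrack(birth_time_s=0.0, origin=origin, direction_deg=direction_deg,
                       velocity_um_per_s=v_um, death_time_s=np.inf)
    tracks = CometTrackSet([track], params, geometry, duration_s=n_frames * 0.5, seed=seed)
    model = model or RenderModel(gaussian_noise_sigma=0.0, pcm_amplitude=0.0)
    return render_movie(tracks, model, config, seed=seed, n_frames=n_frames)
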