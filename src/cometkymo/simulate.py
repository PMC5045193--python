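"""Synthetic one-cell embryo movies with ground-truth comet trajectories.

The simulator emulates time-lapse imaging of an EB-family plus-end marker
(EBP-2::GFP) in a one-cell *C. elegans* embryo: an elliptical cortex
(~50 x 30 um), one or two centrosomes rendered as Gaussian pericentriolar
blobs, and comets nucleating at the centrosomes that move radially outward
at a constant velocity until catastrophe or cortex contact. Frames are
rendered at 0.151 um/px every 500 ms on a 0-255 working scale, with
additive background, optional Poisson resampling, and Gaussian read noise.

Every stochastic step takes an explicit seed; identical parameters and seed
reproduce stacks bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import ImageStack, ImagingConfig, RegionSpec

DEFAULT_SEMI_AXES_UM = (25.0, 15.0)


@dataclass
class EmbryoGeometry:
    """Elliptical cortex plus centrosome positions, in pixel coordinates.

    ``center`` and ``semi_axes_px`` define the cortex ellipse (row, col);
    ``spindle_axis_deg`` orients the centrosome pair along the long axis by
    default.
    """

    center: tuple[float, float]
    semi_axes_px: tuple[float, float]  # (row semi-axis, col semi-axis)
    centrosomes: list[tuple[float, float]]
    spindle_axis_deg: float = 0.0

    def __post_init__(self) -> None:
        for pos in self.centrosomes:
            if self.ellipse_radial_fraction(pos) >= 1.0:
                raise ValueError(f"centrosome {pos} lies outside the cortex ellipse")

    def ellipse_radial_fraction(self, point: tuple[float, float]) -> float:
        r = (point[0] - self.center[0]) / self.semi_axes_px[0]
        c = (point[1] - self.center[1]) / self.semi_axes_px[1]
        return float(np.hypot(r, c))

    def cortex_polygon(self, n_vertices: int = 128) -> list[tuple[float, float]]:
        th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        return [
            (self.center[0] + self.semi_axes_px[0] * np.sin(t),
             self.center[1] + self.semi_axes_px[1] * np.cos(t))
            for t in th
        ]

    @classmethod
    def default(cls, config: ImagingConfig | None = None, n_centrosomes: int = 1,
                image_shape: tuple[int, int] | None = None) -> "EmbryoGeometry":
        """An embryo filling the frame: 25 x 15 um semi-axes at 0.151 um/px."""
        config = config or ImagingConfig()
        a_row = config.um_to_px(DEFAULT_SEMI_AXES_UM[1])   # short axis along rows
        a_col = config.um_to_px(DEFAULT_SEMI_AXES_UM[0])   # long axis along cols
        if image_shape is None:
            image_shape = (int(2 * a_row) + 20, int(2 * a_col) + 20)
        center = (image_shape[0] / 2.0, image_shape[1] / 2.0)
        # centrosome pair sits on the long (col) axis around the embryo center
        offset = a_col * 0.35
        if n_centrosomes == 1:
            centros = [center]
        else:
            centros = [(center[0], center[1] - offset), (center[0], center[1] + offset)]
        return cls(center=center, semi_axes_px=(a_row, a_col), centrosomes=centros)


@dataclass(frozen=True)
class CometSimParams:
    """Kinetic parameters of the comet (growing plus-end) process.

    nucleation_rate_per_s
        Poisson birth rate per centrosome (lambda), comets/s.
    velocity_um_per_s
        Radial growth speed; wild-type astral MTs grow at ~0.88 um/s.
    catastrophe_per_frame
        Probability that a live comet terminates at each frame boundary.
    birth_radius_px
        Radial offset of nucleation from the centrosome center.
    angular_sector_deg / sector_center_deg
        Directions are drawn uniformly in this sector.
    """

    nucleation_rate_per_s: float = 1.26
    velocity_um_per_s: float = 0.88
    catastrophe_per_frame: float = 0.0
    birth_radius_px: float = 5.0
    angular_sector_deg: float = 360.0
    sector_center_deg: float = 90.0
    max_live_comets: int = 2000

    def __post_init__(self) -> None:
        if self.nucleation_rate_per_s < 0:
            raise ValueError("nucleation_rate_per_s must be >= 0")
        if self.velocity_um_per_s <= 0:
            raise ValueError("velocity_um_per_s must be > 0")
        if not (0 <= self.catastrophe_per_frame < 1):
            raise ValueError("catastrophe_per_frame must lie in [0, 1)")
        if self.birth_radius_px < 0:
            raise ValueError("birth_radius_px must be >= 0")


@dataclass(frozen=True)
class RenderModel:
    """Photometric model of a rendered frame on the 0..bit_scale scale.

    The comet spot width defaults to 0.7 px (0.106 um at 0.151 um/px), the
    Gaussian approximation of a diffraction-limited PSF for GFP emission at
    high NA. Comet amplitude 120 over background 20 with read noise sigma 5
    places comets safely above the counting threshold of 40 while leaving
    the noise floor well below it.
    """

    comet_amplitude: float = 120.0
    comet_sigma_px: float = 0.7
    pcm_amplitude: float = 60.0
    pcm_sigma_px: float = 4.0
    background_level: float = 20.0
    gaussian_noise_sigma: float = 5.0
    poisson_noise: bool = False

    def __post_init__(self) -> None:
        for name in ("comet_amplitude", "comet_sigma_px", "pcm_amplitude",
                     "pcm_sigma_px", "background_level", "gaussian_noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CometTrack:
    birth_time_s: float
    origin: tuple[float, float]          # (row, col) at birth_radius from centrosome
    direction_deg: float
    velocity_um_per_s: float
    death_time_s: float
    centrosome_index: int = 0

    def position(self, t_s: float, config: ImagingConfig) -> tuple[float, float] | None:
        """(row, col) at time ``t_s``, or None if the comet is not alive."""
        if not (self.birth_time_s <= t_s < self.death_time_s):
            return None
        d_px = config.um_to_px(self.velocity_um_per_s * (t_s - self.birth_time_s))
        th = np.radians(self.direction_deg)
        return (self.origin[0] + d_px * np.sin(th), self.origin[1] + d_px * np.cos(th))

    def radius_at(self, t_s: float, config: ImagingConfig, birth_radius_px: float) -> float:
        return birth_radius_px + config.um_to_px(self.velocity_um_per_s * (t_s - self.birth_time_s))


@dataclass
class CometTrackSet:
    tracks: list[CometTrack]
    params: CometSimParams
    geometry: EmbryoGeometry
    duration_s: float
    seed: int

    def __len__(self) -> int:
        return len(self.tracks)

    def live_positions(self, t_s: float, config: ImagingConfig) -> list[tuple[float, float]]:
        out = []
        for tr in self.tracks:
            p = tr.position(t_s, config)
            if p is not None:
                out.append(p)
        return out

    def expected_arc_crossings(self, radius_px: float, t0_s: float, t1_s: float,
                               config: ImagingConfig) -> int:
        """Number of tracks whose radial interval spans ``radius_px`` within [t0, t1]."""
        n = 0
        v_px = config.um_to_px(self.params.velocity_um_per_s)
        for tr in self.tracks:
            if radius_px < self.params.birth_radius_px:
                continue
            t_cross = tr.birth_time_s + (radius_px - self.params.birth_radius_px) / v_px
            if tr.birth_time_s <= t_cross <= tr.death_time_s and t0_s <= t_cross <= t1_s:
                n += 1
        return n

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "birth_time_s": tr.birth_time_s,
                    "origin_row": tr.origin[0],
                    "origin_col": tr.origin[1],
                    "direction_deg": tr.direction_deg,
                    "velocity_um_per_s": tr.velocity_um_per_s,
                    "death_time_s": tr.death_time_s,
                    "centrosome_index": tr.centrosome_index,
                }
                for tr in self.tracks
            ]
        )


@dataclass
class GroundTruth:
    tracks: CometTrackSet | None
    noise_free: ImageStack
    pcm_integrated: list[float] = field(default_factory=list)


def _cortex_exit_time(origin, direction_deg, v_px, geometry: EmbryoGeometry, birth_time_s) -> float:
    """Time at which a radially moving comet reaches the cortex ellipse."""
    th = np.radians(direction_deg)
    dr, dc = np.sin(th), np.cos(th)
    ar, ac = geometry.semi_axes_px
    # solve |((origin + s*d) - center)/semi_axes| = 1 for path length s >= 0
    pr = (origin[0] - geometry.center[0]) / ar
    pc = (origin[1] - geometry.center[1]) / ac
    qr, qc = dr / ar, dc / ac
    a = qr * qr + qc * qc
    b = 2 * (pr * qr + pc * qc)
    c = pr * pr + pc * pc - 1.0
    disc = b * b - 4 * a * c
    if disc <= 0:
        return birth_time_s
    s = (-b + np.sqrt(disc)) / (2 * a)
    return birth_time_s + max(s, 0.0) / v_px


def simulate_comets(
    params: CometSimParams,
    geometry: EmbryoGeometry,
    duration_s: float,
    seed: int,
    config: ImagingConfig | None = None,
    t_start_s: float = 0.0,
) -> CometTrackSet:
    """Draw ground-truth comet trajectories.

    Births follow a homogeneous Poisson process at ``nucleation_rate_per_s``
    per centrosome over ``[t_start_s, t_start_s + duration_s]``; directions
    are uniform in the configured sector; each comet dies by per-frame
    Bernoulli catastrophe or on reaching the cortex, whichever comes first.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    config = config or ImagingConfig()
    rng = np.random.default_rng(seed)
    v_px = config.um_to_px(params.velocity_um_per_s)
    mean_life_s = duration_s
    if params.catastrophe_per_frame > 0:
        mean_life_s = min(mean_life_s,
                          config.frame_interval_s / params.catastrophe_per_frame)
    expected_live = params.nucleation_rate_per_s * mean_life_s * max(len(geometry.centrosomes), 1)
    if expected_live > params.max_live_comets:
        raise ValueError(
            f"expected live comets ({expected_live:.0f}) exceeds cap {params.max_live_comets}"
        )
    tracks: list[CometTrack] = []
    for ci, cpos in enumerate(geometry.centrosomes):
        n = rng.poisson(params.nucleation_rate_per_s * duration_s)
        births = np.sort(rng.uniform(t_start_s, t_start_s + duration_s, n))
        half = params.angular_sector_deg / 2.0
        dirs = rng.uniform(params.sector_center_deg - half, params.sector_center_deg + half, n)
        for tb, ang in zip(births, dirs):
            th = np.radians(ang)
            origin = (cpos[0] + params.birth_radius_px * np.sin(th),
                      cpos[1] + params.birth_radius_px * np.cos(th))
            t_cortex = _cortex_exit_time(origin, ang, v_px, geometry, tb)
            if params.catastrophe_per_frame > 0:
                # survive k full frames with probability (1 - p)^k
                k = rng.geometric(params.catastrophe_per_frame)  # frames survived, >= 1
                t_cat = tb + k * config.frame_interval_s
            else:
                t_cat = np.inf
            death = float(min(t_cortex, t_cat))
            tracks.append(CometTrack(float(tb), origin, float(ang),
                                     params.velocity_um_per_s, death, ci))
    return CometTrackSet(tracks, params, geometry, duration_s, seed)


def _add_gaussian_spot(frame: np.ndarray, pos, amplitude: float, sigma: float) -> None:
    """Add an isotropic Gaussian in-place, evaluated on a +-5 sigma patch."""
    if amplitude <= 0:
        return
    r, c = pos
    h, w = frame.shape
    half = max(int(np.ceil(5 * sigma)), 2)
    r0, r1 = int(np.floor(r - half)), int(np.ceil(r + half)) + 1
    c0, c1 = int(np.floor(c - half)), int(np.ceil(c + half)) + 1
    r0, r1 = max(r0, 0), min(r1, h)
    c0, c1 = max(c0, 0), min(c1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy = np.arange(r0, r1) + 0.5
    xx = np.arange(c0, c1) + 0.5
    g = np.exp(-((yy[:, None] - r) ** 2 + (xx[None, :] - c) ** 2) / (2 * sigma**2))
    frame[r0:r1, c0:c1] += amplitude * g


def render_movie(
    tracks: CometTrackSet,
    model: RenderModel,
    config: ImagingConfig,
    seed: int,
    image_shape: tuple[int, int] | None = None,
    n_frames: int | None = None,
    t_start_s: float = 0.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a single-plane movie from a track set.

    Each frame is background + PCM blobs + live-comet spots, then optional
    Poisson resampling, additive Gaussian noise, and clipping to
    [0, bit_scale]. The noise-free render is retained in the ground truth.
    """
    geometry = tracks.geometry
    if image_shape is None:
        image_shape = (
            int(2 * geometry.semi_axes_px[0]) + 20,
            int(2 * geometry.semi_axes_px[1]) + 20,
        )
    n_frames = n_frames if n_frames is not None else config.n_frames
    rng = np.random.default_rng(seed)
    clean = np.zeros((n_frames,) + tuple(image_shape))
    for k in range(n_frames):
        t = t_start_s + k * config.frame_interval_s
        frame = np.full(image_shape, model.background_level, dtype=float)
        for cpos in geometry.centrosomes:
            _add_gaussian_spot(frame, cpos, model.pcm_amplitude, model.pcm_sigma_px)
        for pos in tracks.live_positions(t, config):
            _add_gaussian_spot(frame, pos, model.comet_amplitude, model.comet_sigma_px)
        clean[k] = frame
    noisy = clean.copy()
    if model.poisson_noise:
        noisy = rng.poisson(np.clip(noisy, 0, None)).astype(float)
    if model.gaussian_noise_sigma > 0:
        noisy = noisy + rng.normal(0, model.gaussian_noise_sigma, noisy.shape)
    noisy = np.clip(noisy, 0, config.bit_scale)
    clean = np.clip(clean, 0, config.bit_scale)
    cfg = dataclasses.replace(config, n_frames=n_frames, image_shape=tuple(image_shape))
    stack = ImageStack(noisy[:, None, None], cfg, ["EBP-2"])
    truth = GroundTruth(
        tracks=tracks,
        noise_free=ImageStack(clean[:, None, None], cfg, ["EBP-2"]),
        pcm_integrated=[
            2 * np.pi * model.pcm_amplitude * model.pcm_sigma_px**2 for _ in geometry.centrosomes
        ],
    )
    return stack, truth


def render_if_scene(
    scene: list[dict],
    model: RenderModel,
    config: ImagingConfig,
    n_z: int,
    seed: int,
    image_shape: tuple[int, int] = (128, 128),
    n_channels: int = 1,
    axial_sigma_planes: float = 1.5,
) -> tuple[ImageStack, GroundTruth]:
    """Render a fixed (immunofluorescence-style) multi-channel z-stack.

    ``scene`` entries are dicts with keys ``position`` (row, col),
    ``channel``, ``amplitude``, ``sigma_px`` and ``focal_plane``. Each blob
    is brightest at its focal plane and attenuated on neighboring planes by
    a Gaussian axial factor exp(-(z - z0)^2 / (2 * axial_sigma_planes^2)).
    """
    if n_z < 1:
        raise ValueError("n_z must be >= 1")
    rng = np.random.default_rng(seed)
    clean = np.zeros((1, n_z, n_channels) + tuple(image_shape))
    clean += model.background_level
    for blob in scene:
        ch = int(blob.get("channel", 0))
        z0 = float(blob.get("focal_plane", n_z // 2))
        for z in range(n_z):
            att = np.exp(-((z - z0) ** 2) / (2 * axial_sigma_planes**2))
            _add_gaussian_spot(
                clean[0, z, ch], blob["position"], blob["amplitude"] * att,
                blob.get("sigma_px", model.pcm_sigma_px),
            )
    noisy = clean.copy()
    if model.poisson_noise:
        noisy = rng.poisson(np.clip(noisy, 0, None)).astype(float)
    if model.gaussian_noise_sigma > 0:
        noisy = noisy + rng.normal(0, model.gaussian_noise_sigma, noisy.shape)
    noisy = np.clip(noisy, 0, config.bit_scale)
    clean = np.clip(clean, 0, config.bit_scale)
    cfg = dataclasses.replace(config, n_frames=1, image_shape=tuple(image_shape))
    names = [f"ch{i}" for i in range(n_channels)]
    stack = ImageStack(noisy, cfg, list(names))
    return stack, GroundTruth(tracks=None, noise_free=ImageStack(clean, cfg, list(names)))


def default_regions(geometry: EmbryoGeometry, config: ImagingConfig | None = None) -> list[RegionSpec]:
    """The standard measurement regions for each centrosome of a rendered embryo.

    Per centrosome: a 25-px disc, a 5-px centriolar disc, the 355-degree
    35-px kymograph arc, the proximal counting semicircle at 25 px, the
    midpoint semicircle at 60 px; plus the cortex ring 10 px inside the
    cortex polygon.
    """
    config = config or ImagingConfig()
    regions: list[RegionSpec] = []
    for i, pos in enumerate(geometry.centrosomes):
        tag = f"cen{i}"
        regions += [
            RegionSpec.disc(pos, 25, label=f"{tag}_centrosomal"),
            RegionSpec.disc(pos, 5, label=f"{tag}_centriolar"),
            RegionSpec.arc(pos, 35, span_deg=355, width_px=1, label=f"{tag}_arc355"),
            RegionSpec.arc(pos, 25, span_deg=180, width_px=1, label=f"{tag}_proximal"),
            RegionSpec.arc(pos, 60, span_deg=180, width_px=1, label=f"{tag}_midpoint"),
        ]
    offset = config.um_to_px(1.5)
    regions.append(
        RegionSpec.polygon_offset(geometry.cortex_polygon(), round(offset), label="cortex_ring")
    )
    return regions
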