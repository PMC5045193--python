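"""Shared data model: calibration, image stacks, measurement regions, sampling.

Coordinate convention
---------------------
Images are indexed ``(row, col)``, 0-based. Pixel ``i`` occupies the interval
``[i, i+1)`` along its axis, so its center sits at ``i + 0.5``. All region
geometry (disc membership, arc sample placement, line endpoints) is computed
between *continuous* points and pixel centers under this convention, which
keeps sub-pixel region centers unambiguous.

Angles are measured in degrees from the +col axis, increasing toward the
+row axis (counterclockwise in standard image display with the origin at the
top-left).

Working intensity scale
-----------------------
Stacks are converted on load to floating point on a 0..``bit_scale`` scale
(default 0-255): integer TIFF data are rescaled by ``bit_scale / dtype_max``
and float data are taken as-is. Count thresholds (e.g. the comet threshold
of 40) are interpreted on this working scale.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

logger = logging.getLogger(__name__)

AXES = "TZCYX"


class AmbiguousAxesError(ValueError):
    """Raised when TIFF axis metadata cannot be mapped onto (t, z, c, y, x)."""


@dataclass(frozen=True)
class ImagingConfig:
    """Physical calibration of an acquisition.

    Defaults follow spinning-disc imaging of one-cell *C. elegans* embryos:
    0.151 um pixels, one frame every 500 ms, 61 frames per 30-s movie.
    """

    pixel_size_um: float = 0.151
    frame_interval_s: float = 0.5
    n_frames: int = 61
    bit_scale: float = 255.0
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.bit_scale <= 0:
            raise ValueError("bit_scale must be > 0")

    def px_to_um(self, px: float | np.ndarray) -> float | np.ndarray:
        return px * self.pixel_size_um

    def um_to_px(self, um: float | np.ndarray) -> float | np.ndarray:
        return um / self.pixel_size_um

    def frames_in_window(self, window_s: float) -> int:
        """Number of frames spanning ``window_s`` seconds, endpoints inclusive.

        A 30-s movie at 500 ms/frame has 61 frames, so a 5-s window has 11.
        """
        return int(round(window_s / self.frame_interval_s)) + 1


@dataclass
class ImageStack:
    """A (t, z, c, y, x) fluorescence image with calibration.

    ``data`` is floating point on the working 0..bit_scale scale. Singleton
    axes are permitted; a plain 2-D image is t = z = c = 1.
    """

    data: np.ndarray
    config: ImagingConfig = field(default_factory=ImagingConfig)
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim > 5:
            raise ValueError(f"at most 5 axes (t, z, c, y, x), got {arr.ndim}")
        while arr.ndim < 5:
            arr = arr[np.newaxis]
        if np.any(arr < 0):
            raise ValueError("intensities must be nonnegative")
        self.data = arr
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(arr.shape[2])]
        elif len(self.channel_names) != arr.shape[2]:
            raise ValueError("channel_names length must match channel axis")
        if self.config.image_shape is not None and tuple(self.config.image_shape) != arr.shape[3:]:
            self.config = dataclasses.replace(self.config, image_shape=arr.shape[3:])
        elif self.config.image_shape is None:
            self.config = dataclasses.replace(self.config, image_shape=arr.shape[3:])

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3:]

    def frame(self, t: int = 0, z: int = 0, c: int = 0) -> np.ndarray:
        return self.data[t, z, c]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            return self.channel_names.index(channel)
        return int(channel)

    def crop_time(self, t_start: int, t_stop: int) -> "ImageStack":
        return ImageStack(self.data[t_start:t_stop], self.config, list(self.channel_names))


@dataclass
class RegionSpec:
    """A geometric measurement region in pixel coordinates.

    Kinds
    -----
    disc
        ``center`` + ``diameter_px``; membership is pixel-center distance
        <= diameter/2.
    arc
        Circular arc of ``radius_px`` around ``center`` spanning
        ``arc_span_deg`` (default 355, i.e. a 5-degree wedge excluded); the
        excluded wedge is centered on ``arc_gap_center_deg``. Sampled with a
        radial averaging width of ``width_px``.
    line
        Segment between ``endpoints``, sampled with perpendicular averaging
        width ``width_px``.
    polygon_offset
        The ring lying ``offset_px`` inside a polygon boundary (the cell
        cortex), given by ``vertices``.
    """

    kind: str
    center: tuple[float, float] | None = None
    radius_px: float | None = None
    diameter_px: float | None = None
    arc_span_deg: float = 355.0
    arc_gap_center_deg: float = 0.0
    width_px: int = 5
    endpoints: tuple[tuple[float, float], tuple[float, float]] | None = None
    vertices: list[tuple[float, float]] | None = None
    offset_px: float = 0.0
    label: str = ""

    KINDS = ("disc", "arc", "line", "polygon_offset")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.kind == "disc":
            if self.center is None or self.diameter_px is None or self.diameter_px <= 0:
                raise ValueError("disc requires center and positive diameter_px")
        elif self.kind == "arc":
            if self.center is None or self.radius_px is None or self.radius_px <= 0:
                raise ValueError("arc requires center and positive radius_px")
            if not (0 < self.arc_span_deg <= 360):
                raise ValueError("arc_span_deg must lie in (0, 360]")
        elif self.kind == "line":
            if self.endpoints is None:
                raise ValueError("line requires endpoints")
        elif self.kind == "polygon_offset":
            if self.vertices is None or len(self.vertices) < 3:
                raise ValueError("polygon_offset requires >= 3 vertices")
            if self.offset_px < 0:
                raise ValueError("offset_px must be >= 0")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")

    # -- constructors ------------------------------------------------------
    @classmethod
    def disc(cls, center, diameter_px, label="") -> "RegionSpec":
        return cls(kind="disc", center=tuple(center), diameter_px=float(diameter_px), label=label)

    @classmethod
    def arc(cls, center, radius_px, span_deg=355.0, gap_center_deg=0.0, width_px=5, label="") -> "RegionSpec":
        return cls(
            kind="arc", center=tuple(center), radius_px=float(radius_px),
            arc_span_deg=float(span_deg), arc_gap_center_deg=float(gap_center_deg),
            width_px=int(width_px), label=label,
        )

    @classmethod
    def line(cls, p0, p1, width_px=1, label="") -> "RegionSpec":
        return cls(kind="line", endpoints=(tuple(p0), tuple(p1)), width_px=int(width_px), label=label)

    @classmethod
    def polygon_offset(cls, vertices, offset_px, label="") -> "RegionSpec":
        return cls(kind="polygon_offset", vertices=[tuple(v) for v in vertices],
                   offset_px=float(offset_px), label=label)

    # -- geometry helpers --------------------------------------------------
    def line_length_px(self) -> float:
        if self.kind != "line":
            raise ValueError("line_length_px only defined for line regions")
        (r0, c0), (r1, c1) = self.endpoints
        return float(np.hypot(r1 - r0, c1 - c0))

    def arc_length_px(self) -> float:
        if self.kind != "arc":
            raise ValueError("arc_length_px only defined for arc regions")
        return 2.0 * np.pi * self.radius_px * self.arc_span_deg / 360.0

    # -- JSON --------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items() if v is not None}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSpec":
        d = dict(d)
        for key in ("center",):
            if key in d:
                d[key] = tuple(d[key])
        if "endpoints" in d:
            d["endpoints"] = tuple(tuple(p) for p in d["endpoints"])
        if "vertices" in d:
            d["vertices"] = [tuple(v) for v in d["vertices"]]
        return cls(**d)


def save_regions(regions: Sequence[RegionSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in regions], fh, indent=1)


def load_regions(path) -> list[RegionSpec]:
    with open(path) as fh:
        return [RegionSpec.from_dict(d) for d in json.load(fh)]


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder ``data`` with per-dimension axis labels ``axes`` to TZCYX."""
    axes = axes.upper()
    # Unlabelled page axes ('Q', 'I', 'S') on a single extra dimension are
    # taken as time, matching plain multi-page TIFF movies.
    unknown = [a for a in axes if a not in AXES]
    if len(unknown) == 1 and "T" not in axes:
        axes = axes.replace(unknown[0], "T")
        unknown = []
    if unknown:
        raise AmbiguousAxesError(f"cannot interpret TIFF axes {axes!r}: ambiguous axis {unknown[0]!r}")
    if len(set(axes)) != len(axes):
        raise AmbiguousAxesError(f"repeated axis in TIFF axes {axes!r}")
    out = data
    for ax in AXES:
        if ax not in axes:
            out = np.expand_dims(out, 0)
            axes = ax + axes
    order = [axes.index(ax) for ax in AXES]
    return np.transpose(out, order)


def read_stack(path, config: ImagingConfig | None = None) -> ImageStack:
    """Read a multi-page TIFF as an ImageStack with axes (t, z, c, y, x).

    Integer data are rescaled to the working 0..bit_scale float scale;
    float data are taken as already on the working scale. Calibration stored
    in the file (shaped/ImageJ metadata written by :func:`write_stack`)
    overrides ``config`` defaults, with a log line recording the override.
    """
    config = config or ImagingConfig()
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta = None
        if tif.shaped_metadata:
            meta = tif.shaped_metadata[0]
        elif tif.imagej_metadata:
            meta = tif.imagej_metadata
    arr = _normalize_axes(np.asarray(data), axes)
    if np.issubdtype(arr.dtype, np.integer):
        dtype_max = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(float) * (config.bit_scale / dtype_max)
    else:
        arr = arr.astype(float)
    channel_names = None
    if meta:
        overrides = {}
        for key in ("pixel_size_um", "frame_interval_s", "bit_scale"):
            if key in meta and not np.isclose(meta[key], getattr(config, key)):
                overrides[key] = float(meta[key])
        if overrides:
            logger.info("calibration from %s overrides config: %s", path.name, overrides)
            config = dataclasses.replace(config, **overrides)
        if "channel_names" in meta:
            channel_names = list(meta["channel_names"])
    config = dataclasses.replace(config, n_frames=arr.shape[0], image_shape=arr.shape[3:])
    return ImageStack(arr, config, channel_names)


def write_stack(stack: ImageStack, path) -> None:
    """Write an ImageStack as a float32 multi-page TIFF with calibration metadata."""
    meta = {
        "axes": AXES,
        "pixel_size_um": stack.config.pixel_size_um,
        "frame_interval_s": stack.config.frame_interval_s,
        "bit_scale": stack.config.bit_scale,
        "channel_names": list(stack.channel_names),
    }
    tifffile.imwrite(path, stack.data.astype(np.float32), metadata=meta)


# ---------------------------------------------------------------------------
# Region rasterization and sampling
# ---------------------------------------------------------------------------

def _pixel_centers(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return rr + 0.5, cc + 0.5


def mask_pixels(image_shape: tuple[int, int], region: RegionSpec) -> tuple[np.ndarray, bool]:
    """Boolean pixel mask of a disc or polygon-offset region.

    Returns ``(mask, out_of_frame)`` where ``out_of_frame`` flags a region
    that is partly or fully outside the image. A region entirely outside
    yields an empty mask with the flag set (and a log warning).
    """
    if region.kind == "disc":
        ry, rx = _pixel_centers(image_shape)
        cy, cx = region.center
        mask = (ry - cy) ** 2 + (rx - cx) ** 2 <= (region.diameter_px / 2.0) ** 2
        # out-of-frame check: does the disc extend beyond the image bounds?
        r = region.diameter_px / 2.0
        oob = cy - r < 0 or cx - r < 0 or cy + r > image_shape[0] or cx + r > image_shape[1]
    elif region.kind == "polygon_offset":
        import shapely

        poly = shapely.Polygon([(c, r) for r, c in region.vertices])  # shapely is (x, y)
        ry, rx = _pixel_centers(image_shape)
        pts_x = rx.ravel()
        pts_y = ry.ravel()
        inside = shapely.contains_xy(poly, pts_x, pts_y)
        dist = shapely.distance(shapely.points(np.column_stack([pts_x, pts_y])), poly.exterior)
        signed = np.where(inside, dist, -dist)
        mask = (np.abs(signed - region.offset_px) <= 0.5).reshape(image_shape)
        minx, miny, maxx, maxy = poly.bounds
        oob = minx < 0 or miny < 0 or maxx > image_shape[1] or maxy > image_shape[0]
    else:
        raise ValueError(f"mask_pixels supports disc and polygon_offset, not {region.kind!r}")
    if not mask.any():
        logger.warning("region %s lies entirely outside the image", region.label or region.kind)
        return mask, True
    return mask, bool(oob)


def _bilinear(image: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear interpolation at continuous (row, col) points.

    Points are in the continuous frame where pixel ``i`` is centered at
    ``i + 0.5``; out-of-frame points are clamped and flagged.
    """
    rr = np.asarray(rows, dtype=float) - 0.5
    cc = np.asarray(cols, dtype=float) - 0.5
    in_frame = (rows >= 0) & (cols >= 0) & (rows <= image.shape[0]) & (cols <= image.shape[1])
    vals = ndimage.map_coordinates(image, [rr, cc], order=1, mode="nearest")
    return vals, ~in_frame


def arc_sample_points(region: RegionSpec, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Continuous (rows, cols) of arc sample centers at arc-length spacing ``step``.

    Samples start adjacent to the excluded wedge and proceed in increasing
    angle; each sample sits at the center of its arc-length bin.
    """
    if region.kind != "arc":
        raise ValueError("arc_sample_points requires an arc region")
    if region.arc_span_deg <= 0 or 360.0 - region.arc_span_deg >= 360.0:
        raise ValueError("arc span must leave a wedge smaller than the full circle")
    n = int(np.floor(region.arc_length_px() / step))
    if n < 1:
        raise ValueError("arc too short for the requested step")
    gap = 360.0 - region.arc_span_deg
    start = region.arc_gap_center_deg + gap / 2.0
    dtheta_deg = np.degrees(step / region.radius_px)
    angles = np.radians(start + (np.arange(n) + 0.5) * dtheta_deg)
    cy, cx = region.center
    return cy + region.radius_px * np.sin(angles), cx + region.radius_px * np.cos(angles)


def sample_arc(image: np.ndarray, region: RegionSpec, step: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample a circular arc from a 2-D frame.

    Each profile value is the mean of bilinear interpolations at ``width_px``
    radial offsets centered on ``radius_px``. Returns ``(profile, points,
    out_of_frame)`` where ``points`` is the (n, 2) array of central sample
    coordinates and ``out_of_frame`` flags samples whose center lies outside
    the frame.
    """
    rows, cols = arc_sample_points(region, step)
    cy, cx = region.center
    ur = (rows - cy) / region.radius_px
    uc = (cols - cx) / region.radius_px
    w = region.width_px
    offsets = np.arange(w) - (w - 1) / 2.0
    acc = np.zeros_like(rows)
    oob = np.zeros(rows.shape, dtype=bool)
    for off in offsets:
        vals, bad = _bilinear(image, rows + off * ur, cols + off * uc)
        acc += vals
        if off == 0 or (w % 2 == 0 and off == 0.5):
            oob |= bad
    _, center_oob = _bilinear(image, rows, cols)
    return acc / w, np.column_stack([rows, cols]), center_oob


def sample_line(image: np.ndarray, region: RegionSpec, step: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample a line segment, averaging over ``width_px`` perpendicular offsets."""
    if region.kind != "line":
        raise ValueError("sample_line requires a line region")
    (r0, c0), (r1, c1) = region.endpoints
    length = region.line_length_px()
    n = int(np.floor(length / step))
    if n < 1:
        raise ValueError("line too short for the requested step")
    s = (np.arange(n) + 0.5) * step
    dr, dc = (r1 - r0) / length, (c1 - c0) / length
    rows = r0 + s * dr
    cols = c0 + s * dc
    # perpendicular unit vector
    pr, pc = -dc, dr
    w = region.width_px
    offsets = np.arange(w) - (w - 1) / 2.0
    acc = np.zeros_like(rows)
    for off in offsets:
        vals, _ = _bilinear(image, rows + off * pr, cols + off * pc)
        acc += vals
    _, oob = _bilinear(image, rows, cols)
    return acc / w, np.column_stack([rows, cols]), oob
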