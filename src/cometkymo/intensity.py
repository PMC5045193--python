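"""Region-based fluorescence quantification with focal-plane selection.

Centrosomal signal is the mean intensity in a 25-px-diameter disc centered
on the centrosome, evaluated on every z-plane; the plane with the highest
disc mean is reported (ties break toward the lowest plane index).
Centriolar signal uses a 5-px disc, cytoplasmic signal a same-sized disc at
a user-chosen point, and background a same-sized disc outside the embryo.
Fold changes compare background-subtracted group means against a control
group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ImageStack, RegionSpec, mask_pixels

logger = logging.getLogger(__name__)

COMPARTMENTS = ("centrosomal", "centriolar", "cytoplasmic", "background")


@dataclass
class IntensityMeasurement:
    label: str
    compartment: str
    mean_intensity: float
    chosen_plane: int
    region: RegionSpec
    channel: int | str = 0
    partial: bool = False  # disc partly outside the frame


@dataclass
class FoldChange:
    ratio: float
    numerator_mean: float
    denominator_mean: float
    n_num: int
    n_den: int
    dispersion: float  # SD of per-sample ratios to the control mean
    sample_ratios: np.ndarray | None = None


def _disc_means_by_plane(stack: ImageStack, region: RegionSpec, t: int,
                         channel: int | str) -> tuple[np.ndarray, bool]:
    mask, flag = mask_pixels(stack.shape_yx, region)
    if not mask.any():
        raise ValueError("region lies entirely outside the image")
    c = stack.channel_index(channel)
    means = stack.data[t, :, c][:, mask].mean(axis=1)
    return means, flag


def measure_region(stack: ImageStack, region: RegionSpec, channel: int | str = 0,
                   t: int = 0, compartment: str = "centrosomal",
                   label: str | None = None) -> IntensityMeasurement:
    """Disc mean on the brightest z-plane (lowest index on ties)."""
    if region.kind != "disc":
        raise ValueError("measure_region requires a disc region")
    means, flag = _disc_means_by_plane(stack, region, t, channel)
    plane = int(np.argmax(means))  # argmax takes the lowest index on ties
    return IntensityMeasurement(
        label=label if label is not None else region.label,
        compartment=compartment,
        mean_intensity=float(means[plane]),
        chosen_plane=plane,
        region=region,
        channel=channel,
        partial=flag,
    )


def measure_background(stack: ImageStack, region: RegionSpec, channel: int | str = 0,
                       t: int = 0, plane: int | None = None,
                       embryo_mask: np.ndarray | None = None,
                       label: str | None = None) -> IntensityMeasurement:
    """Same-size disc mean outside the embryo, on a stated plane.

    ``plane`` defaults to 0 for single-plane stacks and should be the paired
    foreground measurement's chosen plane otherwise. Overlap with a provided
    embryo mask is a recorded warning, not an error.
    """
    if region.kind != "disc":
        raise ValueError("measure_background requires a disc region")
    mask, flag = mask_pixels(stack.shape_yx, region)
    if not mask.any():
        raise ValueError("background region lies entirely outside the image")
    if embryo_mask is not None and (mask & embryo_mask).any():
        logger.warning("background region %s overlaps the embryo mask",
                       region.label or "background")
    plane = 0 if plane is None else int(plane)
    c = stack.channel_index(channel)
    val = float(stack.data[t, plane, c][mask].mean())
    return IntensityMeasurement(
        label=label if label is not None else region.label,
        compartment="background",
        mean_intensity=val,
        chosen_plane=plane,
        region=region,
        channel=channel,
        partial=flag,
    )


def paired_measurement(stack: ImageStack, signal_region: RegionSpec,
                       background_region: RegionSpec, channel: int | str = 0,
                       t: int = 0, compartment: str = "centrosomal",
                       ) -> tuple[IntensityMeasurement, IntensityMeasurement]:
    """Measure a signal disc and its background disc on the signal's plane."""
    sig = measure_region(stack, signal_region, channel, t, compartment)
    bg = measure_background(stack, background_region, channel, t, plane=sig.chosen_plane)
    return sig, bg


def fold_change(
    samples: list[tuple[IntensityMeasurement, IntensityMeasurement]],
    controls: list[tuple[IntensityMeasurement, IntensityMeasurement]],
) -> FoldChange:
    """Background-subtracted group-mean ratio of samples over controls.

    Each entry pairs a foreground with its background measurement. The
    dispersion is the SD of per-sample net values divided by the control
    mean, i.e. the spread of individual relative intensities.
    """
    if not samples or not controls:
        raise ValueError("need at least one sample and one control pair")
    net_s = np.array([s.mean_intensity - b.mean_intensity for s, b in samples])
    net_c = np.array([s.mean_intensity - b.mean_intensity for s, b in controls])
    den = float(net_c.mean())
    if den <= 0:
        raise ValueError("control group mean after background subtraction is not positive")
    ratios = net_s / den
    return FoldChange(
        ratio=float(net_s.mean() / den),
        numerator_mean=float(net_s.mean()),
        denominator_mean=den,
        n_num=len(net_s),
        n_den=len(net_c),
        dispersion=float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
        sample_ratios=ratios,
    )
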