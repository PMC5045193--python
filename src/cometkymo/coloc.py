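"""Thresholded pixel-overlap colocalization between two channels.

Within each circular cytoplasmic region (60-px diameter by convention),
pixels above a per-channel threshold form masks M1 and M2; the directional
overlap from channel i to j is 100 * |Mi ∩ Mj| / |Mi| (a Manders-style
fraction with a per-wavelength denominator). Both directions are reported
per region and pooled over the union of regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ImageStack, RegionSpec, mask_pixels


@dataclass
class ColocResult:
    per_region: list[dict] = field(default_factory=list)
    pooled_1_to_2: float = 0.0
    pooled_2_to_1: float = 0.0
    thresholds: tuple[float, float] = (0.0, 0.0)
    undefined_regions: int = 0  # regions with an empty source mask


def choose_threshold(image: np.ndarray, region: RegionSpec, method: str = "quantile",
                     value: float | None = None, q: float = 0.95) -> float:
    """Pick a channel threshold inside a region: ``fixed`` or ``quantile``."""
    if method == "fixed":
        if value is None:
            raise ValueError("fixed threshold requires a value")
        return float(value)
    if method != "quantile":
        raise ValueError(f"unknown threshold method {method!r}")
    mask, _ = mask_pixels(image.shape, region)
    if not mask.any():
        raise ValueError("empty region")
    return float(np.quantile(image[mask], q))


def _directional(m1: np.ndarray, m2: np.ndarray) -> tuple[float, bool]:
    n1 = int(m1.sum())
    if n1 == 0:
        return 0.0, True
    return 100.0 * int((m1 & m2).sum()) / n1, False


def coincidence_fraction(
    stack: ImageStack,
    regions: list[RegionSpec],
    thresholds: tuple[float, float] | None = None,
    t: int = 0,
    z: int = 0,
    quantile: float = 0.95,
) -> ColocResult:
    """Directional suprathreshold-overlap percentages for a 2-channel stack.

    When ``thresholds`` is None, each channel's threshold defaults to its
    ``quantile`` within the union of the regions (the acquisition's
    thresholds are a free choice; the default is recorded in the result).
    """
    if stack.n_channels != 2:
        raise ValueError(f"coincidence_fraction requires exactly 2 channels, got {stack.n_channels}")
    if not regions:
        raise ValueError("at least one region is required")
    ch1 = stack.data[t, z, 0]
    ch2 = stack.data[t, z, 1]
    masks = []
    union = np.zeros(stack.shape_yx, dtype=bool)
    for reg in regions:
        m, _ = mask_pixels(stack.shape_yx, reg)
        masks.append(m)
        union |= m
    if thresholds is None:
        thresholds = (float(np.quantile(ch1[union], quantile)),
                      float(np.quantile(ch2[union], quantile)))
    t1, t2 = thresholds
    result = ColocResult(thresholds=(t1, t2))
    for reg, m in zip(regions, masks):
        m1 = (ch1 > t1) & m
        m2 = (ch2 > t2) & m
        f12, und12 = _directional(m1, m2)
        f21, und21 = _directional(m2, m1)
        result.per_region.append({
            "label": reg.label, "overlap_1_to_2": f12, "overlap_2_to_1": f21,
            "n1": int(m1.sum()), "n2": int(m2.sum()),
            "undefined": bool(und12 or und21),
        })
        result.undefined_regions += int(und12 or und21)
    m1 = (ch1 > t1) & union
    m2 = (ch2 > t2) & union
    result.pooled_1_to_2, _ = _directional(m1, m2)
    result.pooled_2_to_1, _ = _directional(m2, m1)
    return result
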