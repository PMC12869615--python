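"""Spheroid uniformity screening.

Before embedding, each candidate spheroid is imaged once in brightfield and
accepted only if its segmented body is round and of the right size:
circularity > 0.55, roundness > 0.80, and both fitted-ellipse axes within
[350, 450] um (inclusive).  The segmentation pipeline is
8-bit conversion -> despeckle -> Gaussian blur (sigma 10 px) -> Otsu
threshold (dark objects) -> fill holes -> largest component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from spheroquant import imops
from spheroquant.image import Image2D, MaskImage
from spheroquant.imops import RegionProps

__all__ = ["ScreeningCriteria", "ScreeningResult", "screen_spheroid"]


@dataclass(frozen=True)
class ScreeningCriteria:
    """Pass thresholds: strict inequalities for the shape descriptors,
    inclusive bounds for the axis range (in micrometres)."""

    circularity_min: float = 0.55
    roundness_min: float = 0.80
    axis_min_um: float = 350.0
    axis_max_um: float = 450.0

    def __post_init__(self) -> None:
        if not 0 < self.circularity_min < 1:
            raise ValueError("circularity_min must be in (0, 1)")
        if not self.axis_min_um < self.axis_max_um:
            raise ValueError("axis_min_um must be < axis_max_um")


@dataclass(frozen=True)
class ScreeningResult:
    passed: bool
    props: RegionProps
    failures: tuple[str, ...]
    mask: MaskImage | None = None

    def __post_init__(self) -> None:
        if self.passed != (len(self.failures) == 0):
            raise ValueError("passed must equal 'no failures'")


def evaluate_criteria(
    props: RegionProps, criteria: ScreeningCriteria, pixel_size: float
) -> tuple[bool, tuple[str, ...]]:
    """Apply the pass thresholds to measured shape descriptors.

    Strict inequalities for circularity/roundness, inclusive bounds for both
    ellipse axes (converted to micrometres)."""
    failures: list[str] = []
    if not props.circularity > criteria.circularity_min:
        failures.append("circularity")
    if not props.roundness > criteria.roundness_min:
        failures.append("roundness")
    major_um = props.ellipse_major * pixel_size
    minor_um = props.ellipse_minor * pixel_size
    if not (
        criteria.axis_min_um <= minor_um <= criteria.axis_max_um
        and criteria.axis_min_um <= major_um <= criteria.axis_max_um
    ):
        failures.append("axis_range")
    return (not failures), tuple(failures)


def screen_spheroid(
    img: Image2D,
    criteria: ScreeningCriteria = ScreeningCriteria(),
    blur_sigma: float = 10.0,
) -> ScreeningResult:
    """Segment the spheroid body and evaluate the screening criteria.

    The largest dark component is taken as the spheroid (debris satellites
    are ignored); axes are converted to micrometres via the image pixel size.
    """
    u8 = imops.to_uint8(img)
    sm = imops.gaussian_blur(imops.despeckle(u8), blur_sigma)
    mask = imops.auto_threshold(sm, "otsu", dark_objects=True)
    mask = imops.fill_holes(mask)
    props = imops.connected_components(mask)
    if not props:
        raise ValueError("no spheroid detected")
    p = max(props, key=lambda q: q.area)
    passed, failures = evaluate_criteria(p, criteria, img.pixel_size)
    return ScreeningResult(passed=passed, props=p, failures=failures, mask=mask)
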