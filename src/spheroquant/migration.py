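"""Migrating-cell quantification from brightfield time-course projections.

The spheroid body and the migrating cells are segmented with cell-line
specific operator chains (profiles), cells overlapping the spheroid (or an
optional exclusion mask standing in for manual artifact removal) are
dropped, and each remaining cell's migration distance is the Euclidean
distance from its center of mass to the nearest spheroid-boundary pixel,
assuming a linear migration path.

Profiles
--------
``mda_mb_231``
    spheroid: 8-bit -> Gaussian blur (sigma 10) -> Max Entropy (dark);
    cells: 8-bit -> median-filter (disk r=20) background residual -> CLAHE
    (127/256/10) -> despeckle -> Max Entropy.
``m4``
    spheroid: 8-bit -> Gaussian blur (sigma 10) -> Minimum (dark);
    cells: 8-bit -> rolling-ball (r=20) background residual -> despeckle x2
    -> Triangle.

Brightfield objects are darker than background, so the background residual
is computed as (background estimate - image), clipped at 0, which renders
cells bright before contrast enhancement and thresholding; the polarity is a
profile flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure
from scipy import ndimage as ndi

from spheroquant import imops
from spheroquant.image import Image2D, MaskImage
from spheroquant.imops import RegionProps

__all__ = [
    "SegmentationProfile",
    "PROFILES",
    "BoundaryContour",
    "CellRecord",
    "MigrationSummary",
    "segment_spheroid",
    "segment_cells",
    "nearest_boundary_distance",
    "summarize_timecourse",
    "segment_nuclei_expand",
]


@dataclass(frozen=True)
class SegmentationProfile:
    """Cell-line specific operator chain parameters."""

    name: str
    spheroid_threshold: str  # imops threshold method for the body
    cell_threshold: str  # imops threshold method for the cells
    cell_background: str = "median"  # {median, rolling_ball}
    background_radius: int = 20
    use_clahe: bool = True
    n_despeckle: int = 1
    min_cell_area_px: int = 40
    dark_objects: bool = True  # brightfield: objects darker than background
    blur_sigma: float = 10.0

    def __post_init__(self) -> None:
        for m in (self.spheroid_threshold, self.cell_threshold):
            if m not in imops.THRESHOLD_METHODS:
                raise ValueError(f"unknown threshold method {m!r}")
        if self.min_cell_area_px < 0:
            raise ValueError("min_cell_area_px must be >= 0")


PROFILES: dict[str, SegmentationProfile] = {
    "mda_mb_231": SegmentationProfile(
        name="mda_mb_231",
        spheroid_threshold="max_entropy",
        cell_threshold="max_entropy",
        cell_background="median",
        use_clahe=True,
        n_despeckle=1,
    ),
    "m4": SegmentationProfile(
        name="m4",
        spheroid_threshold="minimum",
        cell_threshold="triangle",
        cell_background="rolling_ball",
        use_clahe=False,
        n_despeckle=2,
    ),
}


@dataclass(frozen=True)
class BoundaryContour:
    """Ordered (x, y) pixel coordinates of the spheroid mask boundary.

    Boundary pixels are foreground pixels with at least one 4-connected
    background neighbor, ordered by border tracing (``find_contours``);
    distances are measured to pixel centers.
    """

    points: np.ndarray  # (N, 2) as (x, y)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
            raise ValueError("contour needs >= 8 (x, y) points")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class CellRecord:
    props: RegionProps
    migration_distance_um: float
    timepoint_h: float

    def __post_init__(self) -> None:
        if self.migration_distance_um < 0:
            raise ValueError("migration distance must be >= 0")


@dataclass(frozen=True)
class MigrationSummary:
    """Per-spheroid per-timepoint medians; medians are None when no cells
    migrated (undefined, never reported as zero)."""

    spheroid_id: str
    timepoint_h: float
    n_cells: int
    median_distance_um: float | None
    median_circularity: float | None


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with >= 1 background 4-neighbor, as (x, y)."""
    eroded = ndi.binary_erosion(
        mask, structure=ndi.generate_binary_structure(2, 1), border_value=0
    )
    border = mask & ~eroded
    ys, xs = np.nonzero(border)
    return np.column_stack([xs, ys]).astype(np.float64)


def _trace_order(border_xy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Order border pixels by walking the traced sub-pixel contour."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return border_xy
    longest = max(contours, key=len)  # (row, col) sub-pixel
    tree = cKDTree(border_xy[:, ::-1])  # query in (y, x)
    _, idx = tree.query(longest)
    order: list[int] = []
    seen: set[int] = set()
    for i in idx:
        if i not in seen:
            seen.add(i)
            order.append(i)
    remaining = [i for i in range(len(border_xy)) if i not in seen]
    return border_xy[order + remaining]


def segment_spheroid(
    img: Image2D, profile: SegmentationProfile
) -> tuple[MaskImage, BoundaryContour]:
    """Spheroid-body mask and its ordered boundary contour."""
    u8 = imops.to_uint8(img)
    sm = imops.gaussian_blur(u8, profile.blur_sigma)
    mask = imops.auto_threshold(
        sm, profile.spheroid_threshold, dark_objects=profile.dark_objects
    )
    mask = imops.fill_holes(mask)
    labels = imops.label_components(mask)
    if labels.max() == 0:
        raise ValueError("empty spheroid mask")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    body = labels == np.argmax(sizes)
    body_mask = MaskImage(
        body,
        provenance=f"spheroid:{profile.name}",
        pixel_size=img.pixel_size,
    )
    pts = _boundary_pixels(body)
    return body_mask, BoundaryContour(_trace_order(pts, body))


def _cell_residual(img: Image2D, profile: SegmentationProfile) -> Image2D:
    """Background residual image with cells bright, per profile polarity."""
    u8 = imops.to_uint8(img)
    if profile.cell_background == "median":
        bg = imops.median_filter(u8, profile.background_radius)
    elif profile.cell_background == "rolling_ball":
        # rolling ball runs under the signal; for dark objects estimate the
        # background of the inverted image
        work = u8.with_pixels(255 - np.asarray(u8.pixels)) if profile.dark_objects else u8
        sub = imops.rolling_ball_subtract(work, profile.background_radius)
        res = np.clip(np.rint(sub.pixels), 0, 255).astype(np.uint8)
        return img.with_pixels(res)
    else:
        raise ValueError(f"unknown background mode {profile.cell_background!r}")
    a = np.asarray(u8.pixels, dtype=np.int16)
    b = np.asarray(bg.pixels, dtype=np.int16)
    res = (b - a) if profile.dark_objects else (a - b)
    return img.with_pixels(np.clip(res, 0, 255).astype(np.uint8))


def segment_cells(
    img: Image2D,
    spheroid_mask: MaskImage,
    profile: SegmentationProfile,
    exclusion_mask: MaskImage | None = None,
) -> list[RegionProps]:
    """Migrating-cell components outside the spheroid.

    Any component overlapping the spheroid mask (or the optional exclusion
    mask, the reproducible stand-in for manual artifact removal) is removed;
    components must have area strictly greater than the profile's
    ``min_cell_area_px``.
    """
    res = _cell_residual(img, profile)
    if profile.use_clahe:
        res = imops.clahe(res)
    for _ in range(profile.n_despeckle):
        res = imops.despeckle(res)
    cell_mask = imops.auto_threshold(res, profile.cell_threshold, dark_objects=False)
    props, labels = imops.connected_components(
        cell_mask, min_area_px=0, intensity=img, return_labels=True
    )
    sph = spheroid_mask.pixels
    excl = exclusion_mask.pixels if exclusion_mask is not None else None
    keep: list[RegionProps] = []
    for p in props:
        comp = labels == p.label
        if (comp & sph).any():
            continue
        if excl is not None and (comp & excl).any():
            continue
        if p.area > profile.min_cell_area_px:
            keep.append(p)
    return keep


def nearest_boundary_distance(
    cell_center: tuple[float, float],
    contour: BoundaryContour,
    pixel_size: float = 1.0,
) -> float:
    """Euclidean distance (um) from a cell center to the nearest contour
    point.  Uses a k-d tree; equals an exhaustive scan exactly."""
    tree = cKDTree(contour.points)
    d, _ = tree.query(np.asarray(cell_center, dtype=np.float64))
    return float(d) * pixel_size


def summarize_timecourse(
    frames: Sequence[tuple[float, Image2D]],
    profile: SegmentationProfile,
    spheroid_id: str = "spheroid",
    exclusion_mask: MaskImage | None = None,
) -> tuple[list[MigrationSummary], list[CellRecord]]:
    """Segment every frame and summarize counts/medians per timepoint."""
    timepoints = [t for t, _ in frames]
    if sorted(timepoints) != list(timepoints):
        raise ValueError("timepoints must be sorted")
    summaries: list[MigrationSummary] = []
    records: list[CellRecord] = []
    for t, img in frames:
        body_mask, contour = segment_spheroid(img, profile)
        cells = segment_cells(img, body_mask, profile, exclusion_mask)
        dists = [
            nearest_boundary_distance(c.center_of_mass, contour, img.pixel_size)
            for c in cells
        ]
        for c, d in zip(cells, dists):
            records.append(CellRecord(props=c, migration_distance_um=d, timepoint_h=t))
        if cells:
            summaries.append(
                MigrationSummary(
                    spheroid_id=spheroid_id,
                    timepoint_h=t,
                    n_cells=len(cells),
                    median_distance_um=float(np.median(dists)),
                    median_circularity=float(
                        np.median([c.circularity for c in cells])
                    ),
                )
            )
        else:
            summaries.append(
                MigrationSummary(
                    spheroid_id=spheroid_id,
                    timepoint_h=t,
                    n_cells=0,
                    median_distance_um=None,
                    median_circularity=None,
                )
            )
    return summaries, records


# ---------------------------------------------------------------------------
# 2D nuclei segmentation + constrained expansion (integrin intensity)
# ---------------------------------------------------------------------------


def segment_nuclei_expand(
    dapi: Image2D,
    cell_channel: Image2D,
    nuc_threshold: float = 5000.0,
    size_range_um: tuple[float, float] = (5.0, 35.0),
    max_expansion_um: float = 50.0,
    cell_threshold: float | None = None,
) -> list[tuple[RegionProps, float]]:
    """Fixed-threshold nuclei segmentation with constrained cell expansion.

    Nuclei are DAPI pixels >= ``nuc_threshold`` (holes filled), kept when
    their equivalent diameter lies within ``size_range_um``.  Each nucleus is
    grown into the cell-channel mask (``cell_threshold``; Otsu when None) by
    nearest-nucleus assignment limited to ``max_expansion_um`` of radial
    growth, so expanded regions never overlap.  Holes are filled in the cell
    mask as well.  Returns (nucleus RegionProps, median cell-channel
    intensity of the expanded region) per nucleus.
    """
    if dapi.shape != cell_channel.shape:
        raise ValueError("channels must be registered (same shape)")
    um = dapi.pixel_size
    nuc = np.asarray(dapi.pixels, dtype=np.float64) >= nuc_threshold
    if not nuc.any():
        return []
    nuc = ndi.binary_fill_holes(nuc)
    labels = measure.label(nuc, connectivity=2)
    regions = measure.regionprops(labels)
    lo, hi = size_range_um
    kept = [
        r
        for r in regions
        if lo <= 2.0 * np.sqrt(r.area / np.pi) * um <= hi
    ]
    if not kept:
        return []
    nuc_kept = np.isin(labels, [r.label for r in kept])

    cc = np.asarray(cell_channel.pixels, dtype=np.float64)
    if cell_threshold is None:
        cimg = imops.to_uint8(cell_channel)
        cmask = imops.auto_threshold(cimg, "otsu", dark_objects=False).pixels
    else:
        cmask = cc > cell_threshold
    cmask = ndi.binary_fill_holes(cmask | nuc_kept)

    # nearest-nucleus assignment constrained to the max expansion radius
    dist, (iy, ix) = ndi.distance_transform_edt(~nuc_kept, return_indices=True)
    assigned = labels[iy, ix]
    grow = cmask & (dist * um <= max_expansion_um) & np.isin(assigned, [r.label for r in kept])

    out: list[tuple[RegionProps, float]] = []
    for r in kept:
        region = grow & (assigned == r.label)
        region |= labels == r.label
        med = float(np.median(cc[region]))
        out.append((imops._props_from_region(r, None), med))
    return out
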