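"""Synthetic scenes with known ground truth for the three imaging modalities.

Three generators cover the pipeline's acceptance surface:

* brightfield-like spheroid scenes — a dark roughly circular spheroid body on
  a bright background, with small dark elliptical "migrating cells" placed at
  known distances and elongations;
* SHG-like fiber fields — anti-aliased line segments whose orientation
  distribution (mean angle, von Mises concentration kappa) is known exactly;
* paired forward/backward stacks with a known per-pixel true F/B ratio.

Every generator is deterministic given its truth object (which carries the
seed) and returns/echoes that truth unchanged, so downstream recovery can be
scored against it.  Orientation is axial (period pi): angles are drawn from
von Mises(2*mean_angle, kappa)/2 folded to [0, pi); kappa = 0 means uniform.
Angles are measured from the +x axis with y pointing down, matching the
ellipse-fit convention of the shape descriptors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line_aa

from spheroquant.image import Image2D, ImageStack, write_tiff

__all__ = [
    "CellTruth",
    "SpheroidSceneTruth",
    "FiberFieldTruth",
    "FBStackTruth",
    "make_spheroid_scene",
    "make_fiber_field",
    "sample_fiber_orientations",
    "make_fb_pair",
    "random_scene_truth",
    "write_scene",
]

# intensity levels of the brightfield-like render (arbitrary units on a
# 16-bit-like scale; only contrast matters downstream)
BACKGROUND_LEVEL = 20000.0
SPHEROID_LEVEL = 6000.0
CELL_LEVEL = 9000.0


@dataclass(frozen=True)
class CellTruth:
    """One synthetic migrating cell: an ellipse of given area and elongation."""

    center: tuple[float, float]  # (x, y) px
    area: float  # px^2
    aspect_ratio: float = 1.0  # major/minor, >= 1
    orientation: float = 0.0  # rad from +x axis, y down

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError("cell area must be > 0")
        if not self.aspect_ratio >= 1:
            raise ValueError("aspect_ratio must be >= 1")

    @property
    def semi_axes(self) -> tuple[float, float]:
        """(major, minor) semi-axes of the ellipse with this area/aspect."""
        minor = np.sqrt(self.area / (np.pi * self.aspect_ratio))
        return (self.aspect_ratio * minor, minor)


@dataclass(frozen=True)
class SpheroidSceneTruth:
    """Ground truth for one brightfield-like spheroid scene.

    ``body_texture_amp``/``bg_texture_amp`` control the multiplicative
    low-frequency mottle of the spheroid interior and the background
    (brightfield spheroid bodies show strong internal contrast from packed
    cells; backgrounds show gentle illumination gradients).  Texture is
    deterministic in the seed and never inverts the dark-object polarity.
    """

    spheroid_center: tuple[float, float]  # (x, y) px
    spheroid_radius: float  # px
    cells: tuple[CellTruth, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    body_texture_amp: float = 0.4  # fraction of body level
    body_texture_scale: float = 15.0  # correlation length, px
    bg_texture_amp: float = 0.15  # fraction of background level
    bg_texture_scale: float = 60.0  # px

    def __post_init__(self) -> None:
        if not self.spheroid_radius > 0:
            raise ValueError("spheroid_radius must be > 0")
        cx, cy = self.spheroid_center
        for c in self.cells:
            d = float(np.hypot(c.center[0] - cx, c.center[1] - cy))
            if d - c.semi_axes[0] <= self.spheroid_radius:
                raise ValueError(
                    f"cell at {c.center} overlaps the spheroid disk "
                    f"(distance {d:.1f}, radius {self.spheroid_radius})"
                )

    def cell_boundary_distances(self) -> np.ndarray:
        """True center-to-spheroid-boundary distance per cell, in px."""
        cx, cy = self.spheroid_center
        d = np.array(
            [np.hypot(c.center[0] - cx, c.center[1] - cy) for c in self.cells]
        )
        return d - self.spheroid_radius


def make_spheroid_scene(
    truth: SpheroidSceneTruth,
    shape: tuple[int, int],
    pixel_size: float = 1.0,
) -> tuple[Image2D, SpheroidSceneTruth]:
    """Render a brightfield-like scene (dark spheroid + dark cells on a
    bright background) with additive Gaussian noise of ``truth.noise_sd``.

    The truth object is echoed unchanged.
    """
    h, w = shape
    cx, cy = truth.spheroid_center
    r = truth.spheroid_radius
    if cx - r < 0 or cy - r < 0 or cx + r > w or cy + r > h:
        raise ValueError("shape too small: spheroid disk exceeds the frame")
    for c in truth.cells:
        a = c.semi_axes[0]
        if not (a <= c.center[0] <= w - a and a <= c.center[1] <= h - a):
            raise ValueError(f"shape too small: cell at {c.center} exceeds the frame")

    img = np.full(shape, BACKGROUND_LEVEL, dtype=np.float64)
    rr, cc = draw_disk((cy, cx), r, shape=shape)
    body = np.zeros(shape, dtype=bool)
    body[rr, cc] = True
    img[body] = SPHEROID_LEVEL
    for c in truth.cells:
        major, minor = c.semi_axes
        # draw_ellipse rotation is CCW in (row, col); our orientation is from
        # +x with y down, so pass the negated angle
        rr, cc = draw_ellipse(
            c.center[1], c.center[0], minor, major, shape=shape,
            rotation=-c.orientation,
        )
        img[rr, cc] = CELL_LEVEL
    if truth.body_texture_amp > 0 or truth.bg_texture_amp > 0:
        from scipy import ndimage as ndi

        tex_rng = np.random.default_rng([truth.seed, 1])
        t_body = ndi.gaussian_filter(
            tex_rng.normal(0, 1, shape), truth.body_texture_scale
        )
        t_bg = ndi.gaussian_filter(
            tex_rng.normal(0, 1, shape), truth.bg_texture_scale
        )
        t_body /= max(np.abs(t_body).max(), 1e-12)
        t_bg /= max(np.abs(t_bg).max(), 1e-12)
        mult = np.where(
            body,
            1.0 + truth.body_texture_amp * t_body,
            1.0 + truth.bg_texture_amp * t_bg,
        )
        img = img * mult
    if truth.noise_sd > 0:
        rng = np.random.default_rng([truth.seed, 2])
        img = img + rng.normal(0.0, truth.noise_sd, size=img.shape)
    return Image2D(np.clip(img, 0, None), pixel_size), truth


def random_scene_truth(
    seed: int,
    n_cells: int,
    shape: tuple[int, int] = (512, 512),
    spheroid_radius: float = 80.0,
    distance_range: tuple[float, float] = (20.0, 160.0),
    area_range: tuple[float, float] = (60.0, 200.0),
    aspect_range: tuple[float, float] = (1.0, 2.0),
    noise_sd: float = 0.0,
    min_separation: float = 5.0,
) -> SpheroidSceneTruth:
    """Draw a valid random scene truth: cells at uniform random boundary
    distances and polar angles, non-overlapping and inside the frame."""
    rng = np.random.default_rng(seed)
    h, w = shape
    center = (w / 2.0, h / 2.0)
    cells: list[CellTruth] = []
    attempts = 0
    while len(cells) < n_cells:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place all cells; loosen the geometry")
        dist = rng.uniform(*distance_range)
        theta = rng.uniform(0, 2 * np.pi)
        area = rng.uniform(*area_range)
        aspect = rng.uniform(*aspect_range)
        c = CellTruth(
            center=(
                center[0] + (spheroid_radius + dist) * np.cos(theta),
                center[1] + (spheroid_radius + dist) * np.sin(theta),
            ),
            area=area,
            aspect_ratio=aspect,
            orientation=rng.uniform(0, np.pi),
        )
        a = c.semi_axes[0]
        if not (a + 2 <= c.center[0] <= w - a - 2 and a + 2 <= c.center[1] <= h - a - 2):
            continue
        ok = True
        for prev in cells:
            gap = np.hypot(
                prev.center[0] - c.center[0], prev.center[1] - c.center[1]
            ) - prev.semi_axes[0] - a
            if gap < min_separation:
                ok = False
                break
        if ok:
            cells.append(c)
    return SpheroidSceneTruth(
        spheroid_center=center,
        spheroid_radius=spheroid_radius,
        cells=tuple(cells),
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fiber fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FiberFieldTruth:
    """Ground truth for a fibrous SHG-like texture."""

    mean_angle: float = 0.0  # rad in [0, pi)
    kappa: float = 0.0  # von Mises concentration; 0 = uniform
    n_fibers: int = 200
    fiber_width: float = 3.0  # px
    fiber_length: float = 40.0  # px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if not self.fiber_width > 0:
            raise ValueError("fiber_width must be > 0")


def sample_fiber_orientations(truth: FiberFieldTruth) -> np.ndarray:
    """The axial fiber orientations drawn for this truth, in [0, pi).

    kappa = 0 draws uniform on [0, pi); kappa > 0 draws
    von Mises(2*mean_angle, kappa) / 2 folded to [0, pi).  Deterministic in
    the truth seed; ``make_fiber_field`` renders exactly these angles.
    """
    rng = np.random.default_rng(truth.seed)
    if truth.kappa == 0:
        return rng.uniform(0, np.pi, size=truth.n_fibers)
    if np.isinf(truth.kappa):
        return np.full(truth.n_fibers, truth.mean_angle % np.pi)
    draws = rng.vonmises(2.0 * truth.mean_angle, truth.kappa, size=truth.n_fibers)
    return (draws / 2.0) % np.pi


def make_fiber_field(
    truth: FiberFieldTruth, shape: tuple[int, int], pixel_size: float = 1.0
) -> Image2D:
    """Render anti-aliased line segments with the truth's orientations.

    Segments of length ``fiber_length`` and width ``fiber_width`` are placed
    at uniform random positions; intensity is combined by per-pixel maximum
    (crossings do not double).  Bit-identical for identical (truth, seed).
    """
    h, w = shape
    rng = np.random.default_rng(truth.seed + 1)  # positions; angles use seed
    angles = sample_fiber_orientations(truth)
    canvas = np.zeros(shape, dtype=np.float64)
    half = truth.fiber_length / 2.0
    n_off = max(1, int(np.ceil(truth.fiber_width)))
    offsets = np.linspace(
        -(truth.fiber_width - 1) / 2.0, (truth.fiber_width - 1) / 2.0, n_off
    )
    for ang in angles:
        x0 = rng.uniform(0, w)
        y0 = rng.uniform(0, h)
        dx, dy = np.cos(ang), np.sin(ang)  # y down
        px, py = -dy, dx  # perpendicular
        for off in offsets:
            xa = x0 - half * dx + off * px
            ya = y0 - half * dy + off * py
            xb = x0 + half * dx + off * px
            yb = y0 + half * dy + off * py
            rr, cc, val = line_aa(
                int(round(ya)), int(round(xa)), int(round(yb)), int(round(xb))
            )
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            rr, cc, val = rr[keep], cc[keep], val[keep]
            np.maximum.at(canvas, (rr, cc), val * 200.0)
    return Image2D(canvas, pixel_size)


# ---------------------------------------------------------------------------
# forward/backward SHG pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FBStackTruth:
    """Ground truth for a paired forward/backward stack.

    ``true_ratio`` may be a scalar or a per-pixel map; forward equals
    ``true_ratio x backward`` before noise, pixelwise.
    """

    true_ratio: float | np.ndarray = 2.0
    backward_base: float = 1.0
    noise_sd: float = 0.0
    n_slices: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.true_ratio) <= 0):
            raise ValueError("true_ratio must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


def make_fb_pair(
    truth: FBStackTruth, base_image: Image2D
) -> tuple[ImageStack, ImageStack]:
    """Paired (forward, backward) stacks from a nonnegative base image.

    backward slice = backward_base * base + noise;
    forward slice  = true_ratio * (backward before noise) + noise;
    both clipped at 0, independent noise per slice and channel.
    """
    base = base_image.astype_float()
    if base.min() < 0:
        raise ValueError("base_image must be nonnegative")
    rng = np.random.default_rng(truth.seed)
    ratio = np.asarray(truth.true_ratio, dtype=np.float64)
    fwd, bwd = [], []
    for _ in range(truth.n_slices):
        clean_b = truth.backward_base * base
        clean_f = ratio * clean_b
        if truth.noise_sd > 0:
            b = clean_b + rng.normal(0, truth.noise_sd, base.shape)
            f = clean_f + rng.normal(0, truth.noise_sd, base.shape)
        else:
            b, f = clean_b, clean_f
        bwd.append(np.clip(b, 0, None))
        fwd.append(np.clip(f, 0, None))
    ps = base_image.pixel_size
    return (
        ImageStack.from_array(np.stack(fwd), pixel_size=ps),
        ImageStack.from_array(np.stack(bwd), pixel_size=ps),
    )


def write_scene(
    path_prefix: str | Path, img: Image2D | ImageStack, truth
) -> tuple[Path, Path]:
    """Write a 16-bit TIFF plus a JSON truth sidecar; returns both paths."""
    prefix = Path(path_prefix)
    tif_path = prefix.with_suffix(".tif")
    json_path = prefix.with_suffix(".json")
    if isinstance(img, ImageStack):
        arr = img.as_array()
    else:
        arr = np.asarray(img.pixels)
    arr16 = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    tif_path.parent.mkdir(parents=True, exist_ok=True)
    import tifffile

    tifffile.imwrite(str(tif_path), arr16)
    d = asdict(truth)
    d["truth_type"] = type(truth).__name__
    json_path.write_text(json.dumps(d, default=lambda o: np.asarray(o).tolist()))
    return tif_path, json_path
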