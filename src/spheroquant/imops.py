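"""Named image operators composed by the analysis macros.

These are the primitives of the brightfield / SHG pipelines: bit-depth
conversion, Gaussian blur, despeckle, disk-median filter, CLAHE, rolling-ball
background subtraction, histogram auto-thresholds (Otsu, Li, Max Entropy,
Minimum, Triangle), hole filling, and connected components with shape
descriptors.

Threshold algorithms are implemented here as explicit histogram-criterion
optimizers so their defining criteria can be checked against exhaustive
search; standard filters dispatch to scipy/scikit-image.

Conventions
-----------
* Foreground polarity is explicit: ``dark_objects=True`` selects pixels at or
  below the threshold (brightfield spheroids/cells are darker than
  background), ``False`` selects pixels strictly above it.
* Circularity = 4*pi*area/perimeter**2 with a Crofton perimeter estimator
  (the naive pixel-edge count overestimates the perimeter of smooth shapes).
* Roundness = 4*area/(pi*major_axis**2).
* Foreground components are 8-connected; holes are 4-connected background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import rank as skrank
from skimage.restoration import rolling_ball as _sk_rolling_ball

from spheroquant.image import Image2D, ImageStack, MaskImage

__all__ = [
    "RegionProps",
    "to_uint8",
    "gaussian_blur",
    "despeckle",
    "median_filter",
    "clahe",
    "rolling_ball_subtract",
    "auto_threshold",
    "threshold_index",
    "fill_holes",
    "connected_components",
    "label_components",
    "THRESHOLD_METHODS",
]


# ---------------------------------------------------------------------------
# elementary filters
# ---------------------------------------------------------------------------


def to_uint8(img: Image2D) -> Image2D:
    """Linear rescale of [min, max] to [0, 255], rounded to uint8.

    A constant image maps to all zeros (degenerate range).
    """
    px = img.astype_float()
    if not np.all(np.isfinite(px)):
        raise ValueError("image contains non-finite values")
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros_like(px, dtype=np.uint8)
    else:
        out = np.rint((px - lo) * (255.0 / (hi - lo))).astype(np.uint8)
    return img.with_pixels(out)


def gaussian_blur(img: Image2D, radius_px: float) -> Image2D:
    """Isotropic Gaussian blur with sigma = ``radius_px`` (reflective borders).

    The macro parameter "10-pixel gaussian blur" is interpreted as sigma in
    pixels, the convention of the common GUI implementation; it is exposed so
    callers can substitute their own value.
    """
    if not radius_px > 0:
        raise ValueError(f"radius_px must be > 0, got {radius_px}")
    out = ndi.gaussian_filter(img.astype_float(), sigma=radius_px, mode="reflect")
    return img.with_pixels(out.astype(np.float64))


def despeckle(img: Image2D) -> Image2D:
    """One pass of a 3x3 median filter (the standard 'Despeckle' command)."""
    out = ndi.median_filter(np.asarray(img.pixels), size=3, mode="reflect")
    return img.with_pixels(out)


def median_filter(img: Image2D, radius_px: int) -> Image2D:
    """Median over a circular (disk) neighborhood of the given radius.

    uint8 input uses the sliding-histogram rank filter (fast at large radii);
    other dtypes fall back to the generic selection filter.
    """
    if radius_px < 1:
        raise ValueError(f"radius_px must be >= 1, got {radius_px}")
    footprint = morphology.disk(radius_px)
    px = np.asarray(img.pixels)
    if px.dtype == np.uint8:
        out = skrank.median(px, footprint=footprint)
    else:
        out = ndi.median_filter(px, footprint=footprint, mode="reflect")
    return img.with_pixels(out)


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------


def _clahe_tile_mapping(
    tile: np.ndarray, bins: int, max_slope: float
) -> tuple[np.ndarray, np.ndarray]:
    """Clipped-histogram equalization mapping for one tile.

    Returns (lut, clipped_histogram). The clip limit is
    ``max_slope * n_pixels / bins`` (slope of the equalization transfer
    function in units of the identity slope); clipped excess is redistributed
    uniformly, iterating until no bin exceeds the limit.
    """
    n = tile.size
    hist = np.bincount(
        ((tile.astype(np.int64) * bins) // 256).ravel(), minlength=bins
    ).astype(np.float64)
    if np.isfinite(max_slope):
        clip = max_slope * n / bins
        # redistribute excess until stable (uniform redistribution can push
        # bins back over the limit; cap the loop defensively)
        for _ in range(100):
            excess = np.clip(hist - clip, 0, None).sum()
            if excess <= 1e-9:
                break
            hist = np.minimum(hist, clip)
            hist += excess / bins
    cdf = np.cumsum(hist)
    cdf = cdf / cdf[-1]
    lut = np.clip(np.rint(cdf * 255.0), 0, 255)
    return lut, hist


def clahe(
    img: Image2D,
    blocksize: int = 127,
    bins: int = 256,
    max_slope: float = 10.0,
    return_internals: bool = False,
):
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    The image is divided into a grid of tiles roughly ``blocksize`` pixels on
    a side; each tile's histogram (``bins`` bins) is clipped at
    ``max_slope * tile_pixels / bins`` with uniform redistribution, turned
    into an equalization lookup table, and pixel values are bilinearly
    interpolated between the four surrounding tile mappings.

    ``max_slope=inf`` disables clipping (plain adaptive equalization). If the
    block size exceeds the image, global equalization is used with a warning.

    When ``return_internals`` is true, returns
    ``(Image2D, clipped_histograms, clip_limit_per_tile)`` where
    ``clipped_histograms`` has shape (ny, nx, bins).
    """
    px = np.asarray(img.pixels)
    if px.dtype != np.uint8:
        raise ValueError("clahe requires an 8-bit input (use to_uint8 first)")
    h, w = px.shape
    if blocksize >= min(h, w):
        warnings.warn(
            "CLAHE blocksize exceeds image extent; falling back to global "
            "histogram equalization",
            stacklevel=2,
        )
        lut, hist = _clahe_tile_mapping(px.ravel(), bins, max_slope)
        out = img.with_pixels(lut[(px.astype(np.int64) * bins) // 256].astype(np.uint8))
        if return_internals:
            clip = max_slope * px.size / bins
            return out, hist[None, None, :], clip
        return out

    ny = max(1, int(round(h / blocksize)))
    nx = max(1, int(round(w / blocksize)))
    y_edges = np.linspace(0, h, ny + 1).astype(int)
    x_edges = np.linspace(0, w, nx + 1).astype(int)
    y_centers = (y_edges[:-1] + y_edges[1:]) / 2.0
    x_centers = (x_edges[:-1] + x_edges[1:]) / 2.0

    luts = np.empty((ny, nx, bins))
    hists = np.empty((ny, nx, bins))
    for iy in range(ny):
        for ix in range(nx):
            tile = px[y_edges[iy] : y_edges[iy + 1], x_edges[ix] : x_edges[ix + 1]]
            luts[iy, ix], hists[iy, ix] = _clahe_tile_mapping(tile, bins, max_slope)

    # bilinear interpolation between tile LUTs
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    fy = np.interp(yy, y_centers, np.arange(ny, dtype=np.float64))
    fx = np.interp(xx, x_centers, np.arange(nx, dtype=np.float64))
    iy0 = np.clip(np.floor(fy).astype(int), 0, ny - 1)
    ix0 = np.clip(np.floor(fx).astype(int), 0, nx - 1)
    iy1 = np.minimum(iy0 + 1, ny - 1)
    ix1 = np.minimum(ix0 + 1, nx - 1)
    wy = fy - iy0
    wx = fx - ix0

    bin_idx = (px.astype(np.int64) * bins) // 256
    v00 = luts[iy0, ix0, bin_idx]
    v01 = luts[iy0, ix1, bin_idx]
    v10 = luts[iy1, ix0, bin_idx]
    v11 = luts[iy1, ix1, bin_idx]
    out_px = (
        v00 * (1 - wy) * (1 - wx)
        + v01 * (1 - wy) * wx
        + v10 * wy * (1 - wx)
        + v11 * wy * wx
    )
    out = img.with_pixels(np.clip(np.rint(out_px), 0, 255).astype(np.uint8))
    if return_internals:
        tile_sizes = np.outer(np.diff(y_edges), np.diff(x_edges)).astype(np.float64)
        clip = max_slope * tile_sizes / bins
        return out, hists, clip
    return out


def rolling_ball_subtract(
    img: Image2D, radius_px: int, presmooth: bool = True
) -> Image2D:
    """Subtract a rolling-ball background estimate; result clipped at 0.

    With ``presmooth`` (default, matching the common GUI implementation) the
    ball is fitted to a 3x3-mean-smoothed copy so it does not ride into
    noise dips; the subtraction is from the original pixels.
    """
    if radius_px < 1:
        raise ValueError(f"radius_px must be >= 1, got {radius_px}")
    px = img.astype_float()
    fit_to = ndi.uniform_filter(px, size=3, mode="reflect") if presmooth else px
    background = _sk_rolling_ball(fit_to, radius=radius_px)
    return img.with_pixels(np.clip(px - background, 0, None))


# ---------------------------------------------------------------------------
# histogram auto-thresholds
# ---------------------------------------------------------------------------

THRESHOLD_METHODS = ("otsu", "li", "max_entropy", "minimum", "triangle")


def _histogram_256(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram: integer bins for uint8, rebinned range otherwise."""
    if values.dtype == np.uint8:
        counts = np.bincount(values.ravel(), minlength=256).astype(np.float64)
        centers = np.arange(256, dtype=np.float64)
    else:
        v = values.ravel().astype(np.float64)
        lo, hi = v.min(), v.max()
        if hi == lo:
            raise ValueError("degenerate histogram: constant image")
        counts, edges = np.histogram(v, bins=256, range=(lo, hi))
        counts = counts.astype(np.float64)
        centers = (edges[:-1] + edges[1:]) / 2.0
    return counts, centers


def _otsu_index(counts: np.ndarray, centers: np.ndarray) -> int:
    """Exhaustive maximization of the between-class variance."""
    p = counts / counts.sum()
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu) ** 2 / (w0 * w1)
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    return int(np.argmax(sigma_b[:-1]))


def _max_entropy_index(counts: np.ndarray, centers: np.ndarray) -> int:
    """Kapur's criterion: maximize H(background) + H(foreground)."""
    p = counts / counts.sum()
    P0 = np.cumsum(p)
    # entropy partial sums; 0*log0 := 0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    S = np.cumsum(plogp)
    S_tot = S[-1]
    best, best_k = -np.inf, 0
    for k in range(len(p) - 1):
        w0, w1 = P0[k], 1.0 - P0[k]
        if w0 <= 0 or w1 <= 0:
            continue
        h0 = np.log(w0) - S[k] / w0
        h1 = np.log(w1) - (S_tot - S[k]) / w1
        if h0 + h1 > best:
            best, best_k = h0 + h1, k
    return best_k


def _li_index(counts: np.ndarray, centers: np.ndarray) -> int:
    """Li & Lee iterative minimum-cross-entropy threshold on the histogram."""
    # shift centers so all are strictly positive (log of class means)
    shift = 0.0
    if centers.min() <= 0:
        shift = 1.0 - centers.min()
    c = centers + shift
    p = counts / counts.sum()
    nz = p > 0
    t = float((p * c).sum())  # start at the global mean
    for _ in range(256):
        below = nz & (c <= t)
        above = nz & (c > t)
        if not below.any() or not above.any():
            break
        m0 = (p[below] * c[below]).sum() / p[below].sum()
        m1 = (p[above] * c[above]).sum() / p[above].sum()
        t_next = (m0 - m1) / (np.log(m0) - np.log(m1))
        if abs(t_next - t) < 0.5 * np.min(np.diff(c)):
            t = t_next
            break
        t = t_next
    idx = int(np.searchsorted(c, t, side="right") - 1)
    return min(max(idx, 0), len(c) - 2)


def _minimum_index(counts: np.ndarray, centers: np.ndarray) -> int:
    """Minimum method: smooth (window-3 mean) until exactly two maxima remain,
    then threshold at the minimum between them.  Iteration cap 10,000."""
    h = counts.astype(np.float64).copy()

    def local_maxima(x: np.ndarray) -> np.ndarray:
        # strictly greater than the left neighbor, >= the right (plateau-safe
        # enough for smoothed histograms)
        left = np.r_[-np.inf, x[:-1]]
        right = np.r_[x[1:], -np.inf]
        return np.flatnonzero((x > left) & (x >= right) & (x > 0))

    for _ in range(10_000):
        maxima = local_maxima(h)
        if len(maxima) == 2:
            lo, hi = maxima
            return int(lo + np.argmin(h[lo : hi + 1]))
        if len(maxima) < 2:
            raise ValueError("histogram is unimodal; Minimum method undefined")
        # window-3 moving average with edge replication
        h = np.convolve(np.r_[h[0], h, h[-1]], np.ones(3) / 3.0, mode="valid")
    raise ValueError("Minimum method failed to converge to two maxima")


def _triangle_index(counts: np.ndarray, centers: np.ndarray) -> int:
    """Triangle (geometric) threshold: maximize the distance from the
    histogram to the line joining its peak to the far end of the longer tail."""
    nz = np.flatnonzero(counts)
    if len(nz) < 2:
        raise ValueError("degenerate histogram")
    first, last = nz[0], nz[-1]
    peak = int(np.argmax(counts))
    # work on the longer tail side of the peak
    if (peak - first) >= (last - peak):
        i0, i1 = first, peak  # tail on the left
    else:
        i0, i1 = peak, last  # tail on the right
    x0, y0 = float(i0), float(counts[i0] if i0 != peak else counts[peak])
    x1, y1 = float(i1), float(counts[i1] if i1 != peak else counts[peak])
    xs = np.arange(i0, i1 + 1, dtype=np.float64)
    ys = counts[i0 : i1 + 1]
    # perpendicular distance from (xs, ys) to the line (x0,y0)-(x1,y1)
    d = np.abs((y1 - y0) * xs - (x1 - x0) * ys + x1 * y0 - y1 * x0)
    return int(i0 + np.argmax(d))


_INDEX_FUNCS = {
    "otsu": _otsu_index,
    "max_entropy": _max_entropy_index,
    "li": _li_index,
    "minimum": _minimum_index,
    "triangle": _triangle_index,
}


def threshold_index(counts: np.ndarray, centers: np.ndarray, method: str) -> int:
    """Threshold bin index for a 256-bin histogram by the named method.

    The returned index k partitions the histogram into bins <= k (background
    for bright objects) and bins > k.
    """
    if method not in _INDEX_FUNCS:
        raise ValueError(f"unknown threshold method {method!r}")
    counts = np.asarray(counts, dtype=np.float64)
    if np.count_nonzero(counts) < 2:
        raise ValueError("degenerate histogram: needs >= 2 distinct values")
    return _INDEX_FUNCS[method](counts, np.asarray(centers, dtype=np.float64))


def auto_threshold(
    img_or_stack: Image2D | ImageStack,
    method: str,
    use_stack_histogram: bool = False,
    dark_objects: bool = False,
) -> MaskImage | list[MaskImage]:
    """Auto-threshold an image or stack, returning binary mask(s).

    Foreground = pixels strictly above the threshold value, or at/below it
    when ``dark_objects`` (brightfield objects are darker than background).
    With ``use_stack_histogram`` a single threshold from the pooled stack
    histogram is applied to every slice.
    """
    if isinstance(img_or_stack, ImageStack):
        if use_stack_histogram:
            pooled = img_or_stack.as_array()
            counts, centers = _histogram_256(pooled)
            k = threshold_index(counts, centers, method)
            t = centers[k]
            return [
                _mask_from_threshold(s, t, method, dark_objects)
                for s in img_or_stack
            ]
        return [
            auto_threshold(s, method, dark_objects=dark_objects)
            for s in img_or_stack
        ]
    counts, centers = _histogram_256(np.asarray(img_or_stack.pixels))
    k = threshold_index(counts, centers, method)
    return _mask_from_threshold(img_or_stack, centers[k], method, dark_objects)


def _mask_from_threshold(
    img: Image2D, t: float, method: str, dark_objects: bool
) -> MaskImage:
    px = np.asarray(img.pixels)
    fg = (px <= t) if dark_objects else (px > t)
    pol = "dark" if dark_objects else "bright"
    return MaskImage(
        fg, provenance=f"{method}(t={t:g},{pol})", pixel_size=img.pixel_size
    )


# ---------------------------------------------------------------------------
# binary operations and components
# ---------------------------------------------------------------------------


def fill_holes(mask: MaskImage) -> MaskImage:
    """Set background components not 4-connected to the border to foreground."""
    filled = ndi.binary_fill_holes(mask.pixels)  # default structure = 4-conn
    return MaskImage(
        filled, provenance=mask.provenance + "+fill_holes", pixel_size=mask.pixel_size
    )


@dataclass(frozen=True)
class RegionProps:
    """Geometry of one connected component.

    Coordinates are (x, y) in pixels.  ``circularity`` uses a Crofton
    perimeter estimate and is capped at 1; ``roundness`` is
    4*area/(pi*major_axis**2).  ``ellipse_angle`` is the major-axis angle from
    the +x axis (y pointing down), folded to [0, pi).
    """

    label: int
    area: float
    perimeter: float
    centroid: tuple[float, float]
    center_of_mass: tuple[float, float]
    circularity: float
    roundness: float
    ellipse_major: float
    ellipse_minor: float
    ellipse_angle: float

    @property
    def equivalent_diameter(self) -> float:
        return float(2.0 * np.sqrt(self.area / np.pi))


def _skimage_angle_to_x_axis(orientation: float) -> float:
    # skimage orientation is measured from the row axis; the major-axis
    # direction in (x=col, y=row) coordinates is (-sin O, -cos O)
    ang = np.arctan2(-np.cos(orientation), -np.sin(orientation))
    return float(np.mod(ang, np.pi))

def _props_from_region(r, intensity: np.ndarray | None) -> RegionProps:
    area = float(r.area)
    perim = float(r.perimeter_crofton)
    circ = 1.0 if perim == 0 else min(1.0, 4.0 * np.pi * area / perim**2)
    major = float(r.axis_major_length)
    minor = float(r.axis_minor_length)
    roundness = 1.0 if major == 0 else min(1.0, 4.0 * area / (np.pi * major**2))
    cy, cx = r.centroid
    if intensity is not None:
        wy, wx = r.centroid_weighted
    else:
        wy, wx = cy, cx
    return RegionProps(
        label=int(r.label),
        area=area,
        perimeter=perim,
        centroid=(float(cx), float(cy)),
        center_of_mass=(float(wx), float(wy)),
        circularity=circ,
        roundness=roundness,
        ellipse_major=major,
        ellipse_minor=minor,
        ellipse_angle=_skimage_angle_to_x_axis(float(r.orientation)),
    )


def label_components(mask: MaskImage) -> np.ndarray:
    """8-connected component labeling of a binary mask."""
    return measure.label(mask.pixels, connectivity=2)


def connected_components(
    mask: MaskImage,
    min_area_px: int = 0,
    intensity: Image2D | None = None,
    return_labels: bool = False,
):
    """8-connected components with area strictly > ``min_area_px``.

    Returns a list of :class:`RegionProps` (ellipse fit by second moments);
    with ``return_labels`` also returns the label image (labels of filtered
    components included).  ``intensity`` enables the intensity-weighted
    center of mass; otherwise the binary centroid is used for both fields.
    """
    labels = label_components(mask)
    ints = None if intensity is None else np.asarray(intensity.pixels)
    regions = measure.regionprops(labels, intensity_image=ints)
    props = [
        _props_from_region(r, ints) for r in regions if r.area > min_area_px
    ]
    if return_labels:
        return props, labels
    return props
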