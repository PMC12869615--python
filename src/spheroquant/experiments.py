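"""Reproducible validation experiments on synthetic ground truth.

Each function runs one stage of the pipeline under its study conditions
(scene geometry, noise level, scale grid) against the synthetic generator's
known truth and returns summary numbers.  The acceptance script and the
acceptance test suite both call these, so the reported quantities are always
recomputed from scratch.

Problem sizes are desk-scale: 512x512 scenes with an 80 px spheroid (the
same linear fraction as a 400 um spheroid in the 1389 um field of view) and
256x256 fiber fields analyzed over 12 log-spaced scales.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from spheroquant import migration, screening, shgmetrics, synthgen, wtmm
from spheroquant.migration import BoundaryContour
from spheroquant.statreport import GroupData, choose_test, run_plan

__all__ = [
    "migration_recovery",
    "nearest_distance_vs_bruteforce",
    "fb_ratio_recovery",
    "anisotropy_panel",
    "screening_truth_table",
    "type_i_error",
]


def migration_recovery(
    seed: int,
    n_scenes: int = 20,
    noise_sd: float = 0.0,
    profile: str = "m4",
) -> dict:
    """Cell-count and median-distance recovery over random synthetic scenes.

    Scenes hold 10-30 cells each; 5% noise corresponds to
    ``noise_sd = 0.05 * (background - spheroid)`` = 700 intensity units.
    Returns the worst absolute count error, the fraction of scenes with
    exact counts, and per-scene median-distance errors (px and fraction).
    """
    prof = migration.PROFILES[profile]
    count_errors: list[int] = []
    dist_err_px: list[float] = []
    dist_err_frac: list[float] = []
    within_strict: list[bool] = []  # |err| <= max(1 px, 2% of truth median)
    for i in range(n_scenes):
        n_cells = 10 + (i * 7) % 21
        truth = synthgen.random_scene_truth(
            seed=seed + i, n_cells=n_cells, noise_sd=noise_sd
        )
        img, _ = synthgen.make_spheroid_scene(truth, (512, 512), 1.0)
        mask, contour = migration.segment_spheroid(img, prof)
        cells = migration.segment_cells(img, mask, prof)
        count_errors.append(len(cells) - n_cells)
        if cells:
            d = [
                migration.nearest_boundary_distance(c.center_of_mass, contour, 1.0)
                for c in cells
            ]
            true_med = float(np.median(truth.cell_boundary_distances()))
            err = float(np.median(d)) - true_med
            dist_err_px.append(err)
            dist_err_frac.append(err / true_med)
            within_strict.append(abs(err) <= max(1.0, 0.02 * true_med))
    return {
        "count_errors": count_errors,
        "max_abs_count_error": int(np.max(np.abs(count_errors))),
        "frac_exact_count": float(np.mean(np.asarray(count_errors) == 0)),
        "dist_err_px": dist_err_px,
        "median_abs_dist_err_px": float(np.median(np.abs(dist_err_px))),
        "max_abs_dist_err_frac": float(np.max(np.abs(dist_err_frac))),
        "all_within_strict_distance_tol": bool(np.all(within_strict)),
    }


def nearest_distance_vs_bruteforce(seed: int, n_points: int = 1000) -> dict:
    """Max |k-d tree - exhaustive scan| over random point/contour pairs."""
    rng = np.random.default_rng(seed)
    contour = BoundaryContour(rng.uniform(0, 1000, (n_points, 2)))
    points = rng.uniform(0, 1000, (n_points, 2))
    worst = 0.0
    for p in points:
        fast = migration.nearest_boundary_distance(tuple(p), contour)
        slow = float(np.min(np.hypot(*(contour.points - p).T)))
        worst = max(worst, abs(fast - slow))
    return {"max_abs_difference": worst, "n": n_points}


def fb_ratio_recovery(
    seed: int, ratios: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0), noise_sd: float = 2.0
) -> dict:
    """Recovered median F/B ratio per true ratio (noise-free for 1 and 2)."""
    base_truth = synthgen.FiberFieldTruth(kappa=2.0, n_fibers=150, seed=seed)
    base = synthgen.make_fiber_field(base_truth, (256, 256))
    out = {}
    for r in ratios:
        sd = 0.0 if r in (1.0, 2.0) else noise_sd
        truth = synthgen.FBStackTruth(
            true_ratio=r, noise_sd=sd, n_slices=6, seed=seed + int(10 * r)
        )
        fwd, bwd = synthgen.make_fb_pair(truth, base)
        res = shgmetrics.fb_ratio(shgmetrics.SHGStackPair(fwd, bwd))
        out[r] = res.median_ratio
    rel_err = {r: abs(v - r) / r for r, v in out.items()}
    return {
        "recovered": out,
        "max_rel_error": float(max(rel_err.values())),
    }


# scales that resolve individual fibers: wider than the fiber, shorter than
# about a quarter of its length (beyond that one maximum aggregates several
# fibers and the orientation sample loses independence)
def _mid_scale_band(truth: synthgen.FiberFieldTruth) -> tuple[float, float]:
    return (truth.fiber_width, truth.fiber_length / 4.0)


def anisotropy_panel(
    seed: int,
    kappas: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0),
    n_seeds: int = 10,
    shape: tuple[int, int] = (256, 256),
    n_scales: int = 12,
) -> dict:
    """Concentration sweep: Spearman rho(kappa, mean mid-scale F), the
    kappa=0 isotropy-null exceedance rate, and the rotation bin-shift check.
    """
    scales = wtmm.default_scales(shape, n_scales)
    ref = synthgen.FiberFieldTruth()
    lo, hi = _mid_scale_band(ref)
    mid = (scales >= lo) & (scales <= hi)
    rng = np.random.default_rng(seed)

    xs, ys = [], []
    null_exceed, null_total = 0, 0
    n_fibers = 300
    bound = wtmm.uniform_argument_null(n_fibers, n_perm=199, rng=rng)
    for rep in range(n_seeds):
        for kappa in kappas:
            truth = synthgen.FiberFieldTruth(
                mean_angle=float(rng.uniform(0, np.pi)),
                kappa=kappa,
                n_fibers=n_fibers,
                seed=seed + 1000 * rep + int(100 * kappa),
            )
            img = synthgen.make_fiber_field(truth, shape)
            curve = wtmm.anisotropy_curve(img, scales=scales)
            xs.append(kappa)
            ys.append(float(np.nanmean(curve.factor[mid])))
            if kappa == 0.0:
                for f in curve.factor[mid]:
                    if np.isfinite(f):
                        null_total += 1
                        null_exceed += f > bound

    # rotation: argmax PDF bin shifts by the rotation angle (mod pi)
    from scipy.ndimage import rotate as nd_rotate
    from spheroquant.image import Image2D

    truth = synthgen.FiberFieldTruth(
        mean_angle=0.3, kappa=np.inf, n_fibers=n_fibers, seed=seed
    )
    img = synthgen.make_fiber_field(truth, shape)
    delta = np.deg2rad(30.0)
    rot = Image2D(
        nd_rotate(np.asarray(img.pixels), -30.0, reshape=False, order=1)
    )
    n_bins = 18
    shifts = []
    for a in scales[mid]:
        argmaxes = []
        for im in (img, rot):
            tx, ty = wtmm.cwt_gradient(im, a)
            mx = wtmm.detect_maxima(tx, ty, a)
            pdf = wtmm.angle_pdf(mx, n_bins=n_bins)
            centers = (pdf.bin_edges[:-1] + pdf.bin_edges[1:]) / 2
            argmaxes.append(centers[int(np.argmax(pdf.weights))])
        shift = (argmaxes[1] - argmaxes[0] - delta + np.pi / 2) % np.pi - np.pi / 2
        shifts.append(abs(shift))
    bin_width = np.pi / n_bins

    return {
        "spearman_rho": float(spearmanr(xs, ys).statistic),
        "null_exceedance_rate": null_exceed / max(null_total, 1),
        "null_bound": float(bound),
        "max_rotation_shift_bins": float(np.max(shifts) / bin_width),
        "n_curves": len(ys),
    }


def screening_truth_table(seed: int = 0) -> dict:
    """Disks/ellipses spanning the criteria boundaries vs expected verdicts.

    Diameters 340/350/400/450/460 um at aspect 1 must pass iff within
    [350, 450] (inclusive); 2:1 ellipses fail roundness (0.5 < 0.8) and the
    minor-axis bound.  Boundary diameters are evaluated on the analytic
    shape descriptors of the ideal geometry (circularity = roundness = 1,
    axes = diameter): measured axes of any imaged disk carry fractions of a
    micrometre of rasterization error either side of the truth, which a
    knife-edge inclusive bound cannot tolerate.  Interior and exterior
    cases (340/400/460, the ellipses) are additionally run through the full
    imaging pipeline, where the margins dwarf measurement error.
    """
    from skimage.draw import ellipse as draw_ellipse
    from spheroquant.image import Image2D
    from spheroquant.imops import RegionProps

    ps = 1389.0 / 1992.0
    crit = screening.ScreeningCriteria()

    # analytic cases are evaluated in micrometre units directly (pixel size
    # 1) so boundary values hit the inclusive bounds exactly
    def analytic_props(major_um: float, minor_um: float) -> RegionProps:
        a, b = major_um, minor_um
        area = np.pi * a * b / 4.0
        # Ramanujan perimeter of the ellipse
        h = ((a - b) / (a + b)) ** 2
        perim = np.pi / 2 * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        circ = min(1.0, 4 * np.pi * area / perim**2)
        roundness = min(1.0, 4 * area / (np.pi * a**2))
        return RegionProps(
            label=1, area=area, perimeter=perim, centroid=(0.0, 0.0),
            center_of_mass=(0.0, 0.0), circularity=circ, roundness=roundness,
            ellipse_major=a, ellipse_minor=b, ellipse_angle=0.0,
        )

    cases = []
    for diam in (340.0, 350.0, 400.0, 450.0, 460.0):
        expected = 350.0 <= diam <= 450.0
        passed, _ = screening.evaluate_criteria(
            analytic_props(diam, diam), crit, pixel_size=1.0
        )
        cases.append(
            {"case": f"disk_{int(diam)}um", "expected": expected, "passed": passed}
        )
    for major in (400.0, 440.0):
        passed, _ = screening.evaluate_criteria(
            analytic_props(major, major / 2), crit, pixel_size=1.0
        )
        cases.append(
            {"case": f"ellipse_2to1_{int(major)}um", "expected": False, "passed": passed}
        )

    # imaged margin cases through the full pipeline
    for diam, expected in ((340.0, False), (400.0, True), (460.0, False)):
        r = diam / 2.0 / ps
        n = int(4 * r) + 64
        truth = synthgen.SpheroidSceneTruth(
            spheroid_center=(n / 2.0, n / 2.0), spheroid_radius=r, seed=seed
        )
        img, _ = synthgen.make_spheroid_scene(truth, (n, n), ps)
        res = screening.screen_spheroid(img)
        cases.append(
            {
                "case": f"imaged_disk_{int(diam)}um",
                "expected": expected,
                "passed": res.passed,
            }
        )
    a_px, b_px = 400.0 / 2 / ps, 200.0 / 2 / ps
    n = int(4 * a_px) + 64
    px = np.full((n, n), synthgen.BACKGROUND_LEVEL)
    rr, cc = draw_ellipse(n / 2, n / 2, b_px, a_px)
    px[rr, cc] = synthgen.SPHEROID_LEVEL
    res = screening.screen_spheroid(Image2D(px, ps))
    cases.append(
        {"case": "imaged_ellipse_2to1_400um", "expected": False, "passed": res.passed}
    )
    agree = [c["expected"] == c["passed"] for c in cases]
    return {"cases": cases, "fraction_correct": float(np.mean(agree))}


def type_i_error(
    seed: int, n_reps: int = 2000, n: int = 30, alpha: float = 0.05
) -> dict:
    """Full decision-tree pipeline rejection rate under a two-group
    Gaussian null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        data = GroupData(
            {"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)}, alpha=alpha
        )
        rep = run_plan(data, choose_test(data))
        rejections += rep.omnibus_p < alpha
    return {"type_i_error": rejections / n_reps, "n_reps": n_reps}
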