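"""Run configuration and workflow orchestration.

All randomness flows from one root seed, split per module with
``numpy.random.SeedSequence``; a workflow writes every output CSV into a
manifest with content hashes so a run is reproducible and auditable from
its logged configuration alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from spheroquant import migration, screening, shgmetrics, statreport, synthgen, wtmm
from spheroquant.image import Image2D

log = logging.getLogger("spheroquant")

__all__ = ["RunConfig", "run_workflow", "load_config"]

# brightfield calibration: 1389 um field of view over 1992 px
DEFAULT_PIXEL_SIZE = 1389.0 / 1992.0


@dataclass
class RunConfig:
    pixel_size: float = DEFAULT_PIXEL_SIZE  # um/px
    profile: str = "mda_mb_231"
    alpha: float = 0.05
    seed: int = 0
    n_scales: int = 12
    input_dir: str = "."
    output_dir: str = "out"
    criteria: screening.ScreeningCriteria = field(
        default_factory=screening.ScreeningCriteria
    )

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    def module_seed(self, name: str) -> int:
        """Deterministic per-module child seed derived from the root seed."""
        child = np.random.SeedSequence(
            [self.seed, int.from_bytes(name.encode()[:4].ljust(4, b"\0"), "big")]
        )
        return int(child.generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    crit = raw.pop("criteria", None)
    cfg = RunConfig(**raw)
    if crit:
        cfg.criteria = screening.ScreeningCriteria(**crit)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_workflow(config: RunConfig, workflow: str) -> dict:
    """Execute a named stage sequence; returns the artifact manifest.

    ``full_synthetic_demo`` generates synthetic inputs for every modality and
    runs screening, migration, F/B ratio, anisotropy, and the statistics
    stage end-to-end.  ``migration`` runs the time-course pipeline on a
    synthetic 7-timepoint series.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    in_dir = Path(config.input_dir)
    if not in_dir.exists():
        raise FileNotFoundError(f"input directory not found: {in_dir}")
    artifacts: list[Path] = []

    if workflow == "migration":
        artifacts += _migration_stage(config, out)
    elif workflow == "shg":
        artifacts += _shg_stage(config, out)
    elif workflow == "full_synthetic_demo":
        artifacts += _screening_stage(config, out)
        artifacts += _migration_stage(config, out)
        artifacts += _shg_stage(config, out)
        artifacts += _stats_stage(config, out)
    else:
        raise ValueError(f"unknown workflow {workflow!r}")

    manifest = {
        "workflow": workflow,
        "config": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(config).items()
        },
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("workflow %s wrote %d artifacts to %s", workflow, len(artifacts), out)
    return manifest


def _screening_stage(config: RunConfig, out: Path) -> list[Path]:
    rows = []
    for diam_um in (320.0, 400.0, 480.0):
        r_px = diam_um / 2.0 / config.pixel_size
        shape = (int(4 * r_px) + 64, int(4 * r_px) + 64)
        truth = synthgen.SpheroidSceneTruth(
            spheroid_center=(shape[1] / 2, shape[0] / 2),
            spheroid_radius=r_px,
            seed=config.module_seed("screen"),
        )
        img, _ = synthgen.make_spheroid_scene(truth, shape, config.pixel_size)
        res = screening.screen_spheroid(img, config.criteria)
        rows.append(
            {
                "diameter_um": diam_um,
                "passed": res.passed,
                "failures": ";".join(res.failures),
                "circularity": res.props.circularity,
                "roundness": res.props.roundness,
                "major_um": res.props.ellipse_major * config.pixel_size,
                "minor_um": res.props.ellipse_minor * config.pixel_size,
            }
        )
    path = out / "screening.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


def _migration_stage(config: RunConfig, out: Path) -> list[Path]:
    seed = config.module_seed("migrate")
    profile = migration.PROFILES[config.profile]
    frames = []
    for i, t in enumerate(range(0, 84, 12)):
        # outward drift of 10 px per 12 h; the inner edge stays clear of the
        # segmented body (the MaxEntropy profile's mask overshoots the
        # boundary by ~12 px, see docs/methods.md)
        truth = synthgen.random_scene_truth(
            seed=seed + i,
            n_cells=12,
            distance_range=(30.0 + 10.0 * i, 80.0 + 10.0 * i),
        )
        img, _ = synthgen.make_spheroid_scene(truth, (512, 512), config.pixel_size)
        frames.append((float(t), img))
    summaries, records = migration.summarize_timecourse(frames, profile)
    srows = [asdict(s) for s in summaries]
    crows = [
        {
            "timepoint_h": r.timepoint_h,
            "area_px": r.props.area,
            "x": r.props.center_of_mass[0],
            "y": r.props.center_of_mass[1],
            "circularity": r.props.circularity,
            "distance_um": r.migration_distance_um,
        }
        for r in records
    ]
    p1, p2 = out / "summary.csv", out / "cells.csv"
    pd.DataFrame(srows).to_csv(p1, index=False)
    pd.DataFrame(crows).to_csv(p2, index=False)
    return [p1, p2]


def _shg_stage(config: RunConfig, out: Path) -> list[Path]:
    seed = config.module_seed("shg")
    fiber_truth = synthgen.FiberFieldTruth(
        mean_angle=0.6, kappa=4.0, n_fibers=150, seed=seed
    )
    base = synthgen.make_fiber_field(fiber_truth, (256, 256))
    rows = []
    for ratio in (0.5, 2.0):
        fb_truth = synthgen.FBStackTruth(
            true_ratio=ratio, noise_sd=1.0, n_slices=6, seed=seed
        )
        fwd, bwd = synthgen.make_fb_pair(fb_truth, base)
        res = shgmetrics.fb_ratio(shgmetrics.SHGStackPair(fwd, bwd, "far"))
        rows.append(
            {
                "true_ratio": ratio,
                "median_ratio": res.median_ratio,
                "mask_fraction": res.mask_fraction,
            }
        )
    p1 = out / "fb_results.csv"
    pd.DataFrame(rows).to_csv(p1, index=False)

    scales = wtmm.default_scales((256, 256), config.n_scales)
    curve = wtmm.anisotropy_curve(base, scales=scales)
    p2 = out / "anisotropy.csv"
    pd.DataFrame(
        {
            "scale_px": curve.scales,
            "anisotropy_factor": curve.factor,
            "n_maxima": curve.n_maxima,
            "reliable": curve.reliable,
        }
    ).to_csv(p2, index=False)
    return [p1, p2]


def _stats_stage(config: RunConfig, out: Path) -> list[Path]:
    rng = np.random.default_rng(config.module_seed("stats"))
    data = statreport.GroupData(
        {
            "control": rng.normal(100, 12, 24),
            "treated": rng.normal(80, 12, 24),
            "knockdown": rng.normal(78, 12, 24),
        },
        alpha=config.alpha,
    )
    report = statreport.analyze(data)
    path = out / "stats.json"
    payload = {
        "chosen_test": report.plan.chosen_test,
        "posthoc": report.plan.posthoc,
        "omnibus_p": report.omnibus_p,
        "letters": report.letters,
        "pairwise_p": None
        if report.pairwise_p is None
        else report.pairwise_p.to_dict(),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return [path]
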