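"""Run configuration and end-to-end orchestration.

A run ingests (or simulates) a time-lapse, measures per-seed growth series,
fits the candidate families, selects the best by R², differentiates the
winner and writes every table as CSV together with a manifest recording the
fully resolved configuration and its hash — no hidden constants, so a rerun
with an identical config is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from seedlapse import fitting, morphometry, simulate
from seedlapse.metrics import DEFAULT_IOU_GRID, germination_rate
from seedlapse.simulate import LABEL_GERMINATED, SceneSpec, random_scene
from seedlapse.voc_io import AnnotatedFrame, read_voc, write_voc

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one pipeline run; written beside its outputs."""

    images_dir: str | None = None
    annotations_dir: str | None = None
    out_dir: str = "run"
    threshold: int = 120
    start_h: float = 24.0
    step_h: float = 1.0
    end_h: float = 48.0
    families: tuple[str, ...] = fitting.FAMILIES
    poly_order: int = 3
    monotone_check: bool = True
    noise_factor: float = 0.2
    split_seed: int = 0
    iou_grid: tuple[float, ...] = DEFAULT_IOU_GRID
    # Simulation parameters, used when images_dir is None.
    sim_seed: int = 0
    sim_n_seeds: int = 4
    sim_shape: tuple[int, int] = (256, 256)
    sim_duration_h: float = 48.0
    sim_interval_h: float = 0.5

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def write_stack(
    spec: SceneSpec,
    out_dir: str | Path,
) -> tuple[Path, Path, Path]:
    """Render a scene to disk: images/, annotations/ and truth.csv."""
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    ann_dir = out_dir / "annotations"
    images_dir.mkdir(parents=True, exist_ok=True)
    ann_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, t in enumerate(spec.frame_times()):
        image, frame, _ = simulate.render_frame(spec, float(t), frame_index=i)
        Image.fromarray(image).save(images_dir / f"{frame.image_id}.png")
        write_voc(frame, ann_dir / f"{frame.image_id}.xml", image_size=spec.shape)
        for rec in simulate.frame_truth(spec, float(t)):
            rows.append(
                {
                    "image_id": frame.image_id,
                    "time_h": float(t),
                    "seed_id": rec["seed_id"],
                    "true_area": rec["true_area"],
                    "label": rec["label"],
                }
            )
    truth_path = out_dir / "truth.csv"
    pd.DataFrame(rows).to_csv(truth_path, index=False)
    return images_dir, ann_dir, truth_path


def load_frames(images_dir: str | Path, annotations_dir: str | Path) -> list[tuple[AnnotatedFrame, np.ndarray]]:
    """Pair every VOC XML with its image, ordered by acquisition time."""
    images_dir = Path(images_dir)
    annotations_dir = Path(annotations_dir)
    if not annotations_dir.is_dir():
        raise FileNotFoundError(f"annotation directory not found: {annotations_dir}")
    if not images_dir.is_dir():
        raise FileNotFoundError(f"image directory not found: {images_dir}")
    frames = []
    for xml_path in sorted(annotations_dir.glob("*.xml")):
        frame = read_voc(xml_path)
        matches = [p for ext in (".png", ".jpg", ".jpeg") if (p := images_dir / f"{frame.image_id}{ext}").exists()]
        if not matches:
            raise FileNotFoundError(f"no image for annotation {xml_path.name} in {images_dir}")
        image = np.asarray(Image.open(matches[0]))
        frames.append((frame, image))
    frames.sort(key=lambda fr: fr[0].time_h)
    return frames


def measure_all(
    frames: Sequence[tuple[AnnotatedFrame, np.ndarray]],
    cfg: RunConfig,
) -> list[morphometry.GrowthSeries]:
    """One growth series per seed tracked from the first sampled frame."""
    if not frames:
        raise ValueError("no frames to measure")
    first = next(fr for fr in frames if fr[0].boxes)
    n_tracks = len(first[0].boxes)
    series = []
    for k in range(n_tracks):
        series.append(
            morphometry.assemble_series(
                frames,
                dish_id=f"seed_{k}",
                track=k,
                start_h=cfg.start_h,
                step_h=cfg.step_h,
                end_h=cfg.end_h,
                threshold=cfg.threshold,
            )
        )
    return series


def fit_report_rows(series: morphometry.GrowthSeries, cfg: RunConfig) -> tuple[list[dict], fitting.FitResult]:
    """Table of every candidate fit plus the selected winner."""
    rows = []
    for fam in cfg.families:
        try:
            fit = fitting.fit_family(series, fam, order=cfg.poly_order)
        except ValueError as exc:
            rows.append({"dish": series.dish_id, "family": fam, "r2": None, "r2_residual": None, "expression": f"unfittable: {exc}"})
            continue
        rows.append(
            {
                "dish": series.dish_id,
                "family": fam,
                "r2": round(fit.r2, 4),
                "r2_residual": round(fit.r2_residual, 4),
                "expression": fit.expression(),
            }
        )
    best = fitting.select_best(series, cfg.families, monotone_check=cfg.monotone_check, order=cfg.poly_order)
    return rows, best


def run_pipeline(cfg: RunConfig, scene: SceneSpec | None = None) -> Path:
    """Execute the full pipeline and return the run directory.

    With ``images_dir``/``annotations_dir`` set the run ingests an existing
    dataset; otherwise a synthetic scene (given or drawn from the sim_*
    parameters) is rendered first.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}

    def _stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    t0 = _stage("ingest")
    if cfg.images_dir is not None and cfg.annotations_dir is not None:
        frames = load_frames(cfg.images_dir, cfg.annotations_dir)
    else:
        if scene is None:
            scene = random_scene(
                n_seeds=cfg.sim_n_seeds,
                shape=cfg.sim_shape,
                rng=cfg.sim_seed,
                duration_h=cfg.sim_duration_h,
                interval_h=cfg.sim_interval_h,
            )
        images_dir, ann_dir, _ = write_stack(scene, out_dir / "dataset")
        frames = load_frames(images_dir, ann_dir)
    stage_times["ingest_s"] = time.perf_counter() - t0

    t0 = _stage("morphometry")
    all_series = measure_all(frames, cfg)
    series_rows = [
        {"dish_id": s.dish_id, "time_h": t, "white_count": c}
        for s in all_series
        for t, c in zip(s.times, s.counts)
    ]
    pd.DataFrame(series_rows).to_csv(out_dir / "series.csv", index=False)
    stage_times["morphometry_s"] = time.perf_counter() - t0

    t0 = _stage("fitting")
    fit_rows: list[dict] = []
    deriv_rows: list[dict] = []
    for s in all_series:
        rows, best = fit_report_rows(s, cfg)
        fit_rows.extend(rows)
        if best.family == "polynomial":
            curve = fitting.potential_curve(best, (cfg.start_h, cfg.end_h), grid_step=cfg.step_h)
            deriv = curve.derivative
            deriv_rows.append(
                {
                    "dish": s.dish_id,
                    "equation": best.expression(),
                    "r2": round(best.r2, 4),
                    "derivative_equation": fitting.FitResult(
                        family="polynomial",
                        params=deriv.coeffs,
                        r2=best.r2,
                        r2_residual=best.r2_residual,
                        x=best.x,
                        y=best.y,
                        yhat=best.yhat,
                        order=deriv.degree,
                    ).expression(),
                    "peak_t": round(curve.peak[0], 2),
                    "peak_value": round(curve.peak[1], 2),
                    "grid_peak_t": round(curve.grid_peak[0], 2),
                    "grid_peak_value": round(curve.grid_peak[1], 2),
                }
            )
    pd.DataFrame(fit_rows).to_csv(out_dir / "fit_report.csv", index=False)
    pd.DataFrame(deriv_rows).to_csv(out_dir / "derivative_report.csv", index=False)
    stage_times["fitting_s"] = time.perf_counter() - t0

    t0 = _stage("rates")
    last_frame = frames[-1][0]
    n_total = len(last_frame.boxes)
    n_germ = sum(1 for b in last_frame.boxes if b.label == LABEL_GERMINATED)
    if n_total > 0:
        report = germination_rate(n_germ, n_total)
        pd.DataFrame(
            [{"name": "final_frame", "n_germinated": report.n_germinated, "n_total": report.n_total, "rate_percent": report.rate}]
        ).to_csv(out_dir / "rate_report.csv", index=False)
    stage_times["rates_s"] = time.perf_counter() - t0

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "n_frames": len(frames),
        "n_series": len(all_series),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out_dir
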