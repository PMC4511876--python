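"""End-to-end orchestration: simulate or load stacks, project, detect, and
run the SNR / integrity / co-localization analyses, writing every
intermediate table as plain CSV/JSON so runs can be diffed.

All randomness flows from the master seed in :class:`RunConfig`; re-running
the same config reproduces every numeric output exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import coloc, detect, integrity, prep, snr
from .scenes import SceneConfig, generate_scene, write_scene

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

ALL_STAGES = ("simulate", "prep", "detect", "snr", "integrity", "coloc")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: either ``scene`` (simulate) or
    ``input_stacks`` (two TIFF paths, one per color channel).
    """

    out_dir: str
    stages: tuple[str, ...] = ALL_STAGES
    scene: SceneConfig | None = None
    input_stacks: tuple[str, str] | None = None
    disk_geometry: snr.DiskGeometry = field(default_factory=snr.DiskGeometry)
    max_area_px: int = 40
    min_circularity: float = 0.5
    min_area_px: int = 4  # single-pixel specks are noise, not spots
    smoothing_sigma_px: float = 1.0
    min_prominence: float | None = None  # None -> 5x robust noise SD
    mc_replicates: int = 10
    binarization_threshold: float | None = None  # None -> mode x 2, channel 1
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.scene is None) == (self.input_stacks is None):
            raise ValueError("exactly one input source: scene XOR input_stacks")
        if "simulate" in self.stages and self.scene is None:
            raise ValueError("simulate stage requires a scene config")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    counts: dict[str, int] = field(default_factory=dict)
    wall_time_s: dict[str, float] = field(default_factory=dict)
    seed_chain: dict[str, int] = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _objects_table(objects: list[detect.SignalObject]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "label": o.label, "row": o.centroid[0], "col": o.centroid[1],
            "peak_row": o.peak_location[0], "peak_col": o.peak_location[1],
            "area_px": o.area_px, "circularity": o.circularity,
            "peak_intensity": o.peak_intensity,
        }
        for o in objects
    ])


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the selected stages in order and return the manifest.

    Artifacts written under ``config.out_dir``: simulated stacks and truth
    (simulate), corrected projections and thresholds (prep), object and
    point tables (detect), per-signal SNR CSV and summary JSON (snr),
    integrity report JSON (integrity), overlap JSON (coloc), plus
    ``manifest.json``. On a stage failure, partial outputs are kept and a
    ``FAILED`` marker file names the stage.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__)
    rng = np.random.default_rng(config.seed)
    manifest.seed_chain["master"] = config.seed

    stacks: list[np.ndarray] | None = None
    stage = ""
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            t0 = time.perf_counter()
            scene_cfg = config.scene
            manifest.seed_chain["scene"] = scene_cfg.seed
            stacks, truth = generate_scene(scene_cfg)
            write_scene(out / "scene", stacks, truth, scene_cfg)
            manifest.counts["true_rcps"] = truth.n_rcps()
            manifest.wall_time_s[stage] = time.perf_counter() - t0
        elif config.input_stacks is not None:
            stacks = [prep.read_stack(p) for p in config.input_stacks]

        corrected: list[np.ndarray] = []
        thresholds: list[prep.ThresholdResult] = []
        if "prep" in config.stages:
            stage = "prep"
            t0 = time.perf_counter()
            if stacks is None:
                raise RuntimeError("no input stacks available")
            for i, stack in enumerate(stacks, start=1):
                pair = prep.project(stack)
                thr = prep.mode_threshold(pair.corrected)
                corrected.append(pair.corrected)
                thresholds.append(thr)
                tifffile.imwrite(
                    out / f"corrected_ch{i}.tif",
                    np.clip(np.round(pair.corrected), 0, 65535).astype(np.uint16),
                )
                (out / f"threshold_ch{i}.json").write_text(json.dumps({
                    "mode_value": thr.mode_value,
                    "threshold": thr.threshold,
                    "clip_range": list(thr.clip_range),
                }))
            manifest.wall_time_s[stage] = time.perf_counter() - t0

        objects_per_ch: list[list[detect.SignalObject]] = []
        filtered_per_ch: list[list[detect.SignalObject]] = []
        points_per_ch: list[detect.ColoredPointSet] = []
        if "detect" in config.stages:
            stage = "detect"
            t0 = time.perf_counter()
            for i, (img, thr) in enumerate(zip(corrected, thresholds), start=1):
                objs = detect.segment_signals(img, thr.threshold)
                sized = [o for o in objs if o.area_px >= config.min_area_px]
                kept = detect.filter_clusters(sized, config.max_area_px,
                                              config.min_circularity)
                objects_per_ch.append(objs)
                filtered_per_ch.append(kept)
                _objects_table(kept).to_csv(out / f"objects_ch{i}.csv",
                                            index=False)
                prominence = config.min_prominence
                if prominence is None:
                    prominence = detect.robust_prominence(
                        img, config.smoothing_sigma_px)
                pts = detect.detect_maxima(
                    img, config.smoothing_sigma_px, color=i,
                    min_prominence=prominence,
                )
                points_per_ch.append(pts)
                pd.DataFrame(pts.points, columns=["row", "col", "color"]) \
                    .to_csv(out / f"maxima_ch{i}.csv", index=False)
                manifest.counts[f"detected_ch{i}"] = len(objs)
                manifest.counts[f"filtered_ch{i}"] = len(kept)
                manifest.counts[f"maxima_ch{i}"] = len(pts)
            manifest.wall_time_s[stage] = time.perf_counter() - t0

        if "snr" in config.stages:
            stage = "snr"
            t0 = time.perf_counter()
            snr_summaries = []
            for i, kept in enumerate(filtered_per_ch, start=1):
                centers = [o.peak_location for o in kept]
                retained_idx = snr.exclude_overlapping(
                    centers, config.disk_geometry, kept,
                    corrected[i - 1].shape,
                )
                rows, measurements = [], []
                dropped_degenerate = 0
                for rank, j in enumerate(retained_idx):
                    try:
                        m = snr.measure_snr(corrected[i - 1], centers[j],
                                            config.disk_geometry,
                                            signal_id=kept[j].label)
                    except ValueError:
                        dropped_degenerate += 1
                        continue
                    measurements.append(m)
                    rows.append({
                        "signal_id": m.signal_id,
                        "row": centers[j][0], "col": centers[j][1],
                        "peak": m.peak_intensity, "local_sd": m.local_sd,
                        "r": m.ratio_r, "snr_db": m.snr_db,
                    })
                pd.DataFrame(rows).to_csv(out / f"snr_ch{i}.csv", index=False)
                summary = snr.summarize_intensity(measurements) \
                    if measurements else {"n": 0}
                summary["dropped_degenerate"] = dropped_degenerate
                snr_summaries.append(summary)
                manifest.counts[f"snr_retained_ch{i}"] = len(measurements)
            (out / "snr_summary.json").write_text(
                json.dumps(snr_summaries, indent=2))
            manifest.results["snr"] = snr_summaries
            manifest.wall_time_s[stage] = time.perf_counter() - t0

        if "integrity" in config.stages:
            stage = "integrity"
            t0 = time.perf_counter()
            merged = detect.ColoredPointSet.merge(*points_per_ch)
            obs = integrity.same_color_frequency(merged)
            counts = (len(points_per_ch[0]), len(points_per_ch[1]))
            mc_seed = int(rng.integers(0, 2**31 - 1))
            manifest.seed_chain["monte_carlo"] = mc_seed
            null = integrity.monte_carlo_null(
                counts, merged.image_shape, config.mc_replicates, mc_seed)
            report = integrity.integrity_test([obs], [null])
            (out / "integrity.json").write_text(json.dumps(report, indent=2))
            manifest.results["integrity"] = report
            manifest.wall_time_s[stage] = time.perf_counter() - t0

        if "coloc" in config.stages:
            stage = "coloc"
            t0 = time.perf_counter()
            thr = config.binarization_threshold
            if thr is None:
                thr = thresholds[0].threshold
            res = coloc.pixel_overlap(corrected[0], corrected[1],
                                      binarization_threshold=thr,
                                      smoothing_sigma_px=config.smoothing_sigma_px)
            payload = {
                "n_intersection_px": res.n_intersection_px,
                "n_union_px": res.n_union_px,
                "overlap_fraction": res.overlap_fraction,
                "threshold": res.threshold,
                "empty_union": res.empty_union,
            }
            (out / "overlap.json").write_text(json.dumps(payload, indent=2))
            manifest.results["coloc"] = payload
            manifest.wall_time_s[stage] = time.perf_counter() - t0
    except Exception:
        manifest.failed_stage = stage
        manifest.write(out / "manifest.json")
        (out / "FAILED").write_text(stage)
        raise

    manifest.write(out / "manifest.json")
    return manifest
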