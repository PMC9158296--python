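"""End-to-end orchestration: simulate -> measure -> sweep -> icc.

Every stage writes plain-text artifacts (CSV/JSON) into an output directory,
plus a config snapshot with all defaults materialised so a run is fully
reproducible from the snapshot alone.  A single seed drives every source of
randomness: the cohort simulation streams are split from it deterministically
and the ICC bootstrap reuses it directly.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Iterable, Optional

from . import geometry, landmarks_io, reliability, sweep as sweep_mod
from .simulator import CohortConfig, GroundTruth, simulate_cohort


def write_ground_truth(truth: GroundTruth, path: Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["specimen_id", "true_offset_mm", "theta0_deg"])
        for sid in sorted(truth.true_offset_mm):
            writer.writerow([sid, repr(truth.true_offset_mm[sid]),
                             repr(truth.theta0_deg[sid])])


def write_measurements(measurements: Iterable[geometry.OffsetMeasurement],
                       path: Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["specimen_id", "image_id", "rotation_deg",
                         "offset_mm", "mm_per_px"])
        for m in measurements:
            writer.writerow([m.specimen_id, m.image_id, repr(m.rotation_deg),
                             repr(m.offset_mm), repr(m.calibration.mm_per_px)])


def write_sweeps(sweeps: Iterable[sweep_mod.SpecimenSweep], path: Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["specimen_id", "rotation_deg", "offset_mm"])
        for s in sweeps:
            for angle in sorted(s.curve):
                writer.writerow([s.specimen_id, repr(angle), repr(s.curve[angle])])


def _write_json(obj, path: Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    config: CohortConfig,
    out_dir: str | Path,
    rounds_policy: sweep_mod.RoundsPolicy = "mean_of_rounds",
    n_boot: int = 2000,
) -> dict:
    """Run the full pipeline and write all artifacts under ``out_dir``.

    Returns a summary dict (also written as JSON).  With fewer than two
    measurement rounds the ICC is undefined and reported as null.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    snapshot = {
        "config": dataclasses.asdict(config),
        "rounds_policy": rounds_policy,
        "n_boot": n_boot,
    }
    snapshot["config"]["angle_grid_deg"] = list(config.angle_grid_deg)
    _write_json(snapshot, out / "config_snapshot.json")

    sets, truth = simulate_cohort(config)
    landmarks_io.write_landmarks(sets, out / "landmarks.csv", "csv")
    write_ground_truth(truth, out / "ground_truth.csv")

    measurements = geometry.measure_all(sets)
    write_measurements(measurements, out / "measurements.csv")

    sweeps = sweep_mod.analyze_cohort(measurements, rounds_policy)
    write_sweeps(sweeps, out / "sweeps.csv")
    summary = sweep_mod.summarize_cohort(sweeps)
    _write_json(summary.to_dict(), out / "cohort_summary.json")

    if config.n_rater_rounds >= 2:
        table, _ = reliability.ratings_from_measurements(measurements)
        icc = reliability.icc_bootstrap(table, n_boot=n_boot, seed=config.seed)
        icc_payload = icc.to_dict()
    else:
        icc_payload = {"icc": None,
                       "reason": "ICC undefined with a single measurement round"}
    _write_json(icc_payload, out / "icc.json")

    result = {
        "cohort_summary": summary.to_dict(),
        "icc": icc_payload,
        "n_images": len({(m.specimen_id, m.image_id) for m in measurements}),
    }
    _write_json(result, out / "pipeline_summary.json")
    return result


def load_config(path: Optional[str | Path] = None, seed: Optional[int] = None,
                **overrides) -> CohortConfig:
    """Build a CohortConfig from an optional JSON file plus overrides."""
    params: dict = {}
    if path is not None:
        with Path(path).open(encoding="utf-8") as fh:
            params.update(json.load(fh))
    params.update({k: v for k, v in overrides.items() if v is not None})
    if seed is not None:
        params["seed"] = seed
    if "angle_grid_deg" in params:
        params["angle_grid_deg"] = tuple(float(a) for a in params["angle_grid_deg"])
    return CohortConfig(**params)
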