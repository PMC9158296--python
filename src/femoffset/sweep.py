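"""Rotation-sweep analysis: per-specimen offset curves and cohort statistics.

The operational definitions follow the bench protocol:

* **true offset** — maximum measured offset over all imaged rotations;
* **aligned offset** — offset measured at actuator zero (trochanteric lines
  radiographically superimposed);
* **underestimation** — true minus aligned, also expressed as a percentage of
  the true offset;
* **rotation at maximum** — grid angle at which the maximum occurred
  (negative = external rotation);
* **range +/-10** — spread of the curve over the closed interval
  [-10, +10] degrees.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence, Union

import numpy as np

from .errors import ValidationError
from .geometry import OffsetMeasurement

RoundsPolicy = Literal["mean_of_rounds", "per_round"]

#: summary metrics reported per specimen and aggregated over the cohort
SWEEP_METRICS = (
    "true_offset_mm",
    "aligned_offset_mm",
    "underestimation_mm",
    "underestimation_pct",
    "rotation_at_max_deg",
    "range_pm10_mm",
)


@dataclass(frozen=True)
class SpecimenSweep:
    """One specimen's offset-vs-rotation curve and its derived quantities."""

    specimen_id: str
    curve: Mapping[float, float]  # rotation_deg -> offset_mm
    true_offset_mm: float
    aligned_offset_mm: float
    underestimation_mm: float
    underestimation_pct: float
    rotation_at_max_deg: float
    range_pm10_mm: float
    max_tied: bool = False
    round_id: Optional[int] = None

    @staticmethod
    def from_curve(
        specimen_id: str,
        curve: Mapping[float, float],
        round_id: Optional[int] = None,
    ) -> "SpecimenSweep":
        """Derive the sweep quantities from an offset curve.

        The curve must include the aligned neutral (0 degrees).  Ties for the
        maximum are broken toward the smallest rotation magnitude, then toward
        internal (positive) rotation, and flagged.
        """
        curve = {float(a): float(v) for a, v in curve.items()}
        if 0.0 not in curve:
            raise ValidationError(
                f"specimen {specimen_id!r}: curve lacks the 0-degree aligned "
                "position; aligned offset undefined"
            )
        angles = np.array(sorted(curve))
        values = np.array([curve[a] for a in angles])
        vmax = values.max()
        tied = angles[values == vmax]
        rotation_at_max = float(min(tied, key=lambda a: (abs(a), -a)))
        aligned = curve[0.0]
        under = vmax - aligned
        in_window = (angles >= -10.0) & (angles <= 10.0)
        window = values[in_window]
        return SpecimenSweep(
            specimen_id=specimen_id,
            curve=dict(zip(angles.tolist(), values.tolist())),
            true_offset_mm=float(vmax),
            aligned_offset_mm=float(aligned),
            underestimation_mm=float(under),
            underestimation_pct=float(100.0 * under / vmax) if vmax > 0 else 0.0,
            rotation_at_max_deg=rotation_at_max,
            range_pm10_mm=float(window.max() - window.min()) if window.size else math.nan,
            max_tied=len(tied) > 1,
            round_id=round_id,
        )


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level descriptive statistics of the sweep quantities.

    ``stats`` maps each metric in :data:`SWEEP_METRICS` to
    ``{mean, sd, median, min, max}`` (sample sd, n-1 denominator; ``None``
    for n < 2).  ``rotation_at_max_hist`` counts specimens per grid angle.
    """

    n_specimens: int
    stats: Mapping[str, Mapping[str, Optional[float]]]
    rotation_at_max_hist: Mapping[float, int]

    def to_dict(self) -> dict:
        return {
            "n_specimens": self.n_specimens,
            "stats": {m: dict(s) for m, s in self.stats.items()},
            "rotation_at_max_hist": {repr(a): c for a, c in
                                     sorted(self.rotation_at_max_hist.items())},
        }


def _describe(values: Sequence[float]) -> dict[str, Optional[float]]:
    arr = np.asarray(values, dtype=float)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size >= 2 else None,
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def _curves_by_round(
    measurements: Sequence[OffsetMeasurement],
) -> tuple[str, dict[int, dict[float, float]]]:
    """Group one specimen's measurements into per-round offset curves.

    Multiple measurements of the same angle are interpreted as measurement
    rounds; round indices follow the sorted order of the image ids, so rounds
    pair consistently across angles when image ids encode the round (as the
    simulator's ``..._r<k>`` ids do).
    """
    specimens = {m.specimen_id for m in measurements}
    if len(specimens) != 1:
        raise ValidationError(f"expected one specimen, got {sorted(specimens)}")
    specimen_id = specimens.pop()
    per_angle: dict[float, list[OffsetMeasurement]] = {}
    for m in measurements:
        angle = float(m.rotation_deg)
        if any(prev.image_id == m.image_id for prev in per_angle.get(angle, ())):
            raise ValidationError(
                f"specimen {specimen_id!r}: duplicate measurement for angle "
                f"{angle} (image id {m.image_id!r})"
            )
        per_angle.setdefault(angle, []).append(m)
    n_rounds = {len(v) for v in per_angle.values()}
    if len(n_rounds) != 1:
        raise ValidationError(
            f"specimen {specimen_id!r}: rounds do not cover the same angle grid "
            f"(counts per angle: { {a: len(v) for a, v in sorted(per_angle.items())} })"
        )
    curves: dict[int, dict[float, float]] = {}
    for angle, ms in per_angle.items():
        for r, m in enumerate(sorted(ms, key=lambda m: m.image_id)):
            curves.setdefault(r, {})[angle] = m.offset_mm
    return specimen_id, curves


def analyze_specimen(
    measurements: Sequence[OffsetMeasurement],
    rounds_policy: RoundsPolicy = "mean_of_rounds",
) -> Union[SpecimenSweep, list[SpecimenSweep]]:
    """Build the rotation sweep for one specimen.

    Under ``mean_of_rounds`` (default) the rounds are averaged angle-by-angle
    before maximisation and a single :class:`SpecimenSweep` is returned; under
    ``per_round`` one sweep per measurement round is returned.
    """
    if not measurements:
        raise ValidationError("no measurements supplied")
    specimen_id, curves = _curves_by_round(measurements)
    if rounds_policy == "mean_of_rounds":
        angles = curves[0].keys()
        mean_curve = {
            a: float(np.mean([curves[r][a] for r in curves])) for a in angles
        }
        return SpecimenSweep.from_curve(specimen_id, mean_curve)
    if rounds_policy == "per_round":
        return [
            SpecimenSweep.from_curve(specimen_id, curve, round_id=r)
            for r, curve in sorted(curves.items())
        ]
    raise ValidationError(f"unknown rounds policy {rounds_policy!r}")


def analyze_cohort(
    measurements: Iterable[OffsetMeasurement],
    rounds_policy: RoundsPolicy = "mean_of_rounds",
) -> list[SpecimenSweep]:
    """Per-specimen sweeps for a whole cohort of measurements."""
    by_specimen: dict[str, list[OffsetMeasurement]] = {}
    for m in measurements:
        by_specimen.setdefault(m.specimen_id, []).append(m)
    sweeps: list[SpecimenSweep] = []
    for specimen_id in sorted(by_specimen):
        result = analyze_specimen(by_specimen[specimen_id], rounds_policy)
        sweeps.extend(result if isinstance(result, list) else [result])
    return sweeps


def summarize_cohort(sweeps: Sequence[SpecimenSweep]) -> CohortSummary:
    """Descriptive statistics (mean, sample sd, median, min, max) per metric."""
    if not sweeps:
        raise ValidationError("no sweeps supplied")
    stats = {
        metric: _describe([getattr(s, metric) for s in sweeps])
        for metric in SWEEP_METRICS
    }
    hist = Counter(s.rotation_at_max_deg for s in sweeps)
    return CohortSummary(
        n_specimens=len(sweeps),
        stats=stats,
        rotation_at_max_hist=dict(hist),
    )


def underestimation_from_means(
    mean_true_mm: float, mean_aligned_mm: float
) -> tuple[float, float]:
    """Cohort-mean underestimation (mm, %) from cohort-mean true and aligned
    offsets.  Valid because the mean of per-specimen differences equals the
    difference of means."""
    if mean_true_mm <= 0:
        raise ValidationError("mean true offset must be positive")
    under = mean_true_mm - mean_aligned_mm
    return under, 100.0 * under / mean_true_mm
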