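"""Synthetic fluoroscopic projections of a parametric proximal femur.

The simulator emulates the bench setup the measurement method was designed
for: an isolated proximal femur rotated about its shaft axis in front of a
fluoroscope whose beam is perpendicular to that axis, with a 1-inch metal
sphere in the plane of the bone for scale.  Projection is orthographic
(parallel beam): the in-plane sphere calibration is exactly the
parallel-projection idealisation, so cone-beam magnification is deliberately
out of scope.

Geometry.  Put the shaft axis along the vertical image axis.  The head centre
sits at 3-D perpendicular distance ``R`` (the true offset) from the shaft
axis; when the femur is rotated to the nominal actuator angle ``theta`` the
head-offset vector makes angle ``theta - theta0`` with the image plane, so its
projected horizontal distance from the axis is ``R * |cos(theta - theta0)|``.
``theta0`` is the angular discrepancy between the radiographically *aligned*
neutral (trochanteric lines superimposed, actuator zero) and the rotation that
reveals the full offset; external rotation is negative.  Under orthographic
projection the shaft cylinder's silhouette half-width is constant in theta, so
the cortical border lines never move; the head circle keeps the head radius
(it is a sphere).

Two trochanteric surface points generate the radiographic alignment lines:
by construction they project to the same horizontal coordinate at actuator
zero (lines superimposed) and separate as the femur rotates.  Their exact 3-D
placement is a free parameter of the model — the bench study located the
source surfaces anatomically but did not quantify their geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .landmarks_io import CANONICAL_COUNTS, LandmarkPoint, LandmarkSet

#: angle grid used on the bench: 2-degree steps over +/-10, plus +/-30
DEFAULT_ANGLE_GRID = (-30.0, -10.0, -8.0, -6.0, -4.0, -2.0, 0.0,
                      2.0, 4.0, 6.0, 8.0, 10.0, 30.0)


@dataclass(frozen=True)
class FemurModel3D:
    """Parametric proximal femur for orthographic projection.

    ``offset_plane_deg`` (theta0) is the rotation, relative to the aligned
    neutral, at which the head-offset plane is parallel to the image plane and
    the projected offset is maximal; negative = external rotation.  The
    trochanteric points are given in cylindrical coordinates about the shaft
    axis as (radius_mm, azimuth_deg, height_mm); ``__post_init__`` re-derives
    the posterior radius so both project to the same horizontal coordinate at
    actuator zero.
    """

    true_offset_mm: float
    offset_plane_deg: float
    shaft_radius_mm: float = 15.0
    shaft_length_mm: float = 120.0
    head_radius_mm: float = 22.0
    troch_anterior: tuple[float, float, float] = (21.0, 40.0, 35.0)
    troch_posterior: tuple[float, float, float] = (17.0, -25.0, 30.0)

    def __post_init__(self) -> None:
        if self.true_offset_mm <= 0:
            raise ValidationError("true_offset_mm must be positive")
        if min(self.shaft_radius_mm, self.head_radius_mm, self.shaft_length_mm) <= 0:
            raise ValidationError("femur dimensions must be positive")
        r_a, az_a, z_a = self.troch_anterior
        _, az_p, z_p = self.troch_posterior
        ca, cp = math.cos(math.radians(az_a)), math.cos(math.radians(az_p))
        if abs(cp) < 1e-9:
            raise ValidationError("posterior trochanteric azimuth too close to 90 degrees")
        # superimposed lines at actuator zero: equal projected x by construction
        object.__setattr__(self, "troch_posterior", (r_a * ca / cp, az_p, z_p))

    def projected_offset_mm(self, rotation_deg: float) -> float:
        """Noiseless projected offset R*|cos(theta - theta0)| at the given angle."""
        return self.true_offset_mm * abs(
            math.cos(math.radians(rotation_deg - self.offset_plane_deg))
        )

    def trochanter_projected_x_mm(self, rotation_deg: float) -> tuple[float, float]:
        """Projected horizontal coordinates (mm, relative to the shaft axis)
        of the anterior and posterior trochanteric line sources."""
        out = []
        for r, az, _ in (self.troch_anterior, self.troch_posterior):
            out.append(r * math.cos(math.radians(az + rotation_deg)))
        return out[0], out[1]


@dataclass(frozen=True)
class ImageTruth:
    """Noiseless ground truth recorded alongside one projected LandmarkSet."""

    specimen_id: str
    image_id: str
    rotation_deg: float
    noiseless_offset_mm: float
    troch_anterior_x_px: float
    troch_posterior_x_px: float


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a simulated specimen cohort.

    Defaults mirror the bench study: 11 specimens, true offsets
    N(38.2, 4.9) mm truncated positive, aligned-vs-true angular discrepancy
    N(-3.6, 5.6) degrees, the 13-angle grid, three measurement rounds, and
    0.5 px isotropic annotation noise at 0.25 mm/px detector scale.
    """

    n_specimens: int = 11
    offset_mean_mm: float = 38.2
    offset_sd_mm: float = 4.9
    theta0_mean_deg: float = -3.6
    theta0_sd_deg: float = 5.6
    angle_grid_deg: tuple[float, ...] = DEFAULT_ANGLE_GRID
    landmark_noise_sd_px: float = 0.5
    mm_per_px_true: float = 0.25
    n_rater_rounds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise ValidationError("n_specimens must be >= 1")
        if self.offset_sd_mm < 0 or self.theta0_sd_deg < 0 or self.landmark_noise_sd_px < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.mm_per_px_true <= 0:
            raise ValidationError("mm_per_px_true must be positive")
        if self.n_rater_rounds < 1:
            raise ValidationError("n_rater_rounds must be >= 1")
        grid = tuple(float(a) for a in self.angle_grid_deg)
        if 0.0 not in grid:
            raise ValidationError("angle grid must contain 0 (the aligned neutral)")
        object.__setattr__(self, "angle_grid_deg", grid)


@dataclass(frozen=True)
class GroundTruth:
    """Per-specimen parameters and per-image noiseless offsets for a cohort."""

    true_offset_mm: dict[str, float]
    theta0_deg: dict[str, float]
    images: tuple[ImageTruth, ...]


# image layout (pixels are converted with mm_per_px_true)
_AXIS_X_MM = 100.0
_HEAD_Y_MM = 40.0
_SHAFT_Y_SPAN_MM = (80.0, 180.0)
_SPHERE_CENTER_MM = (25.0, 25.0)
_TROCH_Y_MM = 70.0


def project(
    model: FemurModel3D,
    rotation_deg: float,
    noise_sd_px: float = 0.0,
    mm_per_px_true: float = 0.25,
    rng: Optional[np.random.Generator] = None,
    specimen_id: str = "S00",
    image_id: Optional[str] = None,
) -> tuple[LandmarkSet, ImageTruth]:
    """Project the femur orthographically at one actuator angle.

    Emits the canonical landmark counts (5 medial + 5 lateral cortical points,
    6 head points, 5 calibration-sphere points), each perturbed by isotropic
    Gaussian pixel noise of standard deviation ``noise_sd_px``.  The paired
    :class:`ImageTruth` records the noiseless projected offset and the
    projected positions of the two trochanteric line sources.
    """
    if noise_sd_px < 0:
        raise ValidationError("noise_sd_px must be >= 0")
    if mm_per_px_true <= 0:
        raise ValidationError("mm_per_px_true must be positive")
    if noise_sd_px > 0 and rng is None:
        raise ValidationError("a numpy Generator is required when noise_sd_px > 0")
    if image_id is None:
        image_id = f"ang{rotation_deg:+06.1f}"
    s = mm_per_px_true

    blocks: list[tuple[str, np.ndarray]] = []
    ys = np.linspace(*_SHAFT_Y_SPAN_MM, CANONICAL_COUNTS["medial_cortex"])
    medial_x = (_AXIS_X_MM - model.shaft_radius_mm) / s
    lateral_x = (_AXIS_X_MM + model.shaft_radius_mm) / s
    blocks.append(("medial_cortex",
                   np.column_stack([np.full_like(ys, medial_x), ys / s])))
    blocks.append(("lateral_cortex",
                   np.column_stack([np.full_like(ys, lateral_x), ys / s])))

    head_dx = model.true_offset_mm * math.cos(
        math.radians(rotation_deg - model.offset_plane_deg)
    )
    head_center = np.array([(_AXIS_X_MM + head_dx) / s, _HEAD_Y_MM / s])
    ang = np.radians(np.arange(CANONICAL_COUNTS["head"]) * 360.0 / CANONICAL_COUNTS["head"])
    blocks.append(("head",
                   head_center + (model.head_radius_mm / s)
                   * np.column_stack([np.cos(ang), np.sin(ang)])))

    sphere_center = np.array(_SPHERE_CENTER_MM) / s
    n_cal = CANONICAL_COUNTS["calibration"]
    ang = np.radians(np.arange(n_cal) * 360.0 / n_cal + 18.0)
    blocks.append(("calibration",
                   sphere_center + (12.7 / s)
                   * np.column_stack([np.cos(ang), np.sin(ang)])))

    points: list[LandmarkPoint] = []
    for role, xy in blocks:
        if noise_sd_px > 0:
            xy = xy + rng.normal(0.0, noise_sd_px, size=xy.shape)
        for x, y in xy:
            points.append(LandmarkPoint(specimen_id, image_id, rotation_deg,
                                        role, float(x), float(y)))
    landmark_set = LandmarkSet(specimen_id, image_id, rotation_deg, tuple(points))

    ax, px = model.trochanter_projected_x_mm(rotation_deg)
    truth = ImageTruth(
        specimen_id=specimen_id,
        image_id=image_id,
        rotation_deg=rotation_deg,
        noiseless_offset_mm=model.projected_offset_mm(rotation_deg),
        troch_anterior_x_px=(_AXIS_X_MM + ax) / s,
        troch_posterior_x_px=(_AXIS_X_MM + px) / s,
    )
    return landmark_set, truth


def _specimen_rng(seed: int, specimen: int, *key: int) -> np.random.Generator:
    """Counter-based stream: specimen i's draws are independent of cohort size."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(specimen, *key))
    )


def draw_specimen_model(config: CohortConfig, specimen: int) -> FemurModel3D:
    """Draw one specimen's true offset and offset-plane angle."""
    rng = _specimen_rng(config.seed, specimen)
    offset = rng.normal(config.offset_mean_mm, config.offset_sd_mm)
    while offset <= 0:  # truncate at zero by resampling
        offset = rng.normal(config.offset_mean_mm, config.offset_sd_mm)
    theta0 = rng.normal(config.theta0_mean_deg, config.theta0_sd_deg)
    return FemurModel3D(true_offset_mm=float(offset), offset_plane_deg=float(theta0))


def simulate_cohort(config: CohortConfig) -> tuple[list[LandmarkSet], GroundTruth]:
    """Simulate a full cohort: specimens x angle grid x measurement rounds.

    Each round re-noises the landmarks independently, modelling the rater
    re-annotating the same stored radiograph.  Output is a deterministic
    function of ``config`` (including its seed).
    """
    sets: list[LandmarkSet] = []
    true_offsets: dict[str, float] = {}
    theta0s: dict[str, float] = {}
    image_truths: list[ImageTruth] = []
    width = max(2, len(str(config.n_specimens)))
    for i in range(config.n_specimens):
        specimen_id = f"S{i + 1:0{width}d}"
        model = draw_specimen_model(config, i)
        true_offsets[specimen_id] = model.true_offset_mm
        theta0s[specimen_id] = model.offset_plane_deg
        for j, angle in enumerate(config.angle_grid_deg):
            for r in range(config.n_rater_rounds):
                rng = _specimen_rng(config.seed, i, j, r)
                lm, truth = project(
                    model,
                    angle,
                    noise_sd_px=config.landmark_noise_sd_px,
                    mm_per_px_true=config.mm_per_px_true,
                    rng=rng,
                    specimen_id=specimen_id,
                    image_id=f"ang{angle:+06.1f}_r{r}",
                )
                sets.append(lm)
                if r == 0:
                    image_truths.append(truth)
    return sets, GroundTruth(
        true_offset_mm=true_offsets,
        theta0_deg=theta0s,
        images=tuple(image_truths),
    )
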