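"""Intrarater reliability: ICC(2,1) with a nonparametric bootstrap CI.

The repeatability of the offset measurements is summarised with the
intraclass correlation coefficient under a two-way random-effects model,
single measures, absolute agreement — commonly written ICC(2,1) or ICC(A,1).
Subjects (rows) are the measured quantities (e.g. one offset per
specimen-and-angle image) and columns are the measurement rounds of the
single rater.

With MSR, MSC and MSE the subject, round and residual mean squares of the
two-way ANOVA decomposition, n subjects and k rounds:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

Confidence intervals are percentile bootstrap over subjects: whole rows are
resampled with replacement so a subject's rounds stay paired, the ICC is
recomputed per replicate, and the 2.5/97.5 percentiles are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError

#: agreement bands used to interpret the point estimate
BAND_POOR_BELOW = 0.40
BAND_EXCELLENT_ABOVE = 0.75

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class RatingsTable:
    """Complete n-subjects x k-rounds matrix of measurements."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValidationError(f"ratings must be a 2-D matrix, got shape {arr.shape}")
        n, k = arr.shape
        if n < 2 or k < 2:
            raise ValidationError(f"need >= 2 subjects and >= 2 rounds, got {n}x{k}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("ratings table contains missing or non-finite cells")
        object.__setattr__(self, "values", arr)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rounds(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1) point estimate, optional bootstrap CI and ANOVA components."""

    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    band: str
    degenerate: bool = False
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_boot: Optional[int] = None
    seed: Optional[int] = None
    estimate_outside_ci: bool = False

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "ms_rows": self.ms_rows,
            "ms_cols": self.ms_cols,
            "ms_error": self.ms_error,
            "band": self.band,
            "degenerate": self.degenerate,
            "estimate_outside_ci": self.estimate_outside_ci,
        }


def band_for(icc: float) -> str:
    """Interpretation band: poor < 0.40 <= fair_to_good <= 0.75 < excellent.

    The published cut-offs use strict inequalities on both sides, leaving the
    boundary values unassigned; both boundaries are mapped to fair_to_good.
    """
    if icc < BAND_POOR_BELOW:
        return "poor"
    if icc > BAND_EXCELLENT_ABOVE:
        return "excellent"
    return "fair_to_good"


def _icc_from_matrix(arr: np.ndarray) -> tuple[float, float, float, float, bool]:
    n, k = arr.shape
    if np.all(arr == arr[:, :1]):
        # every subject's rounds are identical: perfect agreement, exactly.
        # (computing the mean squares would leave ICC at 1 - O(eps) because
        # mean(x, x, x) need not equal x in floating point)
        row_var = float(np.var(arr[:, 0], ddof=1))
        return 1.0, k * row_var, 0.0, 0.0, row_var == 0.0
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((arr - grand) ** 2))
    # the residual SS is non-negative by construction; clip the float noise
    # of the subtraction so a perfect-agreement table cannot yield ICC > 1
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ss_total <= _DEGENERATE_TOL * max(1.0, grand**2):
        # all cells (numerically) equal: perfect agreement by convention
        return 1.0, ms_rows, ms_cols, ms_err, True
    denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    if denom == 0:
        return 1.0, ms_rows, ms_cols, ms_err, True
    return (ms_rows - ms_err) / denom, ms_rows, ms_cols, ms_err, False


def icc_2_1(table: RatingsTable) -> ICCResult:
    """Point estimate of ICC(2,1) with its ANOVA mean squares (no CI).

    Negative estimates are reported as computed; an all-equal table is defined
    as perfect agreement (ICC = 1) and flagged degenerate.
    """
    icc, msr, msc, mse, degenerate = _icc_from_matrix(table.values)
    return ICCResult(
        icc=float(icc),
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
        band=band_for(float(icc)),
        degenerate=degenerate,
    )


def icc_bootstrap(
    table: RatingsTable,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> ICCResult:
    """ICC(2,1) with a nonparametric 95% percentile bootstrap CI.

    Resamples subjects (rows) with replacement, keeping each subject's rounds
    together.  Deterministic for a fixed seed.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100 for a percentile CI")
    if seed is None:
        raise ValidationError("an explicit seed is required for reported CIs")
    point = icc_2_1(table)
    rng = np.random.default_rng(seed)
    n = table.n_subjects
    replicates = np.empty(n_boot)
    idx = rng.integers(0, n, size=(n_boot, n))
    for b in range(n_boot):
        replicates[b] = _icc_from_matrix(table.values[idx[b]])[0]
    lo, hi = np.percentile(replicates, [2.5, 97.5])
    outside = not (lo <= point.icc <= hi)
    return ICCResult(
        icc=point.icc,
        ms_rows=point.ms_rows,
        ms_cols=point.ms_cols,
        ms_error=point.ms_error,
        band=point.band,
        degenerate=point.degenerate,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        estimate_outside_ci=outside,
    )


def ratings_from_measurements(measurements) -> tuple[RatingsTable, list[tuple[str, float]]]:
    """Arrange per-image offset measurements into a subjects x rounds table.

    Subjects are (specimen_id, rotation_deg) images; rounds are the repeated
    measurements of each image, paired by sorted image id.  Returns the table
    and the subject labels in row order.
    """
    cells: dict[tuple[str, float], list[tuple[str, float]]] = {}
    for m in measurements:
        key = (m.specimen_id, float(m.rotation_deg))
        cells.setdefault(key, []).append((m.image_id, m.offset_mm))
    subjects = sorted(cells)
    counts = {len(v) for v in cells.values()}
    if len(counts) != 1:
        raise ValidationError("unequal numbers of rounds across images")
    matrix = np.array(
        [[v for _, v in sorted(cells[s])] for s in subjects], dtype=float
    )
    return RatingsTable(matrix), subjects
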