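"""Accuracy metrics and theory comparisons.

Two metrics quantify how well a learned equation tracks ground truth:

* ``epsilon = 1 - Er(T)/Rn(T)`` where ``Er`` is the sum over test points
  in the test interval T of the pointwise relative speed error
  ``|GT - TH| / GT`` and ``Rn = max(T) - min(T)`` is the interval width
  (read literally as the time-interval width; an alternative reading —
  the ground-truth value range — sits behind a flag).  Because Er is a
  raw sum, epsilon depends on the test-point density, so the test grid is
  fixed by configuration (default: the processed-stream grid).
* the time-normalised squared error ``L3 / gamma_t``: the trapezoidal
  time integral of the squared speed difference divided by the spanned
  dimensionless time, making it grid-resolution independent.

``compare_theories`` tabulates the normalised metric for the classical
equation (zero parameters), the inertial two-harmonic correction (betas
derived from the learned lambda1), and the fully learned equation, plus
the improvement ratio of learned over classical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import (
    EquationParams,
    OblateGeometry,
    joe_speed,
    ljoe_speed,
    mjoe_betas_from_lambda1,
    mjoe_speed,
)
from .learner import BIOLRegressor
from .preprocess import FilterConfig, preprocess_series
from .synthetic import GroundTruthSeries

__all__ = [
    "TestInterval",
    "AccuracyReport",
    "accuracy_epsilon",
    "normalized_l3",
    "compare_theories",
    "hyperparameter_search",
]


@dataclass(frozen=True)
class TestInterval:
    """Dimensionless-time evaluation interval with width Rn = end - start."""

    start: float
    end: float

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError(f"need end > start, got [{self.start}, {self.end}]")

    @property
    def width(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class AccuracyReport:
    epsilon: float
    relative_error_sum: float
    interval: TestInterval
    n_points: int


def accuracy_epsilon(
    times,
    phi_dot_gt,
    phi_dot_th,
    interval: TestInterval,
    range_normalisation: str = "time",
) -> AccuracyReport:
    """Prediction accuracy epsilon = 1 - Er/Rn over a test interval.

    Test points with exactly zero ground-truth speed are excluded with a
    warning (division guard).  ``range_normalisation`` selects the Rn
    reading: ``"time"`` (interval width, default) or ``"value"``
    (ground-truth speed range over the interval).
    """
    times = np.asarray(times, dtype=float)
    gt = np.asarray(phi_dot_gt, dtype=float)
    th = np.asarray(phi_dot_th, dtype=float)
    mask = (times >= interval.start) & (times <= interval.end)
    gt, th = gt[mask], th[mask]
    nonzero = gt != 0.0
    if not np.all(nonzero):
        warnings.warn(
            f"excluded {np.count_nonzero(~nonzero)} test points with zero "
            "ground-truth speed"
        )
        gt, th = gt[nonzero], th[nonzero]
    er = float(np.sum(np.abs(gt - th) / gt))
    if range_normalisation == "value":
        rn = float(np.max(gt) - np.min(gt))
    else:
        rn = interval.width
    return AccuracyReport(
        epsilon=1.0 - er / rn,
        relative_error_sum=er,
        interval=interval,
        n_points=int(gt.size),
    )


def normalized_l3(times, phi_dot_gt, phi_dot_th, total_time: float | None = None):
    """Time-averaged squared speed error: trapezoidal integral of
    (GT - TH)^2 over time divided by the spanned dimensionless time."""
    times = np.asarray(times, dtype=float)
    gt = np.asarray(phi_dot_gt, dtype=float)
    th = np.asarray(phi_dot_th, dtype=float)
    span = total_time if total_time is not None else float(times[-1] - times[0])
    if span <= 0:
        raise ValueError(f"time span must be positive, got {span}")
    return float(np.trapezoid((gt - th) ** 2, times)) / span


def compare_theories(
    ground_truth: GroundTruthSeries,
    learned: EquationParams | None,
    geometry: OblateGeometry,
) -> pd.DataFrame:
    """Normalised-error table for the three theories against one series.

    Rows: classical (JOE, zero parameters), inertial correction (M-JOE
    with betas derived from the learned lambda1), and the learned
    equation (L-JOE).  The improvement row reports
    (JOE - LJOE)/LJOE as a percentage.  Without learned parameters only
    the classical row is produced.
    """
    frame = ground_truth.samples
    t = frame["gamma_t"].to_numpy(dtype=float)
    phi = frame["phi"].to_numpy(dtype=float)
    gt_dot = frame["phi_dot"].to_numpy(dtype=float)
    rows = {"JOE": normalized_l3(t, gt_dot, joe_speed(phi, geometry))}
    if learned is not None:
        betas = mjoe_betas_from_lambda1(learned.lambda1, geometry)
        rows["M-JOE"] = normalized_l3(t, gt_dot, mjoe_speed(phi, geometry, betas))
        rows["L-JOE"] = normalized_l3(t, gt_dot, ljoe_speed(phi, geometry, learned))
    table = pd.DataFrame(
        {"normalized_l3": pd.Series(rows)}
    )
    if learned is not None and rows["L-JOE"] > 0:
        table["improvement_pct"] = [
            (rows["JOE"] - rows["L-JOE"]) / rows["L-JOE"] * 100.0
            if name == "L-JOE" else np.nan
            for name in table.index
        ]
    return table


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

#: Default training/test interval setups (dimensionless time).
DEFAULT_SETUPS = (
    ((0.0, 16.0), (16.0, 24.0)),
    ((0.0, 32.0), (32.0, 40.0)),
    ((0.0, 44.0), (44.0, 50.0)),
)


def hyperparameter_search(
    grid,
    processed: pd.DataFrame,
    geometry: OblateGeometry,
    setups=DEFAULT_SETUPS,
    body_type: str = "rigid",
    seed: int = 0,
    **estimator_kwargs,
):
    """Grid search over (stride, series_length, epochs).

    ``grid`` is an iterable of dicts with keys among ``stride``,
    ``series_length``, ``epochs``; each point is scored by the accuracy
    epsilon averaged over the (training, test) interval setups, training
    on the processed stream restricted to each training interval and
    testing on the matching future test interval.  Returns
    ``(best_point, score_table)``; failed runs score as missing and are
    excluded with a warning.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    times = processed["gamma_t"].to_numpy(dtype=float)
    records = []
    for point in grid:
        scores = []
        try:
            for (g0, g1), (t0, t1) in setups:
                train = processed[(times >= g0) & (times <= g1)]
                est = BIOLRegressor(
                    stride=point.get("stride", 0.25),
                    series_length=point.get("series_length", 10),
                    epochs_rigid=point.get("epochs", 200),
                    epochs_deformable=point.get("epochs", 300),
                    body_type=body_type,
                    aspect_ratio=geometry.aspect_ratio,
                    random_state=seed,
                    **estimator_kwargs,
                )
                est.fit(train)
                interval = TestInterval(t0, min(t1, float(times[-1])))
                mask = (times >= interval.start) & (times <= interval.end)
                test = processed[mask]
                report = accuracy_epsilon(
                    test["gamma_t"].to_numpy(dtype=float),
                    test["phi_dot"].to_numpy(dtype=float),
                    est.predict(test["phi_f"].to_numpy(dtype=float)),
                    interval,
                )
                scores.append(report.epsilon)
            mean_eps = float(np.mean(scores))
        except Exception as exc:  # failed run: score as missing
            warnings.warn(f"hyperparameter point {point} failed: {exc}")
            mean_eps = np.nan
        records.append({**point, "mean_accuracy": mean_eps})
    table = pd.DataFrame(records)
    if table["mean_accuracy"].isna().all():
        raise RuntimeError("every hyperparameter point failed")
    best = table.loc[table["mean_accuracy"].idxmax()].to_dict()
    return best, table
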