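"""Five-way activity-intensity-profile classification.

Each fitted participant is assigned exactly one profile by a fixed decision
order:

1. fewer than five log points above the fitted moderate/vigorous breakpoint
   → **non_vigorous** (and the participant is refit with a 2-breakpoint,
   3-segment model, since there is insufficient vigorous activity to model);
2. otherwise, if the model's vigorous-region AUC is at most 70% of the
   empirical vigorous-region AUC → **extremely_active** (the signature of a
   lognormal spike from habitual very-vigorous exercise);
3. otherwise, if the fit's R² is below 0.9 → **outlier**;
4. otherwise **moderately_active** if the angle between the light and
   moderate segment slopes exceeds the unit's angle threshold, else
   **consistent**.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import atan

import numpy as np

from .config import UnitConfig
from .fitting import PiecewiseFit, evaluate_model, fit_breakpoints
from .preprocess import LogPoints

__all__ = [
    "NON_VIGOROUS",
    "CONSISTENT",
    "MODERATELY_ACTIVE",
    "EXTREMELY_ACTIVE",
    "OUTLIER",
    "PROFILE_LABELS",
    "ProfileResult",
    "vigorous_point_count",
    "refit_three_segment",
    "vigorous_auc_ratio",
    "slope_angle_difference",
    "classify",
]

NON_VIGOROUS = "non_vigorous"
CONSISTENT = "consistent"
MODERATELY_ACTIVE = "moderately_active"
EXTREMELY_ACTIVE = "extremely_active"
OUTLIER = "outlier"
PROFILE_LABELS = (NON_VIGOROUS, CONSISTENT, MODERATELY_ACTIVE, EXTREMELY_ACTIVE, OUTLIER)


@dataclass
class ProfileResult:
    """Profile label plus the diagnostics that produced it.

    Diagnostics are populated only for the decision steps that were actually
    evaluated; ``fit`` is the model the label was based on (the 3-segment
    refit for non-vigorous participants, whose R² is then reported).
    """

    label: str
    va_point_count: int
    auc_ratio: float | None
    angle_diff: float | None
    r2: float
    used_three_segment: bool
    fit: PiecewiseFit | None = None
    reason: str | None = None


def vigorous_point_count(points: LogPoints, fit: PiecewiseFit) -> int:
    """Number of log points strictly above the moderate/vigorous breakpoint."""
    if fit.breakpoints.size < 3:
        raise ValueError("vigorous_point_count needs a 4-segment fit")
    return int(np.count_nonzero(points.x > fit.breakpoints[-1]))


def refit_three_segment(points: LogPoints, config: UnitConfig) -> PiecewiseFit:
    """2-breakpoint, 3-segment refit for non-vigorous participants.

    Uses only the first two breakpoint bounds/starts of the unit config.
    """
    return fit_breakpoints(points, config, n_breakpoints=2)


def vigorous_auc_ratio(
    points: LogPoints, fit: PiecewiseFit, scale: str = "linear"
) -> float | None:
    """Model-to-empirical AUC ratio over the vigorous region.

    Both curves are evaluated on the empirical x grid strictly above the
    third breakpoint and integrated by the trapezoidal rule; on the default
    ``"linear"`` scale the integrand is probability (``exp`` of the log
    values), which lets a vigorous-activity spike dominate the empirical
    area.  To blunt single stray tail bins, the highest-x point is excluded
    from *both* curves.  Returns ``None`` when fewer than two points remain
    after the exclusion (the ratio is then undefined and the participant
    cannot be flagged extremely active).
    """
    b3 = fit.breakpoints[-1]
    mask = points.x > b3
    xs = points.x[mask]
    ys = points.y[mask]
    if xs.size < 2:
        return None
    xs, ys = xs[:-1], ys[:-1]  # x is strictly increasing: last point = highest
    if xs.size < 2:
        return None
    model_y = evaluate_model(fit, xs)
    if scale == "linear":
        emp = np.exp(ys)
        mod = np.exp(model_y)
    else:
        emp = ys
        mod = model_y
    auc_emp = float(np.trapezoid(emp, xs))
    auc_mod = float(np.trapezoid(mod, xs))
    if auc_emp == 0.0:
        return None
    return auc_mod / auc_emp


def slope_angle_difference(fit: PiecewiseFit) -> float:
    """|arctan(s2) - arctan(s3)| between light and moderate segment slopes."""
    if fit.slopes.size < 3:
        raise ValueError("slope_angle_difference needs at least 3 segments")
    return abs(atan(fit.slopes[1]) - atan(fit.slopes[2]))


def classify(points: LogPoints, fit: PiecewiseFit, config: UnitConfig) -> ProfileResult:
    """Assign one of the five activity-intensity profiles.

    ``fit`` must be the participant's 4-segment fit; the non-vigorous branch
    refits with 3 segments and reports that refit's R².  A fitting failure
    in the refit marks the participant as an outlier with a reason code
    rather than raising.
    """
    va = vigorous_point_count(points, fit)
    if va < config.min_va_points:
        try:
            refit = refit_three_segment(points, config)
        except Exception as exc:  # degenerate refit: flag, don't crash a cohort
            return ProfileResult(
                label=OUTLIER,
                va_point_count=va,
                auc_ratio=None,
                angle_diff=None,
                r2=fit.r2,
                used_three_segment=False,
                fit=fit,
                reason=f"three-segment refit failed: {exc}",
            )
        return ProfileResult(
            label=NON_VIGOROUS,
            va_point_count=va,
            auc_ratio=None,
            angle_diff=None,
            r2=refit.r2,
            used_three_segment=True,
            fit=refit,
        )
    ratio = vigorous_auc_ratio(points, fit, scale=config.auc_scale)
    if ratio is not None and ratio <= config.auc_ratio_threshold:
        return ProfileResult(
            label=EXTREMELY_ACTIVE,
            va_point_count=va,
            auc_ratio=ratio,
            angle_diff=None,
            r2=fit.r2,
            used_three_segment=False,
            fit=fit,
        )
    if fit.r2 < config.r2_threshold:
        return ProfileResult(
            label=OUTLIER,
            va_point_count=va,
            auc_ratio=ratio,
            angle_diff=None,
            r2=fit.r2,
            used_three_segment=False,
            fit=fit,
        )
    angle = slope_angle_difference(fit)
    label = MODERATELY_ACTIVE if angle > config.angle_threshold else CONSISTENT
    return ProfileResult(
        label=label,
        va_point_count=va,
        auc_ratio=ratio,
        angle_diff=angle,
        r2=fit.r2,
        used_three_segment=False,
        fit=fit,
    )
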