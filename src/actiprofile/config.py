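"""Unit-specific constants and run options.

Everything the pipeline needs to know about an intensity unit lives in a
single immutable :class:`UnitConfig`: histogram bin width, the implausible-
value cap, the tail-outlier gap, the bounds and starting values for the three
breakpoints of the piecewise fit, and the thresholds used by the activity-
intensity-profile classifier.  Two presets are shipped:

``COUNTS``
    Actigraph activity counts per minute.  Breakpoint bounds and starts come
    from the adult cut-point literature (Freedson / Troiano style values).
``MIMS``
    Monitor-Independent Movement Summary units as distributed with the NHANES
    physical activity monitor files.  Bounds and starts are empirically
    derived values; MIMS has no published criterion cut-points.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class UnitConfig:
    """Constants for one intensity unit plus run-level fitting options.

    Parameters
    ----------
    unit_name:
        ``"counts"`` (Actigraph counts/min) or ``"mims"`` (MIMS units/min).
    bin_width:
        Histogram bin width in intensity units.
    implausible_cap:
        Minutes with intensity strictly above this value are discarded as
        physically implausible; ``None`` disables the cap.
    tail_gap:
        A non-zero histogram bin with no other non-zero bin within this
        distance is a tail outlier and is removed.
    breakpoint_bounds:
        Three ordered ``(low, high)`` intervals constraining the breakpoints
        separating sedentary/light, light/moderate and moderate/vigorous
        intensity.
    breakpoint_starts:
        Starting value for each breakpoint, inside its bound.
    angle_threshold:
        Minimum |arctan(s2) - arctan(s3)| (radians) between the light and
        moderate segment slopes for a participant to be called moderately
        active rather than consistent.
    support_max:
        Upper end of the intensity support used by the synthetic generator
        when normalizing densities.
    bin_x, weighted_fit, auc_scale:
        Run options: histogram bin representative (``"midpoint"`` or
        ``"left"``), whether least squares weights points by bin minutes,
        and whether the vigorous-region AUC ratio is computed on the linear
        probability scale or on the log scale.
    """

    unit_name: str
    bin_width: float
    implausible_cap: float | None
    tail_gap: float
    breakpoint_bounds: tuple[tuple[float, float], ...]
    breakpoint_starts: tuple[float, ...]
    angle_threshold: float
    support_max: float
    min_minutes_per_day: int = 600
    min_days: int = 3
    min_nonzero_bins: int = 5
    min_va_points: int = 5
    auc_ratio_threshold: float = 0.70
    r2_threshold: float = 0.90
    bin_x: str = "midpoint"
    weighted_fit: bool = False
    auc_scale: str = "linear"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if len(self.breakpoint_bounds) != len(self.breakpoint_starts):
            raise ValueError("one start per breakpoint bound is required")
        for (lo, hi), start in zip(self.breakpoint_bounds, self.breakpoint_starts):
            if not lo <= start <= hi:
                raise ValueError(f"start {start} outside bound ({lo}, {hi})")
        starts = list(self.breakpoint_starts)
        if starts != sorted(starts):
            raise ValueError("breakpoint starts must be ordered")
        if self.bin_x not in ("midpoint", "left"):
            raise ValueError("bin_x must be 'midpoint' or 'left'")
        if self.auc_scale not in ("linear", "log"):
            raise ValueError("auc_scale must be 'linear' or 'log'")

    def replace(self, **changes) -> "UnitConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def bin_representative(self, k) -> float:
        """x value representing histogram bin ``[k*w, (k+1)*w)``."""
        offset = 0.5 if self.bin_x == "midpoint" else 0.0
        return (k + offset) * self.bin_width

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


COUNTS = UnitConfig(
    unit_name="counts",
    bin_width=100.0,
    implausible_cap=12_000.0,
    tail_gap=1_000.0,
    breakpoint_bounds=((20.0, 200.0), (1_500.0, 2_500.0), (4_000.0, 7_000.0)),
    breakpoint_starts=(100.0, 1_951.0, 5_725.0),
    angle_threshold=0.001,
    support_max=12_000.0,
)

MIMS = UnitConfig(
    unit_name="mims",
    bin_width=0.5,
    implausible_cap=None,
    tail_gap=50.0,
    breakpoint_bounds=((0.5, 1.5), (2.0, 20.0), (5.0, 50.0)),
    breakpoint_starts=(1.0, 5.0, 30.0),
    angle_threshold=0.1,
    support_max=100.0,
)

_PRESETS = {"counts": COUNTS, "mims": MIMS}


def get_unit_config(name: str) -> UnitConfig:
    """Look up a preset by unit name (``"counts"`` or ``"mims"``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown unit {name!r}; expected one of {sorted(_PRESETS)}")
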