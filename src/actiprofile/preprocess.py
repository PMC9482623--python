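"""Filtering, binning and log transform of minute-level intensity series.

The pipeline applies four quality filters in a fixed order before any model
is fitted:

1. **wear filter** — a participant must contribute at least 600 recorded
   minutes per day on at least 3 different days, otherwise the whole
   participant is dropped (days are never dropped individually);
2. **implausible cap** — minutes above the unit's plausibility cap
   (12,000 counts/min; no cap for MIMS) are removed;
3. **tail-outlier removal** — after binning, a non-zero histogram bin with
   no other non-zero bin within the unit's tail gap (1,000 counts or
   50 MIMS) is removed, repeatedly, until nothing is removed;
4. **sparse-distribution filter** — participants with fewer than five
   non-zero bins are dropped.

The surviving histogram is converted to (intensity, ln probability) points,
on which the piecewise-linear fit operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import UnitConfig

__all__ = [
    "ParticipantSeries",
    "BinnedDistribution",
    "LogPoints",
    "filter_min_wear",
    "cap_implausible",
    "bin_intensity",
    "filter_sparse_distribution",
    "remove_tail_outliers",
    "to_log_points",
    "prepare_distribution",
]


@dataclass
class ParticipantSeries:
    """One participant's minute-level intensity values organized by day.

    ``days`` is a list of ``(day_index, values)`` pairs where ``values`` is a
    1-D float array with one entry per recorded minute.  All values must be
    finite and non-negative, and no day may exceed 1440 minutes.
    """

    participant_id: str
    days: list[tuple[int, np.ndarray]]

    def __post_init__(self) -> None:
        clean = []
        for day_index, values in self.days:
            values = np.asarray(values, dtype=float)
            if values.ndim != 1:
                raise ValueError("day values must be one-dimensional")
            if values.size > 1440:
                raise ValueError(
                    f"participant {self.participant_id!r} day {day_index}: "
                    f"{values.size} minutes exceeds 1440"
                )
            if values.size and (not np.all(np.isfinite(values)) or values.min() < 0):
                raise ValueError(
                    f"participant {self.participant_id!r} day {day_index}: "
                    "intensity values must be finite and >= 0"
                )
            clean.append((int(day_index), values))
        self.days = clean

    @property
    def total_minutes(self) -> int:
        return int(sum(v.size for _, v in self.days))

    def all_values(self) -> np.ndarray:
        """All recorded minutes concatenated in day order."""
        if not self.days:
            return np.empty(0)
        return np.concatenate([v for _, v in self.days])


@dataclass
class BinnedDistribution:
    """Empirical intensity histogram with per-bin probabilities.

    Bins are the half-open intervals ``[k*w, (k+1)*w)`` for ``k = 0..kmax``;
    ``x`` holds the representative intensity of each bin (midpoint by
    default), ``minutes`` the integer minute count and ``probability`` the
    fraction ``minutes / total_minutes`` where ``total_minutes`` is the
    participant's minute count at construction.  Tail-outlier removal zeroes
    bins without re-normalizing, so probabilities keep their original
    denominators afterwards.
    """

    bin_width: float
    x: np.ndarray
    minutes: np.ndarray
    probability: np.ndarray
    total_minutes: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.minutes = np.asarray(self.minutes, dtype=int)
        self.probability = np.asarray(self.probability, dtype=float)
        if not (self.x.size == self.minutes.size == self.probability.size):
            raise ValueError("x, minutes and probability must align")

    @property
    def n_nonzero_bins(self) -> int:
        return int(np.count_nonzero(self.minutes))

    @property
    def retained_minutes(self) -> int:
        return int(self.minutes.sum())

    def nonzero(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x, minutes, probability) restricted to occupied bins."""
        mask = self.minutes > 0
        return self.x[mask], self.minutes[mask], self.probability[mask]

    @property
    def tail(self) -> float:
        """Largest occupied bin representative (the 'tail' metric)."""
        xs, _, _ = self.nonzero()
        return float(xs.max()) if xs.size else float("nan")


@dataclass
class LogPoints:
    """(intensity, ln probability) points for occupied bins only."""

    x: np.ndarray
    y: np.ndarray
    minutes: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.y.size:
            raise ValueError("x and y must align")
        if self.x.size and np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("log probabilities must be finite")
        if self.minutes is not None:
            self.minutes = np.asarray(self.minutes, dtype=float)

    def __len__(self) -> int:
        return int(self.x.size)


def filter_min_wear(series: ParticipantSeries, config: UnitConfig) -> bool:
    """True iff the participant satisfies the minimum-wear requirement.

    Counts days with at least ``config.min_minutes_per_day`` recorded minutes
    and requires at least ``config.min_days`` such days.  Participant-level
    decision only; no minutes are altered.
    """
    valid_days = sum(
        1 for _, values in series.days if values.size >= config.min_minutes_per_day
    )
    return valid_days >= config.min_days


def cap_implausible(series: ParticipantSeries, config: UnitConfig) -> ParticipantSeries:
    """Remove minutes above the unit's implausibility cap.

    Identity when the unit defines no cap (MIMS).  Minute order within each
    day is preserved.
    """
    if config.implausible_cap is None:
        return series
    cap = config.implausible_cap
    days = [(d, values[values <= cap]) for d, values in series.days]
    return ParticipantSeries(series.participant_id, days)


def bin_intensity(series: ParticipantSeries, config: UnitConfig) -> BinnedDistribution:
    """Histogram the participant's minutes into fixed-width intensity bins.

    Minutes are assigned to half-open bins ``[k*w, (k+1)*w)``; a value lying
    exactly on a bin edge belongs to the upper bin.  The grid runs densely
    from bin 0 to the highest occupied bin so that interior empty bins are
    represented (with zero minutes).

    Raises
    ------
    ValueError
        If the series holds no minutes.
    """
    values = series.all_values()
    if values.size == 0:
        raise ValueError(f"participant {series.participant_id!r} has no data to bin")
    w = config.bin_width
    k = np.floor(values / w).astype(int)
    kmax = int(k.max())
    minutes = np.bincount(k, minlength=kmax + 1)
    x = np.array([config.bin_representative(i) for i in range(kmax + 1)])
    total = int(values.size)
    return BinnedDistribution(
        bin_width=w,
        x=x,
        minutes=minutes,
        probability=minutes / total,
        total_minutes=total,
    )


def filter_sparse_distribution(dist: BinnedDistribution, config: UnitConfig) -> bool:
    """True iff the histogram has at least ``min_nonzero_bins`` occupied bins."""
    return dist.n_nonzero_bins >= config.min_nonzero_bins


def remove_tail_outliers(dist: BinnedDistribution, config: UnitConfig) -> BinnedDistribution:
    """Iteratively drop isolated non-zero bins.

    A non-zero bin is isolated when no *other* non-zero bin lies within
    ``config.tail_gap`` of its representative x.  Each pass removes the
    highest-x isolated bin; passes repeat until none remains, so the result
    is a fixed point (the operation is idempotent).  Probabilities of
    surviving bins are not re-normalized.
    """
    minutes = dist.minutes.copy()
    probability = dist.probability.copy()
    while True:
        occ = np.flatnonzero(minutes > 0)
        if occ.size < 2:
            break
        xs = dist.x[occ]
        # nearest-neighbour gap among occupied bins (sorted by construction)
        gaps = np.diff(xs)
        left = np.concatenate(([np.inf], gaps))
        right = np.concatenate((gaps, [np.inf]))
        nearest = np.minimum(left, right)
        isolated = occ[nearest > config.tail_gap]
        if isolated.size == 0:
            break
        drop = isolated[-1]  # highest-x isolated bin goes first
        minutes[drop] = 0
        probability[drop] = 0.0
    return BinnedDistribution(
        bin_width=dist.bin_width,
        x=dist.x,
        minutes=minutes,
        probability=probability,
        total_minutes=dist.total_minutes,
    )


def to_log_points(dist: BinnedDistribution) -> LogPoints:
    """Natural-log transform of occupied-bin probabilities.

    One point per bin with ``minutes > 0``; empty bins emit no point because
    ln 0 is undefined.

    Raises
    ------
    ValueError
        If fewer than five occupied bins remain (too sparse to fit).
    """
    xs, mins, probs = dist.nonzero()
    if xs.size < 5:
        raise ValueError(
            f"only {xs.size} non-zero bins; at least 5 are required for fitting"
        )
    return LogPoints(x=xs, y=np.log(probs), minutes=mins)


def prepare_distribution(
    series: ParticipantSeries, config: UnitConfig
) -> tuple[BinnedDistribution, LogPoints]:
    """Cap, bin, de-spike and log-transform one participant.

    Convenience wrapper running filter steps 2-4 for a participant that has
    already passed the wear filter.  Returns the cleaned histogram and its
    log points.
    """
    capped = cap_implausible(series, config)
    dist = bin_intensity(capped, config)
    dist = remove_tail_outliers(dist, config)
    if not filter_sparse_distribution(dist, config):
        raise ValueError(
            f"participant {series.participant_id!r} removed: "
            f"{dist.n_nonzero_bins} non-zero bins < {config.min_nonzero_bins}"
        )
    return dist, to_log_points(dist)
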