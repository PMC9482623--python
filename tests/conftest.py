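import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import actiprofile as ap

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def piecewise_line(x, x0, breakpoints, slopes, y0):
    """Independent hand construction of a continuous piecewise line.

    Builds knot values sequentially and interpolates/extrapolates linearly;
    deliberately avoids the package's evaluate_model code path.
    """
    x = np.asarray(x, dtype=float)
    knots = [float(x0)] + [float(b) for b in breakpoints]
    yk = [float(y0)]
    for i in range(1, len(knots)):
        yk.append(yk[-1] + slopes[i - 1] * (knots[i] - knots[i - 1]))
    out = np.empty_like(x)
    for j, xi in enumerate(x):
        if xi <= knots[0]:
            out[j] = yk[0] + slopes[0] * 0.0
        elif xi >= knots[-1]:
            out[j] = yk[-1] + slopes[-1] * (xi - knots[-1])
        else:
            out[j] = np.interp(xi, knots, yk)
    return out


def log_points_on_line(breakpoints, slopes, x=None, y0=-1.0, x0=None):
    """LogPoints lying exactly on a hand-built piecewise line (counts grid)."""
    if x is None:
        x = np.arange(50.0, 7000.0, 100.0)
    x = np.asarray(x, dtype=float)
    if x0 is None:
        x0 = x.min()
    y = piecewise_line(x, x0, breakpoints, slopes, y0)
    return ap.LogPoints(x=x, y=y)


def series_from_values(values, pid="p", minutes_per_day=1440):
    """Pack a flat value list into a valid ParticipantSeries."""
    values = np.asarray(values, dtype=float)
    days = []
    for i, start in enumerate(range(0, values.size, minutes_per_day)):
        days.append((i + 1, values[start : start + minutes_per_day]))
    return ap.ParticipantSeries(pid, days)


def make_dist(occupied, bin_width=100.0, minutes_each=10, total=None):
    """BinnedDistribution with the given occupied bin representatives."""
    occupied = np.asarray(sorted(occupied), dtype=float)
    k = np.floor(occupied / bin_width).astype(int)
    kmax = int(k.max())
    minutes = np.zeros(kmax + 1, dtype=int)
    minutes[k] = minutes_each
    if total is None:
        total = int(minutes.sum())
    x = (np.arange(kmax + 1) + 0.5) * bin_width
    return ap.BinnedDistribution(
        bin_width=bin_width,
        x=x,
        minutes=minutes,
        probability=minutes / total,
        total_minutes=total,
    )


@pytest.fixture(scope="session")
def counts_config():
    return ap.COUNTS


@pytest.fixture(scope="session")
def mims_config():
    return ap.MIMS
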