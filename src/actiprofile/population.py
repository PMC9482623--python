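"""Cohort-level aggregation: metric summaries, profile counts, heatmap.

Per-participant fits are condensed into distributions of the model
parameters (three cut-points, four decay rates, R², and the "tail" — the
largest retained intensity bin), a table of profile-label counts, and a
participant-count heatmap over (intensity bin, log-probability bin) that
visualizes cohort variability across activity regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import PiecewiseFit
from .preprocess import BinnedDistribution
from .profiles import PROFILE_LABELS, ProfileResult

__all__ = ["PopulationSummary", "summarize_metrics", "probability_heatmap", "mean_probability_marginal"]

METRIC_NAMES = ("b1", "b2", "b3", "s1", "s2", "s3", "s4", "r2", "tail")


@dataclass
class PopulationSummary:
    """Per-metric summary table plus profile-label counts.

    ``metrics`` is indexed by metric name with columns
    ``n, mean, sd, min, q25, median, q75, max``.  Metrics absent for a
    participant (``b3``/``s4`` of a 3-segment refit, ``tail`` when no
    histogram was supplied) are excluded pairwise, so each row's ``n`` is the
    count actually contributing.  ``sd`` uses the unbiased (n-1) estimator
    and is NaN for a single observation.
    """

    metrics: pd.DataFrame
    profile_counts: dict[str, int]
    n_participants: int

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "profile_counts": self.profile_counts,
            "metrics": {
                name: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for name, row in self.metrics.to_dict(orient="index").items()
            },
        }


def _metric_row(fit: PiecewiseFit, profile: ProfileResult, tail: float) -> dict:
    row: dict[str, float] = {name: np.nan for name in METRIC_NAMES}
    b, s = fit.breakpoints, fit.slopes
    for i in range(b.size):
        row[f"b{i + 1}"] = b[i]
    for i in range(s.size):
        row[f"s{i + 1}"] = s[i]
    row["r2"] = profile.r2
    row["tail"] = tail
    return row


def summarize_metrics(
    records: Sequence[tuple[PiecewiseFit, ProfileResult]],
    tails: Sequence[float] | None = None,
) -> PopulationSummary:
    """Aggregate per-participant fits into a population summary.

    ``records`` pairs each participant's reported fit (the 3-segment refit
    for non-vigorous participants) with its profile result; ``tails``
    optionally supplies each participant's maximum retained bin intensity.
    """
    if len(records) == 0:
        raise ValueError("summarize_metrics needs at least one fit")
    if tails is not None and len(tails) != len(records):
        raise ValueError("one tail value per record is required")
    rows = [
        _metric_row(fit, prof, np.nan if tails is None else tails[i])
        for i, (fit, prof) in enumerate(records)
    ]
    df = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    summary = pd.DataFrame(
        {
            "n": df.notna().sum(),
            "mean": df.mean(),
            "sd": df.std(ddof=1),
            "min": df.min(),
            "q25": df.quantile(0.25),
            "median": df.median(),
            "q75": df.quantile(0.75),
            "max": df.max(),
        }
    )
    counts = {label: 0 for label in PROFILE_LABELS}
    for _, prof in records:
        counts[prof.label] += 1
    return PopulationSummary(
        metrics=summary, profile_counts=counts, n_participants=len(records)
    )


def _default_grids(
    dists: Sequence[BinnedDistribution], n_logp_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    w = dists[0].bin_width
    xmax = max(d.tail for d in dists)
    intensity_edges = np.arange(0.0, xmax + w, w)
    logps = np.concatenate([np.log(d.nonzero()[2]) for d in dists])
    lo, hi = float(logps.min()), float(logps.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return intensity_edges, np.linspace(lo, hi, n_logp_bins + 1)


def probability_heatmap(
    dists: Sequence[BinnedDistribution],
    intensity_edges: np.ndarray | None = None,
    logp_edges: np.ndarray | None = None,
    n_logp_bins: int = 40,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Participant-count matrix over (intensity bin, ln-probability bin).

    Cell ``(i, j)`` counts participants whose occupied histogram bin falls
    in intensity column ``i`` with ln(probability) in row bin ``j``;
    participants without an occupied bin in a column contribute nothing to
    it, so each column sums to the number of participants occupying that
    intensity.  Returns ``(matrix, intensity_edges, logp_edges)`` with the
    matrix indexed ``[i, j]``.

    All distributions must share one bin width (one unit); defaults span
    the observed range with equal ln-probability steps.
    """
    if len(dists) == 0:
        raise ValueError("probability_heatmap needs at least one distribution")
    widths = {d.bin_width for d in dists}
    if len(widths) != 1:
        raise ValueError("mixed units: distributions have different bin widths")
    if intensity_edges is None or logp_edges is None:
        auto_x, auto_y = _default_grids(dists, n_logp_bins)
        intensity_edges = auto_x if intensity_edges is None else np.asarray(intensity_edges)
        logp_edges = auto_y if logp_edges is None else np.asarray(logp_edges)
    matrix = np.zeros((len(intensity_edges) - 1, len(logp_edges) - 1))
    for d in dists:
        xs, _, probs = d.nonzero()
        h, _, _ = np.histogram2d(xs, np.log(probs), bins=(intensity_edges, logp_edges))
        matrix += h
    return matrix, np.asarray(intensity_edges), np.asarray(logp_edges)


def mean_probability_marginal(
    dists: Sequence[BinnedDistribution], intensity_edges: np.ndarray
) -> np.ndarray:
    """Mean probability per intensity column (zeros for absent bins)."""
    acc = np.zeros(len(intensity_edges) - 1)
    for d in dists:
        xs, _, probs = d.nonzero()
        idx = np.clip(np.searchsorted(intensity_edges, xs, side="right") - 1, 0, acc.size - 1)
        np.add.at(acc, idx, probs)
    return acc / len(dists)


def plot_heatmap(matrix, intensity_edges, logp_edges, path, unit_name: str = "") -> None:
    """Write the cohort heatmap (participant counts, log-probability vs intensity)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    mesh = ax.pcolormesh(intensity_edges, logp_edges, matrix.T, cmap="viridis")
    fig.colorbar(mesh, ax=ax, label="participants")
    ax.set_xlabel(f"intensity ({unit_name}/min)" if unit_name else "intensity")
    ax.set_ylabel("ln probability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metric_distributions(summary_records, path) -> None:
    """Histogram panel of the per-participant metrics (breakpoints, slopes, R², tail)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.DataFrame(summary_records)
    cols = [c for c in METRIC_NAMES if c in df.columns and df[c].notna().any()]
    n = len(cols)
    ncols = 3
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows))
    for ax, col in zip(np.ravel(axes), cols):
        ax.hist(df[col].dropna(), bins=30)
        ax.set_title(col)
    for ax in np.ravel(axes)[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
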