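"""Readers, writers and the end-to-end pipeline driver.

Input is a minutes CSV with columns ``participant_id, day, value`` (one row
per recorded minute, header required).  Outputs mirror the analysis flow:

``filter_report.csv``
    One row per filter step with participants/minutes remaining.
``models.jsonl``
    One JSON object per participant: fit parameters, R², profile label and
    diagnostics (first line is the resolved run configuration).
``profiles.csv``
    Flat per-participant summary table.
``distributions.jsonl``
    Occupied histogram bins per participant (for heatmaps / re-summaries).
``summary.json``
    Population summary: metric distributions and profile counts.

Every output embeds the resolved, version-stamped configuration: JSON files
carry a ``config`` entry and CSV files a leading ``# config: ...`` comment.

NHANES adaptation: the public PAM minute file maps onto the input schema as
``SEQN -> participant_id``, ``PAXDAYM -> day``, ``PAXMTSM -> value`` (x-axis
MIMS at the minute level); :func:`read_nhanes_pam` applies that renaming to
a CSV export.  No downloading is performed here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import UnitConfig
from .fitting import PiecewiseFit, fit_breakpoints
from .population import PopulationSummary, summarize_metrics
from .preprocess import (
    BinnedDistribution,
    LogPoints,
    ParticipantSeries,
    bin_intensity,
    cap_implausible,
    filter_min_wear,
    filter_sparse_distribution,
    remove_tail_outliers,
    to_log_points,
)
from .profiles import OUTLIER, ProfileResult, classify

logger = logging.getLogger("actiprofile")

FILTER_STEPS = (
    "unfiltered",
    "insufficient_data",
    "implausible_cap",
    "tail_outliers",
    "sparse_distribution",
)

REQUIRED_COLUMNS = ("participant_id", "day", "value")


def _config_stamp(config: UnitConfig) -> dict:
    return {"version": __version__, "config": config.to_dict()}


def read_minutes_csv(path, max_bad_fraction: float = 0.05) -> list[ParticipantSeries]:
    """Read a minutes CSV into per-participant series.

    Rows are grouped by participant and day in order of first appearance.
    Rows with a missing/non-numeric/negative value are rejected with a
    logged warning; if more than ``max_bad_fraction`` of rows are rejected
    the file is considered malformed and an error is raised.
    """
    df = pd.read_csv(path, comment="#", dtype={"participant_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() | (values < 0)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: rejected %d malformed rows", path, n_bad)
        if len(df) and n_bad / len(df) > max_bad_fraction:
            raise ValueError(
                f"{path}: {n_bad}/{len(df)} malformed rows exceeds tolerance"
            )
    df = df.loc[~bad].assign(value=values[~bad])
    out: list[ParticipantSeries] = []
    for pid, group in df.groupby("participant_id", sort=False):
        days = [
            (int(day), day_group["value"].to_numpy(dtype=float))
            for day, day_group in group.groupby("day", sort=False)
        ]
        out.append(ParticipantSeries(str(pid), days))
    return out


def write_minutes_csv(series_list, path, config: UnitConfig | None = None) -> None:
    """Write participant series to the standard minutes CSV."""
    path = Path(path)
    with path.open("w") as fh:
        if config is not None:
            fh.write(f"# config: {json.dumps(_config_stamp(config))}\n")
        fh.write("participant_id,day,value\n")
        for series in series_list:
            for day, values in series.days:
                for v in values:
                    fh.write(f"{series.participant_id},{day},{v:.10g}\n")


def read_nhanes_pam(path) -> list[ParticipantSeries]:
    """Read a CSV export of the NHANES PAM minute file (thin adapter).

    Expects columns ``SEQN`` (participant), ``PAXDAYM`` (day index) and
    ``PAXMTSM`` (x-axis minute-level MIMS); negative PAXMTSM sentinel values
    are dropped by the standard malformed-row rule.
    """
    df = pd.read_csv(path, comment="#")
    colmap = {"SEQN": "participant_id", "PAXDAYM": "day", "PAXMTSM": "value"}
    missing = [c for c in colmap if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing NHANES columns {missing}")
    import io as _io

    buf = _io.StringIO()
    df.rename(columns=colmap)[list(colmap.values())].to_csv(buf, index=False)
    buf.seek(0)
    return read_minutes_csv(buf)


@dataclass
class ParticipantRecord:
    """Everything the pipeline derived for one retained participant."""

    participant_id: str
    dist: BinnedDistribution
    points: LogPoints
    fit: PiecewiseFit
    profile: ProfileResult

    def to_json_dict(self, unit_name: str) -> dict:
        fit = self.profile.fit or self.fit
        return {
            "participant_id": self.participant_id,
            "unit": unit_name,
            "n_segments": int(fit.n_segments),
            "breakpoints": [float(b) for b in fit.breakpoints],
            "slopes": [float(s) for s in fit.slopes],
            "intercept": float(fit.intercept),
            "r2": float(self.profile.r2),
            "label": self.profile.label,
            "va_point_count": int(self.profile.va_point_count),
            "auc_ratio": None
            if self.profile.auc_ratio is None
            else float(self.profile.auc_ratio),
            "angle_diff": None
            if self.profile.angle_diff is None
            else float(self.profile.angle_diff),
            "used_three_segment": bool(self.profile.used_three_segment),
            "tail": float(self.dist.tail),
            "reason": self.profile.reason,
        }


@dataclass
class FilterReport:
    """Per-step participant/minute accounting, mirroring the filter table."""

    table: pd.DataFrame  # columns: step, participants_remaining, minutes_remaining

    def to_csv(self, path, config: UnitConfig | None = None) -> None:
        with Path(path).open("w") as fh:
            if config is not None:
                fh.write(f"# config: {json.dumps(_config_stamp(config))}\n")
            self.table.to_csv(fh, index=False)


def apply_filters(
    series_list, config: UnitConfig
) -> tuple[list[tuple[ParticipantSeries, BinnedDistribution]], FilterReport]:
    """Run the four filter steps, returning survivors and the accounting table.

    Order: wear filter -> implausible cap -> tail-outlier removal (after
    binning) -> sparse-distribution filter.  Participant and minute counts
    are recorded after every step.
    """
    rows = [
        {
            "step": "unfiltered",
            "participants_remaining": len(series_list),
            "minutes_remaining": int(sum(s.total_minutes for s in series_list)),
        }
    ]
    kept = [s for s in series_list if filter_min_wear(s, config)]
    rows.append(
        {
            "step": "insufficient_data",
            "participants_remaining": len(kept),
            "minutes_remaining": int(sum(s.total_minutes for s in kept)),
        }
    )
    capped = [cap_implausible(s, config) for s in kept]
    rows.append(
        {
            "step": "implausible_cap",
            "participants_remaining": len(capped),
            "minutes_remaining": int(sum(s.total_minutes for s in capped)),
        }
    )
    binned: list[tuple[ParticipantSeries, BinnedDistribution | None]] = []
    for s in capped:
        if s.total_minutes == 0:
            binned.append((s, None))
            continue
        dist = remove_tail_outliers(bin_intensity(s, config), config)
        binned.append((s, dist))
    rows.append(
        {
            "step": "tail_outliers",
            "participants_remaining": len(binned),
            "minutes_remaining": int(
                sum(d.retained_minutes for _, d in binned if d is not None)
            ),
        }
    )
    survivors = [
        (s, d)
        for s, d in binned
        if d is not None and filter_sparse_distribution(d, config)
    ]
    rows.append(
        {
            "step": "sparse_distribution",
            "participants_remaining": len(survivors),
            "minutes_remaining": int(sum(d.retained_minutes for _, d in survivors)),
        }
    )
    return survivors, FilterReport(pd.DataFrame(rows))


def analyze_participant(
    series: ParticipantSeries,
    config: UnitConfig,
    dist: BinnedDistribution | None = None,
) -> ParticipantRecord:
    """Cap/bin/clean (unless ``dist`` is given), fit and classify one participant."""
    if dist is None:
        capped = cap_implausible(series, config)
        dist = remove_tail_outliers(bin_intensity(capped, config), config)
        if not filter_sparse_distribution(dist, config):
            raise ValueError(
                f"participant {series.participant_id!r} fails the sparse filter"
            )
    points = to_log_points(dist)
    try:
        fit = fit_breakpoints(points, config, n_breakpoints=3)
        profile = classify(points, fit, config)
    except Exception as exc:
        logger.warning("participant %s: fit failed (%s)", series.participant_id, exc)
        fallback = PiecewiseFit(
            n_segments=1,
            breakpoints=np.empty(0),
            slopes=np.array([0.0]),
            intercept=float(points.y.mean()),
            r2=float("-inf"),
            sse=float(np.sum((points.y - points.y.mean()) ** 2)),
            x_range=(float(points.x.min()), float(points.x.max())),
        )
        profile = ProfileResult(
            label=OUTLIER,
            va_point_count=0,
            auc_ratio=None,
            angle_diff=None,
            r2=float("-inf"),
            used_three_segment=False,
            fit=fallback,
            reason=f"fit failed: {exc}",
        )
        fit = fallback
    return ParticipantRecord(series.participant_id, dist, points, fit, profile)


@dataclass
class PipelineResult:
    report: FilterReport
    records: list[ParticipantRecord]
    summary: PopulationSummary


def run_pipeline(
    series_list: list[ParticipantSeries],
    config: UnitConfig,
    out_dir=None,
) -> PipelineResult:
    """Filter -> fit -> classify -> summarize a cohort; optionally write outputs.

    Raises
    ------
    RuntimeError
        If no participant survives filtering (the CLI maps this to a
        non-zero exit code).
    """
    survivors, report = apply_filters(series_list, config)
    if not survivors:
        raise RuntimeError("all participants were removed by filtering")
    records = [analyze_participant(s, config, dist=d) for s, d in survivors]
    reported_fits = [
        (rec.profile.fit or rec.fit, rec.profile) for rec in records
    ]
    summary = summarize_metrics(reported_fits, tails=[rec.dist.tail for rec in records])
    result = PipelineResult(report=report, records=records, summary=summary)
    if out_dir is not None:
        write_outputs(result, config, out_dir)
    return result


def write_outputs(result: PipelineResult, config: UnitConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _config_stamp(config)
    result.report.to_csv(out / "filter_report.csv", config=config)
    with (out / "models.jsonl").open("w") as fh:
        fh.write(json.dumps({"_run": stamp}) + "\n")
        for rec in result.records:
            fh.write(json.dumps(rec.to_json_dict(config.unit_name)) + "\n")
    with (out / "distributions.jsonl").open("w") as fh:
        fh.write(json.dumps({"_run": stamp}) + "\n")
        for rec in result.records:
            xs, mins, probs = rec.dist.nonzero()
            fh.write(
                json.dumps(
                    {
                        "participant_id": rec.participant_id,
                        "bin_width": rec.dist.bin_width,
                        "x": [float(v) for v in xs],
                        "minutes": [int(m) for m in mins],
                        "probability": [float(p) for p in probs],
                        "total_minutes": rec.dist.total_minutes,
                    }
                )
                + "\n"
            )
    _write_profiles_csv(result.records, config, out / "profiles.csv")
    with (out / "summary.json").open("w") as fh:
        json.dump({**stamp, "summary": result.summary.to_dict()}, fh, indent=2)
        fh.write("\n")


def _write_profiles_csv(records, config: UnitConfig, path) -> None:
    cols = [
        "participant_id", "label", "r2", "b1", "b2", "b3",
        "s1", "s2", "s3", "s4", "va_points", "auc_ratio", "angle_diff",
    ]
    rows = []
    for rec in records:
        fit = rec.profile.fit or rec.fit
        row = dict.fromkeys(cols, "")
        row.update(
            participant_id=rec.participant_id,
            label=rec.profile.label,
            r2=f"{rec.profile.r2:.6g}",
            va_points=rec.profile.va_point_count,
        )
        for i, b in enumerate(fit.breakpoints, start=1):
            row[f"b{i}"] = f"{b:.6g}"
        for i, s in enumerate(fit.slopes, start=1):
            row[f"s{i}"] = f"{s:.6g}"
        if rec.profile.auc_ratio is not None:
            row["auc_ratio"] = f"{rec.profile.auc_ratio:.6g}"
        if rec.profile.angle_diff is not None:
            row["angle_diff"] = f"{rec.profile.angle_diff:.6g}"
        rows.append(row)
    with Path(path).open("w") as fh:
        fh.write(f"# config: {json.dumps(_config_stamp(config))}\n")
        pd.DataFrame(rows, columns=cols).to_csv(fh, index=False)


def read_models_jsonl(path) -> list[dict]:
    """Read a per-participant model file, skipping the config stamp line."""
    out = []
    with Path(path).open() as fh:
        for line in fh:
            obj = json.loads(line)
            if "_run" in obj:
                continue
            out.append(obj)
    return out


def read_distributions_jsonl(path) -> list[BinnedDistribution]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            obj = json.loads(line)
            if "_run" in obj:
                continue
            out.append(
                BinnedDistribution(
                    bin_width=obj["bin_width"],
                    x=np.array(obj["x"]),
                    minutes=np.array(obj["minutes"]),
                    probability=np.array(obj["probability"]),
                    total_minutes=obj["total_minutes"],
                )
            )
    return out
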