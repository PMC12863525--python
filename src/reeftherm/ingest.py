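"""Reading, quality control, and nightly aggregation of reef temperature records.

In situ loggers record at a nominal 10-minute cadence at coral depth, while
satellite sea-surface temperature (SSST) is a single nightly value per
region.  To compare the two, logger records are filtered to the nighttime
window (22:00 through 01:59 local time, matching the satellite's nighttime
read), aggregated into nightly mean/max/min per logger, averaged across the
loggers of a region, and date-joined to the regional SSST series.

All timestamps are interpreted as a single fixed local time zone (Palau,
UTC+9); no conversion logic is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Plausible-water-temperature QC bounds (degC).  Records outside are flagged
#: and excluded from aggregates; they typically reflect air exposure around
#: deployment or retrieval.
QC_BOUNDS = (15.0, 40.0)

#: Nighttime window [start, end) in local clock hours, wrapping midnight.
NIGHT_WINDOW = (22, 2)

REQUIRED_LOGGER_COLUMNS = ("logger_id", "region", "depth_m", "timestamp", "temp_c")


@dataclass
class LoggerSeries:
    """Raw 10-minute temperature records for one deployment of one logger.

    ``records`` is a DataFrame with columns ``timestamp`` (datetime64,
    strictly increasing), ``temp_c`` (float) and ``qc_ok`` (bool; False for
    records outside :data:`QC_BOUNDS`).
    """

    logger_id: str
    region: str
    depth_m: float
    records: pd.DataFrame
    deployment_date: pd.Timestamp
    retrieval_date: pd.Timestamp

    def __post_init__(self) -> None:
        ts = self.records["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("records must be sorted by timestamp")
        if len(ts) > 1 and ts.duplicated().any():
            raise ValueError("duplicate timestamps within a deployment")

    def __len__(self) -> int:
        return len(self.records)


def _qc_flag(temp: pd.Series, bounds: tuple[float, float]) -> pd.Series:
    lo, hi = bounds
    return (temp >= lo) & (temp <= hi)


def read_logger_csv(
    path,
    qc_bounds: tuple[float, float] = QC_BOUNDS,
    split_gap: str | pd.Timedelta = "2D",
) -> list[LoggerSeries]:
    """Read a logger CSV into per-deployment :class:`LoggerSeries`.

    The file must have columns ``logger_id, region, depth_m, timestamp,
    temp_c``.  Rows with unparseable timestamps or temperatures are dropped
    with a logged count; a duplicated (logger, timestamp) pair keeps the
    first row and logs a warning.  Record gaps longer than ``split_gap``
    split a logger's history into separate deployments, each with its own
    deployment (first record) and retrieval (last record) date.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_LOGGER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"logger CSV missing required columns: {missing}")

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    temp = pd.to_numeric(df["temp_c"], errors="coerce")
    bad = ts.isna() | temp.isna()
    if bad.any():
        log.warning("dropping %d malformed rows from %s", int(bad.sum()), path)
    df = df.loc[~bad].assign(timestamp=ts[~bad], temp_c=temp[~bad])
    df = df.sort_values(["logger_id", "timestamp"], kind="mergesort")

    dup = df.duplicated(subset=["logger_id", "timestamp"], keep="first")
    if dup.any():
        log.warning("dropping %d duplicate-timestamp rows (keeping first)", int(dup.sum()))
        df = df.loc[~dup]

    split_gap = pd.Timedelta(split_gap)
    out: list[LoggerSeries] = []
    for logger_id, grp in df.groupby("logger_id", sort=True):
        gaps = grp["timestamp"].diff() > split_gap
        for _, seg in grp.groupby(gaps.cumsum()):
            rec = seg[["timestamp", "temp_c"]].reset_index(drop=True)
            rec["qc_ok"] = _qc_flag(rec["temp_c"], qc_bounds)
            out.append(
                LoggerSeries(
                    logger_id=str(logger_id),
                    region=str(seg["region"].iloc[0]),
                    depth_m=float(seg["depth_m"].iloc[0]),
                    records=rec,
                    deployment_date=rec["timestamp"].iloc[0],
                    retrieval_date=rec["timestamp"].iloc[-1],
                )
            )
    return out


def discard_deployment_edge(series: LoggerSeries) -> LoggerSeries:
    """Drop every record earlier than one day after deployment.

    Loggers are launched on land, so the first day of records can contain
    air temperatures.  The kept interval is closed on the left: a record at
    exactly deployment + 24 h is retained.  May return an empty series.
    """
    cutoff = series.deployment_date + pd.Timedelta(days=1)
    rec = series.records[series.records["timestamp"] >= cutoff].reset_index(drop=True)
    return replace(series, records=rec)


def _night_labels(ts: pd.Series, night_window: tuple[int, int]) -> tuple[pd.Series, pd.Series]:
    """Return (in-window mask, night date label) for timestamps.

    The window is half-open on clock hours and may wrap midnight.  A night
    is labelled by the evening's date: 22:00 of day *d* through 01:59 of day
    *d*+1 all belong to night *d*.
    """
    start, end = night_window
    hours = ts.dt.hour
    if start > end:  # wraps midnight
        mask = (hours >= start) | (hours < end)
    else:
        mask = (hours >= start) & (hours < end)
    labels = (ts - pd.Timedelta(hours=end)).dt.normalize()
    return mask, labels


def night_filter_aggregate(
    series: LoggerSeries,
    night_window: tuple[int, int] = NIGHT_WINDOW,
) -> pd.DataFrame:
    """Nightly mean/max/min/n_obs of QC-passing records in the night window.

    Returns a DataFrame indexed by night date with columns ``mean, max, min,
    n_obs``.  Nights with zero records are omitted.
    """
    rec = series.records[series.records["qc_ok"]]
    mask, labels = _night_labels(rec["timestamp"], night_window)
    rec = rec[mask]
    if rec.empty:
        return pd.DataFrame(columns=["mean", "max", "min", "n_obs"])
    grouped = rec.groupby(labels[mask])["temp_c"]
    out = grouped.agg(mean="mean", max="max", min="min", n_obs="size")
    out.index.name = "date"
    return out


def daily_range(series: LoggerSeries, min_obs: int = 100) -> pd.DataFrame:
    """Per-calendar-day 24-hour temperature range (max - min, degC).

    Days with fewer than ``min_obs`` QC-passing records (default 100 of the
    144 expected at 10-minute cadence) are omitted so partial days do not
    understate the range.
    """
    rec = series.records[series.records["qc_ok"]]
    if rec.empty:
        return pd.DataFrame(columns=["range", "n_obs"])
    day = rec["timestamp"].dt.normalize()
    grouped = rec.groupby(day)["temp_c"]
    out = pd.DataFrame({"range": grouped.max() - grouped.min(), "n_obs": grouped.size()})
    out = out[out["n_obs"] >= min_obs]
    out.index.name = "date"
    return out


def aggregate_nightlies(
    loggers: Iterable[LoggerSeries],
    night_window: tuple[int, int] = NIGHT_WINDOW,
    discard_edge: bool = True,
) -> pd.DataFrame:
    """Stack per-logger nightly aggregates into one long table.

    Returns columns ``date, region, logger_id, mean, max, min, n_obs``.
    """
    frames = []
    for s in loggers:
        if discard_edge:
            s = discard_deployment_edge(s)
        nightly = night_filter_aggregate(s, night_window)
        if nightly.empty:
            continue
        nightly = nightly.reset_index()
        nightly["region"] = s.region
        nightly["logger_id"] = s.logger_id
        frames.append(nightly)
    if not frames:
        return pd.DataFrame(columns=["date", "region", "logger_id", "mean", "max", "min", "n_obs"])
    return pd.concat(frames, ignore_index=True)


def _block_ids(dates: pd.DatetimeIndex, max_step: str | pd.Timedelta = "1D") -> np.ndarray:
    """Contiguous-run ids: a new block starts wherever the date step exceeds
    ``max_step``."""
    if len(dates) == 0:
        return np.array([], dtype=int)
    step = pd.Timedelta(max_step)
    breaks = np.asarray(dates.to_series().diff() > step)
    return np.cumsum(breaks).astype(int)


def build_region_panel(
    nightlies: pd.DataFrame,
    ssst: pd.DataFrame,
    scope: str = "all",
    stat: str = "mean",
    block_step: str | pd.Timedelta = "1D",
) -> pd.DataFrame:
    """Date-aligned paired (in situ, SSST) panel for one region or ``"all"``.

    The in situ value on a date is the unweighted mean of the nightly
    ``stat`` across the region's loggers; for scope ``"all"`` it is the mean
    of region means (and SSST the mean of regional SSST), so a
    logger-rich region does not dominate.  The result is indexed by date
    with columns ``insitu, ssst, block_id``; ``block_id`` increments at
    every gap in the date sequence larger than ``block_step``.
    """
    if stat not in ("mean", "max", "min"):
        raise ValueError(f"unknown nightly statistic {stat!r}")
    region_means = (
        nightlies.groupby(["region", "date"])[stat].mean().rename("insitu").reset_index()
    )
    sat = ssst.copy()
    sat["date"] = pd.to_datetime(sat["date"])
    if scope == "all":
        insitu = region_means.groupby("date")["insitu"].mean()
        sat_series = sat.groupby("date")["sst_c"].mean()
    else:
        insitu = region_means[region_means["region"] == scope].set_index("date")["insitu"]
        sat_series = sat[sat["region"] == scope].set_index("date")["sst_c"]
    panel = pd.concat([insitu, sat_series.rename("ssst")], axis=1, join="inner").sort_index()
    panel = panel.dropna()
    if panel.empty:
        raise ValueError(
            "no shared dates between in situ nightlies "
            f"({_span(region_means['date'])}) and SSST ({_span(sat['date'])}) "
            f"for scope {scope!r}"
        )
    panel["block_id"] = _block_ids(panel.index, block_step)
    panel.index.name = "date"
    return panel


def _span(dates: pd.Series) -> str:
    if dates.empty:
        return "empty"
    return f"{dates.min().date()}..{dates.max().date()}"


def monthly_mean(
    panel: pd.DataFrame,
    min_coverage: float = 0.5,
    value_columns: tuple[str, ...] = ("insitu", "ssst"),
) -> pd.DataFrame:
    """Calendar-month means of nightly values, with a coverage flag.

    Months where fewer than ``min_coverage`` of the nights are present are
    still computed but flagged ``coverage_ok = False`` so downstream
    climatology steps can exclude them.  Indexed by month start date.
    """
    cols = [c for c in value_columns if c in panel.columns]
    months = panel.index.to_period("M")
    grouped = panel[cols].groupby(months)
    out = grouped.mean()
    n = grouped.size()
    out["n_nights"] = n
    out["coverage_ok"] = n / out.index.days_in_month >= min_coverage
    out.index = out.index.to_timestamp()
    out.index.name = "month"
    return out


def gaussian_smooth(
    values: pd.Series,
    bandwidth_days: float = 30.0,
    block_id: pd.Series | np.ndarray | None = None,
) -> pd.Series:
    """Nadaraya-Watson Gaussian-kernel smoother over a dated series.

    The bandwidth is the kernel standard deviation in days (default one
    month).  When ``block_id`` is given, smoothing is done independently
    within each contiguous block so that gaps are not bridged.  Evaluated at
    the observed dates.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 points to smooth")
    if block_id is None:
        block_id = np.zeros(len(values), dtype=int)
    block_id = np.asarray(block_id)
    t = values.index.view("int64") / (86_400e9)  # days since epoch
    y = values.to_numpy(dtype=float)
    out = np.empty_like(y)
    for b in np.unique(block_id):
        sel = block_id == b
        tb, yb = t[sel], y[sel]
        w = np.exp(-0.5 * ((tb[:, None] - tb[None, :]) / bandwidth_days) ** 2)
        out[sel] = w @ yb / w.sum(axis=1)
    return pd.Series(out, index=values.index, name=values.name)
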