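"""CRW-style heat-stress metrics and inter-regional comparisons.

The chain of derived quantities mirrors NOAA Coral Reef Watch practice:

* **MMM** (maximum monthly mean): the warmest calendar-month mean within a
  trailing 12-month window (default) or across a multi-year monthly
  climatology (``variant="climatology"``).
* **Bleaching threshold**: MMM + 1 degC.
* **HotSpot**: the positive excess of a day's temperature over the MMM.
* **DHW** (degree heating weeks): HotSpots of at least 1 degC, divided by 7
  and summed over a trailing 84-day (12-week) window, in degC-weeks.

Because the satellite runs systematically cool relative to in situ records,
the in situ MMM can be anchored to the satellite climatology via the mean
monthly offset (:func:`adjust_insitu_mmm`), so that DHW differences reflect
heat accumulation rather than baseline bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Trailing accumulation window for DHW, days (12 weeks).
DHW_WINDOW_DAYS = 84

#: HotSpots below this magnitude (degC) do not accrue DHW (CRW convention).
DHW_INCLUSION_C = 1.0


@dataclass
class HeatStressProfile:
    """MMM, bleaching threshold, HotSpot and DHW series for one record.

    ``dhw`` is defined on the full daily index; ``coverage_ok`` flags dates
    whose trailing window had sufficient data coverage (windows clipped at
    the start of the series count only in-range days, so a gap-free series
    is fully covered from its first day).
    """

    mmm: float
    threshold: float
    hotspot: pd.Series
    dhw: pd.Series
    coverage_ok: pd.Series
    window_days: int = DHW_WINDOW_DAYS
    variant: str = "crw"

    @property
    def dhw_defined(self) -> pd.Series:
        """DHW masked to dates meeting the window-coverage rule."""
        return self.dhw.where(self.coverage_ok)


@dataclass
class RegionComparison:
    """Per-date temperature difference between two regions for one origin."""

    region_a: str
    region_b: str
    difference: pd.Series  # a - b on shared dates
    mean_difference: float
    pct_a_warmer: float
    pct_b_warmer: float
    pct_tied: float


def _monthly_means(nightly: pd.Series, min_coverage: float) -> tuple[pd.Series, pd.Series]:
    """Calendar-month means of a dated series and their coverage flags."""
    months = nightly.dropna()
    grouped = months.groupby(months.index.to_period("M"))
    means = grouped.mean()
    covered = grouped.size() / means.index.days_in_month >= min_coverage
    return means, covered


def compute_mmm(
    nightly: pd.Series,
    evaluation_month: str | pd.Period | None = None,
    variant: str = "trailing12",
    min_month_coverage: float = 0.5,
) -> float:
    """Maximum monthly mean (degC) of a dated nightly-mean series.

    ``variant="trailing12"`` takes the warmest covered calendar-month mean
    within the 12-month window ending at ``evaluation_month`` (default: the
    last covered month).  ``variant="climatology"`` instead averages each
    calendar month across years and takes the warmest, the operational
    climatology form.  Requires at least 12 covered months overall.
    """
    means, covered = _monthly_means(nightly, min_month_coverage)
    means = means[covered]
    if len(means) < 12:
        raise ValueError(f"need >= 12 covered months for an MMM, have {len(means)}")
    if variant == "climatology":
        return float(means.groupby(means.index.month).mean().max())
    if variant != "trailing12":
        raise ValueError(f"unknown MMM variant {variant!r}")
    if evaluation_month is None:
        eval_month = means.index.max()
    else:
        eval_month = pd.Period(evaluation_month, freq="M")
    window = means[(means.index > eval_month - 12) & (means.index <= eval_month)]
    if window.empty:
        raise ValueError(f"no covered months in the 12-month window ending {eval_month}")
    return float(window.max())


def monthly_offset(insitu_nightly: pd.Series, ssst_daily: pd.Series,
                   min_month_coverage: float = 0.5) -> float:
    """Mean over months of (in situ monthly mean - SSST monthly mean).

    Only months covered in both series contribute.
    """
    m_in, cov_in = _monthly_means(insitu_nightly, min_month_coverage)
    m_sat, cov_sat = _monthly_means(ssst_daily, min_month_coverage)
    both = cov_in[cov_in].index.intersection(cov_sat[cov_sat].index)
    if both.empty:
        raise ValueError("no months covered in both series")
    return float((m_in[both] - m_sat[both]).mean())


def adjust_insitu_mmm(ssst_mmm: float, monthly_offset: float) -> float:
    """In situ MMM anchored to the satellite MMM via the mean monthly offset."""
    return ssst_mmm + monthly_offset


def _trailing_window_sums(values: np.ndarray, window: int) -> np.ndarray:
    """Sum of the trailing ``window`` entries at each position (zero-padded
    before the start)."""
    pad = np.concatenate([np.zeros(window - 1), values])
    return np.lib.stride_tricks.sliding_window_view(pad, window).sum(axis=1)


def compute_dhw(
    nightly: pd.Series,
    mmm: float,
    window_days: int = DHW_WINDOW_DAYS,
    variant: str = "crw",
    min_coverage: float = 0.8,
) -> HeatStressProfile:
    """Degree heating weeks over a trailing sliding window.

    Per day *d*: ``hotspot(d) = max(T(d) - mmm, 0)``.  Under the CRW
    convention (``variant="crw"``) the daily contribution is ``hotspot/7``
    when the HotSpot is at least 1 degC and zero otherwise; the alternative
    ``variant="excess"`` accrues ``max(T - (mmm + 1), 0)/7``, i.e. only the
    excess over the bleaching threshold.  ``DHW(d)`` sums contributions over
    the trailing ``window_days`` days including *d*.  Dates whose trailing
    window (clipped to the series start) has less than ``min_coverage`` of
    days present are flagged as undefined rather than silently deflated.
    """
    if not np.isfinite(mmm):
        raise ValueError("mmm must be finite")
    nightly = nightly.sort_index()
    full_index = pd.date_range(nightly.index.min(), nightly.index.max(), freq="D")
    temp = nightly.reindex(full_index)

    hotspot = (temp - mmm).clip(lower=0.0)
    if variant == "crw":
        contrib = hotspot.where(hotspot >= DHW_INCLUSION_C, 0.0) / 7.0
    elif variant == "excess":
        contrib = (temp - (mmm + DHW_INCLUSION_C)).clip(lower=0.0) / 7.0
    else:
        raise ValueError(f"unknown DHW variant {variant!r}")

    # Trailing-window sums via a strided view: each date's DHW is the sum of
    # its own length-`window_days` window (missing/pre-series days count 0),
    # which makes the result bit-identical to a per-date recomputation.
    dhw = pd.Series(
        _trailing_window_sums(contrib.fillna(0.0).to_numpy(), window_days),
        index=full_index,
    )

    present = temp.notna().to_numpy(dtype=float)
    n_present = _trailing_window_sums(present, window_days)
    denom = np.minimum(np.arange(1, len(full_index) + 1), window_days)
    coverage_ok = pd.Series(n_present / denom >= min_coverage, index=full_index)

    return HeatStressProfile(
        mmm=float(mmm),
        threshold=float(mmm) + 1.0,
        hotspot=hotspot,
        dhw=dhw,
        coverage_ok=coverage_ok,
        window_days=window_days,
        variant=variant,
    )


def compare_regions(
    panel_a: pd.DataFrame | pd.Series,
    panel_b: pd.DataFrame | pd.Series,
    origin: str = "insitu",
    region_a: str = "a",
    region_b: str = "b",
) -> RegionComparison:
    """Per-date difference between two regional series of one data origin.

    Accepts panels (DataFrames with an ``insitu``/``ssst`` column selected by
    ``origin``) or plain dated Series.  Percentages use strict inequality;
    exact float ties are reported separately, so the three percentages sum
    to 100.
    """
    a = panel_a[origin] if isinstance(panel_a, pd.DataFrame) else panel_a
    b = panel_b[origin] if isinstance(panel_b, pd.DataFrame) else panel_b
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError(f"no shared dates between {region_a} and {region_b}")
    diff = (a[shared] - b[shared]).astype(float)
    n = len(diff)
    return RegionComparison(
        region_a=region_a,
        region_b=region_b,
        difference=diff,
        mean_difference=float(diff.mean()),
        pct_a_warmer=100.0 * float((diff > 0).sum()) / n,
        pct_b_warmer=100.0 * float((diff < 0).sum()) / n,
        pct_tied=100.0 * float((diff == 0).sum()) / n,
    )
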