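"""Walk-forward out-of-sample evaluation of satellite-to-in situ calibration.

An expanding training window ends at each forecast origin *t*; the
calibration regression (in situ on SSST) fit on all rows with date <= *t*
predicts the in situ metric for the half-open horizon (t, t + 30 days], but
only for rows in the same contiguous data block as the origin so forecasts
never bridge field-season gaps.  Origins advance by exactly 30 calendar
days from the first origin; an origin falling in a gap simply yields a
skipped window.  The benchmark is the training-period mean of the in situ
metric ("mean of means"): a useful satellite calibration must beat it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_FIRST_ORIGIN = "2019-04-01"
DEFAULT_HORIZON_DAYS = 30


@dataclass
class WalkForwardWindow:
    origin: pd.Timestamp
    n_predicted: int
    mae: float
    baseline_mae: float


@dataclass
class WalkForwardReport:
    """Per-window and mean MAE of walk-forward calibration forecasts."""

    metric: str
    scope: str
    horizon_days: int
    first_origin: pd.Timestamp
    windows: list[WalkForwardWindow]
    mean_mae: float
    baseline_mean_mae: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "origin": [w.origin for w in self.windows],
                "n_predicted": [w.n_predicted for w in self.windows],
                "mae": [w.mae for w in self.windows],
                "baseline_mae": [w.baseline_mae for w in self.windows],
            }
        )


def _fit_predict(train: pd.DataFrame, target: pd.DataFrame) -> np.ndarray:
    x = train["ssst"].to_numpy(dtype=float)
    y = train["insitu"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta[0] + beta[1] * target["ssst"].to_numpy(dtype=float)


def walk_forward_validate(
    panel: pd.DataFrame,
    metric: str = "nightly_mean",
    scope: str = "all",
    first_origin: str | pd.Timestamp = DEFAULT_FIRST_ORIGIN,
    horizon_days: int = DEFAULT_HORIZON_DAYS,
    step_days: int = DEFAULT_HORIZON_DAYS,
    min_train: int = 10,
) -> WalkForwardReport:
    """Expanding-window walk-forward validation on a paired panel.

    ``panel`` is a date-indexed DataFrame with columns ``insitu, ssst,
    block_id``.  For each origin: train on all rows with date <= origin,
    predict rows in (origin, origin + horizon] belonging to the origin's
    block, and record the MAE alongside the train-mean baseline MAE.
    Windows with no eligible rows (origin in a gap, or nothing to predict)
    are skipped.  Raises if fewer than ``min_train`` training rows exist at
    the first origin, or if no window yields any prediction.
    """
    panel = panel.sort_index()
    first_origin = pd.Timestamp(first_origin)
    idx = panel.index
    if (idx <= first_origin).sum() < min_train:
        raise ValueError(
            f"need at least {min_train} training rows on or before {first_origin.date()}"
        )

    step = pd.Timedelta(days=step_days)
    horizon = pd.Timedelta(days=horizon_days)
    windows: list[WalkForwardWindow] = []
    origin = first_origin
    last = idx.max()
    while origin < last:
        train = panel[idx <= origin]
        at_origin = panel[idx == origin]
        if len(train) >= min_train and not at_origin.empty:
            block = at_origin["block_id"].iloc[-1]
            target = panel[
                (idx > origin) & (idx <= origin + horizon) & (panel["block_id"] == block)
            ]
            if not target.empty:
                pred = _fit_predict(train, target)
                truth = target["insitu"].to_numpy(dtype=float)
                baseline = float(train["insitu"].mean())
                windows.append(
                    WalkForwardWindow(
                        origin=origin,
                        n_predicted=len(target),
                        mae=float(np.mean(np.abs(truth - pred))),
                        baseline_mae=float(np.mean(np.abs(truth - baseline))),
                    )
                )
        origin = origin + step

    if not windows:
        raise ValueError("no valid walk-forward windows")
    return WalkForwardReport(
        metric=metric,
        scope=scope,
        horizon_days=horizon_days,
        first_origin=first_origin,
        windows=windows,
        mean_mae=float(np.mean([w.mae for w in windows])),
        baseline_mean_mae=float(np.mean([w.baseline_mae for w in windows])),
    )
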