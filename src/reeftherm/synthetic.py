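"""Synthetic paired logger/satellite temperature datasets with known ground truth.

The generator emulates the study design the rest of the package analyses:
multiple in situ loggers per region recording at a 10-minute cadence, and a
single daily nighttime satellite value (SSST) per region.  Both share a
seasonal cycle and a regional latent random-walk trend; the in situ records
add a diurnal sinusoid, AR(1) daily noise, per-logger offsets, and
white-noise jitter, while the satellite series carries its own AR(1) noise
and a constant origin bias (SSST minus in situ, expected negative since
satellites read the cool skin layer at night).

Daily-resolution components (season, latent trend, AR(1) noise) are held
piecewise-constant over a "process day" running 02:00-01:59 local time, so
that the whole night window 22:00-01:59 sees a single daily value.  This
makes noise-free nightly aggregates match the satellite value exactly (up to
the configured bias), which downstream modules rely on for exact checks.

A second generator, :func:`simulate_latent_panel`, draws directly from the
multivariate random-walk observation model used by the state-space module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .ingest import LoggerSeries

DEFAULT_REGIONS = ("Northern", "Western", "Southern")

#: Default mean-temperature offsets (degC) between regions, mirroring the
#: typical ordering on Palauan barrier reefs: Western warmest, Northern
#: coolest (more water movement), Southern intermediate.
DEFAULT_REGION_OFFSETS = {"Northern": -0.2, "Western": 0.1, "Southern": 0.0}

#: Hour of day (local) at which the diurnal sinusoid peaks.
DIURNAL_PEAK_HOUR = 15.0

_TEN_MIN_PER_DAY = 144


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the paired logger/satellite generator.

    Defaults describe a plausible tropical reef setting: base temperature
    near 29 degC with a ~1 degC seasonal swing peaking in July, a 0.5 degC
    diurnal amplitude at logger depth, a -0.58 degC satellite bias, and
    moderately persistent daily noise (AR(1) phi = 0.7, sigma = 0.2 degC).
    """

    start_date: str = "2018-01-01"
    end_date: str = "2019-12-31"
    regions: tuple[str, ...] = DEFAULT_REGIONS
    loggers_per_region: int = 3
    base_temp_c: float = 28.8
    seasonal_amplitude: float = 1.2
    seasonal_phase: float = 196.0  # day-of-year of the seasonal peak
    diurnal_amplitude: float = 0.5
    origin_bias: float = -0.58  # SSST minus in situ, degC
    ar1_phi: float = 0.7
    ar1_sigma: float = 0.2
    jitter_sigma: float = 0.02
    logger_spread_sigma: float = 0.1  # SD of constant per-logger offsets
    latent_sigma_shared: float = 0.02  # random-walk innovation SD, degC/day
    latent_sigma_specific: float = 0.01
    region_offsets: Mapping[str, float] | None = None
    gap_schedule: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if not abs(self.ar1_phi) < 1:
            raise ValueError("ar1_phi must satisfy |phi| < 1")
        for name in (
            "ar1_sigma",
            "jitter_sigma",
            "logger_spread_sigma",
            "latent_sigma_shared",
            "latent_sigma_specific",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        start, end = pd.Timestamp(self.start_date), pd.Timestamp(self.end_date)
        if start >= end:
            raise ValueError("start_date must precede end_date")
        if (end - start) < pd.Timedelta(days=2):
            raise ValueError("date span shorter than 2 days is degenerate")
        if self.loggers_per_region < 1:
            raise ValueError("need at least one logger per region")

    def offsets(self) -> dict[str, float]:
        if self.region_offsets is not None:
            return dict(self.region_offsets)
        return {r: DEFAULT_REGION_OFFSETS.get(r, 0.0) for r in self.regions}


@dataclass
class GroundTruth:
    """Generating parameters plus the realized per-logger draws.

    ``night_diurnal_factor`` is the mean of the diurnal sinusoid over the
    10-minute sample times of the night window; the satellite value includes
    ``diurnal_amplitude * night_diurnal_factor`` so that (in situ nightly
    mean - SSST) equals exactly ``-origin_bias`` in the noise-free case.
    """

    config: SyntheticConfig
    night_diurnal_factor: float
    region_offsets: dict[str, float]
    logger_offsets: dict[str, float]
    logger_depths: dict[str, float]

    def to_flat_dict(self) -> dict[str, object]:
        flat: dict[str, object] = {}
        for k, v in asdict(self.config).items():
            flat[f"config.{k}"] = v
        flat["night_diurnal_factor"] = self.night_diurnal_factor
        for r, v in self.region_offsets.items():
            flat[f"region_offset.{r}"] = v
        for l, v in self.logger_offsets.items():
            flat[f"logger_offset.{l}"] = v
        for l, v in self.logger_depths.items():
            flat[f"logger_depth.{l}"] = v
        return flat

    def write(self, path) -> None:
        lines = [f"{k} = {v!r}" for k, v in self.to_flat_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class SyntheticDataset:
    loggers: list[LoggerSeries]
    ssst: pd.DataFrame  # columns: region, date, sst_c
    truth: GroundTruth


def night_diurnal_factor(
    night_window: tuple[int, int] = (22, 2),
    peak_hour: float = DIURNAL_PEAK_HOUR,
) -> float:
    """Mean of the unit diurnal sinusoid over the night window's 10-minute grid."""
    start, end = night_window
    n_hours = (end - start) % 24
    hours = (start + np.arange(n_hours * 6) / 6.0) % 24
    return float(np.mean(np.cos(2 * np.pi * (hours - peak_hour) / 24.0)))


def _ar1(rng: np.random.Generator, phi: float, sigma: float, n: int) -> np.ndarray:
    """Stationary AR(1) path of length n (returns zeros when sigma == 0)."""
    innov = rng.normal(0.0, sigma, size=n)
    if sigma == 0.0:
        return np.zeros(n)
    x0 = rng.normal(0.0, sigma / np.sqrt(1 - phi**2))
    path = lfilter([1.0], [1.0, -phi], innov)
    # add the decaying contribution of the stationary initial value
    path += x0 * phi ** np.arange(1, n + 1)
    return path


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate paired in situ logger series and daily regional SSST.

    Returns per-logger :class:`~reeftherm.ingest.LoggerSeries` at 10-minute
    cadence (with the configured gap intervals removed), a daily SSST table
    (``region, date, sst_c``), and the :class:`GroundTruth` record of every
    generating parameter and realized draw.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    offsets = config.offsets()

    days = pd.date_range(config.start_date, config.end_date, freq="D")
    n_days = len(days)
    doy = days.dayofyear.to_numpy()
    seasonal = config.base_temp_c + config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.seasonal_phase) / 365.25
    )

    shared_trend = np.cumsum(rng.normal(0.0, config.latent_sigma_shared, n_days))
    region_trend = {
        r: shared_trend + np.cumsum(rng.normal(0.0, config.latent_sigma_specific, n_days))
        for r in config.regions
    }
    insitu_noise = {r: _ar1(rng, config.ar1_phi, config.ar1_sigma, n_days) for r in config.regions}
    ssst_noise = {r: _ar1(rng, config.ar1_phi, config.ar1_sigma, n_days) for r in config.regions}

    nd_factor = night_diurnal_factor()

    # --- satellite table --------------------------------------------------
    ssst_frames = []
    for r in config.regions:
        value = (
            seasonal
            + offsets[r]
            + region_trend[r]
            + config.diurnal_amplitude * nd_factor
            + config.origin_bias
            + ssst_noise[r]
        )
        ssst_frames.append(pd.DataFrame({"region": r, "date": days, "sst_c": value}))
    ssst = pd.concat(ssst_frames, ignore_index=True)

    # --- logger records ---------------------------------------------------
    # Records run from 02:00 of the first day to 01:50 following the last
    # day, so every "process day" (02:00-01:59) in the span is complete.
    start = days[0] + pd.Timedelta(hours=2)
    timestamps = start + pd.to_timedelta(np.arange(n_days * _TEN_MIN_PER_DAY) * 10, unit="min")
    day_index = np.asarray((timestamps - pd.Timedelta(hours=2)).normalize().view("int64"))
    day_index = ((day_index - day_index[0]) // 86_400_000_000_000).astype(int)
    hour = timestamps.hour.to_numpy() + timestamps.minute.to_numpy() / 60.0
    diurnal = config.diurnal_amplitude * np.cos(2 * np.pi * (hour - DIURNAL_PEAK_HOUR) / 24.0)

    gap_mask = np.zeros(len(timestamps), dtype=bool)
    ts_day = timestamps.normalize()
    for g_start, g_end in config.gap_schedule:
        gap_mask |= np.asarray((ts_day >= pd.Timestamp(g_start)) & (ts_day < pd.Timestamp(g_end)))

    loggers: list[LoggerSeries] = []
    logger_offsets: dict[str, float] = {}
    logger_depths: dict[str, float] = {}
    for r in config.regions:
        base = (seasonal + offsets[r] + region_trend[r] + insitu_noise[r])[day_index] + diurnal
        for j in range(config.loggers_per_region):
            logger_id = f"{r[:1]}{j + 1:02d}"
            offset = float(rng.normal(0.0, config.logger_spread_sigma))
            depth = float(np.round(rng.uniform(1.0, 5.0), 1))
            jitter = rng.normal(0.0, config.jitter_sigma, len(timestamps))
            temp = base + offset + jitter
            rec = pd.DataFrame(
                {"timestamp": timestamps[~gap_mask], "temp_c": temp[~gap_mask]}
            ).reset_index(drop=True)
            rec["qc_ok"] = True
            logger_offsets[logger_id] = offset
            logger_depths[logger_id] = depth
            loggers.append(
                LoggerSeries(
                    logger_id=logger_id,
                    region=r,
                    depth_m=depth,
                    records=rec,
                    deployment_date=rec["timestamp"].iloc[0],
                    retrieval_date=rec["timestamp"].iloc[-1],
                )
            )

    truth = GroundTruth(
        config=config,
        night_diurnal_factor=nd_factor,
        region_offsets=offsets,
        logger_offsets=logger_offsets,
        logger_depths=logger_depths,
    )
    return SyntheticDataset(loggers=loggers, ssst=ssst, truth=truth)


def loggers_to_frame(loggers: Sequence[LoggerSeries]) -> pd.DataFrame:
    """Flatten logger series into the CSV schema
    (logger_id, region, depth_m, timestamp, temp_c)."""
    frames = []
    for s in loggers:
        frames.append(
            pd.DataFrame(
                {
                    "logger_id": s.logger_id,
                    "region": s.region,
                    "depth_m": s.depth_m,
                    "timestamp": s.records["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S"),
                    "temp_c": s.records["temp_c"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write loggers.csv, ssst.csv and ground_truth.txt to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "loggers": out / "loggers.csv",
        "ssst": out / "ssst.csv",
        "truth": out / "ground_truth.txt",
    }
    loggers_to_frame(dataset.loggers).to_csv(paths["loggers"], index=False)
    sat = dataset.ssst.copy()
    sat["date"] = sat["date"].dt.strftime("%Y-%m-%d")
    sat.to_csv(paths["ssst"], index=False)
    dataset.truth.write(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Daily paired-series generators for inference studies
# ---------------------------------------------------------------------------


def simulate_paired_series(
    n: int,
    seed: int,
    slope: float = 1.0,
    bias: float = 0.0,
    phi_error: float = 0.7,
    sigma_error: float = 0.3,
    phi_x: float = 0.5,
    sigma_x: float = 1.0,
    error: str = "ar1",
    start_date: str = "2018-01-01",
) -> pd.DataFrame:
    """Paired daily (ssst, insitu) series with a known linear relation.

    ``insitu = bias + slope * ssst + e`` where the predictor anomaly is
    AR(1) with persistence ``phi_x`` and the error is AR(1) (``error=
    "ar1"``) with the given persistence, or white noise (``error="iid"``).
    ``bias`` is the in situ minus satellite offset (the negative of the
    satellite origin bias).  Used for type-I-error calibration and
    bias-recovery studies of the comparison regression.
    """
    rng = np.random.default_rng(seed)
    x = _ar1(rng, phi_x, sigma_x, n)
    if error == "ar1":
        e = _ar1(rng, phi_error, sigma_error, n)
    elif error == "iid":
        e = rng.normal(0.0, sigma_error, n)
    else:
        raise ValueError(f"unknown error kind {error!r}")
    dates = pd.date_range(start_date, periods=n, freq="D")
    frame = pd.DataFrame({"insitu": bias + slope * x + e, "ssst": x}, index=dates)
    frame.index.name = "date"
    frame["block_id"] = 0
    return frame


def simulate_paired_panel(
    n: int,
    seed: int,
    regions: Sequence[str] = DEFAULT_REGIONS,
    slope: float = 1.0,
    bias: float = 0.0,
    phi_error: float = 0.7,
    phi_x: float = 0.5,
    sigma_x_shared: float = 0.8,
    sigma_x_specific: float = 0.5,
    sigma_e_shared: float = 0.2,
    sigma_e_specific: float = 0.2,
    start_date: str = "2018-01-01",
) -> dict[str, pd.DataFrame]:
    """Multi-region paired panels sharing common predictor and error
    components, for Driscoll-Kraay calibration studies.

    Each region's predictor is a shared AR(1) plus a region-specific AR(1)
    (persistence ``phi_x``); errors likewise share a common AR(1) component
    (persistence ``phi_error``), giving the cross-sectional correlation the
    Driscoll-Kraay estimator is designed for.
    """
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start_date, periods=n, freq="D")
    x_common = _ar1(rng, phi_x, sigma_x_shared, n)
    e_common = _ar1(rng, phi_error, sigma_e_shared, n)
    panels = {}
    for r in regions:
        x = x_common + _ar1(rng, phi_x, sigma_x_specific, n)
        e = e_common + _ar1(rng, phi_error, sigma_e_specific, n)
        frame = pd.DataFrame({"insitu": bias + slope * x + e, "ssst": x}, index=dates)
        frame.index.name = "date"
        frame["block_id"] = 0
        panels[r] = frame
    return panels


# ---------------------------------------------------------------------------
# Latent random-walk panel generator (state-space ground truth)
# ---------------------------------------------------------------------------

ORIGINS = ("insitu", "ssst")


def panel_series_names(regions: Sequence[str] = DEFAULT_REGIONS) -> list[str]:
    return [f"{o}_{r}" for o in ORIGINS for r in regions]


@dataclass
class LatentPanel:
    """Simulated multivariate random-walk panel with its generating truth."""

    observations: pd.DataFrame  # standardized (or raw, see `standardized`)
    raw: pd.DataFrame
    states: pd.DataFrame
    grouping: str
    state_of_series: dict[str, str]
    loadings: dict[str, float]
    shared_sigma2: float
    specific_sigma2: dict[str, float]
    obs_sigma2: dict[str, float]
    standardized: bool


def innovation_covariance(
    shared_sigma2: float, specific_sigma2: Sequence[float]
) -> np.ndarray:
    """Compound-symmetric process covariance Q = shared * J + diag(specific)."""
    m = len(specific_sigma2)
    q = np.full((m, m), shared_sigma2) + np.diag(np.asarray(specific_sigma2, dtype=float))
    eig = np.linalg.eigvalsh(q)
    if eig.min() < -1e-12:
        raise ValueError("implied innovation covariance is not positive semi-definite")
    return q


def simulate_latent_panel(
    grouping: str,
    T: int,
    loadings: Mapping[str, float] | None = None,
    shared_sigma2: float = 0.01,
    specific_sigma2: Mapping[str, float] | float = 0.02,
    obs_sigma2: Mapping[str, float] | float = 0.05,
    regions: Sequence[str] = DEFAULT_REGIONS,
    seed: int = 0,
    standardize: bool = True,
) -> LatentPanel:
    """Draw six observed series from grouped latent random walks.

    ``grouping`` is ``"region"`` (each region has a latent state, observed
    by both origins) or ``"origin"`` (each data origin has a latent state,
    observed in all regions).  States evolve as random walks whose
    innovations have compound-symmetric covariance ``shared_sigma2 * J +
    diag(specific_sigma2)``; each observed series is ``loading * state``
    plus Gaussian observation error.  With ``standardize=True`` (the form
    consumed by the state-space module) each series is z-scored; ``raw``
    keeps the unscaled values for parameter-recovery checks.
    """
    if T < 10:
        raise ValueError("T must be at least 10")
    if grouping == "region":
        states = list(regions)
        state_of = {name: name.split("_", 1)[1] for name in panel_series_names(regions)}
    elif grouping == "origin":
        states = list(ORIGINS)
        state_of = {name: name.split("_", 1)[0] for name in panel_series_names(regions)}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    names = panel_series_names(regions)
    if loadings is None:
        loadings = {name: 1.0 for name in names}
    if not isinstance(specific_sigma2, Mapping):
        specific_sigma2 = {s: float(specific_sigma2) for s in states}
    if not isinstance(obs_sigma2, Mapping):
        obs_sigma2 = {name: float(obs_sigma2) for name in names}

    q = innovation_covariance(shared_sigma2, [specific_sigma2[s] for s in states])
    rng = np.random.default_rng(seed)
    innov = rng.multivariate_normal(np.zeros(len(states)), q, size=T, method="svd")
    x = np.cumsum(innov, axis=0)
    states_df = pd.DataFrame(x, columns=states, index=pd.RangeIndex(T, name="t"))

    obs = {}
    for name in names:
        s = state_of[name]
        noise = rng.normal(0.0, np.sqrt(obs_sigma2[name]), size=T)
        obs[name] = loadings[name] * states_df[s].to_numpy() + noise
    raw = pd.DataFrame(obs, index=states_df.index)

    if standardize:
        z = (raw - raw.mean()) / raw.std(ddof=1)
    else:
        z = raw.copy()

    return LatentPanel(
        observations=z,
        raw=raw,
        states=states_df,
        grouping=grouping,
        state_of_series=state_of,
        loadings=dict(loadings),
        shared_sigma2=float(shared_sigma2),
        specific_sigma2=dict(specific_sigma2),
        obs_sigma2=dict(obs_sigma2),
        standardized=standardize,
    )
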