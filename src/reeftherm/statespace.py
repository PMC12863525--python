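"""Multivariate random-walk latent-state models for paired temperature panels.

Six standardized nightly-mean series (two data origins x three regions) are
modelled as noisy observations of a small number of latent random walks
under two competing groupings:

* ``"region"`` — three latent states, one per region, observed by both the
  in situ and satellite series of that region (the hypothesis that the two
  origins measure the same regional trend with error);
* ``"origin"`` — two latent states, one per data origin, observed in all
  three regions (the hypothesis that in situ and satellite data track
  distinct sub-surface vs. skin-layer trends shared among regions).

States evolve as random walks with compound-symmetric innovation covariance
``Q = shared * J + diag(specific)`` (variance shared among states plus
state-specific variance); each series has its own loading and observation
error variance.  Likelihoods come from the Kalman filter (statsmodels'
state-space machinery, which handles missing observations entry-wise);
models are compared by AIC and each series' variability is partitioned, on
the innovation scale, into group-shared, inter-group, and observation-error
components.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.statespace.mlemodel import MLEModel

#: Approximate-diffuse initial state variance.
DIFFUSE_VARIANCE = 1e7

GROUPINGS = ("region", "origin")


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateSpaceSpec:
    """Mapping of observed series onto latent states for one grouping.

    Series are named ``{origin}_{region}`` (e.g. ``insitu_Northern``).  The
    first series loading on each state is fixed at 1 for identifiability;
    the remaining loadings, the shared and state-specific innovation
    variances, and the per-series observation variances are free.
    """

    grouping: str
    series: tuple[str, ...]
    states: tuple[str, ...]
    state_index: tuple[int, ...]  # series -> state position
    fixed_loading: tuple[bool, ...]

    @classmethod
    def for_series(cls, series: Sequence[str], grouping: str) -> "StateSpaceSpec":
        if grouping not in GROUPINGS:
            raise ValueError(f"grouping must be one of {GROUPINGS}")
        part = 0 if grouping == "origin" else 1
        labels = [name.split("_", 1)[part] for name in series]
        states = tuple(dict.fromkeys(labels))  # preserve first-seen order
        state_index = tuple(states.index(l) for l in labels)
        seen: set[int] = set()
        fixed = []
        for si in state_index:
            fixed.append(si not in seen)
            seen.add(si)
        return cls(
            grouping=grouping,
            series=tuple(series),
            states=states,
            state_index=state_index,
            fixed_loading=tuple(fixed),
        )

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def k_params(self) -> int:
        """Free parameters: non-fixed loadings + shared variance +
        state-specific variances + per-series observation variances."""
        return (self.n_series - self.n_states) + 1 + self.n_states + self.n_series


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class _LatentWalkModel(MLEModel):
    """statsmodels state-space model: grouped random walks + loadings.

    Parameter vector: free loadings (in series order), then log shared
    innovation variance, log state-specific variances, log observation
    variances.  ``free_mask`` selects which loadings are free; fixed ones
    are pinned at 1.
    """

    def __init__(
        self,
        endog: pd.DataFrame,
        spec: StateSpaceSpec,
        free_mask: Sequence[bool] | None = None,
        initial_variance: float = DIFFUSE_VARIANCE,
    ):
        self.spec = spec
        self.free_mask = (
            np.asarray(free_mask, dtype=bool)
            if free_mask is not None
            else ~np.asarray(spec.fixed_loading)
        )
        m = spec.n_states
        # plain ndarray endog: the date index is carried by the caller, and
        # statsmodels would otherwise warn about index frequency
        super().__init__(np.asarray(endog, dtype=float), k_states=m)
        # approximate-diffuse prior: x_1 ~ N(0, kappa I)
        self.ssm.initialize_known(np.zeros(m), initial_variance * np.eye(m))
        self.ssm["transition"] = np.eye(m)
        self.ssm["selection"] = np.eye(m)

    @property
    def param_names(self):
        names = [f"loading.{s}" for s, free in zip(self.spec.series, self.free_mask) if free]
        names.append("log_var.shared")
        names += [f"log_var.state.{s}" for s in self.spec.states]
        names += [f"log_var.obs.{s}" for s in self.spec.series]
        return names

    @property
    def start_params(self):
        p = self.spec.n_series
        diffs = np.diff(np.asarray(self.endog, dtype=float), axis=0)
        v = np.nanvar(diffs, axis=0)
        v0 = float(np.nanmean(v)) if np.isfinite(np.nanmean(v)) else 0.1
        v0 = max(v0, 1e-4)
        return np.concatenate(
            [
                np.ones(int(self.free_mask.sum())),
                [np.log(v0 / 4.0)],
                np.full(self.spec.n_states, np.log(v0 / 2.0)),
                np.full(p, np.log(v0 / 2.0)),
            ]
        )

    def unpack(self, params: np.ndarray):
        params = np.asarray(params, dtype=float)
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite parameters")
        n_free = int(self.free_mask.sum())
        m = self.spec.n_states
        p = self.spec.n_series
        loadings = np.ones(p)
        loadings[self.free_mask] = params[:n_free]
        shared = np.exp(params[n_free])
        specific = np.exp(params[n_free + 1 : n_free + 1 + m])
        obs = np.exp(params[n_free + 1 + m : n_free + 1 + m + p])
        return loadings, shared, specific, obs

    def update(self, params, **kwargs):
        params = super().update(params, **kwargs)
        loadings, shared, specific, obs = self.unpack(params)
        m, p = self.spec.n_states, self.spec.n_series
        design = np.zeros((p, m))
        design[np.arange(p), list(self.spec.state_index)] = loadings
        self.ssm["design"] = design
        self.ssm["state_cov"] = np.full((m, m), shared) + np.diag(specific)
        self.ssm["obs_cov"] = np.diag(obs)
        return params


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def standardize(series: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score each column (full-series mean and SD, ddof=1).

    Missing entries stay missing.  Returns the standardized frame and a
    frame of the per-series ``mean``/``sd`` used, for inversion.  A
    zero-variance series is an error.
    """
    mean = series.mean()
    sd = series.std(ddof=1)
    if (series.count() < 2).any():
        raise ValueError("every series needs at least 2 non-missing values")
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance series cannot be standardized: {bad}")
    stats = pd.DataFrame({"mean": mean, "sd": sd})
    return (series - mean) / sd, stats


def unstandardize(z: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`standardize` using its stored statistics."""
    return z * stats["sd"] + stats["mean"]


def _fingerprint(endog: pd.DataFrame) -> str:
    arr = np.ascontiguousarray(endog.to_numpy(dtype=float))
    return hashlib.sha1(arr.tobytes()).hexdigest()


def kalman_loglik(
    observations: pd.DataFrame,
    grouping: str,
    loadings: Mapping[str, float] | Sequence[float],
    shared_var: float,
    specific_var: Mapping[str, float] | Sequence[float],
    obs_var: Mapping[str, float] | Sequence[float],
    initial_variance: float = DIFFUSE_VARIANCE,
) -> float:
    """Exact Gaussian log-likelihood of fixed parameters via the Kalman filter.

    ``observations`` is a (T x p) frame (NaNs allowed and skipped
    entry-wise).  The state transition is the identity (random walk) with a
    known N(0, ``initial_variance`` I) initial state.
    """
    spec = StateSpaceSpec.for_series(list(observations.columns), grouping)
    model = _LatentWalkModel(
        observations, spec, free_mask=np.ones(spec.n_series, dtype=bool),
        initial_variance=initial_variance,
    )
    if isinstance(loadings, Mapping):
        loadings = [loadings[s] for s in spec.series]
    if isinstance(specific_var, Mapping):
        specific_var = [specific_var[s] for s in spec.states]
    if isinstance(obs_var, Mapping):
        obs_var = [obs_var[s] for s in spec.series]
    for name, vals in (("specific", specific_var), ("obs", obs_var)):
        if np.any(np.asarray(vals, dtype=float) < 0):
            raise ValueError(f"negative {name} variance")
    if shared_var < 0:
        raise ValueError("negative shared variance")
    floor = 1e-300  # exp/log round trip for exact-zero variances
    params = np.concatenate(
        [
            np.asarray(loadings, dtype=float),
            [np.log(max(shared_var, floor))],
            np.log(np.maximum(np.asarray(specific_var, dtype=float), floor)),
            np.log(np.maximum(np.asarray(obs_var, dtype=float), floor)),
        ]
    )
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameters")
    return float(model.loglike(params))


@dataclass
class StateSpaceFit:
    """Maximum-likelihood fit of one grouping's latent random-walk model."""

    spec: StateSpaceSpec
    loadings: pd.Series  # per series, fixed ones = 1
    shared_var: float
    specific_var: pd.Series  # per state
    obs_var: pd.Series  # per series
    loglik: float
    k: int
    aic: float
    smoothed_states: pd.DataFrame
    smoothed_state_var: pd.DataFrame
    converged: bool
    n_obs: int
    data_fingerprint: str

    @property
    def grouping(self) -> str:
        return self.spec.grouping


def fit_statespace(
    observations: pd.DataFrame,
    grouping: str,
    n_starts: int = 5,
    seed: int = 0,
    maxiter: int = 2000,
    initial_variance: float = DIFFUSE_VARIANCE,
) -> StateSpaceFit:
    """Maximize the likelihood over loadings, innovation and observation
    variances, from multiple seeded starts.

    The first start is a moment-based initialization (loadings 1, variances
    split from the mean first-difference variance); the rest perturb it with
    seeded Gaussian noise.  The best converged start is kept; if every start
    fails, an error carries the best diagnostics.
    """
    spec = StateSpaceSpec.for_series(list(observations.columns), grouping)
    model = _LatentWalkModel(observations, spec, initial_variance=initial_variance)
    rng = np.random.default_rng(seed)
    base = model.start_params
    starts = [base]
    for _ in range(max(0, n_starts - 1)):
        starts.append(base + rng.normal(0.0, 0.5, size=base.shape))

    best = None
    errors: list[str] = []
    for sp in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(start_params=sp, method="lbfgs", maxiter=maxiter,
                                disp=False)
            ll = float(res.llf)
            if np.isfinite(ll) and (best is None or ll > best[0]):
                best = (ll, res)
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            errors.append(str(exc))
    if best is None:
        raise RuntimeError(f"state-space fit failed from all starts: {errors}")

    ll, res = best
    loadings, shared, specific, obs = model.unpack(res.params)
    k = spec.k_params
    aic = -2.0 * ll + 2.0 * k
    sm_states = pd.DataFrame(
        res.smoothed_state.T, index=observations.index, columns=list(spec.states)
    )
    sm_var = pd.DataFrame(
        np.diagonal(res.smoothed_state_cov, axis1=0, axis2=1),
        index=observations.index,
        columns=list(spec.states),
    )
    return StateSpaceFit(
        spec=spec,
        loadings=pd.Series(loadings, index=list(spec.series)),
        shared_var=float(shared),
        specific_var=pd.Series(specific, index=list(spec.states)),
        obs_var=pd.Series(obs, index=list(spec.series)),
        loglik=ll,
        k=k,
        aic=aic,
        smoothed_states=sm_states,
        smoothed_state_var=sm_var,
        converged=bool(res.mle_retvals.get("converged", True))
        if isinstance(getattr(res, "mle_retvals", None), dict)
        else True,
        n_obs=int(observations.count().sum()),
        data_fingerprint=_fingerprint(observations),
    )


@dataclass
class ModelComparison:
    aic: dict[str, float]
    delta_aic: float  # aic(first) - aic(second)
    selected: str


def compare_models(fit_a: StateSpaceFit, fit_b: StateSpaceFit) -> ModelComparison:
    """AIC comparison of two fits on identical data (lower AIC wins)."""
    if fit_a.data_fingerprint != fit_b.data_fingerprint:
        raise ValueError("fits were computed on different data")
    aic = {fit_a.grouping: fit_a.aic, fit_b.grouping: fit_b.aic}
    selected = fit_a.grouping if fit_a.aic <= fit_b.aic else fit_b.grouping
    return ModelComparison(aic=aic, delta_aic=fit_a.aic - fit_b.aic, selected=selected)


def variance_partition(fit: StateSpaceFit) -> pd.DataFrame:
    """Per-series decomposition of innovation-scale variance into proportions.

    Random walks are nonstationary, so the decomposition uses the variance
    of one-step increments: for series *i* loading on state *s*,

    * ``group_shared``  = loading^2 x state-specific innovation variance
      (variation shared with other series observing the same state),
    * ``inter_origin``  = loading^2 x shared innovation variance (variation
      common to all states, i.e. crossing the grouping),
    * ``obs_error``     = the series' observation error variance.

    Proportions are normalized to sum to 1 per series and are invariant to
    rescaling all series by a common factor.
    """
    rows = {}
    for i, name in enumerate(fit.spec.series):
        lam2 = float(fit.loadings[name]) ** 2
        state = fit.spec.states[fit.spec.state_index[i]]
        comps = np.array(
            [
                lam2 * float(fit.specific_var[state]),
                lam2 * fit.shared_var,
                float(fit.obs_var[name]),
            ]
        )
        total = comps.sum()
        if total <= 0:
            raise ValueError(f"series {name} has degenerate (zero) total variance")
        rows[name] = comps / total
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["group_shared", "inter_origin", "obs_error"]
    )
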