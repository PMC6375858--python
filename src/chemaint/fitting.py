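"""Single-parameter calibration of the chemostat models to biomass data.

Four one-knob strategies, mirroring how maintenance models are adjusted in
practice: scale the shared decay rate (``kdec``), scale all gross yields
(``y_scale``), set the maintenance energy coefficient (``m``), or scale all
maximum yields (``ymax_scale``). The objective is the sum of squared
relative deviations of predicted from observed total biomass across
dilution rates, minimized by a deterministic bounded scalar search; the
module also produces the percent-deviation report (per dilution rate and
for the high/low biomass ratio) used to compare models against the
two-reactor experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import defaults
from .herbert import FeedSpec, GuildKinetics, ReactorConfig, steady_state_chain
from .pirt import TBASpec, community_tba
from .units import ThermoContext

STRATEGIES = ("kdec", "y_scale", "m", "ymax_scale")


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class Observation:
    d: float
    x_obs: float  # gVS/L
    sem: float = 0.0
    residual_vfa: float | None = None
    ch4_rate: float | None = None

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise FitError("dilution rate must be positive")
        if self.x_obs < 0 or self.sem < 0:
            raise FitError("biomass and SEM must be >= 0")


@dataclass(frozen=True)
class ObservationSet:
    rows: tuple[Observation, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise FitError("at least one observation required")

    @property
    def d(self) -> np.ndarray:
        return np.array([r.d for r in self.rows])

    @property
    def x_obs(self) -> np.ndarray:
        return np.array([r.x_obs for r in self.rows])

    @property
    def sem(self) -> np.ndarray:
        return np.array([r.sem for r in self.rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                d_per_day=self.d,
                x_gvs_per_l=self.x_obs,
                sem_gvs_per_l=self.sem,
                vfa_gcod_per_l=[r.residual_vfa for r in self.rows],
                ch4_l_per_day=[r.ch4_rate for r in self.rows],
            )
        )

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[float, float]], sem: float = 0.0):
        return cls(tuple(Observation(d=d, x_obs=x, sem=sem) for d, x in pairs))


@dataclass(frozen=True)
class DeviationReport:
    """Percent deviations of predictions from observations."""

    d: tuple[float, ...]
    percent: tuple[float, ...]  # 100 (pred - obs)/obs per dilution rate
    ratio_percent: float | None  # biomass-ratio error for the two-rate case


def deviation_report(
    predicted: Mapping[float, float] | Sequence[float], obs: ObservationSet
) -> DeviationReport:
    """Per-rate percent deviation and, for two rates, the ratio deviation
    ``100 [(pred_hi/pred_lo) / (obs_hi/obs_lo) - 1]`` (hi = larger D)."""
    if isinstance(predicted, Mapping):
        try:
            pred = np.array([predicted[r.d] for r in obs.rows])
        except KeyError as exc:
            raise FitError(f"prediction missing for dilution rate {exc}") from exc
    else:
        pred = np.asarray(list(predicted), dtype=float)
        if pred.shape != obs.d.shape:
            raise FitError("predicted and observed lengths differ")
    if np.any(obs.x_obs <= 0):
        raise FitError("percent deviations need positive observations")
    percent = 100.0 * (pred - obs.x_obs) / obs.x_obs
    ratio = None
    if len(obs.rows) == 2 and obs.rows[0].d != obs.rows[1].d:
        hi, lo = (0, 1) if obs.rows[0].d > obs.rows[1].d else (1, 0)
        if pred[lo] > 0:
            ratio = 100.0 * (
                (pred[hi] / pred[lo]) / (obs.x_obs[hi] / obs.x_obs[lo]) - 1.0
            )
    return DeviationReport(d=tuple(obs.d), percent=tuple(percent), ratio_percent=ratio)


@dataclass
class FitResult:
    strategy: str
    fitted_value: float
    predicted: dict[float, float]
    deviations: DeviationReport
    objective_value: float
    bounds: tuple[float, float]
    n_evaluations: int


Predictor = Callable[[float, float], float]  # (theta, d) -> total biomass gVS/L


def make_predictor(
    strategy: str,
    *,
    guilds: Sequence[GuildKinetics] | None = None,
    feed: FeedSpec | None = None,
    config: ReactorConfig | None = None,
    ctx: ThermoContext | None = None,
    y_max_override: Mapping[str, float] | None = None,
    complete_conversion: bool = False,
) -> Predictor:
    """Bind a model family and a strategy into ``f(theta, d) -> gVS/L``.

    ``kdec``/``y_scale`` rebuild the Herbert chain with the shared decay rate
    set to theta / all gross yields multiplied by theta; ``m``/``ymax_scale``
    rebuild the TBA spec with maintenance energy theta (kJ Cmol^-1 h^-1) /
    all Y_max multiplied by theta.
    """
    if strategy not in STRATEGIES:
        raise FitError(f"unknown strategy {strategy!r}; options {STRATEGIES}")
    feed = feed or FeedSpec(defaults.FEED_TOTAL_COD, defaults.FEED_FRACTIONS)
    config = config or ReactorConfig()
    ctx = ctx or ThermoContext()

    if strategy in ("kdec", "y_scale"):
        base = list(guilds or defaults.adm1_guilds())

        def predict(theta: float, d: float) -> float:
            if strategy == "kdec":
                mod = [replace(g, k_dec=theta) for g in base]
            else:
                mod = [replace(g, y=g.y * theta) for g in base]
            state = steady_state_chain(
                mod, feed, replace(config, d=d),
                complete_conversion=complete_conversion,
            )
            return state.total_biomass_gvs

        return predict

    def predict_tba(theta: float, d: float) -> float:
        if strategy == "m":
            spec = TBASpec.from_context(
                replace(ctx, m_g=theta), y_max_override=y_max_override
            )
        else:
            spec = TBASpec.from_context(replace(ctx, m_g=ctx.m_g), y_max_override=y_max_override)
            spec = TBASpec(
                ctx=spec.ctx,
                y_max={k: v * theta for k, v in spec.y_max.items()},
                maintenance=spec.maintenance,
                product_fractions=spec.product_fractions,
            )
        state = community_tba(feed, spec, replace(config, d=d))
        return state.total_biomass_gvs

    return predict_tba


DEFAULT_BOUNDS = {
    "kdec": (0.0, 0.5),
    "y_scale": (1e-3, 2.0),
    "m": (0.0, 20.0),
    "ymax_scale": (1e-3, 50.0),
}


def fit_scalar(
    predictor: Predictor,
    strategy: str,
    obs: ObservationSet,
    bounds: tuple[float, float] | None = None,
    *,
    objective: str = "relative",
    sem_weighted: bool = False,
    xatol: float = 1e-10,
) -> FitResult:
    """Deterministic bounded scalar least squares on total biomass.

    ``objective='relative'`` minimizes sum(((pred-obs)/obs)^2); ``'absolute'``
    uses raw residuals; ``sem_weighted`` divides residuals by the SEM where
    it is positive. Predictor failures propagate with the offending theta.
    """
    if strategy not in STRATEGIES:
        raise FitError(f"unknown strategy {strategy!r}")
    lo, hi = bounds or DEFAULT_BOUNDS[strategy]
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise FitError("bounds must be finite with lo < hi")
    n_eval = 0

    def objective_fn(theta: float) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            pred = np.array([predictor(theta, r.d) for r in obs.rows])
        except Exception as exc:
            raise FitError(f"predictor failed at parameter {theta!r}: {exc}") from exc
        if objective == "relative":
            resid = (pred - obs.x_obs) / obs.x_obs
        elif objective == "absolute":
            resid = pred - obs.x_obs
        else:
            raise FitError(f"unknown objective {objective!r}")
        if sem_weighted:
            sem = np.where(obs.sem > 0, obs.sem, 1.0)
            resid = resid / sem
        return float(np.sum(resid**2))

    res = minimize_scalar(
        objective_fn, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    theta = float(res.x)
    # the bounded search never evaluates the exact endpoints; snap if better
    for edge in (lo, hi):
        if objective_fn(edge) < res.fun:
            theta = edge
    predicted = {r.d: predictor(theta, r.d) for r in obs.rows}
    report = deviation_report(predicted, obs)
    return FitResult(
        strategy=strategy,
        fitted_value=theta,
        predicted=predicted,
        deviations=report,
        objective_value=objective_fn(theta),
        bounds=(lo, hi),
        n_evaluations=n_eval,
    )


def profile_objective(
    predictor: Predictor,
    strategy: str,
    obs: ObservationSet,
    grid: Sequence[float],
    *,
    objective: str = "relative",
) -> pd.DataFrame:
    """Exact objective evaluations over a parameter grid (no smoothing)."""
    rows = []
    for theta in grid:
        pred = np.array([predictor(theta, r.d) for r in obs.rows])
        if objective == "relative":
            obj = float(np.sum(((pred - obs.x_obs) / obs.x_obs) ** 2))
        else:
            obj = float(np.sum((pred - obs.x_obs) ** 2))
        row = {"parameter": theta, "objective": obj}
        for r, p in zip(obs.rows, pred):
            row[f"dev_pct_d{r.d:g}"] = 100.0 * (p - r.x_obs) / r.x_obs
        rows.append(row)
    return pd.DataFrame(rows)
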