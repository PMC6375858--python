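"""Synthetic chemostat observations with the noise structure of the study.

The generator takes a ground-truth model (Herbert chain, TBA or a dFBA
guild set), computes its steady state per dilution rate, and overlays
i.i.d. Gaussian observation noise; means over replicates are reported with
SEM = sd/sqrt(n), matching how the two-reactor experiment reports biomass
(0.92 +/- 0.03 and 0.94 +/- 0.03 gVS/L). Time series come from the dynamic
simulator with optional feeding disturbances (the real experiment lost feed
pump capacity early on).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import defaults
from .dfba import build_toy_guild, dfba_simulate
from .fitting import Observation, ObservationSet
from .herbert import (
    FeedSpec,
    GuildKinetics,
    ReactorConfig,
    simulate_dynamic,
    steady_state_chain,
)
from .pirt import TBASpec, community_tba
from .units import ThermoContext

MODELS = ("herbert_chain", "pirt_tba", "dfba")


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class GroundTruth:
    """Which model generates the data, with its full parameterization."""

    model: str
    d_list: tuple[float, ...]
    feed: FeedSpec
    reactor: ReactorConfig
    guilds: tuple[GuildKinetics, ...] | None = None  # herbert_chain
    tba: TBASpec | None = None  # pirt_tba
    dfba_guilds: tuple[str, ...] = ()  # dfba (toy guild ids)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise SynthError(f"unknown model {self.model!r}; options {MODELS}")
        if not self.d_list:
            raise SynthError("d_list must be non-empty")

    def total_biomass(self, d: float) -> float:
        """Noise-free steady-state community biomass, gVS/L."""
        if self.model == "herbert_chain":
            state = steady_state_chain(
                list(self.guilds), self.feed, replace(self.reactor, d=d)
            )
            return state.total_biomass_gvs
        if self.model == "pirt_tba":
            return community_tba(
                self.feed, self.tba, replace(self.reactor, d=d)
            ).total_biomass_gvs
        total = 0.0
        for gid in self.dfba_guilds:
            res = dfba_simulate(build_toy_guild(gid), d)
            total += res.steady.x
        return total

    def residual_vfa(self, d: float) -> float:
        if self.model == "herbert_chain":
            state = steady_state_chain(
                list(self.guilds), self.feed, replace(self.reactor, d=d)
            )
            return sum(state.residual.values())
        return 0.0


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian observation noise; draws below zero are truncated (counted)."""

    sd_biomass: float = 0.03  # gVS/L, per replicate
    sd_vfa: float = 0.0  # gCOD/L
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_biomass < 0 or self.sd_vfa < 0:
            raise SynthError("noise sds must be >= 0")
        if self.n_replicates < 1:
            raise SynthError("need at least one replicate")


@dataclass
class GeneratedObservations:
    observations: ObservationSet
    truth: dict[float, float]  # noise-free biomass per d
    truncated: int  # number of negative draws clipped to zero
    washouts: tuple[float, ...]  # dilution rates at which the model washed out


def generate_observations(gt: GroundTruth, noise: NoiseModel) -> GeneratedObservations:
    """Steady state per dilution rate plus replicate-averaged Gaussian noise."""
    rng = np.random.default_rng(noise.seed)
    rows = []
    truth: dict[float, float] = {}
    truncated = 0
    washouts = []
    for d in gt.d_list:
        x_true = gt.total_biomass(d)
        truth[d] = x_true
        if x_true <= 0:
            washouts.append(d)
        draws = x_true + rng.normal(0.0, noise.sd_biomass, size=noise.n_replicates)
        truncated += int(np.sum(draws < 0))
        draws = np.clip(draws, 0.0, None)
        vfa_true = gt.residual_vfa(d)
        if noise.sd_vfa > 0:
            vfa_draws = vfa_true + rng.normal(0.0, noise.sd_vfa, size=noise.n_replicates)
            truncated += int(np.sum(vfa_draws < 0))
            vfa = float(np.mean(np.clip(vfa_draws, 0.0, None)))
        else:
            vfa = vfa_true
        rows.append(
            Observation(
                d=d,
                x_obs=float(np.mean(draws)),
                sem=noise.sd_biomass / np.sqrt(noise.n_replicates),
                residual_vfa=vfa,
            )
        )
    return GeneratedObservations(
        observations=ObservationSet(tuple(rows)),
        truth=truth,
        truncated=truncated,
        washouts=tuple(washouts),
    )


def generate_timeseries(
    gt: GroundTruth,
    noise: NoiseModel,
    sample_times: Sequence[float],
    *,
    d: float | None = None,
    disturbance: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Sampled dynamic trajectory with observation noise.

    ``disturbance=(t_start, t_stop, factor)`` scales the influent by
    ``factor`` (< 1 emulates a failing feed pump) inside the window; methane
    production drops during the window and recovers afterwards. Only the
    Herbert chain supports time series (the other models are steady-state
    constructs here).
    """
    if gt.model != "herbert_chain":
        raise SynthError("time series are generated from the herbert_chain model")
    times = np.asarray(list(sample_times), dtype=float)
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise SynthError("sample times must be strictly increasing and >= 0")
    d = d if d is not None else gt.d_list[0]
    t_end = float(times[-1])
    scale = None
    if disturbance is not None:
        t0, t1, factor = disturbance
        if not 0 <= t0 < t1 <= t_end:
            raise SynthError("disturbance window must lie within the sampled horizon")

        def scale(t: float) -> float:
            return factor if t0 <= t <= t1 else 1.0

    traj = simulate_dynamic(
        list(gt.guilds), gt.feed, replace(gt.reactor, d=d), t_end,
        n_points=max(800, 4 * len(times)), feed_scale=scale,
    )
    rng = np.random.default_rng(noise.seed)
    x_total = np.sum([traj.biomass[g.name] for g in gt.guilds], axis=0)
    x_s = np.interp(times, traj.t, x_total) / ThermoContext().biomass_cod_per_gvs
    vfa_s = np.interp(times, traj.t, np.sum(list(traj.substrate.values()), axis=0))
    ch4_s = np.interp(times, traj.t, traj.methane_rate)
    x_noisy = np.clip(x_s + rng.normal(0, noise.sd_biomass, len(times)), 0, None)
    vfa_noisy = np.clip(vfa_s + rng.normal(0, noise.sd_vfa, len(times)), 0, None)
    return pd.DataFrame(
        dict(
            t_days=times,
            x_gvs_per_l=x_noisy,
            vfa_gcod_per_l=vfa_noisy,
            ch4_l_per_day=ch4_s,
        )
    )


def experiment_fixture(
    *, ctx: ThermoContext | None = None
) -> tuple[GroundTruth, ObservationSet]:
    """The two-reactor study conditions and its printed biomass observations.

    Feed 37.2 gCOD/L split 45/45/10 over acetic/butyric/propionic acid, 6 L
    working volume at 310.15 K, dilution rates 0.18 and 0.07 1/d; observed
    community biomass 0.92 +/- 0.03 and 0.94 +/- 0.03 gVS/L.
    """
    guilds = tuple(defaults.adm1_guilds())
    gt = GroundTruth(
        model="herbert_chain",
        d_list=defaults.DILUTION_RATES,
        feed=FeedSpec(defaults.FEED_TOTAL_COD, defaults.FEED_FRACTIONS),
        reactor=ReactorConfig(
            volume=defaults.REACTOR_VOLUME_L,
            d=defaults.DILUTION_RATES[0],
            temperature=defaults.REACTOR_TEMPERATURE_K,
        ),
        guilds=guilds,
    )
    obs = ObservationSet(
        tuple(
            Observation(
                d=d,
                x_obs=defaults.OBSERVED_BIOMASS[d][0],
                sem=defaults.OBSERVED_BIOMASS[d][1],
                residual_vfa=defaults.OBSERVED_VFA[d][0],
            )
            for d in defaults.DILUTION_RATES
        )
    )
    return gt, obs
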