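"""Thermodynamic black-box model: maintenance as substrate consumption (Pirt).

The apparent yield at chemostat steady state is

    Y_app = Y_max / (1 + m * Y_max / D)

with ``m`` the maintenance rate expressed as substrate consumed per biomass
per day. ``m`` derives from a single energy coefficient (kJ per Cmol biomass
per hour) through each guild's catabolic Gibbs energy, and ``Y_max`` either
from the Gibbs-energy dissipation correlation or supplied directly. The
guild cascade is the same as in the Herbert module; this model is
algebraically identical to the Herbert one under ``k_dec = m * Y_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .herbert import ChainError, FeedSpec, ReactorConfig, SteadyState, _topological_compounds, GuildKinetics
from .units import CompoundSpec, ThermoContext, maintenance_energy_to_substrate_rate, ymax_dissipation


def apparent_yield_pirt(y_max: float, m: float, d: float) -> float:
    """Apparent yield ``Y_max / (1 + m Y_max / D)``; m in gCOD_S/gCOD_X/d."""
    if d <= 0:
        raise ChainError("dilution rate must be positive")
    return y_max / (1.0 + m * y_max / d)


def biomass_tba(y_app: float, s_in: float, s_dot_i: float, d: float, s: float = 0.0) -> float:
    """Steady-state biomass ``Y_app (S_in + S_dot_i/D - S)`` in gCOD/L."""
    if d <= 0:
        raise ChainError("dilution rate must be positive")
    consumed = s_in + s_dot_i / d - s
    if consumed < 0:
        raise ChainError("negative substrate consumption")
    return y_app * consumed


def yield_ratio(m: float, y_max: float, d_hi: float, d_lo: float) -> float:
    """Ratio of apparent yields at two dilution rates, (1+mY/d_lo)/(1+mY/d_hi)."""
    return apparent_yield_pirt(y_max, m, d_hi) / apparent_yield_pirt(y_max, m, d_lo)


def yield_vs_dilution_curve(
    m_list: Sequence[float], y_max: float, d_grid: Sequence[float]
) -> pd.DataFrame:
    """Normalized ``Y_app/Y_max`` curves over a dilution-rate grid.

    The half-way point ``Y_app/Y_max = 0.5`` sits exactly at ``D = m*Y_max``;
    curves for larger m lie strictly below those for smaller m.
    """
    d_arr = np.asarray(list(d_grid), dtype=float)
    if np.any(d_arr <= 0):
        raise ChainError("dilution grid must be positive")
    rows = []
    for m in m_list:
        for d in d_arr:
            rows.append(
                dict(d=d, m=m, y_app_over_y_max=apparent_yield_pirt(y_max, m, d) / y_max)
            )
    return pd.DataFrame(rows)


@dataclass
class TBASpec:
    """Per-substrate maximum yields and maintenance rates for the cascade.

    ``y_max`` in gCOD_X per gCOD_S and ``maintenance`` in gCOD_S per gCOD_X
    per day, keyed by substrate compound. ``product_fractions`` routes
    non-biomass COD exactly as in the Herbert chain.
    """

    ctx: ThermoContext
    y_max: Mapping[str, float]
    maintenance: Mapping[str, float]
    product_fractions: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sub, y in self.y_max.items():
            if y <= 0:
                raise ChainError(f"{sub}: Y_max must be positive")
        for sub, m in self.maintenance.items():
            if m < 0:
                raise ChainError(f"{sub}: maintenance must be >= 0")

    @classmethod
    def from_context(
        cls,
        ctx: ThermoContext | None = None,
        compounds: Mapping[str, CompoundSpec] | None = None,
        substrates: Sequence[str] = ("acetate", "propionate", "butyrate", "h2"),
        *,
        y_max_override: Mapping[str, float] | None = None,
        include_anabolic_carbon: bool = False,
    ) -> "TBASpec":
        """Build the spec from an energy coefficient and a compound table.

        Maintenance is charged to each guild's own catabolic substrate; Y_max
        comes from the dissipation correlation unless overridden.
        """
        ctx = ctx or ThermoContext()
        compounds = compounds or defaults.DEFAULT_COMPOUNDS
        y_max: dict[str, float] = {}
        maint: dict[str, float] = {}
        fractions = {
            g["substrate"]: dict(g["products"]) for g in defaults.ADM1_GUILDS.values()
        }
        for sub in substrates:
            comp = compounds[sub]
            if y_max_override and sub in y_max_override:
                y_max[sub] = y_max_override[sub]
            else:
                y_max[sub] = ymax_dissipation(
                    comp, ctx, include_anabolic_carbon=include_anabolic_carbon
                ).y_cod
            maint[sub] = maintenance_energy_to_substrate_rate(ctx, comp)
        return cls(ctx=ctx, y_max=y_max, maintenance=maint, product_fractions=fractions)

    def apparent_yield(self, substrate: str, d: float) -> float:
        return apparent_yield_pirt(self.y_max[substrate], self.maintenance[substrate], d)

    def herbert_equivalent(self, substrate: str) -> float:
        """The decay rate ``k_dec = m * Y_max`` that makes Eq-2 match Eq-5b."""
        return self.maintenance[substrate] * self.y_max[substrate]


def community_tba(
    feed: FeedSpec,
    spec: TBASpec,
    config: ReactorConfig,
    *,
    residual: Mapping[str, float] | None = None,
    ch4_per_cod: float = 0.35,
) -> SteadyState:
    """Per-guild biomass over the VFA cascade with Pirt apparent yields.

    Residual substrate defaults to zero (the experiment ran at > 99%
    conversion); pass Herbert-model S* values to relax that. Maintenance
    substrate ends up in catabolic products, so COD closes without an inert
    pool.
    """
    d = config.d
    if d <= 0:
        raise ChainError("dilution rate must be positive")
    residual = dict(residual or {})
    guilds = [
        GuildKinetics(
            name=f"tba_{sub}",
            substrate=sub,
            y=min(spec.y_max[sub], 0.999),
            mu_max=1.0,
            k_s=1.0,
            product_fractions=spec.product_fractions.get(sub, {}),
        )
        for sub in spec.y_max
    ]
    order = _topological_compounds(guilds, feed)
    by_substrate = {g.substrate: g for g in guilds}
    production: dict[str, float] = {c: 0.0 for c in order}
    biomass: dict[str, float] = {}
    residual_out: dict[str, float] = {}
    for compound in order:
        available = feed.concentration(compound) + production[compound] / d
        guild = by_substrate.get(compound)
        if guild is None:
            residual_out[compound] = available if compound != "methane" else 0.0
            continue
        s = min(residual.get(compound, 0.0), available)
        consumed = available - s
        y_app = spec.apparent_yield(compound, d)
        biomass[guild.name] = biomass_tba(y_app, available, 0.0, d, s)
        residual_out[compound] = s
        non_biomass = (1.0 - y_app) * consumed * d
        for product, frac in guild.product_fractions.items():
            production[product] = production.get(product, 0.0) + frac * non_biomass

    ch4_cod_rate = production.get("methane", 0.0)
    cod_in = d * feed.total_cod
    soluble = sum(v for c, v in residual_out.items() if c != "methane")
    cod_out = d * (soluble + sum(biomass.values())) + ch4_cod_rate
    closure = abs(cod_in - cod_out) / cod_in if cod_in > 0 else 0.0
    return SteadyState(
        d=d,
        biomass_cod=biomass,
        residual={c: v for c, v in residual_out.items() if c != "methane"},
        production=production,
        inert_cod=0.0,
        methane_rate=ch4_cod_rate * config.volume * ch4_per_cod,
        cod_closure=closure,
        washed_out=frozenset(),
        biomass_cod_per_gvs=spec.ctx.biomass_cod_per_gvs,
    )
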