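"""Reduced-ADM1 chemostat model: maintenance as biomass decay (Herbert form).

Each trophic guild grows on one COD pool with Monod kinetics and loses
biomass at a constant specific decay rate ``k_dec``; the four-guild VFA
cascade (butyrate/propionate oxidizers feeding acetoclastic and
hydrogenotrophic methanogens) is solved either algebraically at steady state
or as the full ODE system. Decayed biomass leaves the reactor as inert
soluble COD (the disintegration/hydrolysis recycling of the full ADM1 is a
0.5%-level effect and is deliberately excluded).

At steady state the apparent yield is ``Y_app = Y / (k_dec/D + 1)`` and the
residual substrate of a surviving guild is the classical
``S* = K_S (D + k_dec) / (mu_max - D - k_dec)``.
"""

from __future__ import annotations

import graphlib
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .units import ThermoContext


class ChainError(ValueError):
    """Raised for infeasible cascades or malformed guild sets."""


@dataclass(frozen=True)
class GuildKinetics:
    """One trophic population: gross yield, Monod kinetics, decay, products.

    ``y`` is the gross yield in gCOD biomass per gCOD substrate;
    ``product_fractions`` routes the non-biomass COD of the catabolized
    substrate to downstream pools (fractions sum to 1).
    """

    name: str
    substrate: str
    y: float
    mu_max: float
    k_s: float
    k_dec: float = 0.0
    product_fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.y < 1:
            raise ChainError(f"{self.name}: gross yield must lie in (0, 1)")
        if self.mu_max <= 0 or self.k_s <= 0:
            raise ChainError(f"{self.name}: mu_max and K_S must be positive")
        if self.k_dec < 0:
            raise ChainError(f"{self.name}: k_dec must be >= 0")
        total = sum(self.product_fractions.values())
        if self.product_fractions and abs(total - 1.0) > 1e-12:
            raise ChainError(f"{self.name}: product fractions sum to {total}, not 1")

    def mu(self, s: float) -> float:
        """Monod specific growth rate at substrate concentration ``s``."""
        return self.mu_max * s / (self.k_s + s) if s > 0 else 0.0


@dataclass(frozen=True)
class FeedSpec:
    """Influent COD and its split over compounds (fractions sum to 1)."""

    total_cod: float
    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.total_cod < 0:
            raise ChainError("feed COD must be >= 0")
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-12:
            raise ChainError(f"feed fractions sum to {total}, not 1")

    def concentration(self, compound: str) -> float:
        return self.total_cod * self.fractions.get(compound, 0.0)


@dataclass(frozen=True)
class ReactorConfig:
    """CSTR volume (L), dilution rate (1/d) and temperature (K)."""

    volume: float = 6.0
    d: float = 0.18
    temperature: float = 310.15

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ChainError("volume must be positive")
        if self.d < 0:
            raise ChainError("dilution rate must be >= 0")


@dataclass
class SteadyState:
    """Steady-state solution of the guild cascade (all COD in gCOD/L)."""

    d: float
    biomass_cod: dict[str, float]  # per guild
    residual: dict[str, float]  # per compound
    production: dict[str, float]  # internal production rate, gCOD/L/d
    inert_cod: float  # decay-derived soluble inert pool
    methane_rate: float  # L/d at the configured CH4/COD factor
    cod_closure: float  # relative COD imbalance
    washed_out: frozenset[str]
    biomass_cod_per_gvs: float = 33.6 / 24.6

    @property
    def total_biomass_cod(self) -> float:
        return sum(self.biomass_cod.values())

    @property
    def biomass_gvs(self) -> dict[str, float]:
        return {k: v / self.biomass_cod_per_gvs for k, v in self.biomass_cod.items()}

    @property
    def total_biomass_gvs(self) -> float:
        return self.total_biomass_cod / self.biomass_cod_per_gvs


def apparent_yield_herbert(y: float, k_dec: float, d: float) -> float:
    """Steady-state apparent yield ``Y / (k_dec/D + 1)`` (gCOD_X per gCOD_S)."""
    if d <= 0:
        raise ChainError("dilution rate must be positive")
    return y / (k_dec / d + 1.0)


def residual_substrate(guild: GuildKinetics, d: float) -> float | None:
    """Substrate level S* at which net growth balances dilution; None = washout."""
    loss = d + guild.k_dec
    if loss >= guild.mu_max:
        return None
    return guild.k_s * loss / (guild.mu_max - loss)


def critical_dilution(guild: GuildKinetics, s_in: float) -> float | None:
    """Highest sustainable dilution rate on feed ``s_in``; None if never positive."""
    if s_in <= 0:
        raise ChainError("feed concentration must be positive")
    d_crit = guild.mu_max * s_in / (guild.k_s + s_in) - guild.k_dec
    return d_crit if d_crit > 0 else None


def _topological_compounds(
    guilds: Sequence[GuildKinetics], feed: FeedSpec
) -> list[str]:
    """Order compounds so producers precede consumers; cycles are an error."""
    graph: dict[str, set[str]] = {}
    for g in guilds:
        for product in g.product_fractions:
            graph.setdefault(product, set()).add(g.substrate)
    for name in list(feed.fractions) + [g.substrate for g in guilds]:
        graph.setdefault(name, set())
    try:
        order = list(graphlib.TopologicalSorter(graph).static_order())
    except graphlib.CycleError as exc:  # pragma: no cover - guarded by inputs
        raise ChainError(f"cascade is cyclic: {exc}") from exc
    return order


def steady_state_chain(
    guilds: Sequence[GuildKinetics],
    feed: FeedSpec,
    config: ReactorConfig,
    *,
    complete_conversion: bool = False,
    ch4_per_cod: float = 0.35,
    ctx: ThermoContext | None = None,
) -> SteadyState:
    """Solve the trophic cascade at steady state, compound by compound.

    For each compound in topological order the consuming guild (at most one)
    sits at its residual concentration S*; everything above S* in the feed
    plus internal production is consumed, a fraction ``Y_app`` of it becomes
    biomass and the non-biomass COD is routed to the guild's products.
    Washed-out guilds contribute zero biomass and pass their substrate
    through. With ``complete_conversion=True`` residuals are forced to zero
    (the experimental regime: > 99% conversion).
    """
    d = config.d
    if d <= 0:
        raise ChainError("steady-state cascade needs a positive dilution rate")
    by_substrate: dict[str, GuildKinetics] = {}
    for g in guilds:
        if g.substrate in by_substrate:
            raise ChainError(
                f"two guilds consume {g.substrate}; use compete() for that scenario"
            )
        by_substrate[g.substrate] = g
    for compound, frac in feed.fractions.items():
        if frac > 0 and compound not in by_substrate and compound != "methane":
            raise ChainError(f"no guild consumes fed compound {compound!r}")

    cod_per_gvs = (ctx or ThermoContext()).biomass_cod_per_gvs
    order = _topological_compounds(guilds, feed)
    production: dict[str, float] = {c: 0.0 for c in order}
    residual: dict[str, float] = {}
    biomass: dict[str, float] = {g.name: 0.0 for g in guilds}
    washed: set[str] = set()

    for compound in order:
        available = feed.concentration(compound) + production[compound] / d
        guild = by_substrate.get(compound)
        if guild is None:
            residual[compound] = available if compound != "methane" else 0.0
            continue
        s_star = residual_substrate(guild, d)
        if s_star is None or s_star >= available:
            washed.add(guild.name)
            residual[compound] = available
            continue
        if complete_conversion:
            s_star = 0.0
        consumed = available - s_star
        if consumed < 0:
            raise ChainError(f"infeasible cascade: negative consumption of {compound}")
        residual[compound] = s_star
        biomass[guild.name] = apparent_yield_herbert(guild.y, guild.k_dec, d) * consumed
        non_biomass = (1.0 - guild.y) * consumed * d  # gCOD/L/d
        for product, frac in guild.product_fractions.items():
            production[product] = production.get(product, 0.0) + frac * non_biomass

    inert = sum(g.k_dec * biomass[g.name] for g in guilds) / d
    ch4_cod_rate = production.get("methane", 0.0)  # gCOD/L/d, leaves as gas
    methane_rate = ch4_cod_rate * config.volume * ch4_per_cod

    cod_in = d * feed.total_cod
    soluble_out = sum(v for c, v in residual.items() if c != "methane")
    cod_out = d * (soluble_out + sum(biomass.values()) + inert) + ch4_cod_rate
    closure = abs(cod_in - cod_out) / cod_in if cod_in > 0 else 0.0

    return SteadyState(
        d=d,
        biomass_cod=biomass,
        residual={c: v for c, v in residual.items() if c != "methane"},
        production=production,
        inert_cod=inert,
        methane_rate=methane_rate,
        cod_closure=closure,
        washed_out=frozenset(washed),
        biomass_cod_per_gvs=cod_per_gvs,
    )


@dataclass
class ChainTrajectory:
    """Dynamic simulation output (concentrations in gCOD/L, rates per day)."""

    t: np.ndarray
    biomass: dict[str, np.ndarray]
    substrate: dict[str, np.ndarray]
    inert: np.ndarray
    ch4_cod_rate: np.ndarray  # gCOD/L/d
    methane_rate: np.ndarray  # L/d

    def final_state(self) -> tuple[dict[str, float], dict[str, float]]:
        return (
            {k: float(v[-1]) for k, v in self.biomass.items()},
            {k: float(v[-1]) for k, v in self.substrate.items()},
        )


def simulate_dynamic(
    guilds: Sequence[GuildKinetics],
    feed: FeedSpec,
    config: ReactorConfig,
    t_end: float,
    *,
    x0: Mapping[str, float] | float = 0.05,
    s0: Mapping[str, float] | None = None,
    n_points: int = 500,
    rtol: float = 1e-8,
    ch4_per_cod: float = 0.35,
    feed_scale: Callable[[float], float] | None = None,
    method: str = "LSODA",
) -> ChainTrajectory:
    """Integrate the CSTR mass balances ``dX/dt = (mu - k_dec - D) X`` and
    ``dS/dt = D (S_in - S) - (mu/Y) X + upstream production``.

    Methane is stripped to the gas phase instantly (tracked as a rate, not a
    state); decayed biomass accumulates in a soluble inert pool that leaves
    with the effluent. ``feed_scale`` optionally scales the influent with
    time (feeding disturbances).
    """
    if t_end <= 0:
        raise ChainError("t_end must be positive")
    d = config.d
    compounds = [c for c in _topological_compounds(guilds, feed) if c != "methane"]
    c_index = {c: i for i, c in enumerate(compounds)}
    n_c = len(compounds)
    g_list = list(guilds)
    scale = feed_scale or (lambda _t: 1.0)

    def unpack(yv: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        return yv[:n_c], yv[n_c : n_c + len(g_list)], yv[-1]

    def rhs(t: float, yv: np.ndarray) -> np.ndarray:
        s, x, inert = unpack(yv)
        ds = np.empty(n_c)
        sc = scale(t)
        for i, c in enumerate(compounds):
            ds[i] = d * (sc * feed.concentration(c) - s[i])
        dx = np.empty(len(g_list))
        dinert = -d * inert
        for j, g in enumerate(g_list):
            si = max(s[c_index[g.substrate]], 0.0)
            mu = g.mu(si)
            q = mu / g.y * x[j]  # gCOD/L/d substrate uptake
            dx[j] = (mu - g.k_dec - d) * x[j]
            ds[c_index[g.substrate]] -= q
            for product, frac in g.product_fractions.items():
                if product in c_index:
                    ds[c_index[product]] += frac * (1.0 - g.y) * q
            dinert += g.k_dec * x[j]
        return np.concatenate([ds, dx, [dinert]])

    s_init = np.array(
        [
            (s0 or {}).get(c, feed.concentration(c)) if s0 is not None
            else feed.concentration(c)
            for c in compounds
        ]
    )
    if isinstance(x0, Mapping):
        x_init = np.array([x0.get(g.name, 0.0) for g in g_list])
    else:
        x_init = np.full(len(g_list), float(x0))
    y0 = np.concatenate([s_init, x_init, [0.0]])
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method=method, t_eval=t_eval, rtol=rtol, atol=1e-12
    )
    if not sol.success:  # pragma: no cover - diagnostics path
        raise ChainError(f"ODE solver failed: {sol.message}")

    ch4 = np.zeros_like(sol.t)
    for j, g in enumerate(g_list):
        frac_ch4 = g.product_fractions.get("methane", 0.0)
        if frac_ch4:
            s_g = np.clip(sol.y[c_index[g.substrate]], 0.0, None)
            mu = g.mu_max * s_g / (g.k_s + s_g)
            ch4 += frac_ch4 * (1.0 - g.y) * mu / g.y * sol.y[n_c + j]
    return ChainTrajectory(
        t=sol.t,
        biomass={g.name: sol.y[n_c + j] for j, g in enumerate(g_list)},
        substrate={c: sol.y[c_index[c]] for c in compounds},
        inert=sol.y[-1],
        ch4_cod_rate=ch4,
        methane_rate=ch4 * config.volume * ch4_per_cod,
    )


@dataclass(frozen=True)
class CompetitionReport:
    """Outcome of two guilds competing for one substrate at dilution rate d."""

    d: float
    s_star_a: float | None
    s_star_b: float | None
    winner: str  # guild name, "tie" or "none"
    crossover_d: float | None  # D where S*_a == S*_b, if inside (0, min D_crit)


def compete(guild_a: GuildKinetics, guild_b: GuildKinetics, d: float) -> CompetitionReport:
    """Classical R* competition: the guild with the lower S* at D excludes the
    other; also reports the crossover dilution rate where the ranking flips."""
    if guild_a.substrate != guild_b.substrate:
        raise ChainError("competing guilds must share a substrate")
    sa = residual_substrate(guild_a, d)
    sb = residual_substrate(guild_b, d)
    if sa is None and sb is None:
        winner = "none"
    elif sa is None:
        winner = guild_b.name
    elif sb is None:
        winner = guild_a.name
    elif math.isclose(sa, sb, rel_tol=1e-12, abs_tol=1e-15):
        winner = "tie"
    else:
        winner = guild_a.name if sa < sb else guild_b.name

    # crossover: S*_a(D) = S*_b(D) reduces to a quadratic in the net loss rate
    def diff(dd: float) -> float:
        ra = residual_substrate(guild_a, dd)
        rb = residual_substrate(guild_b, dd)
        assert ra is not None and rb is not None
        return ra - rb

    d_max_a = guild_a.mu_max - guild_a.k_dec
    d_max_b = guild_b.mu_max - guild_b.k_dec
    hi = min(d_max_a, d_max_b) * (1.0 - 1e-9)
    crossover = None
    if hi > 0:
        from scipy.optimize import brentq

        grid = np.linspace(1e-9, hi, 256)
        vals = [diff(g) for g in grid]
        for (g1, v1), (g2, v2) in zip(zip(grid, vals), zip(grid[1:], vals[1:])):
            if v1 == 0.0:
                crossover = float(g1)
                break
            if v1 * v2 < 0:
                crossover = float(brentq(diff, g1, g2, xtol=1e-14))
                break
    return CompetitionReport(
        d=d, s_star_a=sa, s_star_b=sb, winner=winner, crossover_d=crossover
    )
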