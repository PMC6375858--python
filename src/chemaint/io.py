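"""Tabular and config I/O: TSV (tab-separated, '.' decimal, header row)
throughout, YAML for keyed configuration. Unknown config keys are errors.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .dfba import MetabolicNetwork
from .fitting import Observation, ObservationSet
from .herbert import FeedSpec, GuildKinetics, ReactorConfig, SteadyState
from .units import CompoundSpec, ElementalComposition


class IOError_(ValueError):
    pass


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(required) - set(df.columns)
    if missing:
        raise IOError_(f"{path}: missing columns {sorted(missing)}")
    return df


# -- compounds ---------------------------------------------------------------

def read_compounds(path: str | Path) -> dict[str, CompoundSpec]:
    """Compound table: name, formula (CcHhOoNn counts), molar_mass_g_per_mol,
    dg_cat_kj_per_mol (empty for non-catabolic compounds), notes."""
    df = _read_tsv(path, ["name", "formula", "molar_mass_g_per_mol"])
    out: dict[str, CompoundSpec] = {}
    for _, row in df.iterrows():
        c, h, o, n = _parse_formula(str(row["formula"]))
        dg = row.get("dg_cat_kj_per_mol")
        dg = None if dg is None or (isinstance(dg, float) and math.isnan(dg)) else float(dg)
        if c > 0:
            comp = ElementalComposition(1.0, h / c, o / c, n / c)
            spec = CompoundSpec(
                name=row["name"], molar_mass=float(row["molar_mass_g_per_mol"]),
                n_carbon=int(c), composition=comp, dg_cat=dg,
            )
        else:
            gamma = 4 * c + h - 2 * o - 3 * n
            spec = CompoundSpec(
                name=row["name"], molar_mass=float(row["molar_mass_g_per_mol"]),
                n_carbon=0, composition=None, dg_cat=dg, cod_per_mol=8.0 * gamma,
            )
        out[spec.name] = spec
    return out


def _parse_formula(formula: str) -> tuple[float, float, float, float]:
    import re

    counts = {"C": 0.0, "H": 0.0, "O": 0.0, "N": 0.0}
    for elem, num in re.findall(r"([CHON])([0-9.]*)", formula):
        counts[elem] += float(num) if num else 1.0
    return counts["C"], counts["H"], counts["O"], counts["N"]


# -- guilds ------------------------------------------------------------------

GUILD_COLUMNS = [
    "name", "substrate", "y_cod", "mu_max_per_day", "ks_gcod_per_l",
    "kdec_per_day", "products",
]


def read_guilds(path: str | Path) -> list[GuildKinetics]:
    """Guild table with products in ``compound:fraction;compound:fraction``
    syntax."""
    df = _read_tsv(path, GUILD_COLUMNS)
    guilds = []
    for _, row in df.iterrows():
        guilds.append(
            GuildKinetics(
                name=row["name"],
                substrate=row["substrate"],
                y=float(row["y_cod"]),
                mu_max=float(row["mu_max_per_day"]),
                k_s=float(row["ks_gcod_per_l"]),
                k_dec=float(row["kdec_per_day"]),
                product_fractions=_parse_products(str(row["products"])),
            )
        )
    return guilds


def write_guilds(guilds: Sequence[GuildKinetics], path: str | Path) -> None:
    rows = [
        dict(
            name=g.name, substrate=g.substrate, y_cod=g.y, mu_max_per_day=g.mu_max,
            ks_gcod_per_l=g.k_s, kdec_per_day=g.k_dec,
            products=";".join(f"{c}:{f:g}" for c, f in g.product_fractions.items()),
        )
        for g in guilds
    ]
    pd.DataFrame(rows, columns=GUILD_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_products(spec: str) -> dict[str, float]:
    out: dict[str, float] = {}
    if not spec or spec == "nan":
        return out
    for item in spec.split(";"):
        if not item.strip():
            continue
        try:
            name, frac = item.split(":")
            out[name.strip()] = float(frac)
        except ValueError as exc:
            raise IOError_(f"bad product entry {item!r} (want compound:fraction)") from exc
    return out


# -- observations ------------------------------------------------------------

OBS_COLUMNS = ["d_per_day", "x_gvs_per_l", "sem_gvs_per_l"]


def read_observations(path: str | Path) -> ObservationSet:
    df = _read_tsv(path, OBS_COLUMNS)
    rows = []
    for _, row in df.iterrows():
        vfa = row.get("vfa_gcod_per_l")
        ch4 = row.get("ch4_l_per_day")
        rows.append(
            Observation(
                d=float(row["d_per_day"]),
                x_obs=float(row["x_gvs_per_l"]),
                sem=float(row["sem_gvs_per_l"]),
                residual_vfa=None if vfa is None or pd.isna(vfa) else float(vfa),
                ch4_rate=None if ch4 is None or pd.isna(ch4) else float(ch4),
            )
        )
    return ObservationSet(tuple(rows))


def write_observations(obs: ObservationSet, path: str | Path) -> None:
    obs.to_frame().to_csv(path, sep="\t", index=False)


# -- steady-state report -----------------------------------------------------

def steady_state_frame(state: SteadyState) -> pd.DataFrame:
    """One row per guild plus a totals row; units in the column names."""
    rows = [
        dict(
            guild=name,
            x_gcod_per_l=x,
            x_gvs_per_l=x / state.biomass_cod_per_gvs,
            washed_out=name in state.washed_out,
        )
        for name, x in state.biomass_cod.items()
    ]
    rows.append(
        dict(
            guild="TOTAL",
            x_gcod_per_l=state.total_biomass_cod,
            x_gvs_per_l=state.total_biomass_gvs,
            washed_out=False,
        )
    )
    return pd.DataFrame(rows)


def write_steady_state(state: SteadyState, path: str | Path) -> None:
    steady_state_frame(state).to_csv(path, sep="\t", index=False)


# -- metabolic networks ------------------------------------------------------

NETWORK_COLUMNS = ["reaction_id", "stoichiometry", "lb", "ub", "is_biomass", "is_ngam"]


def read_network(path: str | Path, *, uptake_reaction: str = "uptake") -> MetabolicNetwork:
    """Network TSV: stoichiometry in ``met:coef;met:coef`` syntax; exactly one
    biomass and one NGAM reaction flagged with 1."""
    df = _read_tsv(path, NETWORK_COLUMNS)
    stoich: dict[str, dict[str, float]] = {}
    lb: dict[str, float] = {}
    ub: dict[str, float] = {}
    biomass = ngam = None
    mets: list[str] = []
    for _, row in df.iterrows():
        rid = row["reaction_id"]
        entries = _parse_products(str(row["stoichiometry"]))
        stoich[rid] = entries
        for met in entries:
            if met not in mets:
                mets.append(met)
        lb[rid] = float(row["lb"])
        ub[rid] = math.inf if math.isinf(float(row["ub"])) else float(row["ub"])
        if int(row["is_biomass"]):
            biomass = rid
        if int(row["is_ngam"]):
            ngam = rid
    if biomass is None or ngam is None:
        raise IOError_(f"{path}: need one is_biomass and one is_ngam reaction")
    return MetabolicNetwork(
        metabolites=tuple(mets),
        reactions=tuple(stoich),
        stoichiometry=stoich,
        lb=lb,
        ub=ub,
        biomass_reaction=biomass,
        ngam_reaction=ngam,
        uptake_reaction=uptake_reaction,
    )


def write_network(network: MetabolicNetwork, path: str | Path) -> None:
    rows = []
    for rid in network.reactions:
        rows.append(
            dict(
                reaction_id=rid,
                stoichiometry=";".join(
                    f"{m}:{c:.17g}" for m, c in network.stoichiometry[rid].items()
                ),
                lb=network.lb[rid],
                ub=network.ub[rid],
                is_biomass=int(rid == network.biomass_reaction),
                is_ngam=int(rid == network.ngam_reaction),
            )
        )
    pd.DataFrame(rows, columns=NETWORK_COLUMNS).to_csv(path, sep="\t", index=False)


# -- config ------------------------------------------------------------------

REACTOR_KEYS = {"volume_l", "dilution_per_day", "temperature_k"}
FEED_KEYS = {"total_gcod_per_l", "fractions"}


def read_run_config(path: str | Path) -> dict:
    """Strict YAML config: top-level keys ``reactor`` and ``feed``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"reactor", "feed"}
    if unknown:
        raise IOError_(f"{path}: unknown config keys {sorted(unknown)}")
    out: dict = {}
    if "reactor" in raw:
        bad = set(raw["reactor"]) - REACTOR_KEYS
        if bad:
            raise IOError_(f"{path}: unknown reactor keys {sorted(bad)}")
        out["reactor"] = ReactorConfig(
            volume=raw["reactor"].get("volume_l", 6.0),
            d=raw["reactor"].get("dilution_per_day", 0.18),
            temperature=raw["reactor"].get("temperature_k", 310.15),
        )
    if "feed" in raw:
        bad = set(raw["feed"]) - FEED_KEYS
        if bad:
            raise IOError_(f"{path}: unknown feed keys {sorted(bad)}")
        out["feed"] = FeedSpec(
            total_cod=raw["feed"]["total_gcod_per_l"],
            fractions=raw["feed"]["fractions"],
        )
    return out
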