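"""Elemental, COD and Gibbs-energy bookkeeping for anaerobic chemostat models.

Everything downstream (the ADM1-style guild chain, the thermodynamic
black-box yields, the dFBA toy networks) speaks gCOD, days, kJ and Cmol.
This module owns the conversions between those currencies:

* chemical oxygen demand (COD) from elemental composition via the degree of
  reduction (1 Cmol with degree of reduction ``gamma`` carries ``8*gamma``
  gCOD);
* maintenance expressed as energy (kJ per Cmol biomass per hour), as ATP
  turnover (mmol ATP per g dry weight per hour) and as substrate consumption
  (gCOD substrate per gCOD biomass per day);
* maximum growth yields from the Gibbs-energy dissipation correlation;
* small chemostat arithmetic (doubling time, theoretical methane ceiling).

Biomass is normalized per carbon mole as CH1.8O0.5N0.2 (24.6 g VS per Cmol,
degree of reduction 4.2, hence 33.6 gCOD per Cmol and 1.366 gCOD per gVS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class UnitsError(ValueError):
    """Raised for physically inconsistent compositions or conversions."""


@dataclass(frozen=True)
class ElementalComposition:
    """Stoichiometric subscripts per carbon mole (c is always 1)."""

    c: float = 1.0
    h: float = 0.0
    o: float = 0.0
    n: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.c - 1.0) > 1e-12:
            raise UnitsError("compositions are normalized per Cmol; c must be 1")
        if min(self.h, self.o, self.n) < 0:
            raise UnitsError("negative stoichiometric subscripts")


#: Default biomass composition CH1.8O0.5N0.2.
BIOMASS_COMPOSITION = ElementalComposition(1.0, 1.8, 0.5, 0.2)
#: g VS (== g dry organic matter) per Cmol of the default biomass.
BIOMASS_GVS_PER_CMOL = 24.6


def degree_of_reduction(comp: ElementalComposition) -> float:
    """Electron equivalents per Cmol: 4c + h - 2o - 3n.

    Nitrogen is counted at the ammonia reference level (-3), the convention
    under which biomass CH1.8O0.5N0.2 carries 4.2 electron equivalents.
    """
    gamma = 4.0 * comp.c + comp.h - 2.0 * comp.o - 3.0 * comp.n
    if gamma < 0:
        raise UnitsError("non-oxidizable composition (negative degree of reduction)")
    return gamma


def cod_of(comp: ElementalComposition, molar_mass: float) -> tuple[float, float]:
    """COD content of a composition: (gCOD per Cmol, gCOD per gram).

    ``molar_mass`` is grams per Cmol. One electron equivalent demands a
    quarter mole of O2, i.e. 8 g COD.
    """
    if molar_mass <= 0:
        raise UnitsError("molar mass must be positive")
    per_cmol = 8.0 * degree_of_reduction(comp)
    return per_cmol, per_cmol / molar_mass


@dataclass(frozen=True)
class CompoundSpec:
    """A substrate/product with its COD and catabolic-energy bookkeeping.

    ``composition`` is per Cmol for carbon compounds and ``None`` for
    molecular species without carbon bookkeeping of that form (H2); for the
    latter ``cod_per_mol`` and ``n_carbon`` are taken at face value.
    ``dg_cat`` is the Gibbs energy change of the catabolic reaction in kJ per
    mol of compound consumed (negative = exergonic); ``None`` for compounds
    that are not catabolized (CH4, CO2).
    """

    name: str
    molar_mass: float  # g per mol (of the molecule)
    n_carbon: int
    composition: ElementalComposition | None = None
    dg_cat: float | None = None
    cod_per_mol: float | None = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise UnitsError(f"{self.name}: molar mass must be positive")
        if self.composition is not None:
            mass_from_formula = self.n_carbon * (
                12.011 * self.composition.c
                + 1.008 * self.composition.h
                + 15.999 * self.composition.o
                + 14.007 * self.composition.n
            )
            if abs(mass_from_formula - self.molar_mass) > 5e-3 * self.molar_mass:
                raise UnitsError(
                    f"{self.name}: molar mass {self.molar_mass} inconsistent with "
                    f"composition (expected {mass_from_formula:.3f})"
                )
            per_cmol, _ = cod_of(self.composition, self.molar_mass / max(self.n_carbon, 1))
            expected = per_cmol * self.n_carbon
            if self.cod_per_mol is None:
                object.__setattr__(self, "cod_per_mol", expected)
            elif abs(self.cod_per_mol - expected) > 1e-3 * max(expected, 1.0):
                raise UnitsError(
                    f"{self.name}: cod_per_mol {self.cod_per_mol} inconsistent with "
                    f"composition (expected {expected:.4g})"
                )
        elif self.cod_per_mol is None:
            raise UnitsError(f"{self.name}: cod_per_mol required when composition absent")

    @property
    def cod_per_g(self) -> float:
        return float(self.cod_per_mol) / self.molar_mass

    @property
    def dg_cat_magnitude(self) -> float:
        if self.dg_cat is None:
            raise UnitsError(f"{self.name}: no catabolic Gibbs energy configured")
        return abs(self.dg_cat)


@dataclass(frozen=True)
class ThermoContext:
    """Temperature, maintenance energy and biomass conventions.

    ``m_g`` is the maintenance Gibbs-energy coefficient in kJ per Cmol biomass
    per hour (9.8 is the literature value for anaerobes at 37 C; the study
    this package replicates argues for < 0.2 at the dilution rates of
    anaerobic digestion). ``dg_atp`` is the phosphorylation energy assumed
    per mol ATP.
    """

    temperature: float = 310.15  # K
    m_g: float = 9.8  # kJ Cmol^-1 h^-1
    dg_atp: float = 70.0  # kJ per mol ATP
    biomass: ElementalComposition = field(default_factory=lambda: BIOMASS_COMPOSITION)
    biomass_molar_mass: float = BIOMASS_GVS_PER_CMOL  # g VS per Cmol

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.dg_atp <= 0 or self.biomass_molar_mass <= 0:
            raise UnitsError("temperature, dg_atp and biomass molar mass must be positive")
        if self.m_g < 0:
            raise UnitsError("maintenance energy must be >= 0")

    @property
    def biomass_cod_per_cmol(self) -> float:
        return cod_of(self.biomass, self.biomass_molar_mass)[0]

    @property
    def biomass_cod_per_gvs(self) -> float:
        return cod_of(self.biomass, self.biomass_molar_mass)[1]


def yield_vs_to_cod(y_mgvs_per_gcod: float, ctx: ThermoContext | None = None) -> float:
    """Convert an apparent yield in mgVS per gCOD substrate to gCOD_X per gCOD_S."""
    ctx = ctx or ThermoContext()
    if y_mgvs_per_gcod < 0:
        raise UnitsError("yield must be >= 0")
    return y_mgvs_per_gcod * 1e-3 * ctx.biomass_cod_per_gvs


def maintenance_energy_to_atp(m_g: float, ctx: ThermoContext | None = None) -> float:
    """kJ Cmol^-1 h^-1 -> mmol ATP gDW^-1 h^-1 (dry weight == VS here)."""
    ctx = ctx or ThermoContext()
    if m_g < 0:
        raise UnitsError("maintenance energy must be >= 0")
    return m_g / ctx.dg_atp / ctx.biomass_molar_mass * 1e3


def maintenance_substrate_to_energy(
    q_umol_per_g_h: float, compound: CompoundSpec, ctx: ThermoContext | None = None
) -> float:
    """umol substrate gDW^-1 h^-1 -> kJ Cmol^-1 h^-1 via the catabolic energy."""
    ctx = ctx or ThermoContext()
    if q_umol_per_g_h < 0:
        raise UnitsError("uptake rate must be >= 0")
    dg = compound.dg_cat_magnitude
    if dg == 0:
        raise UnitsError(f"{compound.name}: catabolic Gibbs energy is zero")
    return q_umol_per_g_h * 1e-6 * ctx.biomass_molar_mass * dg


def maintenance_energy_to_substrate_rate(
    ctx: ThermoContext, compound: CompoundSpec
) -> float:
    """Maintenance energy -> substrate consumption, gCOD_S per gCOD_X per day.

    The energy drawn per Cmol biomass per hour is supplied by catabolizing
    ``m_g / |dG_cat|`` mol of the compound; the result is expressed per gCOD
    of biomass and per day.
    """
    dg = compound.dg_cat_magnitude
    if dg == 0:
        raise UnitsError(f"{compound.name}: catabolic Gibbs energy is zero")
    mol_per_cmol_h = ctx.m_g / dg
    return mol_per_cmol_h * 24.0 * float(compound.cod_per_mol) / ctx.biomass_cod_per_cmol


def gibbs_dissipation(n_carbon: int, gamma_per_c: float) -> float:
    """Dissipation correlation, kJ per Cmol biomass formed.

    ``200 + 18*(6-C)^1.8 + exp(((3.8-gamma)^2)^0.16 * (3.6+0.4*C))`` with C
    the carbon chain length of the carbon source and gamma its degree of
    reduction per carbon.
    """
    if n_carbon < 1:
        raise UnitsError("dissipation correlation needs a carbon source with C >= 1")
    return (
        200.0
        + 18.0 * (6.0 - n_carbon) ** 1.8
        + math.exp(((3.8 - gamma_per_c) ** 2) ** 0.16 * (3.6 + 0.4 * n_carbon))
    )


@dataclass(frozen=True)
class YmaxResult:
    """Dissipation-method maximum yield for one substrate."""

    dg_dis: float  # kJ per Cmol biomass
    y_cmol: float  # Cmol_X per Cmol substrate (per mol for carbon-free substrates)
    y_cod: float  # gCOD_X per gCOD_S


def ymax_dissipation(
    compound: CompoundSpec,
    ctx: ThermoContext | None = None,
    *,
    include_anabolic_carbon: bool = False,
) -> YmaxResult:
    """Maximum growth yield from the Gibbs-energy dissipation method.

    The catabolic energy harvested per substrate unit, divided by the
    dissipation required per Cmol biomass, gives the maximum yield. For
    carbon substrates the unit is one Cmol of substrate and the yield is
    capped at the carbon-limited maximum of 1 Cmol/Cmol; for carbon-free
    electron donors (H2) the unit is one mol and CO2 (C=1, gamma=0) is taken
    as the carbon source in the correlation. With
    ``include_anabolic_carbon=True`` the substrate carbon assimilated into
    biomass is charged as well: Y = |dG'| / (dG_dis + |dG'|).
    """
    ctx = ctx or ThermoContext()
    dg = compound.dg_cat_magnitude
    if compound.dg_cat is not None and compound.dg_cat >= 0:
        raise UnitsError(
            f"{compound.name}: catabolism is endergonic under the supplied conditions; "
            "provide a physiological-condition dG_cat"
        )
    if compound.n_carbon >= 1:
        gamma_per_c = float(compound.cod_per_mol) / 8.0 / compound.n_carbon
        dg_dis = gibbs_dissipation(compound.n_carbon, gamma_per_c)
        dg_per_unit = dg / compound.n_carbon  # per Cmol substrate
        cod_per_unit = float(compound.cod_per_mol) / compound.n_carbon
        denom = dg_dis + dg_per_unit if include_anabolic_carbon else dg_dis
        y_cmol = min(dg_per_unit / denom, 1.0)
    else:
        # autotrophic carbon source (CO2): C=1, gamma=0 in the correlation
        dg_dis = gibbs_dissipation(1, 0.0)
        dg_per_unit = dg  # per mol of the electron donor
        cod_per_unit = float(compound.cod_per_mol)
        y_cmol = dg_per_unit / dg_dis
    y_cod = y_cmol * ctx.biomass_cod_per_cmol / cod_per_unit
    return YmaxResult(dg_dis=dg_dis, y_cmol=y_cmol, y_cod=y_cod)


def doubling_time(d: float) -> float:
    """Steady-state doubling time ln(2)/D in days (mu equals D in a chemostat)."""
    if d <= 0:
        raise UnitsError("dilution rate must be positive")
    return math.log(2.0) / d


def max_methane_rate(
    volume: float, hrt: float, feed_cod: float, ch4_per_cod: float = 0.35
) -> float:
    """Theoretical methane ceiling, L per day, for complete COD conversion.

    ``ch4_per_cod`` defaults to 0.35 L CH4 per gCOD (0 C, 1 atm); multiply by
    T/273.15 for a gas-temperature correction if desired.
    """
    if min(volume, hrt, ch4_per_cod) <= 0 or feed_cod < 0:
        raise UnitsError("volume, HRT and CH4/COD factor must be positive, feed >= 0")
    return volume / hrt * feed_cod * ch4_per_cod
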