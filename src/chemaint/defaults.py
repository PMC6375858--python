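"""Default parameter tables for the VFA-fed anaerobic chemostat system.

Compound table
    Acetate, propionate, butyrate, H2, CH4, CO2 with molar masses and example
    catabolic Gibbs energies. The fatty-acid and H2 values are physiological
    (pH ~7, low H2) rather than standard-condition numbers, because syntrophic
    fatty-acid oxidation is endergonic at standard conditions; the acetate
    value of -31 kJ/mol is the one implied by converting 120 umol acetate
    gDW^-1 h^-1 of maintenance into 0.09 kJ Cmol^-1 h^-1.

Guild table
    The four-population degradation cascade of a VFA-fed digester with the
    ADM1 default parameters: butyrate and propionate oxidizers feeding
    acetoclastic and hydrogenotrophic methanogens. Yields in gCOD_X/gCOD_S,
    Monod mu_max = k_m * Y with the ADM1 uptake constants, decay 0.02 d^-1.

Experiment fixture
    Two 6 L CSTRs at 37 C, D = 0.18 and 0.07 d^-1, fed 37.2 gCOD/L of
    45/45/10 acetic/butyric/propionic acid (COD basis).
"""

from __future__ import annotations

from .units import CompoundSpec, ElementalComposition

ACETATE = CompoundSpec(
    name="acetate",
    molar_mass=60.052,
    n_carbon=2,
    composition=ElementalComposition(1.0, 2.0, 1.0, 0.0),
    dg_cat=-31.0,
)
PROPIONATE = CompoundSpec(
    name="propionate",
    molar_mass=74.079,
    n_carbon=3,
    composition=ElementalComposition(1.0, 2.0, 2.0 / 3.0, 0.0),
    dg_cat=-15.0,
)
BUTYRATE = CompoundSpec(
    name="butyrate",
    molar_mass=88.106,
    n_carbon=4,
    composition=ElementalComposition(1.0, 2.0, 0.5, 0.0),
    dg_cat=-17.5,
)
HYDROGEN = CompoundSpec(
    name="h2",
    molar_mass=2.016,
    n_carbon=0,
    composition=None,
    dg_cat=-8.0,  # per mol H2, physiological; about -33/4 at standard conditions
    cod_per_mol=16.0,
)
METHANE = CompoundSpec(
    name="methane",
    molar_mass=16.043,
    n_carbon=1,
    composition=ElementalComposition(1.0, 4.0, 0.0, 0.0),
    dg_cat=None,
)
CO2 = CompoundSpec(
    name="co2",
    molar_mass=44.009,
    n_carbon=1,
    composition=ElementalComposition(1.0, 0.0, 2.0, 0.0),
    dg_cat=None,
)

DEFAULT_COMPOUNDS: dict[str, CompoundSpec] = {
    c.name: c for c in (ACETATE, PROPIONATE, BUTYRATE, HYDROGEN, METHANE, CO2)
}

#: ADM1 default kinetics for the four-guild chain (COD basis, 35-37 C set).
#: mu_max = k_m * Y with k_m (gCOD_S/gCOD_X/d): ac 8, pro 13, c4 20, h2 35.
ADM1_GUILDS: dict[str, dict] = {
    "acetoclastic": dict(
        substrate="acetate",
        y=0.05,
        mu_max=0.40,
        k_s=0.15,
        k_dec=0.02,
        products={"methane": 1.0},
    ),
    "propionate_oxidizer": dict(
        substrate="propionate",
        y=0.04,
        mu_max=0.52,
        k_s=0.10,
        k_dec=0.02,
        products={"acetate": 0.57, "h2": 0.43},
    ),
    "butyrate_oxidizer": dict(
        substrate="butyrate",
        y=0.06,
        mu_max=1.20,
        k_s=0.20,
        k_dec=0.02,
        products={"acetate": 0.80, "h2": 0.20},
    ),
    "hydrogenotrophic": dict(
        substrate="h2",
        y=0.06,
        mu_max=2.10,
        k_s=7.0e-6,
        k_dec=0.02,
        products={"methane": 1.0},
    ),
}

def adm1_guilds(**overrides) -> list:
    """Instantiate the four default guilds as ``GuildKinetics`` objects.

    ``overrides`` maps a guild name to a dict of field overrides.
    """
    from .herbert import GuildKinetics

    out = []
    for name, p in ADM1_GUILDS.items():
        kw = dict(p)
        kw["product_fractions"] = kw.pop("products")
        kw.update(overrides.get(name, {}))
        out.append(GuildKinetics(name=name, **kw))
    return out


#: Feed of the two-reactor experiment: COD fractions of 37.2 gCOD/L total.
FEED_TOTAL_COD = 37.2
FEED_FRACTIONS = {"acetate": 0.45, "butyrate": 0.45, "propionate": 0.10}

REACTOR_VOLUME_L = 6.0
REACTOR_TEMPERATURE_K = 310.15
DILUTION_RATES = (0.18, 0.07)

#: Observed steady-state community biomass, gVS/L, mean +/- SEM per D.
OBSERVED_BIOMASS = {0.18: (0.92, 0.03), 0.07: (0.94, 0.03)}
#: Observed residual VFA, gCOD/L, mean +/- SEM per D.
OBSERVED_VFA = {0.18: (0.337, 0.263), 0.07: (0.341, 0.383)}
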