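import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")

from chemaint import defaults
from chemaint.dfba import build_toy_guild, dfba_simulate, pirt_equivalent
from chemaint.herbert import FeedSpec, ReactorConfig
from chemaint.units import ThermoContext

DILUTION_RATES = (0.18, 0.07)
GUILD_IDS = ("acetoclastic", "hydrogenotrophic", "propionate", "butyrate")


@pytest.fixture(scope="session")
def ctx():
    return ThermoContext()


@pytest.fixture(scope="session")
def guilds():
    return defaults.adm1_guilds()


@pytest.fixture(scope="session")
def feed():
    return FeedSpec(defaults.FEED_TOTAL_COD, defaults.FEED_FRACTIONS)


@pytest.fixture
def reactor():
    return ReactorConfig(volume=6.0, d=0.18, temperature=310.15)


@pytest.fixture(scope="session")
def dfba_steady_states():
    """All four toy guilds simulated to steady state at both dilution rates.

    Computed once per session (the dFBA Euler runs are the slowest fixtures);
    keyed by (guild_id, d) -> (DFBAResult, PirtEquivalent, GuildFBA).
    """
    out = {}
    for gid in GUILD_IDS:
        guild = build_toy_guild(gid)
        eq = pirt_equivalent(guild)
        for d in DILUTION_RATES:
            res = dfba_simulate(guild, d)
            out[(gid, d)] = (res, eq, guild)
    return out
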