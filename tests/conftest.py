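import pytest
from hypothesis import HealthCheck, settings

from lagturn.biotime_io import CommunityTimeSeries

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_series(data, community_id="c1", taxon_group="all"):
    """Build a CommunityTimeSeries from {year: iterable} (one sample per year)
    or {year: {sample_id: iterable}} (explicit samples)."""
    presence = {}
    for year, val in data.items():
        if isinstance(val, dict):
            for sid, species in val.items():
                presence[(year, sid)] = frozenset(species)
        else:
            presence[(year, "s1")] = frozenset(val)
    return CommunityTimeSeries(
        community_id=community_id, presence=presence, taxon_group=taxon_group
    )


@pytest.fixture
def toy_series():
    """Six fully observed years with a gentle one-species-per-year replacement."""
    species = [f"sp{i}" for i in range(10)]
    data = {2000 + t: set(species[t : t + 6]) for t in range(6)}
    return make_series(data)
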