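import pytest
from hypothesis import HealthCheck, settings

import famseg

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixtures():
    """The three reconstructed study families (deterministic)."""
    return famseg.build_paper_fixtures()


@pytest.fixture(scope="session")
def cascades(fixtures):
    """(candidates, funnel) per family from one cascade run."""
    out = {}
    for fid, fx in fixtures.items():
        out[fid] = famseg.run_family_cascade(
            fx.annotations, fx.genotypes, fx.config, fx.thresholds
        )
    return out
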