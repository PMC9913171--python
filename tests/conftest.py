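import pytest

from blastscore import build_fixture_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic validation-study cohort (121 HGBL + 47 B-ALL)."""
    return build_fixture_cohort()
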