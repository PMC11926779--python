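from pathlib import Path

import pytest

from prolai import SyntheticForcingSpec, generate_forcing

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_csv() -> Path:
    """Two-year synthetic forcing file shipped with the tests."""
    return DATA_DIR / "forcing_2yr_synthetic.csv"


@pytest.fixture(scope="session")
def two_year_forcing():
    """Freshly generated two-year temperate forcing, fixed seed."""
    return generate_forcing(SyntheticForcingSpec(years=2, seed=7))
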