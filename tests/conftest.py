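import pytest

from algafuel.io import (
    load_reference_class_totals,
    load_reference_fuel_table,
    load_reference_pigments,
    load_reference_profiles,
)


@pytest.fixture(scope="session")
def reference_profiles():
    """Per-salinity FAME profiles packaged with the library."""
    return load_reference_profiles()


@pytest.fixture(scope="session")
def reference_fuel_table():
    """Published fuel-property cells as printed strings."""
    return load_reference_fuel_table()


@pytest.fixture(scope="session")
def reference_class_totals():
    return load_reference_class_totals()


@pytest.fixture(scope="session")
def reference_pigments():
    return load_reference_pigments()
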