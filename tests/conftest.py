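import pytest

from evigrade import FprpConfig, load_table1, load_table2


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def config():
    return FprpConfig()


def find_row(fixture, variant, ethnicity=None, cancer_type=None, model=None):
    """Locate a fixture row by variant and optional strata."""
    for record in fixture.records:
        if record.variant != variant:
            continue
        if ethnicity is not None and record.ethnicity.value != ethnicity:
            continue
        if cancer_type is not None and record.cancer_type.value != cancer_type:
            continue
        if model is not None and record.model.value != model:
            continue
        return record
    raise LookupError(f"no row for {variant} / {ethnicity} / {cancer_type}")
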