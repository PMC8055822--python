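import pytest

from phosphoshift import (
    PipelineParams,
    default_design,
    invert_printed_table,
    load_reference_shift_table,
    load_reference_wt_only_table,
)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def reference_shift_table():
    return load_reference_shift_table()


@pytest.fixture(scope="session")
def reference_wt_only_table():
    return load_reference_wt_only_table()


@pytest.fixture(scope="session")
def reference_site_records(reference_shift_table):
    """Noiseless site quantifications inverted from the published
    36-site shift table."""
    return invert_printed_table(reference_shift_table)


@pytest.fixture(scope="session")
def wt_only_site_records(reference_wt_only_table):
    return invert_printed_table(reference_wt_only_table)


@pytest.fixture
def fixed_params():
    return PipelineParams(dd_cutoff_mode="fixed", dd_fixed_cutoff=1.0)
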