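import pytest

from mitopair import (
    DiagnosticTable,
    SimConfig,
    generate_cohort,
    load_reference,
    load_somatic_catalogue,
)


@pytest.fixture(scope="session")
def ref():
    """Bundled rCRS with region map and vertebrate mitochondrial codon table."""
    return load_reference()


@pytest.fixture(scope="session")
def rmap(ref):
    return ref.region_map


@pytest.fixture(scope="session")
def catalogue(ref):
    """The 46 published somatic variants of the 86-pair HCC cohort."""
    return load_somatic_catalogue(ref)


@pytest.fixture(scope="session")
def diag_table():
    return DiagnosticTable.bundled()


@pytest.fixture(scope="session")
def small_cohort(ref):
    """A 10-case synthetic cohort shared by read-only tests."""
    return generate_cohort(SimConfig(n_cases=10, seed=11), ref=ref)
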