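import pytest

from clonotrace import barcode_design as bd


@pytest.fixture(scope="session")
def template():
    return bd.default_template()


@pytest.fixture(scope="session")
def varset():
    return bd.load_default_varset()


@pytest.fixture(scope="session")
def mutated_base(template):
    return bd.apply_fixed_mutations(template)


@pytest.fixture(scope="session")
def alleles(template, varset):
    return bd.sample_alleles(template, varset, 30, seed=7)


@pytest.fixture(scope="session")
def toy_varset():
    """Two variable codons with two synonymous options each (4 barcodes)."""
    return bd.VariablePositionSet(
        (
            (9, ("GTT", "GTC")),
            (10, ("GGA", "GGG")),
        )
    )
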