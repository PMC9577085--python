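import pytest

from nanopk import ResponseSurfaceModel, Term, datasets


@pytest.fixture(scope="session")
def ccd_design():
    return datasets.ccd_design()


@pytest.fixture(scope="session")
def particle_size_table():
    return datasets.ccd_particle_size()


@pytest.fixture(scope="session")
def reduced_fit(ccd_design, particle_size_table):
    """The reduced particle-size model: intercept + x1 + x2 + x2^2."""
    model = ResponseSurfaceModel.from_dataframe(
        ccd_design, particle_size_table, "particle_size",
        terms=[Term.linear(0), Term.linear(1), Term.quadratic(1)])
    return model.fit()
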