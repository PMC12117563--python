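"""Shared synthetic fixtures: everything is generated, nothing downloaded."""

import pytest

from fvkit.fixtures import FixtureSpec, make_complex, make_fv, make_ideal_secondary
from fvkit.pipeline import standardize_entry


@pytest.fixture(scope="session")
def fv():
    """Paired VH/VL fixture, cysteines 15 A apart."""
    return make_fv(FixtureSpec(seed=7, fv_separation=15.0))


@pytest.fixture(scope="session")
def complex_fixture():
    """One Fv bound to a 60-residue antigen with exactly 5 CDR contacts."""
    return make_complex(FixtureSpec(seed=7, target_contacts=5))


@pytest.fixture(scope="session")
def standardized_ref(complex_fixture):
    """The standardized H/L + antigen reference complex of the fixture."""
    outs, outcome = standardize_entry(complex_fixture.model,
                                      complex_fixture.engine)
    assert outcome.status == "ok"
    assert len(outs) == 1
    return outs[0][1]


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_secondary("helix", 12)
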