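"""Shared fixtures: small synthetic structures sized for fast tests."""

import pytest

from aptadock import synthgen


@pytest.fixture(scope="session")
def small_params() -> synthgen.GenParams:
    """Reduced globule sizes; same topology as the full-size defaults."""
    return synthgen.GenParams(seed=7, n_res_rbd=30, n_res_hbd=15)


@pytest.fixture(scope="session")
def small_receptor(small_params):
    return synthgen.make_toy_receptor(small_params)


@pytest.fixture(scope="session")
def small_heterodimer(small_params):
    return synthgen.make_toy_aptamer("heterodimer", small_params)


@pytest.fixture(scope="session")
def default_receptor():
    return synthgen.make_toy_receptor(synthgen.GenParams(seed=1))
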