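"""Shared fixtures.

The condition scan of the core network is expensive (a dozen regulation
runs), so it is computed once per session and shared by the landscape and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import metstab as ms
from metstab.library import toy_chain_condition


@pytest.fixture(scope="session")
def core_model():
    return ms.build_core_model()


@pytest.fixture(scope="session")
def ensemble(core_model):
    return ms.default_condition_ensemble(core_model)


@pytest.fixture(scope="session")
def core_landscape(core_model, ensemble):
    return ms.scan_conditions(core_model, ensemble)


@pytest.fixture(scope="session")
def chain3():
    model = ms.build_toy_chain(3)
    condition = toy_chain_condition(model, demand=0.1)
    return model, condition


@pytest.fixture(scope="session")
def chain3_converged(chain3):
    model, condition = chain3
    regulated, trace = ms.run_regulation(
        model, condition, ms.RegulationConfig(seed=1)
    )
    assert trace.converged
    return regulated, condition, trace


def random_reversible_kinetics(rng, n_sub=1, n_prod=1):
    """A random reversible kinetics draw for property tests."""
    return ms.ReactionKinetics(
        v_forward=float(rng.uniform(0.2, 5.0)),
        v_backward=float(rng.uniform(0.2, 5.0)),
        km_substrates=tuple(rng.uniform(0.2, 3.0, n_sub)),
        km_products=tuple(rng.uniform(0.2, 3.0, n_prod)),
        k_eq=float(rng.uniform(0.1, 10.0)),
    )
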