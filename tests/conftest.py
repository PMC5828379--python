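"""Shared fixtures: packaged parameter sets and cached noiseless simulations."""

from __future__ import annotations

import pytest

from navclamp.gating import PACKAGED_LABELS, load_params
from navclamp.protocols import PROTOCOL_FACTORIES, simulate


@pytest.fixture(scope="session")
def params() -> dict:
    return {label: load_params(label) for label in PACKAGED_LABELS}


@pytest.fixture(scope="session")
def noiseless(params):
    """Memoized noiseless simulation: ``noiseless(group, protocol_name)``.

    The slow-inactivation protocol simulates 30-s sweeps; caching keeps the
    suite fast while every test sees identical data.
    """
    cache: dict = {}

    def get(group: str, proto_name: str):
        key = (group, proto_name)
        if key not in cache:
            cache[key] = simulate(PROTOCOL_FACTORIES[proto_name](), params[group])
        return cache[key]

    return get
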