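import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from piburden import generate_inputs
from piburden.ontology import StratumOntology


@pytest.fixture(scope="session")
def bundle():
    """Small synthetic bundle shared across read-only tests."""
    return generate_inputs(seed=1, scale=0.01)


@pytest.fixture()
def tiny_ontology():
    """Minimal ontology: diabetes × pi_status only (4 strata)."""
    return StratumOntology(
        factors={"diabetes": ("no", "yes"), "pi_status": ("active", "inactive")}
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
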