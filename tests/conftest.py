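"""Shared fixtures: expensive simulations computed once per session."""

import numpy as np
import pytest

from atrisim.ionic import (
    CellParameters, REFERENCE_ELECTROLYTES, apply_fibrosis_remodelling,
)
from atrisim.monodomain import strand_cv_protocol
from atrisim.protocols0d import limit_cycle_ap


@pytest.fixture(scope="session")
def healthy_params():
    return CellParameters()


@pytest.fixture(scope="session")
def fibrotic_params(healthy_params):
    return apply_fibrosis_remodelling(healthy_params)


@pytest.fixture(scope="session")
def baseline_lc(healthy_params):
    """Healthy limit-cycle AP at reference electrolytes, CL 1000 ms:
    (biomarkers, trace, prepace result)."""
    return limit_cycle_ap(healthy_params, REFERENCE_ELECTROLYTES,
                          cl_ms=1000.0, n_prepace=100)


@pytest.fixture(scope="session")
def healthy_strand(healthy_params):
    """Healthy 1-cm strand run at CL 1000 ms: (cv, blocked, result)."""
    return strand_cv_protocol(healthy_params, REFERENCE_ELECTROLYTES,
                              cl_ms=1000.0, n_prepace=100)


@pytest.fixture(scope="session")
def fibrotic_strand(fibrotic_params):
    """Fibrotic strand (remodelled cells + reduced coupling) at CL 1000 ms."""
    return strand_cv_protocol(fibrotic_params, REFERENCE_ELECTROLYTES,
                              cl_ms=1000.0, n_prepace=100,
                              strand_conductivity=0.14)
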