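import numpy as np
import pytest

from exprsel.mm_pathway import MMPathwayParams, optimize_expression
from exprsel.report import run_fig4

#: canonical seed for all stochastic tests
SEED = 0


@pytest.fixture(scope="session")
def mm_km1_optimum():
    """Grid optimum of the Km=1, no-cost two-step pathway (shared, ~1 s)."""
    params = MMPathwayParams(Km=1.0)
    best, curve = optimize_expression(params)
    return params, best, curve


@pytest.fixture(scope="session")
def growth_100_settings():
    """The 100-setting growth-model sweep at the canonical seed (~5 s)."""
    df, summary = run_fig4(n=100, seed=SEED)
    return df, summary
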