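import numpy as np
import pandas as pd
import pytest

from prismscreen import synth


@pytest.fixture
def small_screen():
    """Tiny screen with two MOA blocks and planted actives (deterministic)."""
    drm, truth = synth.generate_screen(
        n_compounds=30,
        n_lines=12,
        moa_spec={"MOA_X": 6, "MOA_Y": 6},
        frac_active=0.4,
        seed=123,
    )
    return drm, truth


@pytest.fixture
def small_expression():
    lines = [f"L{i:02d}" for i in range(12)]
    expr, truth = synth.generate_expression(
        n_genes=300, lines=lines, group_a=lines[:6], deg_frac=0.1, seed=7
    )
    return expr, truth, lines
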