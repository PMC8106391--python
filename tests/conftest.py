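import numpy as np
import pytest

from ecosens.stacks import MonthlyStack, SynthConfig
from ecosens import synthetic


@pytest.fixture(scope="session")
def small_scene():
    """Quiet 12x12 scene with TVDI driver, 19 years, fixed seed."""
    cfg = SynthConfig(n_rows=12, n_cols=12, n_years=19, seed=11)
    return cfg, synthetic.generate_scene(cfg)


@pytest.fixture(scope="session")
def recovery_scene():
    """~200-pixel scene used for coefficient-recovery checks (228 months)."""
    cfg = SynthConfig(n_rows=15, n_cols=14, n_years=19, seed=7, gap_fraction=0.0)
    return cfg, synthetic.generate_scene(cfg)


def make_stack(values, start_year=2000, tag="ndvi"):
    """Monthly stack from a (n_time, nr, nc) array with contiguous months."""
    values = np.asarray(values, dtype=float)
    n_t = values.shape[0]
    tidx = [(start_year + t // 12, t % 12 + 1) for t in range(n_t)]
    return MonthlyStack(values=values, time_index=tidx, variable_tag=tag)
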