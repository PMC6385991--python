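import numpy as np
import pytest

from ordinalgs.kernels import KernelSet, MarkerMatrix
from ordinalgs.synthetic import SyntheticConfig, simulate_markers, simulate_trial


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated trial shared by fast tests: J=80, I=3, C=3."""
    cfg = SyntheticConfig(I=3, J=80, m=150, seed=42, missing_cell_fraction=0.15)
    rng = np.random.default_rng(cfg.seed)
    raw = simulate_markers(cfg.J, cfg.m, cfg.maf_range, rng)
    markers = MarkerMatrix(line_ids=cfg.line_ids, raw=raw)
    kernels = KernelSet.from_markers(markers, I=cfg.I)
    table, truth = simulate_trial(cfg, kernels.G1, rng)
    return cfg, markers, kernels, table, truth
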