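import numpy as np
import pytest
from hypothesis import settings

import skincap as sc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def head_params() -> sc.LayerParams:
    """Head-scale constants: lambda = 1 (space in units of lambda), tau = 1 s,
    so the power-law window covers the tens-of-ms range of real artifacts."""
    return sc.LayerParams.from_constants(1.0, 1000.0)


@pytest.fixture(scope="session")
def unit_params() -> sc.LayerParams:
    return sc.LayerParams.from_constants(1.0, 1.0)


@pytest.fixture(scope="session")
def referenced_scene():
    """Default scene against a physical reference electrode, with the
    paper-style 50 Hz pre-subtraction applied; shared by removal tests."""
    cfg = sc.SceneConfig(seed=42, reference="reference-electrode")
    rec, comp = sc.generate_recording(cfg)
    pre = sc.subtract_line_noise(rec)
    return cfg, rec, pre, comp
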