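import numpy as np
import pytest

from synrec import SynthConfig, generate_volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synth():
    """One small rendered volume with truth, shared across tests."""
    cfg = SynthConfig(
        width=384, height=384, n_sections=8, n_synapses=2, n_distractors=1,
        length_range=(70.0, 110.0), min_separation=130.0, seed=0,
    )
    stack, truth = generate_volume(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def default_synth():
    """The generator's default study conditions, seed 0."""
    cfg = SynthConfig(seed=0)
    stack, truth = generate_volume(cfg)
    return cfg, stack, truth


def random_boxes(rng, n, section=0, span=200, size=(8, 40)):
    """Valid random detection boxes for fusion/screening tests."""
    from synrec import DetectionBox

    out = []
    for j in range(n):
        x1 = int(rng.integers(0, span))
        y1 = int(rng.integers(0, span))
        w = int(rng.integers(*size))
        h = int(rng.integers(*size))
        out.append(DetectionBox(section=section, index=j, x1=x1, y1=y1,
                                x2=x1 + w, y2=y1 + h,
                                score=float(rng.uniform(0, 1))))
    return out
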