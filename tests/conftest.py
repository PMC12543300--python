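import numpy as np
import pandas as pd
import pytest

from morphnet import morpho_io, synthgen

TOY_SWC = """\
# toy neuron: soma root, one stem, one bifurcation, two tips
1 1 0 0 0 5 -1
2 3 10 0 0 1 1
3 3 20 0 0 1 2
4 3 20 10 0 1 3
5 3 20 -10 0 1 3
"""


@pytest.fixture
def toy_swc_path(tmp_path):
    p = tmp_path / "toy.swc"
    p.write_text(TOY_SWC)
    return p


@pytest.fixture
def toy_recon(toy_swc_path):
    return morpho_io.read_swc(toy_swc_path)


@pytest.fixture
def small_table():
    """Deterministic 30-neuron, 12-feature class-structured table."""
    spec = synthgen.SynthSpec(
        n_neurons=30, n_features=12, classes={"A": 15, "B": 15},
        within_class_corr=0.4, seed=11,
    )
    return synthgen.synth_feature_table(spec)


@pytest.fixture
def default_table():
    """Generator defaults: 120 neurons, 3 classes, 42 features."""
    return synthgen.synth_feature_table(synthgen.SynthSpec(seed=7))
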