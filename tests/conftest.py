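import numpy as np
import pytest

from halfsibsim import (
    GeneticSystem,
    build_synthetic_map,
    sample_qtl_effects,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_system(rng):
    """A compact 2-group system: 6 QTL + 4 markers, mixed dominance."""
    gmap = build_synthetic_map(2, 6, 4, 80.0, rng)
    effects = sample_qtl_effects("additive_dominance", 6, rng)
    return GeneticSystem(gmap, effects, "additive_dominance")


@pytest.fixture
def additive_system(rng):
    gmap = build_synthetic_map(3, 12, 8, 100.0, rng)
    effects = sample_qtl_effects("additive", 12, rng)
    return GeneticSystem(gmap, effects, "additive")


@pytest.fixture
def case_study_system(rng):
    """Full-size synthetic stand-in: 7 groups, 63 QTL, 194 markers."""
    gmap = build_synthetic_map(7, 63, 194, 100.0, rng)
    effects = sample_qtl_effects("additive", 63, rng)
    return GeneticSystem(gmap, effects, "additive")
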