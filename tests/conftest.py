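import numpy as np
import pytest

from excluscan import (
    SelectionModel,
    apply_conjugation_selection,
    generate_reference,
    simulate_insertion_library,
)

PLANTED_GENE = "orf_p001"


@pytest.fixture(scope="session")
def small_reference():
    """A 10-gene two-replicon reference used across modules."""
    return generate_reference(10, gene_length_range=(300, 900), seed=42)


@pytest.fixture(scope="session")
def planted_experiment():
    """A simulated screen with one exclusion gene (effect 20, base rate 0.01)."""
    ref, ann = generate_reference(50, seed=1)
    lib = simulate_insertion_library(ref, 10_000, seed=101)
    model = SelectionModel(base_rate=0.01, effects={PLANTED_GENE: 20.0})
    out = apply_conjugation_selection(lib, model, ann, seed=102)
    return ref, ann, lib, out, model


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
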