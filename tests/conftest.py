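import numpy as np
import pytest

from cloneval.simulate import (
    DEFAULT_PRIMER_MASK,
    DEFAULT_REFERENCE,
    PcrModel,
    SeqErrorModel,
    make_spikein_templates,
    simulate_pcr,
    simulate_sequencing,
)


@pytest.fixture(scope="session")
def reference():
    return DEFAULT_REFERENCE


@pytest.fixture(scope="session")
def primer_mask():
    return DEFAULT_PRIMER_MASK


@pytest.fixture(scope="session")
def wt_templates(reference, primer_mask):
    """Single wild-type template covering the whole amplicon."""
    return make_spikein_templates(reference, [None], [1.0], primer_mask=primer_mask)


@pytest.fixture(scope="session")
def small_run(wt_templates):
    """A modest simulated run with PCR and sequencer errors, reused by the
    alignment/selection/validation oracle tests."""
    pool = simulate_pcr(
        wt_templates, PcrModel(doublings=43, sub_rate=2.5e-6), 4000, seed=11
    )
    model = SeqErrorModel.from_aggregate(wt_templates.reference, 0.0015, 0.0015)
    return simulate_sequencing(pool, model, 4000, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
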