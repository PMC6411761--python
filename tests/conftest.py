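import numpy as np
import pytest

from bhsii import (
    ResponseSheet,
    SimulationConfig,
    load_default_instrument,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def instrument():
    return load_default_instrument()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-config cohort, shared across tests that only read it."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_scores(default_cohort):
    scores = default_cohort.scores()
    meta = default_cohort.metadata
    scores = scores.merge(meta[["subject_id", "group"]], on="subject_id")
    return scores


def make_sheet(instrument, fill=0, subject_id="D001", timepoint="T0", **overrides):
    """A complete sheet with every item at ``fill``, then overrides."""
    values = {item_id: fill for item_id in instrument.item_ids}
    values.update(overrides)
    return ResponseSheet(subject_id=subject_id, timepoint=timepoint, values=values)


@pytest.fixture
def sheet_factory(instrument):
    def _make(fill=0, **kwargs):
        return make_sheet(instrument, fill=fill, **kwargs)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
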