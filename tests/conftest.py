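import numpy as np
import pytest

import vaxtrace as vt
from vaxtrace import cohort, inspection, ptmodel


@pytest.fixture(scope="session")
def table():
    return vt.load_evidence_table()


@pytest.fixture(scope="session")
def tiny_bundle(table):
    """A 6-participant cohort (2 per attitude group), fixed seed."""
    config = cohort.default_cohort_config(
        sizes={"anti": 2, "neutral": 2, "pro": 2}, table=table
    )
    return cohort.generate_cohort(config, seed=11)


@pytest.fixture(scope="session")
def tiny_summaries(tiny_bundle, table):
    return inspection.process_events(tiny_bundle.events, tiny_bundle.decisions, table)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_bundle, tiny_summaries, table):
    return ptmodel.build_model_dataset(
        table, tiny_bundle.ratings, tiny_summaries, tiny_bundle.decisions
    )


def make_toy_dataset(n_participants=3, n_vaccines=2, seed=5):
    """A small hand-assembled ModelDataset (not via the generator), with a
    mix of weighted, neglected and ignored outcomes."""
    rng = np.random.default_rng(seed)
    y = (rng.random((n_participants, n_vaccines)) < 0.5).astype(float)
    rating_mag = rng.integers(1, 6, size=(n_participants, n_vaccines, 6)).astype(float)
    p = rng.uniform(1e-5, 0.99, size=(n_vaccines, 6))
    p[0, 5] = np.nan  # one benefit without a presented probability
    m_prelec = rng.random((n_participants, n_vaccines, 6)) < 0.5
    m_half = ~m_prelec & (rng.random((n_participants, n_vaccines, 6)) < 0.5)
    m_prelec[:, 0, 5] = False  # missing probability can only be half-weighted
    X = rng.standard_normal((n_vaccines, 4))
    return ptmodel.ModelDataset(
        participant_ids=[f"p{i}" for i in range(n_participants)],
        brands=[f"v{j}" for j in range(n_vaccines)],
        y=y,
        rating_mag=rating_mag,
        p=p,
        m_prelec=m_prelec,
        m_half=m_half,
        X=X,
    )


@pytest.fixture()
def toy_dataset():
    return make_toy_dataset()
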