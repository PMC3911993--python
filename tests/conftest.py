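import numpy as np
import pytest

import pathsem as ps

FIG1_DEGRADATION = {
    ("RLS2", "dp39"),
    ("RLS2", "dp12"),
    ("RLS2", "dp37"),
    ("RSS174", "dp44"),
    ("RSS175", "dp44"),
    ("dp39", "dp7"),
    ("dp39", "dp15"),
    ("dp39", "dp17"),
}
FIG1_REGULATION = {("RSS174", "RLS2"), ("RSS175", "RLS2"), ("RLS2", "RLS2")}


@pytest.fixture(scope="session")
def fig1_records():
    return ps.fragment_fixture(0)


@pytest.fixture(scope="session")
def fig1_graph(fig1_records):
    return ps.build_prior_graph(fig1_records, ps.rodermel_regulation())


@pytest.fixture(scope="session")
def prior_skeleton(fig1_graph):
    return ps.to_sem_skeleton(fig1_graph)


@pytest.fixture(scope="session")
def final_truth():
    return ps.rubisco_fixture("final")


@pytest.fixture(scope="session")
def prior_truth():
    return ps.rubisco_fixture("prior")


@pytest.fixture(scope="session")
def study_data(final_truth):
    """One study-scale draw (n=48) from the final-structure truth."""
    return ps.simulate(final_truth, n=48, seed=101)


@pytest.fixture(scope="session")
def big_data(final_truth):
    """A large-sample draw for consistency checks."""
    return ps.simulate(final_truth, n=5000, seed=202)


def interval_record(pid, mass, intervals, tier="fragment", ref="REF"):
    if tier == "intact":
        ref = pid
    return ps.ProteinRecord(
        id=pid, tier=tier, mass_kda=mass, reference_subunit=ref,
        evidence=frozenset(intervals),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
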