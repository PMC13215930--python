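import warnings

import pytest

from ismanp import anp, fixtures, ism


@pytest.fixture(scope="session")
def study():
    """Expanded bundled example tables (18-factor drowning-risk system)."""
    return fixtures.load_fixtures()


@pytest.fixture(scope="session")
def reachability(study):
    """Reachability matrix reconstructed from the bundled reachable sets."""
    return ism.reachability_from_sets(study.reachable_sets)


@pytest.fixture(scope="session")
def partition(reachability):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ism.partition_levels(reachability)


@pytest.fixture(scope="session")
def network(study, reachability):
    """ANP influence network over the bundled reachability and clusters."""
    return anp.build_network(reachability, study.cluster_of, study.cluster_order)
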