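import numpy as np
import pytest

import brainstates as bs


@pytest.fixture(scope="session")
def toy_seq() -> bs.StateSequence:
    """The worked example sequence [1 1 1 2 2 3 2 2] at TR = 3 s."""
    return bs.StateSequence(labels=np.array([1, 1, 1, 2, 2, 3, 2, 2]), k=3, tr=3.0)


@pytest.fixture(scope="session")
def small_parc() -> bs.RegionParcellation:
    """21 regions, 3 per system."""
    return bs.generate_parcellation(21, {s: 3 for s in bs.SYSTEMS}, seed=11)


@pytest.fixture(scope="session")
def small_net(small_parc) -> bs.StructuralNetwork:
    return bs.generate_connectome(small_parc, density=0.5, seed=11)


@pytest.fixture(scope="session")
def cohort40() -> "bs.synthetic.Cohort":
    """Default-condition cohort: 40 subjects, 50 regions, 5 planted states."""
    return bs.generate_cohort(bs.CohortConfig(n_subjects=40), seed=7)


@pytest.fixture(scope="session")
def fitted40(cohort40):
    """Concatenated matrix and fitted k = 5 model for the default cohort."""
    X, index = bs.concatenate_scans(cohort40.scans)
    model = bs.fit_kmeans(X, 5, n_reps=20, seed=1)
    return X, index, model
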