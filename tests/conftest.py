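import pytest

from qtalert import CohortSpec, cohort_from_smiles, load_alert_dictionary


@pytest.fixture(scope="session")
def dictionary():
    return load_alert_dictionary()


@pytest.fixture(scope="session")
def alerts_by_name(dictionary):
    return {a.name: a for a in dictionary}


@pytest.fixture(scope="session")
def synthetic_dictionary(dictionary):
    """The sub-dictionary the cohort generator can plant independently."""
    names = set(CohortSpec().prevalences)
    return [a for a in dictionary if a.name in names]


@pytest.fixture
def small_pos_cohort():
    return cohort_from_smiles(
        [
            ("p1", "CCN(CC)CC"),  # tertiary aliphatic amine
            ("p2", "Clc1ccccc1"),  # aryl halide
            ("p3", "COc1ccccc1"),  # alkylaryl ether
        ],
        label="positive",
    )


@pytest.fixture
def small_neg_cohort():
    return cohort_from_smiles(
        [("n1", "CCCC"), ("n2", "CCO")],
        label="negative",
    )
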