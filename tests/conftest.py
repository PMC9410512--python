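import numpy as np
import pandas as pd
import pytest

from gfabric import (
    ExpressionSet,
    GeneSetCollection,
    compare_conditions,
    compute_fabric,
    make_three_condition_fixture,
)


def es_from_matrix(values, genes=None, condition="A", columns=None) -> ExpressionSet:
    """Build an ExpressionSet from a plain (genes x replicates) array."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    columns = columns or [f"r{j}" for j in range(arr.shape[1])]
    return ExpressionSet(condition, pd.DataFrame(arr, index=genes, columns=columns))


def es_from_log2(profiles, genes=None, condition="A") -> ExpressionSet:
    """ExpressionSet whose log2 values equal the given profiles exactly."""
    return es_from_matrix(2.0 ** np.asarray(profiles, dtype=float), genes, condition)


@pytest.fixture(scope="session")
def fixture_study():
    return make_three_condition_fixture(7)


@pytest.fixture(scope="session")
def fixture_fabrics(fixture_study):
    study, _ = fixture_study
    return {label: compute_fabric(es) for label, es in study.items()}


@pytest.fixture(scope="session")
def fixture_regulations(fixture_fabrics):
    reg_in = compare_conditions(fixture_fabrics["NN"], fixture_fabrics["IN"])
    reg_it = compare_conditions(fixture_fabrics["NN"], fixture_fabrics["IT"])
    return reg_in, reg_it


@pytest.fixture(scope="session")
def fixture_pathway(fixture_study):
    _, truth = fixture_study
    return GeneSetCollection({truth.set_name: truth.pathway})
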