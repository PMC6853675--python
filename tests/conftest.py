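import numpy as np
import pytest
from hypothesis import settings

from qab.curation import RawActivityRecord
from qab.synthetic import SyntheticSpec, generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def record(**kw):
    """A valid raw IC50 record with overridable fields."""
    base = dict(
        molecule_id="CHEMBL1",
        smiles="CCO",
        value=100.0,
        unit="nM",
        relation="=",
        target_type="SINGLE PROTEIN",
        organism="Homo sapiens",
    )
    base.update(kw)
    return RawActivityRecord(**base)


@pytest.fixture
def raw_records():
    """Five records of which two fail the curation criteria."""
    return [
        record(molecule_id="CHEMBL1"),
        record(molecule_id="CHEMBL2", value=5.0, unit="uM"),  # wrong unit
        record(molecule_id="CHEMBL3", relation=">"),  # censored value
        record(molecule_id="CHEMBL4", value=10.0),
        record(molecule_id="CHEMBL5", value=1.0),
    ]


@pytest.fixture
def linear_data():
    """Small linear-scenario dataset (fingerprints, activities, truth)."""
    return generate(SyntheticSpec(n_molecules=80, scenario="linear", seed=11))


@pytest.fixture
def clustered_data():
    return generate(
        SyntheticSpec(n_molecules=120, scenario="clustered_linear", seed=7)
    )


@pytest.fixture
def similar_actives_data():
    return generate(
        SyntheticSpec(n_molecules=200, scenario="similar_actives", seed=5)
    )
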