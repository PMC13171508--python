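import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hmgrqsar import qsar
from hmgrqsar.dataset import cleanse
from hmgrqsar.synthetic import GeneratorSpec, generate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

#: the nine published core scaffolds, exactly as printed (note the stray
#: typographic spaces, which the readers must strip before parsing)
TABLE4_SMILES_RAW = {
    1: "O=C1CCC [C@@H](CC [C@H]2CC = CC3 = CCCC [C@@H]32)O1",
    2: "c1ccc (-c2nc [nH]c2-c2ccccc2)cc1",
    3: "c1ccccc1",
    4: "C1 = CC2 = CCCC [C@@H]2CC1",
    5: "O=C(Nc1ccccc1)c1 [nH]cc (-c2ccccc2)c1-c1ccccc1",
    6: "O=C(NCc1ccccc1)c1 [nH]cc (-c2ccccc2)c1-c1ccccc1",
    7: "c1ccc (-c2cc [nH]c2-c2ccccc2)cc1",
    8: "O=C1CCC [C@@H](/C=C/c2c (C3CC3)nc3ccccc3c2Sc2ccccc2)O1",
    9: "O=C(Nc1ccccc1)c1c [nH]c (-c2ccccc2)c1-c1ccccc1",
}


@pytest.fixture(scope="session")
def table4_smiles():
    return dict(TABLE4_SMILES_RAW)


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic dataset (seed 42, noise_sd 0.5) plus its ledger."""
    return generate(GeneratorSpec())


@pytest.fixture(scope="session")
def curated_records(default_dataset):
    table, _ = default_dataset
    records, report = cleanse(table)
    assert report.balances()
    return records


@pytest.fixture(scope="session")
def default_fingerprints(curated_records):
    return qsar.featurize(curated_records)


@pytest.fixture(scope="session")
def suite_reports(curated_records, default_fingerprints):
    """The ten-model suite trained once on the default synthetic dataset."""
    y = [r.pic50 for r in curated_records]
    return qsar.train_suite(default_fingerprints, y, qsar.SplitSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
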