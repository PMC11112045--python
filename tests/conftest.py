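import numpy as np
import pytest

from gslmpp import SyntheticSpec, generate_dataset, scaffold_split


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_regression_records():
    """32-molecule noise-controlled regression draw, all assigned to train."""
    records = generate_dataset(
        SyntheticSpec(n_molecules=32, n_clusters=4, task_type="regression", seed=0))
    for rec in records:
        rec.split = "train"
    return records


@pytest.fixture(scope="session")
def clustered_regression_records():
    """200-molecule, 5-cluster regression draw with a scaffold split."""
    records = generate_dataset(
        SyntheticSpec(n_molecules=200, n_clusters=5, task_type="regression",
                      noise_sd=0.25, seed=7))
    return scaffold_split(records, seed=0)


@pytest.fixture()
def tiny_csv(tmp_path):
    """Three valid molecules, one blank target cell, one broken SMILES row."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "smiles,activity,toxicity\n"
        "CCO,1.2,0\n"
        "c1ccccc1,0.5,\n"
        "not_a_molecule,9.9,1\n"
        "CC(=O)O,-0.3,1\n")
    return path
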