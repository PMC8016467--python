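import numpy as np
import pytest

import dtikit
from dtikit.train_eval import _xy

# 20+ (SMILES, alias) pairs writing the same molecule two ways
MOLECULE_ALIASES = [
    ("CCO", "OCC"),
    ("C(C)C", "CC(C)"),
    ("c1ccccc1", "C1=CC=CC=C1"),
    ("c1ccncc1", "C1=CC=NC=C1"),
    ("CC(=O)O", "OC(C)=O"),
    ("CC(=O)N", "NC(C)=O"),
    ("CCCC", "C(C)CC"),
    ("CCN", "NCC"),
    ("COC", "COC"),
    ("CSC", "CSC"),
    ("C1CCCCC1", "C1CCCCC1"),
    ("CC(C)(C)C", "CC(C)(C)C"),
    ("c1ccc(O)cc1", "Oc1ccccc1"),
    ("c1ccc(N)cc1", "Nc1ccccc1"),
    ("c1ccc(Cl)cc1", "Clc1ccccc1"),
    ("CC(=O)OC", "COC(C)=O"),
    ("C=CC", "CC=C"),
    ("C#CC", "CC#C"),
    ("OCCO", "C(O)CO"),
    ("CC(N)C(=O)O", "OC(=O)C(N)C"),
    ("c1ccc2ccccc2c1", "c1ccc2ccccc2c1"),
    ("CCOC(=O)C", "CC(=O)OCC"),
]

# small encoder configs: keep neural tests fast on one CPU
TINY = {
    "morgan": {"hidden": [32, 8], "n_bits": 256},
    "pubchem": {"hidden": [32, 8]},
    "daylight": {"hidden": [32, 8], "n_bits": 256},
    "desc2d": {"hidden": [16, 8]},
    "cnn_smiles": {"max_len": 40, "embed_dim": 8, "filters": [8, 8],
                   "kernels": [3, 3], "output_dim": 8},
    "cnn_rnn_smiles": {"max_len": 40, "embed_dim": 8, "filters": [8, 8],
                       "kernels": [3, 3], "rnn_hidden": 8, "output_dim": 8},
    "espf_transformer": {"max_len": 20, "vocab_size": 40, "min_freq": 2,
                         "embed_dim": 8, "n_heads": 2, "n_layers": 1,
                         "ff_dim": 16, "output_dim": 8},
    "mpnn": {"hidden_dim": 8, "n_steps": 2, "readout": "mean", "output_dim": 8},
    "aac": {"hidden": [16, 8]},
    "paac": {"lam": 5, "weight": 0.05, "hidden": [16, 8]},
    "conjoint_triad": {"hidden": [32, 8]},
    "quasi_seq": {"maxlag": 5, "weight": 0.1, "hidden": [16, 8]},
    "cnn_protein": {"max_len": 100, "embed_dim": 8, "filters": [8, 8],
                    "kernels": [3, 5], "output_dim": 8},
    "cnn_rnn_protein": {"max_len": 60, "embed_dim": 8, "filters": [8, 8],
                        "kernels": [3, 5], "rnn_hidden": 8, "output_dim": 8},
    "espf_transformer_protein": {"max_len": 60, "vocab_size": 40, "min_freq": 2,
                                 "embed_dim": 8, "n_heads": 2, "n_layers": 1,
                                 "ff_dim": 16, "output_dim": 8},
}


def tiny_model(drug, prot, **kw):
    kw.setdefault("epochs", 1)
    kw.setdefault("batch_size", 8)
    kw.setdefault("decoder_hidden", (16, 8))
    kw.setdefault("seed", 0)
    return dtikit.DTIModel(drug_encoder=drug, protein_encoder=prot,
                           drug_config=TINY[drug], protein_config=TINY[prot], **kw)


@pytest.fixture(scope="session")
def small_dataset():
    spec = dtikit.SyntheticSpec(n_drugs=8, n_targets=4, observed_fraction=1.0,
                                noise_sd=0.2, effect_size=1.0, seed=3)
    return dtikit.generate(spec)


@pytest.fixture(scope="session")
def small_splits(small_dataset):
    return dtikit.data_process(small_dataset, "random", (0.7, 0.1, 0.2), seed=1)


@pytest.fixture(scope="session")
def small_xy(small_splits):
    return _xy(small_splits.train)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
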