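"""Default hyperparameters and key-value configuration files.

Every tunable of the library lives in :data:`DEFAULTS`; any value can be
overridden through a YAML config file or a plain dict, so a saved
configuration fully determines featurization, architecture and training.
"""

from __future__ import annotations

import copy

import yaml

DEFAULTS = {
    "drug_encoders": {
        "morgan": {"radius": 2, "n_bits": 1024, "hidden": [1024, 256, 64]},
        "pubchem": {"hidden": [1024, 256, 64]},
        "daylight": {"n_bits": 2048, "max_path": 7, "hidden": [1024, 256, 64]},
        "desc2d": {"hidden": [256, 128, 64]},
        "cnn_smiles": {
            "max_len": 100, "embed_dim": 64, "filters": [32, 64, 96],
            "kernels": [4, 6, 8], "output_dim": 128,
        },
        "cnn_rnn_smiles": {
            "max_len": 100, "embed_dim": 64, "filters": [32, 64, 96],
            "kernels": [4, 6, 8], "rnn_hidden": 64, "output_dim": 128,
        },
        "espf_transformer": {
            "max_len": 50, "vocab_size": 100, "min_freq": 2, "embed_dim": 64,
            "n_heads": 4, "n_layers": 2, "ff_dim": 128, "output_dim": 64,
        },
        "mpnn": {"hidden_dim": 64, "n_steps": 3, "readout": "mean", "output_dim": 64},
    },
    "protein_encoders": {
        "aac": {"hidden": [256, 128, 64]},
        "paac": {"lam": 30, "weight": 0.05, "hidden": [256, 128, 64]},
        "conjoint_triad": {"hidden": [512, 128, 64]},
        "quasi_seq": {"maxlag": 30, "weight": 0.1, "hidden": [256, 128, 64]},
        "cnn_protein": {
            "max_len": 1000, "embed_dim": 64, "filters": [32, 64, 96],
            "kernels": [4, 8, 12], "output_dim": 128,
        },
        "cnn_rnn_protein": {
            "max_len": 1000, "embed_dim": 64, "filters": [32, 64, 96],
            "kernels": [4, 8, 12], "rnn_hidden": 64, "output_dim": 128,
        },
        "espf_transformer_protein": {
            "max_len": 545, "vocab_size": 100, "min_freq": 2, "embed_dim": 64,
            "n_heads": 4, "n_layers": 2, "ff_dim": 128, "output_dim": 64,
        },
    },
    "decoder": {"hidden": [1024, 1024, 512]},
    "train": {
        "epochs": 10,
        "batch_size": 32,
        "learning_rate": 1e-3,
        "seed": 0,
        "early_stop_patience": 0,  # 0 disables early stopping
        "valid_metric": None,  # None -> CI for regression, AUROC for classification
        "f1_threshold": 0.5,
    },
    # the five default repurposing/screening ensemble members, spanning the
    # five encoder families (fingerprint-MLP, CNN, transformer, MPNN, CNN)
    "ensemble": [
        ["morgan", "aac"],
        ["cnn_smiles", "cnn_protein"],
        ["espf_transformer", "espf_transformer_protein"],
        ["mpnn", "cnn_protein"],
        ["daylight", "conjoint_triad"],
    ],
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def merge_config(base: dict, overrides: dict | None) -> dict:
    """Recursive dict merge; override values win, unknown keys are rejected."""
    if overrides is None:
        return copy.deepcopy(base)
    out = copy.deepcopy(base)
    for key, val in overrides.items():
        if key not in out:
            raise KeyError(f"unknown config key {key!r}; valid: {sorted(out)}")
        if isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def read_config(path) -> dict:
    """Load a YAML config file as a plain dict (empty file -> {})."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
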