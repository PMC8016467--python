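"""Encoder registry and architectures: the unifying half of the framework.

Eight compound encoders and seven protein encoders are registered by name;
any pairing assembles into a full model (8 x 7 = 56 architectures).  Each
registry entry couples a *featurizer* (string -> features) with an encoder
*architecture* (features -> fixed-dimension embedding):

====================  ==============  =========================
name                  input kind      architecture
====================  ==============  =========================
morgan/pubchem/
daylight/desc2d       vector          MLP
aac/paac/
conjoint_triad/
quasi_seq             vector          MLP
cnn_*                 token sequence  CNN + global max-pool
cnn_rnn_*             token sequence  CNN + bidirectional RNN
espf_transformer*     token sequence  transformer (masked)
mpnn                  graph           message passing + readout
====================  ==============  =========================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem, protein
from ._autograd import Tensor, concat, softmax
from ._layers import MLP, BiRNN, Conv1d, Embedding, Linear, Module, TransformerBlock
from .bpe import SubstructureVocab, train_substructure_vocab
from .config import DEFAULTS, merge_config
from .tokenize import PROTEIN_VOCAB_SIZE, SMILES_VOCAB_SIZE

__all__ = [
    "EncoderSpec",
    "DRUG_ENCODER_NAMES",
    "PROTEIN_ENCODER_NAMES",
    "make_encoder_spec",
    "build_encoder",
    "featurize_batch",
    "needs_vocab",
]

DRUG_ENCODER_NAMES = (
    "morgan", "pubchem", "daylight", "desc2d",
    "cnn_smiles", "cnn_rnn_smiles", "espf_transformer", "mpnn",
)
PROTEIN_ENCODER_NAMES = (
    "aac", "paac", "conjoint_triad", "quasi_seq",
    "cnn_protein", "cnn_rnn_protein", "espf_transformer_protein",
)

_INPUT_KIND = {
    "morgan": "vector", "pubchem": "vector", "daylight": "vector", "desc2d": "vector",
    "aac": "vector", "paac": "vector", "conjoint_triad": "vector", "quasi_seq": "vector",
    "cnn_smiles": "token_sequence", "cnn_rnn_smiles": "token_sequence",
    "cnn_protein": "token_sequence", "cnn_rnn_protein": "token_sequence",
    "espf_transformer": "token_sequence", "espf_transformer_protein": "token_sequence",
    "mpnn": "graph",
}

_VECTOR_DIMS = {
    "morgan": lambda hp: hp["n_bits"],
    "pubchem": lambda hp: 881,
    "daylight": lambda hp: hp["n_bits"],
    "desc2d": lambda hp: len(chem.DESCRIPTOR_NAMES),
    "aac": lambda hp: 20,
    "paac": lambda hp: 20 + hp["lam"],
    "conjoint_triad": lambda hp: 343,
    "quasi_seq": lambda hp: 20 + hp["maxlag"],
}


@dataclass
class EncoderSpec:
    """A named encoder with resolved hyperparameters and output dimension."""

    name: str
    side: str  # drug | protein
    input_kind: str
    hyperparams: dict = field(default_factory=dict)
    output_dim: int = 0

    def __post_init__(self):
        if self.output_dim <= 0:
            raise ValueError(f"encoder {self.name}: output_dim must be positive")
        if self.input_kind != _INPUT_KIND[self.name]:
            raise ValueError(
                f"encoder {self.name}: input kind {self.input_kind!r} inconsistent"
            )


def _registry(side: str) -> dict:
    return DEFAULTS["drug_encoders"] if side == "drug" else DEFAULTS["protein_encoders"]


def _check_name(name: str, side: str) -> None:
    valid = DRUG_ENCODER_NAMES if side == "drug" else PROTEIN_ENCODER_NAMES
    if name not in valid:
        raise KeyError(
            f"unknown {side} encoder {name!r}; registered encoders: {', '.join(valid)}"
        )


def make_encoder_spec(name: str, side: str, overrides: dict | None = None) -> EncoderSpec:
    """Resolve a registry name plus overrides into a full :class:`EncoderSpec`."""
    _check_name(name, side)
    hp = merge_config(_registry(side)[name], overrides)
    if name in _VECTOR_DIMS:
        out_dim = hp["hidden"][-1]
    else:
        out_dim = hp["output_dim"]
    return EncoderSpec(name=name, side=side, input_kind=_INPUT_KIND[name],
                       hyperparams=hp, output_dim=out_dim)


def needs_vocab(name: str) -> bool:
    return name.startswith("espf_transformer")


# ---------------------------------------------------------------------------
# featurization (string -> batch features)
# ---------------------------------------------------------------------------

def featurize_one(name: str, item: str, hp: dict, vocab: SubstructureVocab | None = None):
    """Featurize a single SMILES string or protein sequence for encoder ``name``."""
    if name == "morgan":
        return chem.morgan_fingerprint(item, radius=hp["radius"], n_bits=hp["n_bits"]).bits
    if name == "pubchem":
        return chem.pubchem_fingerprint(item).bits
    if name == "daylight":
        return chem.daylight_fingerprint(item, n_bits=hp["n_bits"], max_path=hp["max_path"]).bits
    if name == "desc2d":
        return chem.descriptors_2d(item).values
    if name == "aac":
        return protein.aac(item).values
    if name == "paac":
        return protein.pseudo_aac(item, lam=hp["lam"], weight=hp["weight"]).values
    if name == "conjoint_triad":
        return protein.conjoint_triad(item).values
    if name == "quasi_seq":
        return protein.quasi_seq_order(item, maxlag=hp["maxlag"], weight=hp["weight"]).values
    if name in ("cnn_smiles", "cnn_rnn_smiles"):
        return chem.smiles_label_encode(item, max_len=hp["max_len"])
    if name in ("cnn_protein", "cnn_rnn_protein"):
        return protein.seq_label_encode(item, max_len=hp["max_len"])
    if name == "espf_transformer":
        if vocab is None:
            raise ValueError("espf_transformer requires a trained substructure vocabulary")
        return chem.espf_smiles_encode(item, vocab, max_len=hp["max_len"])
    if name == "espf_transformer_protein":
        if vocab is None:
            raise ValueError(
                "espf_transformer_protein requires a trained substructure vocabulary")
        return protein.espf_protein_encode(item, vocab, max_len=hp["max_len"])
    if name == "mpnn":
        return chem.smiles_to_graph(item)
    raise KeyError(f"unknown encoder {name!r}")


def featurize_batch(name: str, items, hp: dict, vocab: SubstructureVocab | None = None,
                    cache: dict | None = None):
    """Featurize a batch, caching repeated strings.

    Returns the batch-feature object the matching architecture consumes:
    a (batch, dim) float array for vectors, an ``{"indices", "mask"}`` dict
    for token sequences, or a list of :class:`~dtikit.chem.MolGraph`.
    """
    feats = []
    for item in items:
        key = (name, item)
        if cache is not None and key in cache:
            feats.append(cache[key])
            continue
        f = featurize_one(name, item, hp, vocab)
        if cache is not None:
            cache[key] = f
        feats.append(f)
    kind = _INPUT_KIND[name]
    if kind == "vector":
        return np.stack([np.asarray(f, dtype=float) for f in feats])
    if kind == "token_sequence":
        return {
            "indices": np.stack([f.indices for f in feats]),
            "mask": np.stack([f.mask for f in feats]),
        }
    return feats  # graphs


def train_vocab_for(name: str, corpus, hp: dict) -> SubstructureVocab:
    """Train the substructure vocabulary an ESPF encoder needs."""
    return train_substructure_vocab(corpus, target_size=hp["vocab_size"],
                                    min_freq=hp["min_freq"])


# ---------------------------------------------------------------------------
# architectures (batch features -> embedding Tensor)
# ---------------------------------------------------------------------------

class VectorEncoder(Module):
    def __init__(self, rng, spec: EncoderSpec):
        super().__init__()
        in_dim = _VECTOR_DIMS[spec.name](spec.hyperparams)
        self.mlp = self.add_module("mlp", MLP(rng, in_dim, spec.hyperparams["hidden"]))

    def __call__(self, batch) -> Tensor:
        return self.mlp(Tensor(batch))


class _ConvStack(Module):
    def __init__(self, rng, hp: dict, vocab_size: int):
        super().__init__()
        self.embed = self.add_module("embed", Embedding(rng, vocab_size, hp["embed_dim"]))
        chans = [hp["embed_dim"]] + list(hp["filters"])
        self.convs = [
            self.add_module(f"conv{i}", Conv1d(rng, a, b, k))
            for i, (a, b, k) in enumerate(zip(chans[:-1], chans[1:], hp["kernels"]))
        ]

    def __call__(self, indices: np.ndarray) -> Tensor:
        x = self.embed(indices).transpose(0, 2, 1)  # (batch, emb, steps)
        for conv in self.convs:
            x = conv(x).relu()
        return x  # (batch, filters[-1], reduced_steps)


class CNNEncoder(Module):
    """Character CNN with global max-pool readout."""

    def __init__(self, rng, spec: EncoderSpec, vocab_size: int):
        super().__init__()
        hp = spec.hyperparams
        self.stack = self.add_module("stack", _ConvStack(rng, hp, vocab_size))
        self.out = self.add_module("out", Linear(rng, hp["filters"][-1], hp["output_dim"]))

    def __call__(self, batch) -> Tensor:
        h = self.stack(batch["indices"]).max(axis=2)
        return self.out(h).relu()


class CNNRNNEncoder(Module):
    """Character CNN whose feature map feeds a bidirectional RNN."""

    def __init__(self, rng, spec: EncoderSpec, vocab_size: int):
        super().__init__()
        hp = spec.hyperparams
        self.stack = self.add_module("stack", _ConvStack(rng, hp, vocab_size))
        self.rnn = self.add_module("rnn", BiRNN(rng, hp["filters"][-1], hp["rnn_hidden"]))
        self.out = self.add_module("out", Linear(rng, 2 * hp["rnn_hidden"], hp["output_dim"]))

    def __call__(self, batch) -> Tensor:
        h = self.stack(batch["indices"]).transpose(0, 2, 1)  # (batch, steps', ch)
        steps = h.shape[1]
        # conv stages shorten the sequence from the right; clip the mask
        mask = batch["mask"][:, :steps].astype(float)
        mask[mask.sum(axis=1) == 0, 0] = 1.0  # degenerate: keep one step
        return self.out(self.rnn(h, mask)).relu()


class TransformerEncoder(Module):
    """Masked multi-head self-attention over substructure tokens."""

    def __init__(self, rng, spec: EncoderSpec, vocab_size: int):
        super().__init__()
        hp = spec.hyperparams
        dim = hp["embed_dim"]
        self.embed = self.add_module("embed", Embedding(rng, vocab_size, dim))
        self.pos = self.add_param("pos", rng.normal(0.0, 0.02, size=(hp["max_len"], dim)))
        self.blocks = [
            self.add_module(f"block{i}", TransformerBlock(rng, dim, hp["n_heads"], hp["ff_dim"]))
            for i in range(hp["n_layers"])
        ]
        self.out = self.add_module("out", Linear(rng, dim, hp["output_dim"]))

    def __call__(self, batch) -> Tensor:
        indices, mask = batch["indices"], batch["mask"].astype(float)
        if np.any(mask.sum(axis=1) == 0):
            raise ValueError("transformer encoder received an all-padding sequence")
        steps = indices.shape[1]
        x = self.embed(indices) + self.pos[:steps]
        for block in self.blocks:
            x = block(x, mask)
        m = Tensor(mask[:, :, None])
        pooled = (x * m).sum(axis=1) / Tensor(mask.sum(axis=1, keepdims=True))
        return self.out(pooled).relu()


class MPNNEncoder(Module):
    """Message passing over the molecular graph with sum/mean readout."""

    def __init__(self, rng, spec: EncoderSpec):
        super().__init__()
        hp = spec.hyperparams
        d = hp["hidden_dim"]
        self.n_steps = hp["n_steps"]
        self.readout = hp["readout"]
        if self.readout not in ("sum", "mean"):
            raise ValueError("mpnn readout must be 'sum' or 'mean'")
        self.atom_in = self.add_module("atom_in", Linear(rng, chem.ATOM_FEATURE_DIM, d))
        self.msg = self.add_module("msg", Linear(rng, d + chem.BOND_FEATURE_DIM, d))
        self.upd = self.add_module("upd", Linear(rng, 2 * d, d))
        self.out = self.add_module("out", Linear(rng, d, hp["output_dim"]))

    def _encode_graph(self, graph) -> Tensor:
        h = self.atom_in(Tensor(graph.atom_features)).relu()  # (n_atoms, d)
        n = graph.n_atoms
        if graph.bond_list.size:
            src = np.concatenate([graph.bond_list[:, 0], graph.bond_list[:, 1]])
            dst = np.concatenate([graph.bond_list[:, 1], graph.bond_list[:, 0]])
            efeat = np.concatenate([graph.bond_features, graph.bond_features])
            # scatter matrix A[dst, edge] = 1 sums incoming messages per atom
            scatter = np.zeros((n, len(src)))
            scatter[dst, np.arange(len(src))] = 1.0
        for _ in range(self.n_steps):
            if graph.bond_list.size:
                edge_in = concat([h[src], Tensor(efeat)], axis=1)
                messages = Tensor(scatter) @ self.msg(edge_in).relu()
            else:
                messages = Tensor(np.zeros_like(h.data))
            h = self.upd(concat([h, messages], axis=1)).relu()
        pooled = h.sum(axis=0) if self.readout == "sum" else h.mean(axis=0)
        return self.out(pooled.reshape(1, -1)).relu()

    def __call__(self, batch) -> Tensor:
        return concat([self._encode_graph(g) for g in batch], axis=0)


def build_encoder(spec: EncoderSpec, rng: np.random.Generator,
                  vocab: SubstructureVocab | None = None) -> Module:
    """Instantiate the architecture for a resolved encoder spec."""
    name = spec.name
    _check_name(name, spec.side)
    if name in _VECTOR_DIMS:
        return VectorEncoder(rng, spec)
    if name in ("cnn_smiles", "cnn_rnn_smiles", "cnn_protein", "cnn_rnn_protein"):
        vocab_size = SMILES_VOCAB_SIZE if spec.side == "drug" else PROTEIN_VOCAB_SIZE
        cls = CNNEncoder if name.startswith("cnn_rnn") is False else CNNRNNEncoder
        return cls(rng, spec, vocab_size)
    if needs_vocab(name):
        if vocab is None:
            raise ValueError(f"encoder {name} requires a substructure vocabulary")
        return TransformerEncoder(rng, spec, vocab.size)
    if name == "mpnn":
        return MPNNEncoder(rng, spec)
    raise KeyError(name)
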