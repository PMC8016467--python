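"""Protein sequence featurizers: the seven target-side input representations.

Vector descriptors
    * ``aac`` — amino-acid composition, the 20-dim frequency vector.
    * ``paac`` — pseudo amino-acid composition (Chou): composition plus
      ``lam`` sequence-order correlation factors computed from
      hydrophobicity, hydrophilicity and side-chain mass, jointly
      normalized so all ``20 + lam`` components sum to 1.
    * ``conjoint_triad`` — 343-dim count vector of overlapping residue
      triplets after mapping the 20 amino acids onto 7 physicochemical
      classes (Shen's grouping).
    * ``quasi_seq`` — quasi-sequence-order: composition plus ``maxlag``
      lag-coupling numbers from a packaged amino-acid distance matrix,
      jointly normalized to sum 1.

Sequence encodings
    * ``cnn_protein`` / ``cnn_rnn_protein`` — character-level label encoding
      over a 25-symbol alphabet (20 canonical residues, X/U/O, PAD, UNK).
    * ``espf_transformer_protein`` — substructure tokens from a byte-pair
      encoded vocabulary (see :mod:`dtikit.bpe`).

Non-canonical letters (X and anything outside the 20-letter alphabet) are
excluded from composition counts — the effective length shrinks — and map
to UNK in token encodings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .bpe import SubstructureVocab, espf_encode
from .tokenize import PROTEIN_CHARSET, PROTEIN_VOCAB_SIZE, TokenSequence, label_encode

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Shen's 7-class grouping for the conjoint-triad descriptor
CONJOINT_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")
_CLASS_OF = {aa: ci for ci, group in enumerate(CONJOINT_CLASSES) for aa in group}

__all__ = [
    "CompositionVector",
    "aac",
    "pseudo_aac",
    "conjoint_triad",
    "quasi_seq_order",
    "seq_label_encode",
    "espf_protein_encode",
    "load_property_table",
    "load_distance_matrix",
]


@dataclass(frozen=True)
class CompositionVector:
    """A real-valued protein descriptor vector with its scheme tag."""

    values: np.ndarray
    scheme: str  # aac | paac | ct | qso

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError(f"{self.scheme} descriptor must be finite and >= 0")

    @property
    def dim(self) -> int:
        return len(self.values)


def _canonical_counts(sequence: str):
    """Counts over the 20 canonical letters; non-canonical letters are dropped."""
    counts = np.zeros(20)
    dropped = 0
    for ch in sequence:
        i = _AA_INDEX.get(ch)
        if i is None:
            dropped += 1
        else:
            counts[i] += 1
    if dropped:
        logger.info("dropped %d non-canonical residues from composition", dropped)
    return counts, dropped


def aac(sequence: str) -> CompositionVector:
    """Amino-acid composition: 20 frequencies summing to 1."""
    counts, _ = _canonical_counts(sequence)
    total = counts.sum()
    if total == 0:
        raise ValueError("effective sequence length is 0 (no canonical residues)")
    return CompositionVector(values=counts / total, scheme="aac")


# ---------------------------------------------------------------------------
# packaged constant tables
# ---------------------------------------------------------------------------

def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("dtikit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


_PROPERTY_CACHE = {}


def load_property_table() -> np.ndarray:
    """Z-normalized (20, 3) property matrix: hydrophobicity, hydrophilicity, mass.

    Normalization uses the population standard deviation over the 20 amino
    acids, the convention of pseudo amino-acid composition.
    """
    if "props" not in _PROPERTY_CACHE:
        df = _read_packaged("aa_properties.tsv").set_index("aa").loc[list(AMINO_ACIDS)]
        raw = df[["hydrophobicity", "hydrophilicity", "side_chain_mass"]].to_numpy(float)
        _PROPERTY_CACHE["props"] = (raw - raw.mean(0)) / raw.std(0)
    return _PROPERTY_CACHE["props"]


def load_distance_matrix() -> np.ndarray:
    """Packaged (20, 20) physicochemical amino-acid distance matrix."""
    if "dist" not in _PROPERTY_CACHE:
        df = _read_packaged("aa_distance_matrix.tsv").set_index("aa")
        _PROPERTY_CACHE["dist"] = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)].to_numpy(float)
    return _PROPERTY_CACHE["dist"]


# ---------------------------------------------------------------------------
# order-aware descriptors
# ---------------------------------------------------------------------------

def pseudo_aac(sequence: str, lam: int = 30, weight: float = 0.05) -> CompositionVector:
    """Chou's pseudo amino-acid composition, dimension ``20 + lam``.

    The correlation factor at lag ``k`` averages, over all residue pairs
    ``(i, i+k)``, the mean squared difference of the three z-scored
    physicochemical properties.  Components are jointly normalized:
    the first 20 are ``f_u / (1 + w * sum(theta))`` with ``f`` the
    composition frequencies, the last ``lam`` are
    ``w * theta_k / (1 + w * sum(theta))``, so the whole vector sums to 1.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    seq = [ch for ch in sequence if ch in _AA_INDEX]
    n = len(seq)
    if n == 0:
        raise ValueError("effective sequence length is 0 (no canonical residues)")
    if n <= lam:
        raise ValueError(
            f"sequence has {n} canonical residues but lam={lam}; lower lam below "
            "the sequence length"
        )
    props = load_property_table()
    pvec = props[[_AA_INDEX[ch] for ch in seq]]  # (n, 3)
    theta = np.empty(lam)
    for k in range(1, lam + 1):
        diff = pvec[: n - k] - pvec[k:]
        theta[k - 1] = np.mean(diff**2)  # mean over pairs AND the 3 properties
    freqs = aac("".join(seq)).values
    denom = 1.0 + weight * theta.sum()
    values = np.concatenate([freqs / denom, weight * theta / denom])
    return CompositionVector(values=values, scheme="paac")


def conjoint_triad(sequence: str) -> CompositionVector:
    """Conjoint-triad descriptor: 7^3 = 343 counts of overlapping class triplets.

    The vector sums to (effective length - 2).  Cell index of classes
    (a, b, c) is ``a*49 + b*7 + c``.
    """
    seq = [_CLASS_OF[ch] for ch in sequence if ch in _CLASS_OF]
    if len(seq) < 3:
        raise ValueError("conjoint triad needs at least 3 canonical residues")
    counts = np.zeros(343)
    for i in range(len(seq) - 2):
        counts[seq[i] * 49 + seq[i + 1] * 7 + seq[i + 2]] += 1
    return CompositionVector(values=counts, scheme="ct")


def quasi_seq_order(sequence: str, maxlag: int = 30, weight: float = 0.1) -> CompositionVector:
    """Quasi-sequence-order descriptor, dimension ``20 + maxlag``.

    The coupling number at lag ``d`` is the sum over positions of the
    squared packaged distance between residues ``d`` apart.  Joint
    normalization as in :func:`pseudo_aac` makes the vector sum to 1.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    seq = [ch for ch in sequence if ch in _AA_INDEX]
    n = len(seq)
    if n == 0:
        raise ValueError("effective sequence length is 0 (no canonical residues)")
    if n <= maxlag:
        raise ValueError(
            f"sequence has {n} canonical residues but maxlag={maxlag}; lower maxlag"
        )
    dist = load_distance_matrix()
    idx = np.array([_AA_INDEX[ch] for ch in seq])
    tau = np.empty(maxlag)
    for d in range(1, maxlag + 1):
        tau[d - 1] = np.sum(dist[idx[: n - d], idx[d:]] ** 2)
    freqs = aac("".join(seq)).values
    denom = 1.0 + weight * tau.sum()
    values = np.concatenate([freqs / denom, weight * tau / denom])
    return CompositionVector(values=values, scheme="qso")


# ---------------------------------------------------------------------------
# token encodings
# ---------------------------------------------------------------------------

def seq_label_encode(sequence: str, max_len: int = 1000) -> TokenSequence:
    """Character-level index encoding over the protein alphabet, padded/truncated."""
    return label_encode(sequence, PROTEIN_CHARSET, max_len, PROTEIN_VOCAB_SIZE)


def espf_protein_encode(sequence: str, vocab: SubstructureVocab, max_len: int = 545) -> TokenSequence:
    """Substructure-token encoding of a protein sequence via a BPE vocabulary."""
    return espf_encode(sequence, vocab, max_len)
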