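"""Character-level token encoding shared by the sequence encoders.

Both the SMILES CNN/CNN+RNN encoders and the protein-sequence encoders
consume fixed-length integer index sequences with an accompanying binary
mask.  PAD is index 0 (so masks and zero padding coincide) and UNK is
index 1; content symbols start at index 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

PAD_INDEX = 0
UNK_INDEX = 1

# fixed 64-symbol SMILES charset: organic + common bracket atoms, aromatic
# lowercase, ring digits, bond/branch/stereo punctuation
SMILES_SYMBOLS = (
    "#", "%", "(", ")", "+", "-", ".", "/",
    "0", "1", "2", "3", "4", "5", "6", "7", "8", "9",
    "=", "@",
    "A", "B", "C", "D", "E", "F", "G", "H", "I", "K", "L", "M",
    "N", "O", "P", "R", "S", "T", "U", "V", "W", "X", "Y", "Z",
    "[", "\\", "]",
    "a", "b", "c", "d", "e", "g", "i", "l", "n", "o", "r", "s", "t", "u",
    ":", "~", "*",
)
assert len(SMILES_SYMBOLS) == 64

# 23 content symbols: 20 canonical amino acids, X (unknown), U, O (rare
# translated residues) -> 25 including PAD and UNK
PROTEIN_SYMBOLS = tuple("ACDEFGHIKLMNPQRSTVWYXUO")

SMILES_CHARSET = {s: i + 2 for i, s in enumerate(SMILES_SYMBOLS)}
PROTEIN_CHARSET = {s: i + 2 for i, s in enumerate(PROTEIN_SYMBOLS)}

SMILES_VOCAB_SIZE = len(SMILES_CHARSET) + 2
PROTEIN_VOCAB_SIZE = len(PROTEIN_CHARSET) + 2


@dataclass(frozen=True)
class TokenSequence:
    """Fixed-length integer encoding of a string.

    ``indices`` and ``mask`` both have length ``max_len``; the mask is 1 on
    real tokens and 0 on padding.  ``vocab_size`` bounds every index.
    """

    indices: np.ndarray
    mask: np.ndarray
    max_len: int
    vocab_size: int

    def __post_init__(self):
        if len(self.indices) != self.max_len or len(self.mask) != self.max_len:
            raise ValueError("indices and mask must both have length max_len")
        if self.indices.max(initial=0) >= self.vocab_size:
            raise ValueError("token index exceeds vocabulary size")

    @property
    def content_length(self) -> int:
        return int(self.mask.sum())


def label_encode(text, charset: dict, max_len: int, vocab_size: int) -> TokenSequence:
    """Left-aligned, zero-padded character encoding; truncates beyond max_len.

    Characters outside ``charset`` map to the UNK index.
    """
    symbols = list(text)[:max_len]
    if len(text) > max_len:
        logger.info("truncating input of length %d to max_len %d", len(text), max_len)
    idx = np.zeros(max_len, dtype=np.int64)
    mask = np.zeros(max_len, dtype=np.int64)
    for i, ch in enumerate(symbols):
        idx[i] = charset.get(ch, UNK_INDEX)
        mask[i] = 1
    return TokenSequence(indices=idx, mask=mask, max_len=max_len, vocab_size=vocab_size)
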