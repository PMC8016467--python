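"""Substructure vocabulary mining by byte-pair encoding (BPE).

Frequent sub-tokens (explicit substructure "words") are mined from a corpus
of SMILES strings or protein sequences: starting from single characters, the
most frequent adjacent token pair is merged repeatedly until the vocabulary
reaches a target size or no pair reaches the minimum frequency.  Strings are
then tokenized by replaying the merges in training order and the resulting
substructure tokens feed the transformer encoders.

Ties between equally frequent pairs break lexicographically on the token
pair, so vocabulary training is fully deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .tokenize import PAD_INDEX, UNK_INDEX, TokenSequence

__all__ = [
    "SubstructureVocab",
    "train_substructure_vocab",
    "espf_encode",
    "tokenize_with_vocab",
    "write_vocab",
    "read_vocab",
]


@dataclass
class SubstructureVocab:
    """Ordered substructure tokens with frequencies and merge rules.

    ``tokens`` starts with the sorted base alphabet (single characters),
    followed by merged substructures in creation order.  ``merges`` lists the
    (left, right) token pairs in the order they were learned.  Token indices
    for encoding are offset by 2: PAD is 0 and UNK is 1.
    """

    tokens: list
    frequencies: list
    merges: list = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        if len(self.tokens) != len(self.frequencies):
            raise ValueError("tokens and frequencies must align")
        self._index = {t: i + 2 for i, t in enumerate(self.tokens)}

    @property
    def size(self) -> int:
        """Total index space including PAD and UNK."""
        return len(self.tokens) + 2

    def index_of(self, token: str) -> int:
        return self._index.get(token, UNK_INDEX)


def _pair_counts(corpus_tokens, weights):
    counts = Counter()
    for toks, w in zip(corpus_tokens, weights):
        for a, b in zip(toks, toks[1:]):
            counts[(a, b)] += w
    return counts


def train_substructure_vocab(corpus, target_size: int, min_freq: int = 2) -> SubstructureVocab:
    """Mine a substructure vocabulary from a corpus of strings.

    Standard BPE: iteratively merge the most frequent adjacent token pair
    (ties broken lexicographically) until the vocabulary holds
    ``target_size`` tokens or no pair occurs at least ``min_freq`` times.
    Duplicate corpus strings count with their multiplicity.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus must be nonempty")
    string_counts = Counter(corpus)
    corpus_tokens = [list(s) for s in string_counts]
    weights = list(string_counts.values())

    alphabet = sorted({ch for s in corpus for ch in s})
    if target_size < len(alphabet):
        raise ValueError(
            f"target_size {target_size} below base alphabet size {len(alphabet)}"
        )
    tokens = list(alphabet)
    merges = []
    while len(tokens) < target_size:
        counts = _pair_counts(corpus_tokens, weights)
        if not counts:
            break
        best_count = max(counts.values())
        if best_count < min_freq:
            break
        best = min(p for p, c in counts.items() if c == best_count)
        merged = best[0] + best[1]
        merges.append(best)
        tokens.append(merged)
        for toks in corpus_tokens:
            i = 0
            while i < len(toks) - 1:
                if toks[i] == best[0] and toks[i + 1] == best[1]:
                    toks[i : i + 2] = [merged]
                else:
                    i += 1

    # frequencies: occurrences of each token in the fully merged corpus
    # (alphabet characters absorbed into merges may end at 0)
    tok_counts = Counter()
    for toks, w in zip(corpus_tokens, weights):
        for t in toks:
            tok_counts[t] += w
    freqs = [int(tok_counts.get(t, 0)) for t in tokens]
    return SubstructureVocab(tokens=tokens, frequencies=freqs, merges=merges)


def tokenize_with_vocab(s: str, vocab: SubstructureVocab) -> list:
    """Split a string into substructure tokens by replaying the merge rules."""
    toks = list(s)
    for left, right in vocab.merges:
        merged = left + right
        i = 0
        while i < len(toks) - 1:
            if toks[i] == left and toks[i + 1] == right:
                toks[i : i + 2] = [merged]
            else:
                i += 1
    return toks


def espf_encode(s: str, vocab: SubstructureVocab, max_len: int) -> TokenSequence:
    """Substructure-token index encoding, padded/truncated to ``max_len``."""
    toks = tokenize_with_vocab(s, vocab)[:max_len]
    idx = np.full(max_len, PAD_INDEX, dtype=np.int64)
    mask = np.zeros(max_len, dtype=np.int64)
    for i, t in enumerate(toks):
        idx[i] = vocab.index_of(t)
        mask[i] = 1
    return TokenSequence(indices=idx, mask=mask, max_len=max_len, vocab_size=vocab.size)


def write_vocab(vocab: SubstructureVocab, path) -> None:
    """Write ``token<TAB>frequency`` lines, base alphabet first, merge order after.

    The merge rules are recorded in a comment header so the exact
    tokenization (not just the token list) survives a round-trip.
    """
    with open(path, "w") as fh:
        for left, right in vocab.merges:
            fh.write(f"#merge\t{left}\t{right}\n")
        for tok, freq in zip(vocab.tokens, vocab.frequencies):
            fh.write(f"{tok}\t{freq}\n")


def read_vocab(path) -> SubstructureVocab:
    """Read a vocabulary file written by :func:`write_vocab`.

    Files without the ``#merge`` header (e.g. hand-written vocabularies) fall
    back to reconstructing each multi-character token, in creation order,
    from the first split into two earlier tokens.
    """
    tokens, freqs, merges = [], [], []
    with open(path) as fh:
        for ln in fh:
            if not ln.rstrip("\n"):
                continue
            if ln.startswith("#"):
                parts = ln.rstrip("\n").split("\t")
                if parts[0] == "#merge" and len(parts) == 3:
                    merges.append((parts[1], parts[2]))
                continue
            tok, freq = ln.rstrip("\n").split("\t")
            tokens.append(tok)
            freqs.append(int(freq))
    if not merges:
        known = set()
        for tok in tokens:
            if len(tok) > 1:
                for cut in range(1, len(tok)):
                    if tok[:cut] in known and tok[cut:] in known:
                        merges.append((tok[:cut], tok[cut:]))
                        break
                else:
                    raise ValueError(
                        f"token {tok!r} cannot be decomposed into earlier tokens")
            known.add(tok)
    return SubstructureVocab(tokens=tokens, frequencies=freqs, merges=merges)
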