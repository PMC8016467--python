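"""Protein descriptor correctness against hand-coded references."""

import numpy as np
import pytest

from dtikit import protein
from dtikit.protein import AMINO_ACIDS, CONJOINT_CLASSES
from dtikit.tokenize import PROTEIN_CHARSET, UNK_INDEX


def paac_reference(seq, lam, w):
    """Chou's pseudo amino-acid composition, written directly from the equations."""
    props = protein.load_property_table()
    idx = [AMINO_ACIDS.index(ch) for ch in seq]
    n = len(idx)
    theta = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(n - k):
            a, b = props[idx[i]], props[idx[i + k]]
            total += np.mean((a - b) ** 2)
        theta.append(total / (n - k))
    freqs = np.zeros(20)
    for i in idx:
        freqs[i] += 1
    freqs /= n
    denom = 1.0 + w * sum(theta)
    return np.concatenate([freqs / denom, w * np.array(theta) / denom])


def qso_reference(seq, maxlag, w):
    """Quasi-sequence-order, written directly from the published equations."""
    dist = protein.load_distance_matrix()
    idx = [AMINO_ACIDS.index(ch) for ch in seq]
    n = len(idx)
    tau = []
    for d in range(1, maxlag + 1):
        tau.append(sum(dist[idx[i], idx[i + d]] ** 2 for i in range(n - d)))
    freqs = np.zeros(20)
    for i in idx:
        freqs[i] += 1
    freqs /= n
    denom = 1.0 + w * sum(tau)
    return np.concatenate([freqs / denom, w * np.array(tau) / denom])


def triad_reference(seq):
    """Exhaustive triad enumerator over the 7-class mapping."""
    cls = {aa: c for c, grp in enumerate(CONJOINT_CLASSES) for aa in grp}
    v = np.zeros(343)
    for i in range(len(seq) - 2):
        a, b, c = cls[seq[i]], cls[seq[i + 1]], cls[seq[i + 2]]
        v[a * 49 + b * 7 + c] += 1
    return v


def random_sequences(rng, n, lo=10, hi=60):
    return ["".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, size=rng.integers(lo, hi)))
            for _ in range(n)]


class TestAAC:
    def test_homopolymer(self):
        v = protein.aac("AAAA").values
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_uniform_sequence(self):
        v = protein.aac(AMINO_ACIDS).values
        assert np.allclose(v, 0.05)

    def test_two_thirds_one_third(self):
        v = protein.aac("AAC").values
        assert v[AMINO_ACIDS.index("A")] == pytest.approx(2 / 3)
        assert v[AMINO_ACIDS.index("C")] == pytest.approx(1 / 3)

    def test_x_excluded_from_counts(self):
        assert np.allclose(protein.aac("AXXA").values, protein.aac("AA").values)

    def test_all_noncanonical_rejected(self):
        with pytest.raises(ValueError):
            protein.aac("XXX")


class TestPAAC:
    def test_weight_zero_reduces_to_composition(self):
        seq = "ACDEFGHIKLMNP"
        v = protein.pseudo_aac(seq, lam=3, weight=0.0).values
        assert np.allclose(v[:20], protein.aac(seq).values)
        assert np.allclose(v[20:], 0.0)

    def test_dimension(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        assert protein.pseudo_aac(seq, lam=30).dim == 50

    def test_matches_handcoded_reference(self):
        seq = "ACDKWEGHMILP"  # a 12-mer
        v = protein.pseudo_aac(seq, lam=2, weight=0.05).values
        assert np.allclose(v, paac_reference(seq, 2, 0.05), atol=1e-10)

    def test_too_short_sequence_names_lambda(self):
        with pytest.raises(ValueError, match="lam"):
            protein.pseudo_aac("ACD", lam=5)


class TestConjointTriad:
    def test_homotriad(self):
        v = protein.conjoint_triad("AAA").values
        assert v.sum() == 1 and v[0] == 1

    def test_overlapping_triads(self):
        v = protein.conjoint_triad("AAAA").values
        assert v[0] == 2 and v.sum() == 2

    def test_sum_is_length_minus_two(self, rng):
        for seq in random_sequences(rng, 10):
            assert protein.conjoint_triad(seq).values.sum() == len(seq) - 2

    def test_matches_exhaustive_enumerator(self, rng):
        assert np.array_equal(protein.conjoint_triad("ARNDC").values,
                              triad_reference("ARNDC"))
        for seq in random_sequences(rng, 5):
            assert np.array_equal(protein.conjoint_triad(seq).values,
                                  triad_reference(seq))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            protein.conjoint_triad("AC")


class TestQSO:
    def test_weight_zero_reduces_to_composition(self):
        seq = "ACDEFGHIKLMNP"
        v = protein.quasi_seq_order(seq, maxlag=3, weight=0.0).values
        assert np.allclose(v[:20], protein.aac(seq).values)
        assert np.allclose(v[20:], 0.0)

    def test_dimension(self):
        seq = AMINO_ACIDS * 2
        assert protein.quasi_seq_order(seq, maxlag=30).dim == 50

    def test_matches_handcoded_reference(self):
        seq = "ACDKWEGHMILPQRS"  # a 15-mer
        v = protein.quasi_seq_order(seq, maxlag=3, weight=0.1).values
        assert np.allclose(v, qso_reference(seq, 3, 0.1), atol=1e-10)

    def test_too_long_lag_rejected(self):
        with pytest.raises(ValueError, match="maxlag"):
            protein.quasi_seq_order("ACDEF", maxlag=10)


class TestNormalization:
    """aac/paac/qso each sum to 1 over random sequences."""

    def test_sums_to_one(self, rng):
        for seq in random_sequences(rng, 100, lo=12, hi=80):
            assert protein.aac(seq).values.sum() == pytest.approx(1.0, abs=1e-9)
            assert protein.pseudo_aac(seq, lam=5).values.sum() == pytest.approx(1.0, abs=1e-9)
            assert protein.quasi_seq_order(seq, maxlag=5).values.sum() == pytest.approx(1.0, abs=1e-9)


class TestPermutationSensitivity:
    def test_shuffling_changes_order_descriptors_but_never_aac(self, rng):
        changed = {"ct": 0, "paac": 0, "qso": 0}
        n_trials = 20
        for seq in random_sequences(rng, n_trials, lo=25, hi=60):
            perm = "".join(rng.permutation(list(seq)))
            if perm == seq:
                continue
            assert np.allclose(protein.aac(seq).values, protein.aac(perm).values)
            if not np.array_equal(protein.conjoint_triad(seq).values,
                                  protein.conjoint_triad(perm).values):
                changed["ct"] += 1
            if not np.allclose(protein.pseudo_aac(seq, 5).values,
                               protein.pseudo_aac(perm, 5).values):
                changed["paac"] += 1
            if not np.allclose(protein.quasi_seq_order(seq, 5).values,
                               protein.quasi_seq_order(perm, 5).values):
                changed["qso"] += 1
        # order-aware descriptors change with probability ~1
        assert all(v >= n_trials - 1 for v in changed.values()), changed


class TestTokenEncodings:
    def test_pad_and_content(self):
        ts = protein.seq_label_encode("ACD", max_len=5)
        assert ts.mask.tolist() == [1, 1, 1, 0, 0]
        assert ts.indices[0] == PROTEIN_CHARSET["A"]

    def test_truncation_of_long_sequence(self):
        ts = protein.seq_label_encode("A" * 1200, max_len=1000)
        assert ts.mask.sum() == 1000

    def test_ambiguity_code_maps_to_unk(self):
        ts = protein.seq_label_encode("B", max_len=3)
        assert ts.indices[0] == UNK_INDEX
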