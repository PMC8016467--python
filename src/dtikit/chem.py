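"""Compound featurizers: the eight drug-side input representations.

Bit-vector fingerprints
    * ``morgan`` — hashed circular (ECFP-style) fingerprint of atom
      environments up to a radius; default radius 2, 1024 bits.
    * ``pubchem`` — 881 substructure presence keys evaluated against the
      packaged key-definition table (element counts, ring features, bonded
      element pairs, atom environments, SMARTS patterns).  Keys whose
      definition would need 3D information are fixed at 0; the table is
      2D-only and documents each key.
    * ``daylight`` — hashed linear-path (topological) fingerprint; default
      2048 bits.

Real-valued descriptors
    * ``desc2d`` — a fixed panel of 2D physicochemical descriptors, each
      mapped through an empirical-CDF normalizer fitted on a packaged
      reference molecule set, so outputs lie in [0, 1].

Sequence / graph encodings
    * ``cnn_smiles`` / ``cnn_rnn_smiles`` — character-level label encoding
      of the SMILES string over a fixed 64-symbol charset.
    * ``espf_transformer`` — substructure tokens from a byte-pair encoded
      vocabulary (:mod:`dtikit.bpe`).
    * ``mpnn`` — molecular graph with per-atom and per-bond feature rows.

All featurizers are deterministic and canonical-invariant: two SMILES of
the same molecule produce identical output.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator

from .bpe import SubstructureVocab, espf_encode
from .iodata import parse_smiles
from .tokenize import SMILES_CHARSET, SMILES_VOCAB_SIZE, TokenSequence, label_encode

logger = logging.getLogger(__name__)

__all__ = [
    "BitVector",
    "DescriptorVector",
    "MolGraph",
    "morgan_fingerprint",
    "pubchem_fingerprint",
    "daylight_fingerprint",
    "descriptors_2d",
    "smiles_label_encode",
    "smiles_to_graph",
    "DESCRIPTOR_NAMES",
]


@dataclass(frozen=True)
class BitVector:
    """Fixed-length binary fingerprint."""

    bits: np.ndarray
    length: int

    def __post_init__(self):
        if len(self.bits) != self.length:
            raise ValueError("bit array length disagrees with declared length")
        if not set(np.unique(self.bits)) <= {0, 1}:
            raise ValueError("fingerprint entries must be 0/1")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class DescriptorVector:
    """Real-valued descriptor vector with aligned names."""

    values: np.ndarray
    names: tuple

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise ValueError("values and names must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor values must be finite")


@dataclass(frozen=True)
class MolGraph:
    """Molecular graph: atom feature rows, undirected bond list, bond features."""

    atom_features: np.ndarray  # (n_atoms, atom_dim)
    bond_list: np.ndarray  # (n_bonds, 2) each bond stored once
    bond_features: np.ndarray  # (n_bonds, bond_dim)

    def __post_init__(self):
        if self.bond_list.size and self.bond_list.max() >= len(self.atom_features):
            raise ValueError("bond index out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_features)


def _mol(smiles: str):
    mol = parse_smiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    return mol


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 1024) -> BitVector:
    """Hashed circular fingerprint of atom environments up to ``radius``."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 64:
        raise ValueError("n_bits must be >= 64")
    mol = _mol(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.int8)
    bits[list(fp.GetOnBits())] = 1
    return BitVector(bits=bits, length=n_bits)


def daylight_fingerprint(smiles: str, n_bits: int = 2048, max_path: int = 7) -> BitVector:
    """Hashed linear-path fingerprint over bond paths up to ``max_path``.

    Paths of length 0 (typed atoms) are hashed in as well, so a single-atom
    molecule still gets a nonzero fingerprint; longer paths come from the
    standard topological path enumeration.
    """
    if n_bits < 64:
        raise ValueError("n_bits must be >= 64")
    mol = _mol(smiles)
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=max_path, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.int8)
    bits[list(fp.GetOnBits())] = 1
    for atom in mol.GetAtoms():  # length-0 paths
        key = f"atom:{atom.GetAtomicNum()}:{int(atom.GetIsAromatic())}:{atom.GetFormalCharge()}"
        bits[zlib.crc32(key.encode()) % n_bits] = 1
    return BitVector(bits=bits, length=n_bits)


# --- PubChem-style 881 substructure keys -----------------------------------

_PUBCHEM_CACHE = {}


def load_pubchem_keys():
    """Parse the packaged 881-entry key-definition table.

    Each row: ``index<TAB>kind<TAB>params<TAB>description``.  Kinds:
    ``element`` (symbol, min count), ``ring`` (size, variant, min count),
    ``ring_arom`` (variant, min count), ``pair`` (two atomic symbols bonded),
    ``smarts`` (pattern, min match count) and ``zero`` (always 0; definition
    needs information outside 2D scope).
    """
    if "keys" not in _PUBCHEM_CACHE:
        rows = []
        with resources.files("dtikit.data").joinpath("pubchem_keys.tsv").open() as fh:
            for ln in fh:
                if ln.startswith("#") or not ln.strip():
                    continue
                idx, kind, params, _desc = ln.rstrip("\n").split("\t")
                rows.append((int(idx), kind, params))
        if len(rows) != 881:
            raise RuntimeError(f"pubchem key table has {len(rows)} entries, expected 881")
        _PUBCHEM_CACHE["keys"] = rows
        _PUBCHEM_CACHE["smarts"] = {}
    return _PUBCHEM_CACHE["keys"]


def _compiled_smarts(pattern: str):
    cache = _PUBCHEM_CACHE.setdefault("smarts", {})
    if pattern not in cache:
        q = Chem.MolFromSmarts(pattern)
        if q is None:
            raise RuntimeError(f"packaged SMARTS {pattern!r} failed to compile")
        cache[pattern] = q
    return cache[pattern]


def _ring_profile(mol):
    """Per-SSSR-ring (size, variant-flags) profile used by the ring keys."""
    out = []
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        size = len(ring)
        aromatic = all(a.GetIsAromatic() for a in atoms)
        carbon_only = all(a.GetSymbol() == "C" for a in atoms)
        has_n = any(a.GetSymbol() == "N" for a in atoms)
        hetero = any(a.GetSymbol() != "C" for a in atoms)
        bonds = []
        n = len(ring)
        for k in range(n):
            bonds.append(mol.GetBondBetweenAtoms(ring[k], ring[(k + 1) % n]))
        saturated = all(b.GetBondType() == Chem.BondType.SINGLE for b in bonds)
        unsat_nonarom = (not aromatic) and (not saturated)
        out.append(
            dict(
                size=size,
                aromatic=aromatic,
                carbon_only=carbon_only,
                has_n=has_n,
                hetero=hetero,
                saturated=saturated,
                unsat_nonarom=unsat_nonarom,
            )
        )
    return out


def _ring_variant_count(profile, size: int, variant: str) -> int:
    def match(r):
        if r["size"] != size:
            return False
        if variant == "any":
            return True
        if variant == "carbon_sat_arom":
            return r["carbon_only"] and (r["saturated"] or r["aromatic"])
        if variant == "nitrogen_sat_arom":
            return r["has_n"] and (r["saturated"] or r["aromatic"])
        if variant == "hetero_sat_arom":
            return r["hetero"] and (r["saturated"] or r["aromatic"])
        if variant == "carbon_unsat":
            return r["carbon_only"] and r["unsat_nonarom"]
        if variant == "nitrogen_unsat":
            return r["has_n"] and r["unsat_nonarom"]
        if variant == "hetero_unsat":
            return r["hetero"] and r["unsat_nonarom"]
        raise ValueError(f"unknown ring variant {variant!r}")

    return sum(1 for r in profile if match(r))


def pubchem_fingerprint(smiles: str) -> BitVector:
    """881-bit substructure-key vector per the packaged key-definition table."""
    mol = _mol(smiles)
    keys = load_pubchem_keys()
    bits = np.zeros(881, dtype=np.int8)
    element_counts = {}
    for atom in mol.GetAtoms():
        element_counts[atom.GetSymbol()] = element_counts.get(atom.GetSymbol(), 0) + 1
    n_h = sum(a.GetTotalNumHs() for a in mol.GetAtoms())
    element_counts["H"] = element_counts.get("H", 0) + n_h
    profile = _ring_profile(mol)
    arom_rings = sum(1 for r in profile if r["aromatic"])
    hetero_arom = sum(1 for r in profile if r["aromatic"] and r["hetero"])

    for idx, kind, params in keys:
        if kind == "zero":
            continue
        if kind == "element":
            sym, mn = params.split(",")
            on = element_counts.get(sym, 0) >= int(mn)
        elif kind == "ring":
            size, variant, mn = params.split(",")
            on = _ring_variant_count(profile, int(size), variant) >= int(mn)
        elif kind == "ring_arom":
            variant, mn = params.split(",")
            count = hetero_arom if variant == "hetero" else arom_rings
            on = count >= int(mn)
        elif kind == "pair":
            a, b = params.split(",")
            q = _compiled_smarts(f"[#{a}]~[#{b}]")
            on = mol.HasSubstructMatch(q)
        elif kind == "smarts":
            pattern, mn = params.rsplit(",", 1)
            matches = mol.GetSubstructMatches(_compiled_smarts(pattern), uniquify=True)
            on = len(matches) >= int(mn)
        else:
            raise RuntimeError(f"unknown key kind {kind!r} at index {idx}")
        if on:
            bits[idx] = 1
    return BitVector(bits=bits, length=881)


# ---------------------------------------------------------------------------
# 2D descriptors
# ---------------------------------------------------------------------------

# fixed descriptor panel; order matters and matches the packaged quantile table
DESCRIPTOR_NAMES = (
    "MolWt", "HeavyAtomMolWt", "ExactMolWt", "MolLogP", "MolMR", "TPSA",
    "LabuteASA", "NumHDonors", "NumHAcceptors", "NumRotatableBonds",
    "NumAromaticRings", "NumAliphaticRings", "NumSaturatedRings", "RingCount",
    "FractionCSP3", "HeavyAtomCount", "NHOHCount", "NOCount",
    "NumHeteroatoms", "NumValenceElectrons", "qed", "BertzCT", "BalabanJ",
    "Chi0", "Chi1", "Chi0n", "Chi1n", "Chi2n", "Chi0v", "Chi1v",
    "Kappa1", "Kappa2", "Kappa3", "HallKierAlpha",
    "MaxPartialCharge", "MinPartialCharge",
    "NumRadicalElectrons", "FpDensityMorgan1", "FpDensityMorgan2",
    "FpDensityMorgan3",
)

_DESC_FUNCS = {name: fn for name, fn in Descriptors.descList}
_QUANTILE_CACHE = {}


def raw_descriptors(smiles: str) -> DescriptorVector:
    """Un-normalized descriptor panel; failures become NaN (normalized later)."""
    mol = _mol(smiles)
    values = np.empty(len(DESCRIPTOR_NAMES))
    for i, name in enumerate(DESCRIPTOR_NAMES):
        try:
            values[i] = float(_DESC_FUNCS[name](mol))
        except Exception:  # descriptor failure for this molecule
            values[i] = np.nan
    # NaN allowed here; DescriptorVector built only after normalization
    dv = object.__new__(DescriptorVector)
    object.__setattr__(dv, "values", values)
    object.__setattr__(dv, "names", DESCRIPTOR_NAMES)
    return dv


def _load_quantiles() -> np.ndarray:
    """(n_descriptors, n_quantiles) reference quantiles for CDF normalization."""
    if "q" not in _QUANTILE_CACHE:
        rows = {}
        with resources.files("dtikit.data").joinpath("descriptor_quantiles.tsv").open() as fh:
            header = None
            for ln in fh:
                if ln.startswith("#") or not ln.strip():
                    continue
                if header is None:
                    header = ln.rstrip("\n").split("\t")
                    continue
                parts = ln.rstrip("\n").split("\t")
                rows[parts[0]] = np.array([float(x) for x in parts[1:]])
        _QUANTILE_CACHE["q"] = np.stack([rows[n] for n in DESCRIPTOR_NAMES])
    return _QUANTILE_CACHE["q"]


def descriptors_2d(smiles: str) -> DescriptorVector:
    """Descriptor panel mapped through the empirical-CDF normalizer to [0, 1].

    A descriptor that fails for a molecule is imputed at the normalization
    midpoint (0.5) and logged.
    """
    raw = raw_descriptors(smiles).values
    quantiles = _load_quantiles()
    n_q = quantiles.shape[1]
    cdf_levels = (np.arange(n_q) + 0.5) / n_q
    out = np.empty(len(raw))
    for i, v in enumerate(raw):
        if not np.isfinite(v):
            logger.warning("descriptor %s failed for %r; imputing midpoint",
                           DESCRIPTOR_NAMES[i], smiles)
            out[i] = 0.5
            continue
        q = quantiles[i]
        if q[-1] == q[0]:  # constant descriptor on the reference set
            out[i] = 0.5
        else:
            out[i] = float(np.interp(v, q, cdf_levels, left=0.0, right=1.0))
    return DescriptorVector(values=out, names=DESCRIPTOR_NAMES)


# ---------------------------------------------------------------------------
# token and graph encodings
# ---------------------------------------------------------------------------

def smiles_label_encode(smiles: str, max_len: int = 100) -> TokenSequence:
    """Character-level index encoding over the fixed SMILES charset."""
    return label_encode(smiles, SMILES_CHARSET, max_len, SMILES_VOCAB_SIZE)


def espf_smiles_encode(smiles: str, vocab: SubstructureVocab, max_len: int = 50) -> TokenSequence:
    """Substructure-token encoding of a SMILES string via a BPE vocabulary."""
    return espf_encode(smiles, vocab, max_len)


_GRAPH_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se", "Na", "K")
_BOND_ORDERS = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)

ATOM_FEATURE_DIM = len(_GRAPH_ELEMENTS) + 1 + 6 + 1 + 1 + 5  # 28
BOND_FEATURE_DIM = len(_BOND_ORDERS) + 2  # 6


def _atom_row(atom) -> np.ndarray:
    row = np.zeros(ATOM_FEATURE_DIM)
    sym = atom.GetSymbol()
    pos = _GRAPH_ELEMENTS.index(sym) if sym in _GRAPH_ELEMENTS else len(_GRAPH_ELEMENTS)
    row[pos] = 1.0
    deg = min(atom.GetDegree(), 5)
    row[len(_GRAPH_ELEMENTS) + 1 + deg] = 1.0
    base = len(_GRAPH_ELEMENTS) + 1 + 6
    row[base] = float(atom.GetFormalCharge())
    row[base + 1] = 1.0 if atom.GetIsAromatic() else 0.0
    nh = min(atom.GetTotalNumHs(), 4)
    row[base + 2 + nh] = 1.0
    return row


def smiles_to_graph(smiles: str) -> MolGraph:
    """Molecular graph with one-hot atom/bond features for the MPNN encoder.

    Atom rows: element one-hot (fixed list + other), degree one-hot (0-5),
    formal charge, aromaticity flag, total-H one-hot (0-4).  Bond rows: bond
    order one-hot (single/double/triple/aromatic), in-ring flag, conjugation
    flag.  Multi-fragment (dot-separated) SMILES stay a disconnected graph.
    """
    mol = _mol(smiles)
    atoms = np.stack([_atom_row(a) for a in mol.GetAtoms()]) if mol.GetNumAtoms() else np.zeros((0, ATOM_FEATURE_DIM))
    bonds, feats = [], []
    for b in mol.GetBonds():
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        row = np.zeros(BOND_FEATURE_DIM)
        if b.GetBondType() in _BOND_ORDERS:
            row[_BOND_ORDERS.index(b.GetBondType())] = 1.0
        row[len(_BOND_ORDERS)] = 1.0 if b.IsInRing() else 0.0
        row[len(_BOND_ORDERS) + 1] = 1.0 if b.GetIsConjugated() else 0.0
        feats.append(row)
    bond_list = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    bond_features = np.stack(feats) if feats else np.zeros((0, BOND_FEATURE_DIM))
    return MolGraph(atom_features=atoms, bond_list=bond_list, bond_features=bond_features)
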