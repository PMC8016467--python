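"""Dataset model and I/O: pairs tables, affinity matrices, FASTA, unit
conversion, binarization and train/valid/test splitting.

The in-memory model is an :class:`InteractionDataset`: deduplicated compound
and protein records plus (compound-index, protein-index, label) triples.  The
task kind (regression vs classification) is auto-detected from the labels:
a label set contained in {0, 1} means classification, anything else means
regression.

Splits come in three flavours.  ``random`` shuffles pairs; ``cold_drug`` and
``cold_protein`` partition the *entities* so that no compound (respectively
protein) that occurs in the test fold is ever seen during training — the
standard protocol for judging generalization to novel chemistry or novel
targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem
from rdkit.rdBase import BlockLogs

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "CompoundRecord",
    "ProteinRecord",
    "InteractionDataset",
    "SplitResult",
    "read_pairs_table",
    "write_pairs_table",
    "read_affinity_matrix",
    "read_fasta",
    "convert_affinity_to_pscale",
    "convert_pscale_to_affinity",
    "binarize",
    "detect_task",
    "data_process",
]


@dataclass(frozen=True)
class CompoundRecord:
    """A small molecule: identifier plus canonicalizable SMILES."""

    id: str
    smiles: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("compound id must be nonempty")
        mol = parse_smiles(self.smiles)
        if mol is None or mol.GetNumHeavyAtoms() < 1:
            raise ValueError(f"compound {self.id!r}: invalid SMILES {self.smiles!r}")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein target: identifier plus amino-acid sequence.

    Sequences are uppercase over the 20 canonical letters plus X for unknown,
    length at least 3.
    """

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if len(self.sequence) < 3:
            raise ValueError(f"protein {self.id!r}: sequence shorter than 3 residues")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"protein {self.id!r}: sequence must be uppercase")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal characters {sorted(bad)!r} "
                "(allowed: 20 canonical amino acids plus X)"
            )


def parse_smiles(smiles: str):
    """Parse a SMILES string, returning an RDKit Mol or None (quiet)."""
    if not isinstance(smiles, str) or not smiles:
        return None
    with BlockLogs():
        return Chem.MolFromSmiles(smiles)


@dataclass
class InteractionDataset:
    """Aligned (compound, protein, label) triples with a task kind.

    ``pairs`` holds index triples into ``compounds``/``proteins``.  ``task``
    is ``"regression"`` or ``"classification"``; ``label_units`` records the
    scale of the labels (``"pKd"`` after p-scale conversion, ``"nM"`` raw,
    ``"binary"`` after binarization, or ``"raw"``).
    """

    compounds: list  # list[CompoundRecord]
    proteins: list  # list[ProteinRecord]
    pairs: list  # list[(int, int, float)]
    task: str = "regression"
    label_units: str = "raw"
    skip_report: dict = field(default_factory=dict)

    def __post_init__(self):
        nc, nt = len(self.compounds), len(self.proteins)
        seen = set()
        for ci, pi, lab in self.pairs:
            if not (0 <= ci < nc and 0 <= pi < nt):
                raise ValueError(f"pair index ({ci},{pi}) out of range")
            if (ci, pi) in seen:
                raise ValueError(f"duplicate (compound, protein) pair ({ci},{pi})")
            seen.add((ci, pi))
        cids = [c.id for c in self.compounds]
        pids = [p.id for p in self.proteins]
        if len(set(cids)) != nc or len(set(pids)) != nt:
            raise ValueError("record ids must be unique within a dataset")
        if self.task == "classification":
            labs = {lab for _, _, lab in self.pairs}
            if not labs <= {0.0, 1.0}:
                raise ValueError("classification labels must all be 0 or 1")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.pairs], dtype=float)

    def triples(self):
        """Yield (smiles, sequence, label) for every pair."""
        for ci, pi, lab in self.pairs:
            yield self.compounds[ci].smiles, self.proteins[pi].sequence, lab

    def subset(self, pair_indices) -> "InteractionDataset":
        """Dataset restricted to the given pair positions (records re-indexed)."""
        sel = [self.pairs[i] for i in pair_indices]
        cmap, pmap = {}, {}
        compounds, proteins, pairs = [], [], []
        for ci, pi, lab in sel:
            if ci not in cmap:
                cmap[ci] = len(compounds)
                compounds.append(self.compounds[ci])
            if pi not in pmap:
                pmap[pi] = len(proteins)
                proteins.append(self.proteins[pi])
            pairs.append((cmap[ci], pmap[pi], lab))
        return InteractionDataset(
            compounds, proteins, pairs, task=self.task, label_units=self.label_units
        )

    @classmethod
    def from_triples(cls, triples, task: str | None = None, label_units: str = "raw",
                     skip_invalid: bool = False) -> "InteractionDataset":
        """Build a dataset from (smiles, sequence, label) triples.

        Compounds and proteins are deduplicated by their string; duplicate
        (compound, protein) pairs keep the first occurrence (silently
        averaging labels would hide data errors).  With ``skip_invalid``,
        rows whose SMILES does not parse are dropped and counted in
        ``skip_report`` instead of raising.
        """
        compounds, proteins, pairs = [], [], []
        cidx, pidx, seen = {}, {}, set()
        report = {"invalid_smiles": 0, "duplicate_pairs": 0, "invalid_sequence": 0}
        for smiles, seq, lab in triples:
            if smiles not in cidx:
                mol = parse_smiles(smiles)
                if mol is None or mol.GetNumHeavyAtoms() < 1:
                    if skip_invalid:
                        report["invalid_smiles"] += 1
                        logger.warning("skipping row with unparseable SMILES %r", smiles)
                        continue
                    raise ValueError(f"invalid SMILES {smiles!r}")
            seq = str(seq).upper()
            try:
                if seq not in pidx:
                    ProteinRecord(id="tmp", sequence=seq)
            except ValueError:
                if skip_invalid:
                    report["invalid_sequence"] += 1
                    logger.warning("skipping row with invalid sequence %r", seq[:30])
                    continue
                raise
            if smiles not in cidx:
                cidx[smiles] = len(compounds)
                compounds.append(CompoundRecord(id=f"drug_{len(compounds)}", smiles=smiles))
            if seq not in pidx:
                pidx[seq] = len(proteins)
                proteins.append(ProteinRecord(id=f"target_{len(proteins)}", sequence=seq))
            key = (cidx[smiles], pidx[seq])
            if key in seen:
                report["duplicate_pairs"] += 1
                logger.warning("dropping duplicate pair %r", key)
                continue
            seen.add(key)
            pairs.append((key[0], key[1], float(lab)))
        if task is None:
            task = detect_task([lab for _, _, lab in pairs]) if pairs else "regression"
        ds = cls(compounds, proteins, pairs, task=task, label_units=label_units)
        ds.skip_report = report
        return ds


def detect_task(labels) -> str:
    """Classification iff every label is 0 or 1; otherwise regression."""
    labels = list(labels)
    if not labels:
        raise ValueError("cannot detect task from empty labels")
    return "classification" if set(float(x) for x in labels) <= {0.0, 1.0} else "regression"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {"smiles": "smiles", "sequence": "target_sequence", "label": "label"}


def read_pairs_table(path, column_map: dict | None = None) -> InteractionDataset:
    """Read a delimited (TSV/CSV by extension) pairs table into a dataset.

    ``column_map`` overrides the default column names
    ``{"smiles": "smiles", "sequence": "target_sequence", "label": "label"}``.
    Rows with unparseable SMILES are skipped, logged and counted in the
    dataset's ``skip_report``.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={cols["smiles"]: str, cols["sequence"]: str},
                     float_precision="round_trip")
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise KeyError(
            f"pairs table {path} is missing required column(s) {missing}; "
            f"present: {list(df.columns)}"
        )
    triples = zip(df[cols["smiles"]], df[cols["sequence"]], df[cols["label"]].astype(float))
    return InteractionDataset.from_triples(triples, skip_invalid=True)


def write_pairs_table(ds: InteractionDataset, path, column_map: dict | None = None) -> None:
    """Write a dataset back to the pairs-table format (round-trip exact)."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    rows = [
        {cols["smiles"]: s, cols["sequence"]: q, cols["label"]: repr(lab)}
        for s, q, lab in ds.triples()
    ]
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(rows, columns=list(cols.values())).to_csv(path, sep=sep, index=False)


_MISSING_SENTINELS = {"", "nan", "NaN", "NAN", "na", "NA"}


def read_affinity_matrix(drugs_path, targets_path, matrix_path) -> InteractionDataset:
    """Read a benchmark-style drug x target affinity matrix layout.

    ``drugs_path``: one SMILES per line (rows of the matrix).  ``targets_path``:
    FASTA, or one sequence per line (columns).  ``matrix_path``: dense
    whitespace/tab-delimited matrix; empty cells and NaN spellings are
    treated as unobserved and dropped.  Returns one pair per observed cell.
    """
    with open(drugs_path) as fh:
        smiles = [ln.strip() for ln in fh if ln.strip()]
    with open(targets_path) as fh:
        first = fh.read()
    if first.lstrip().startswith(">"):
        records = _parse_fasta_text(first)
        sequences = [r.sequence for r in records]
    else:
        sequences = [ln.strip().upper() for ln in first.splitlines() if ln.strip()]
    rows = []
    with open(matrix_path) as fh:
        for ln in fh:
            if ln.strip() or ln.rstrip("\n"):
                rows.append(ln.rstrip("\n").split("\t") if "\t" in ln else ln.split())
    rows = [r for r in rows if any(c.strip() for c in r)]
    if len(rows) != len(smiles):
        raise ValueError(
            f"matrix has {len(rows)} rows but drugs file lists {len(smiles)} compounds"
        )
    triples = []
    for i, row in enumerate(rows):
        if len(row) != len(sequences):
            raise ValueError(
                f"matrix row {i} has {len(row)} cells but targets file lists "
                f"{len(sequences)} proteins"
            )
        for j, cell in enumerate(row):
            if cell.strip() in _MISSING_SENTINELS:
                continue
            triples.append((smiles[i], sequences[j], float(cell)))
    return InteractionDataset.from_triples(triples)


def _parse_fasta_text(text: str):
    out = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"record {rec.id!r}: illegal sequence characters {sorted(bad)!r}")
        out.append(ProteinRecord(id=rec.id, sequence=seq))
    return out


def read_fasta(path) -> list:
    """Read protein records from FASTA; id is the header up to first whitespace."""
    with open(path) as fh:
        return _parse_fasta_text(fh.read())


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# unit conversion / binarization
# ---------------------------------------------------------------------------

def convert_affinity_to_pscale(value_nm):
    """Convert an affinity in nanomolar to the p-scale: ``-log10(nM * 1e-9)``.

    1 nM -> 9.0; 10 uM -> 5.0.  Strictly decreasing: stronger binders (lower
    nM) get higher p-scale values.
    """
    arr = np.asarray(value_nm, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("affinity must be positive (nM) for p-scale conversion")
    out = -np.log10(arr * 1e-9)
    return float(out) if np.isscalar(value_nm) or arr.ndim == 0 else out


def convert_pscale_to_affinity(pvalue):
    """Inverse of :func:`convert_affinity_to_pscale`: p-scale back to nM."""
    arr = np.asarray(pvalue, dtype=float)
    out = 10.0 ** (-arr) * 1e9
    return float(out) if np.isscalar(pvalue) or arr.ndim == 0 else out


def binarize(labels, threshold: float, direction: str = "ge"):
    """Threshold real labels to {0,1}: 1 iff label >= threshold (or <= for 'le')."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    arr = np.asarray(list(labels), dtype=float)
    if arr.size == 0:
        return []
    out = (arr >= threshold) if direction == "ge" else (arr <= threshold)
    return out.astype(int).tolist()


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitResult:
    """Train/valid/test datasets plus the split provenance."""

    train: InteractionDataset
    valid: InteractionDataset
    test: InteractionDataset
    method: str
    fractions: tuple
    seed: int

    @property
    def sizes(self) -> tuple:
        return (len(self.train), len(self.valid), len(self.test))


def _split_counts(n: int, fractions) -> tuple:
    """test = floor(n*f_test), valid = floor(n*f_valid), remainder to train."""
    f_train, f_valid, f_test = fractions
    n_test = int(math.floor(n * f_test))
    n_valid = int(math.floor(n * f_valid))
    return n - n_valid - n_test, n_valid, n_test


def data_process(
    ds: InteractionDataset,
    method: str = "random",
    fractions=(0.7, 0.1, 0.2),
    seed: int = 0,
) -> SplitResult:
    """Split a dataset into train/valid/test folds.

    ``method``: ``random`` (over pairs), ``cold_drug`` or ``cold_protein``
    (over entities: the corresponding entity id sets of the three folds are
    pairwise disjoint, so test entities are genuinely unseen).  Identical
    seeds give identical splits.  For cold splits the achieved *pair*
    fractions are approximate (entities carry unequal pair counts) and are
    reported in the log.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    n = len(ds)
    if method == "random":
        order = rng.permutation(n)
        n_train, n_valid, n_test = _split_counts(n, fractions)
        idx_train = order[:n_train]
        idx_valid = order[n_train:n_train + n_valid]
        idx_test = order[n_train + n_valid:]
    elif method in ("cold_drug", "cold_protein"):
        n_ent = len(ds.compounds) if method == "cold_drug" else len(ds.proteins)
        if n_ent < 3:
            raise ValueError(
                f"{method} split needs at least 3 distinct entities, got {n_ent}"
            )
        order = rng.permutation(n_ent)
        e_train, e_valid, e_test = _split_counts(n_ent, fractions)
        if min(e_train, e_valid, e_test) < 1:
            raise ValueError(
                f"{method} split infeasible: fractions {fractions} leave an empty "
                f"fold with only {n_ent} entities"
            )
        fold_of = np.empty(n_ent, dtype=int)
        fold_of[order[:e_train]] = 0
        fold_of[order[e_train:e_train + e_valid]] = 1
        fold_of[order[e_train + e_valid:]] = 2
        key = 0 if method == "cold_drug" else 1
        folds = ([], [], [])
        for i, pair in enumerate(ds.pairs):
            folds[fold_of[pair[key]]].append(i)
        idx_train, idx_valid, idx_test = (np.array(f, dtype=int) for f in folds)
        achieved = tuple(len(f) / n if n else 0.0 for f in folds)
        logger.info("%s split achieved pair fractions %s (requested %s)",
                    method, achieved, fractions)
    else:
        raise ValueError(
            f"unknown split method {method!r}; expected random, cold_drug or cold_protein"
        )
    return SplitResult(
        train=ds.subset(sorted(idx_train.tolist())),
        valid=ds.subset(sorted(idx_valid.tolist())),
        test=ds.subset(sorted(idx_test.tolist())),
        method=method,
        fractions=fractions,
        seed=seed,
    )
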