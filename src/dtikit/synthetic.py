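"""Deterministic synthetic DTI datasets with planted affinity structure.

The generator builds drugs by seeded assembly of fragments from a packaged
bank of valid SMILES pieces and targets as seeded random sequences over the
20-letter alphabet (length 50-200).  The planted affinity is

    label(d, t) = 7 + effect_size * z(<u_d, v_t>) + Gaussian(0, noise_sd)

where ``u_d`` is a fixed linear projection of the drug's Morgan fingerprint
and ``v_t`` a fixed projection of the target's amino-acid composition, and
``z`` standardizes the bilinear term over the full drug x target grid.  The
signal therefore lives exactly in features the models consume, so trained
models can genuinely recover it, and the 7 p-scale offset puts labels on a
realistic pKd-like range.  ``effect_size = 0`` gives pure-noise labels (the
null control); ``observed_fraction`` subsamples the grid the way public
affinity matrices are sparsely observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .chem import morgan_fingerprint
from .iodata import CompoundRecord, InteractionDataset, ProteinRecord, binarize
from .protein import AMINO_ACIDS, aac

__all__ = ["SyntheticSpec", "generate", "make_binary", "load_fragment_bank"]

# the projection defining the planted signal is part of the generator's
# definition, not of the sampled noise: fixed seed, independent of spec.seed
_PROJECTION_SEED = 987654321
_PROJECTION_DIM = 8
_FP_BITS = 1024


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_drugs: int = 50
    n_targets: int = 20
    observed_fraction: float = 0.5
    noise_sd: float = 0.3
    effect_size: float = 1.0
    seed: int = 7

    def __post_init__(self):
        if self.n_drugs < 2 or self.n_targets < 2:
            raise ValueError("need at least 2 drugs and 2 targets")
        if not 0 < self.observed_fraction <= 1:
            raise ValueError("observed_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def load_fragment_bank() -> list:
    """The packaged bank of concatenation-safe SMILES fragments."""
    with resources.files("dtikit.data").joinpath("smiles_fragments.txt").open() as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def _sample_drugs(rng: np.random.Generator, n: int) -> list:
    bank = load_fragment_bank()
    seen, out = set(), []
    while len(out) < n:
        k = int(rng.integers(1, 4))
        smiles = "".join(bank[i] for i in rng.integers(0, len(bank), size=k))
        if smiles in seen:
            continue
        seen.add(smiles)
        out.append(CompoundRecord(id=f"drug_{len(out)}", smiles=smiles))
    return out


def _sample_targets(rng: np.random.Generator, n: int) -> list:
    out = []
    for i in range(n):
        length = int(rng.integers(50, 201))
        seq = "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, size=length))
        out.append(ProteinRecord(id=f"target_{i}", sequence=seq))
    return out


def _planted_signal(drugs, targets) -> np.ndarray:
    """Standardized bilinear signal over the full drug x target grid."""
    prng = np.random.default_rng(_PROJECTION_SEED)
    P_drug = prng.normal(size=(_FP_BITS, _PROJECTION_DIM)) / np.sqrt(_FP_BITS)
    P_prot = prng.normal(size=(20, _PROJECTION_DIM)) / np.sqrt(20)
    U = np.stack([morgan_fingerprint(d.smiles, 2, _FP_BITS).bits for d in drugs]) @ P_drug
    V = np.stack([aac(t.sequence).values for t in targets]) @ P_prot
    raw = U @ V.T  # (n_drugs, n_targets)
    sd = raw.std()
    if sd == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def generate(spec: SyntheticSpec) -> InteractionDataset:
    """Sample one dataset under the given study conditions (fully seeded)."""
    rng = np.random.default_rng(spec.seed)
    drugs = _sample_drugs(rng, spec.n_drugs)
    targets = _sample_targets(rng, spec.n_targets)
    signal = _planted_signal(drugs, targets)
    labels = 7.0 + spec.effect_size * signal + rng.normal(
        0.0, spec.noise_sd, size=signal.shape)
    pairs = []
    for i in range(spec.n_drugs):
        for j in range(spec.n_targets):
            pairs.append((i, j, float(labels[i, j])))
    if spec.observed_fraction < 1:
        n_keep = max(2, int(round(len(pairs) * spec.observed_fraction)))
        keep = rng.choice(len(pairs), size=n_keep, replace=False)
        pairs = [pairs[k] for k in sorted(keep)]
    used_d = sorted({i for i, _, _ in pairs})
    used_t = sorted({j for _, j, _ in pairs})
    dmap = {i: k for k, i in enumerate(used_d)}
    tmap = {j: k for k, j in enumerate(used_t)}
    return InteractionDataset(
        compounds=[drugs[i] for i in used_d],
        proteins=[targets[j] for j in used_t],
        pairs=[(dmap[i], tmap[j], lab) for i, j, lab in pairs],
        task="regression",
        label_units="pKd",
    )


def make_binary(spec: SyntheticSpec, threshold_quantile: float = 0.5) -> InteractionDataset:
    """Classification variant: labels binarized at an empirical quantile."""
    if not 0 < threshold_quantile < 1:
        raise ValueError("threshold_quantile must be in (0, 1)")
    ds = generate(spec)
    thr = float(np.quantile(ds.labels, threshold_quantile))
    blabels = binarize(ds.labels, thr, direction="ge")
    if len(set(blabels)) < 2:
        raise ValueError(
            f"degenerate class distribution at quantile {threshold_quantile}")
    pairs = [(ci, pi, float(b)) for (ci, pi, _), b in zip(ds.pairs, blabels)]
    return InteractionDataset(
        compounds=ds.compounds, proteins=ds.proteins, pairs=pairs,
        task="classification", label_units="binary",
    )
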