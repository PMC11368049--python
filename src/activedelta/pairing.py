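"""Cross-merged training pairs and anchor-vs-candidate prediction pairs.

The pairing convention is fixed package-wide: a pair is (first = reference,
second = candidate) and its label is delta = potency(second) -
potency(first), so a positive predicted delta means "the candidate improves
on the reference". Cross-merging an n-molecule training set yields all n^2
ordered pairs (self-pairs included), which is the combinatorial data
expansion that lets models learn potency *differences*; because every label
is a difference, adding a constant assay offset to all potencies leaves the
training targets bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import fingerprint_matrix
from .dataio import CompoundDataset, MoleculeRecord


@dataclass(frozen=True)
class PairExample:
    """Ordered molecule pair; delta is None for prediction-time inputs."""

    first: MoleculeRecord
    second: MoleculeRecord
    delta: Optional[float] = None


def cross_merge(train: CompoundDataset,
                include_self_pairs: bool = True) -> List[PairExample]:
    """All ordered training pairs with difference labels, row-major in
    training order.

    ``include_self_pairs`` (default) gives the full n^2 expansion with
    zero-delta anchoring examples; switching it off gives n(n-1) pairs for
    ablation.
    """
    if len(train) == 0:
        raise ValueError("cross_merge requires a non-empty training set")
    pairs: List[PairExample] = []
    for a in train.records:
        for b in train.records:
            if not include_self_pairs and a.id == b.id:
                continue
            pairs.append(PairExample(first=a, second=b,
                                     delta=b.potency - a.potency))
    return pairs


def anchor_pairs(anchor: MoleculeRecord,
                 pool: CompoundDataset) -> List[PairExample]:
    """Pair the anchor against every pool molecule, in pool order.

    These are prediction-time inputs (no labels): the model scores each
    candidate's predicted improvement over the anchor.
    """
    if len(pool) == 0:
        raise ValueError("anchor_pairs requires a non-empty pool")
    return [PairExample(first=anchor, second=rec, delta=None)
            for rec in pool.records]


def best_in_train(train: CompoundDataset) -> MoleculeRecord:
    """The currently most potent training compound (the anchor).

    Ties break to the earliest training position, keeping the anchor
    deterministic.
    """
    if len(train) == 0:
        raise ValueError("best_in_train requires a non-empty training set")
    best = train.records[0]
    for rec in train.records[1:]:
        if rec.potency > best.potency:
            best = rec
    return best


def paired_fingerprint_matrix(pairs: Sequence[PairExample],
                              kind: str = "morgan_r2_2048") -> np.ndarray:
    """Concatenated (first ++ second) fingerprints, one row per pair.

    Row width is twice the single-molecule fingerprint length.
    """
    first = fingerprint_matrix([p.first.smiles for p in pairs], kind)
    second = fingerprint_matrix([p.second.smiles for p in pairs], kind)
    return np.hstack([first, second])


def pair_deltas(pairs: Sequence[PairExample]) -> np.ndarray:
    deltas = [p.delta for p in pairs]
    if any(d is None for d in deltas):
        raise ValueError("unlabeled pair in a labeled-pair context")
    return np.asarray(deltas, dtype=float)


def pairs_to_frame(pairs: Sequence[PairExample]) -> pd.DataFrame:
    """Tidy export (first_smiles, second_smiles, delta) for inspection."""
    return pd.DataFrame({
        "first_smiles": [p.first.smiles for p in pairs],
        "second_smiles": [p.second.smiles for p in pairs],
        "delta": [p.delta for p in pairs],
    })
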