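"""Compound dataset ingestion, validation, deduplication, splits, and the
active-learning cold start.

Potency orientation is uniform across the package: LARGER value = MORE
potent. Raw binding constants (K_i, where smaller is stronger) are mapped
onto this scale at load time with ``log_transform`` (potency = -log10(K_i),
i.e. pK_i), so every downstream selection rule is a plain argmax.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import try_canonical_smiles


class EmptyDatasetError(ValueError):
    """No valid rows survived loading."""


class InsufficientDataError(ValueError):
    """Operation needs more records than the dataset holds."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: stable identifier, canonical SMILES, oriented potency."""

    id: str
    smiles: str
    potency: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.potency):
            raise ValueError(f"record {self.id}: potency must be finite")


@dataclass
class LoadReport:
    """Bookkeeping of rows dropped while loading a CSV."""

    n_rows: int = 0
    n_valid: int = 0
    n_invalid_smiles: int = 0
    n_missing_potency: int = 0
    n_nonpositive_raw: int = 0
    n_duplicates: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CompoundDataset:
    """Ordered, duplicate-free collection of molecule records.

    ``role`` distinguishes the paper-style dataset roles: ``train`` (the
    growing active-learning training set), ``learning`` (the pool the
    policies select from), and ``test`` (held out).
    """

    records: List[MoleculeRecord] = field(default_factory=list)
    role: str = "train"
    name: str = "dataset"
    load_report: Optional[LoadReport] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> MoleculeRecord:
        return self.records[i]

    @property
    def ids(self) -> List[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> List[str]:
        return [r.smiles for r in self.records]

    @property
    def potencies(self) -> np.ndarray:
        return np.array([r.potency for r in self.records], dtype=float)

    def validate(self) -> None:
        ids = self.ids
        if len(set(ids)) != len(ids):
            raise ValueError(f"dataset {self.name}: duplicate ids")

    def with_records(self, records: Sequence[MoleculeRecord],
                     role: Optional[str] = None) -> "CompoundDataset":
        return CompoundDataset(records=list(records), role=role or self.role,
                               name=self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "SMILES": self.smiles, "potency": self.potencies}
        )

    def to_csv(self, path) -> None:
        # %.17g keeps the serialize/load round trip exact to the bit
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, role: str = "train",
                   name: str = "dataset") -> "CompoundDataset":
        records = [
            MoleculeRecord(id=str(r.id), smiles=str(r.SMILES), potency=float(r.potency))
            for r in df.itertuples(index=False)
        ]
        ds = cls(records=records, role=role, name=name)
        ds.validate()
        return ds


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition parameters. ``precomputed`` mode reads
    membership from a ``split`` column instead of re-splitting."""

    train_fraction: float = 0.8
    seed: int = 0
    mode: str = "random"  # random | precomputed

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.mode not in ("random", "precomputed"):
            raise ValueError(f"unknown split mode {self.mode!r}")


def load_dataset(path, smiles_col: str = "SMILES", potency_col: str = "potency",
                 log_transform: bool = False, id_col: Optional[str] = None,
                 name: Optional[str] = None, role: str = "train") -> CompoundDataset:
    """Read a compound CSV into a validated, deduplicated dataset.

    Rows with unparseable SMILES or missing potency are dropped and counted
    in the attached :class:`LoadReport`. With ``log_transform``, potency is
    -log10 of the raw value (pK_i orientation); non-positive raw values are
    dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (smiles_col, potency_col):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not in {path.name}: {list(df.columns)}")

    report = LoadReport(n_rows=len(df))
    records: List[MoleculeRecord] = []
    seen = set()
    id_values = df[id_col].tolist() if id_col else [None] * len(df)
    for i, (raw_smiles, raw_value, raw_id) in enumerate(
            zip(df[smiles_col], df[potency_col], id_values)):
        canon = try_canonical_smiles(raw_smiles)
        if canon is None:
            report.n_invalid_smiles += 1
            continue
        try:
            value = float(raw_value)
        except (TypeError, ValueError):
            report.n_missing_potency += 1
            continue
        if not math.isfinite(value):
            report.n_missing_potency += 1
            continue
        if log_transform:
            if value <= 0:
                report.n_nonpositive_raw += 1
                warnings.warn(
                    f"row {i}: non-positive raw value {value} under log_transform; dropped"
                )
                continue
            value = -math.log10(value)
        if canon in seen:
            report.n_duplicates += 1
            continue
        seen.add(canon)
        rid = str(raw_id) if raw_id is not None else f"{path.stem}-{i}"
        records.append(MoleculeRecord(id=rid, smiles=canon, potency=value))

    report.n_valid = len(records)
    if not records:
        raise EmptyDatasetError(f"{path}: no valid rows")
    ds = CompoundDataset(records=records, role=role, name=name or path.stem,
                         load_report=report)
    ds.validate()
    return ds


def deduplicate(ds: CompoundDataset) -> CompoundDataset:
    """Keep the first occurrence of each canonical SMILES."""
    seen = set()
    kept = []
    for rec in ds.records:
        canon = try_canonical_smiles(rec.smiles)
        key = canon if canon is not None else rec.smiles
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return ds.with_records(kept)


def split_dataset(ds: CompoundDataset, spec: SplitSpec,
                  split_labels: Optional[Sequence[str]] = None
                  ) -> Tuple[CompoundDataset, CompoundDataset]:
    """Partition into train/test per the split spec.

    ``precomputed`` mode requires ``split_labels`` ('train'/'test' per
    record, e.g. read from a CSV split column), mirroring fixed external
    splits rather than re-splitting.
    """
    if spec.mode == "precomputed":
        if split_labels is None or len(split_labels) != len(ds):
            raise ValueError("precomputed mode needs one split label per record")
        train = [r for r, lab in zip(ds.records, split_labels) if lab == "train"]
        test = [r for r, lab in zip(ds.records, split_labels) if lab == "test"]
    else:
        rng = np.random.default_rng(spec.seed)
        order = rng.permutation(len(ds))
        n_train = int(round(spec.train_fraction * len(ds)))
        train_idx = set(order[:n_train].tolist())
        train = [r for i, r in enumerate(ds.records) if i in train_idx]
        test = [r for i, r in enumerate(ds.records) if i not in train_idx]
    return (ds.with_records(train, role="train"),
            ds.with_records(test, role="test"))


def load_precomputed_split(path, smiles_col: str = "SMILES",
                           potency_col: str = "potency",
                           split_col: str = "split", **kwargs
                           ) -> Tuple[CompoundDataset, CompoundDataset]:
    """Load a CSV carrying its own train/test membership column."""
    ds = load_dataset(path, smiles_col=smiles_col, potency_col=potency_col, **kwargs)
    df = pd.read_csv(path)
    if split_col not in df.columns:
        raise KeyError(f"column {split_col!r} not found")
    labels = {try_canonical_smiles(s): str(lab)
              for s, lab in zip(df[smiles_col], df[split_col])}
    per_record = [labels.get(r.smiles, "train") for r in ds.records]
    return split_dataset(ds, SplitSpec(mode="precomputed"), split_labels=per_record)


def cold_start(ds: CompoundDataset, seed: int
               ) -> Tuple[CompoundDataset, CompoundDataset]:
    """Draw the two random starting compounds; the rest become the pool.

    Deterministic given (dataset order, seed). The pair is drawn uniformly
    without replacement, matching the two-datapoint initial training sets
    the active-learning protocol starts from.
    """
    if len(ds) < 3:
        raise InsufficientDataError(
            f"cold start needs >= 3 records, got {len(ds)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ds), size=2, replace=False)
    chosen_set = set(int(c) for c in chosen)
    train = [ds.records[i] for i in sorted(chosen_set)]
    pool = [r for i, r in enumerate(ds.records) if i not in chosen_set]
    return (ds.with_records(train, role="train"),
            ds.with_records(pool, role="learning"))
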