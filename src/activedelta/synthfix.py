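"""Synthetic compound libraries with a learnable potency landscape.

Molecules are assembled from a fixed fragment grammar (ring-system
templates, ring substituents, and side chains), guaranteeing valid,
duplicate-free canonical SMILES with diverse Murcko scaffolds and no
external data. Potency follows a linear landscape on the same Morgan
fingerprint bits the models consume:

    potency(m) = w . fp(m) + assay_offset + Normal(0, noise_sd)

with a sparse weight vector w drawn once per seed. ``hit_skew`` adds extra
weight onto the fingerprint bits of a few designated "active series" core
scaffolds, which separates a top potency tail concentrated in (at least
two) distinct scaffold classes — so top-decile hit sets are small,
well-defined, and scaffold-diverse, mimicking a skewed pK_i distribution.
The landscape stays *exactly* linear in fingerprint bits at noise_sd = 0.

``hard_mode`` applies the signal to a withheld fingerprint kind (atom
pairs) instead, for graceful-degradation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .chem import (FP_LENGTHS, fingerprint_matrix, murcko_scaffold,
                   try_canonical_smiles)
from .dataio import CompoundDataset, MoleculeRecord, SplitSpec, split_dataset

# --- fragment grammar ----------------------------------------------------
# Each template has one substitution slot {a}; an optional prefix chain can
# be concatenated in front (the first template atom accepts a bond).
# Substituent rings use closure digit 7 to avoid clashes with template
# closure digits.

RING_TEMPLATES: Tuple[str, ...] = (
    "c1ccc({a})cc1",            # benzene
    "c1ccnc({a})c1",            # pyridine (2-sub)
    "c1cc({a})ccn1",            # pyridine (4-sub)
    "c1cnc({a})nc1",            # pyrimidine
    "c1cc({a})cs1",             # thiophene
    "c1cc({a})co1",             # furan
    "c1cc({a})c[nH]1",          # pyrrole
    "C1CCN({a})CC1",            # piperidine (N-sub)
    "C1CCC({a})CC1",            # cyclohexane
    "c1ccc2cc({a})ccc2c1",      # naphthalene
    "c1ccc(-c2ccc({a})cc2)cc1",  # biphenyl
    "O=C1CCCN1{a}",             # 2-pyrrolidinone (N-sub)
    "c1ccc2[nH]c({a})cc2c1",    # indole
    "c1ccc2nc({a})ccc2c1",      # quinoline
    "O=C(Nc1ccc({a})cc1)C",     # acetanilide
    "c1nc({a})no1",             # oxadiazole
)

SIDE_CHAINS: Tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CCO", "CO", "OC", "OCC", "N", "NC",
    "N(C)C", "CCN", "F", "Cl", "Br", "C(F)(F)F", "C#N", "C(=O)O",
    "C(=O)N", "C(=O)OC", "S(C)(=O)=O", "CNC(C)=O", "OC(F)F", "CCCO",
)

RING_SUBS: Tuple[str, ...] = (
    "-c7ccccc7", "Cc7ccccc7", "-c7ccncc7", "CCc7ccccc7", "Oc7ccccc7",
    "C(=O)N7CCCC7", "N7CCOCC7", "-c7ccc(F)cc7", "-c7ccc(C)cc7",
    "CN7CCCC7",
)

PREFIX_CHAINS: Tuple[str, ...] = ("", "C", "CC", "OC", "FC(F)(F)",
                                  "NC(=O)", "CN")

#: Templates whose core scaffolds carry the hit-skew potency boost.
ACTIVE_SERIES_TEMPLATES: Tuple[int, ...] = (3, 9, 13)  # pyrimidine,
# naphthalene, quinoline cores

#: Small fixed library for generator="fixture_list" (common drug-like
#: molecules; synthetic stand-in, not a benchmark set).
FIXTURE_SMILES: Tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O", "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "Cc1ccccc1", "c1ccc2ccccc2c1", "CCO", "CC(=O)Nc1ccc(O)cc1",
    "CN1CCC[C@H]1c1cccnc1", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "NC(=O)c1ccccc1", "Oc1ccccc1", "Clc1ccccc1Cl", "CCN(CC)CC",
    "O=C1CCCN1", "c1ccsc1", "c1ccoc1", "c1cc[nH]c1", "C1CCNCC1",
    "C1CCOC1", "CC(C)(C)c1ccccc1", "COc1ccccc1", "CC(=O)c1ccccc1",
    "N#Cc1ccccc1", "FC(F)(F)c1ccccc1", "OCc1ccccc1", "NCc1ccccc1",
    "O=Cc1ccccc1", "CC(N)Cc1ccccc1", "OC(=O)c1ccccc1",
    "c1ccc(-c2ccccc2)cc1", "c1ccc2[nH]ccc2c1", "c1ccc2ncccc2c1",
    "Cc1cccnc1", "Cc1ccncc1", "CSc1ccccc1", "O=S(=O)(N)c1ccccc1",
)


class GenerationError(RuntimeError):
    """The grammar could not supply the requested library size."""


@dataclass
class LandscapeSpec:
    """Parameters of one synthetic potency landscape."""

    library_size: int = 300
    generator: str = "enumerated_fragments"  # or fixture_list
    signal: Optional[np.ndarray] = None  # weight vector over fp bits
    noise_sd: float = 0.3
    assay_offset: float = 6.0
    hit_skew: float = 1.5
    seed: int = 0
    n_signal_bits: int = 120
    signal_scale: float = 0.35
    hard_mode: bool = False

    def __post_init__(self) -> None:
        if self.library_size < 30:
            raise ValueError("library_size must be >= 30")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.generator not in ("enumerated_fragments", "fixture_list"):
            raise ValueError(f"unknown generator {self.generator!r}")

    @property
    def signal_kind(self) -> str:
        return "atom_pair" if self.hard_mode else "morgan_r2_2048"

    def to_json_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "signal"}
        d["signal"] = None if self.signal is None else self.signal.tolist()
        return d


def _core_scaffold_smiles() -> List[str]:
    """Canonical cores of the active-series templates (slot filled with C)."""
    cores = []
    for i in ACTIVE_SERIES_TEMPLATES:
        smi = try_canonical_smiles(RING_TEMPLATES[i].format(a="C"))
        assert smi is not None
        cores.append(murcko_scaffold(smi).smiles)
    return cores


def build_signal(spec: LandscapeSpec) -> np.ndarray:
    """The landscape's sparse weight vector, derived once from the seed.

    A base of ``n_signal_bits`` random bits carries Gaussian weights; the
    fingerprint bits of the active-series core scaffolds receive an extra
    ``hit_skew``-scaled weight so molecules built on those cores form a
    separated top tail.
    """
    if spec.signal is not None:
        return np.asarray(spec.signal, dtype=float)
    n_bits = FP_LENGTHS[spec.signal_kind]
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(spec.seed), 101]).generate_state(1)[0])
    w = np.zeros(n_bits, dtype=float)
    idx = rng.choice(n_bits, size=min(spec.n_signal_bits, n_bits),
                     replace=False)
    w[idx] = rng.normal(0.0, spec.signal_scale, size=len(idx))
    if spec.hit_skew > 0:
        cores = _core_scaffold_smiles()
        core_fps = fingerprint_matrix(cores, spec.signal_kind)
        for row in core_fps:
            on = np.flatnonzero(row)
            if len(on):
                w[on] += spec.hit_skew / len(on)
    return w


def _enumerate_smiles(size: int, rng: np.random.Generator) -> List[str]:
    """Assemble valid canonical SMILES from the grammar until ``size``
    distinct molecules exist."""
    seen = set()
    out: List[str] = []
    attempts = 0
    max_attempts = 200 * size
    while len(out) < size and attempts < max_attempts:
        attempts += 1
        template = RING_TEMPLATES[int(rng.integers(len(RING_TEMPLATES)))]
        if rng.random() < 0.30:
            slot = RING_SUBS[int(rng.integers(len(RING_SUBS)))]
        else:
            slot = SIDE_CHAINS[int(rng.integers(len(SIDE_CHAINS)))]
        prefix = PREFIX_CHAINS[int(rng.integers(len(PREFIX_CHAINS)))]
        candidate = prefix + template.format(a=slot)
        canon = try_canonical_smiles(candidate)
        if canon is None or canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    if len(out) < size:
        raise GenerationError(
            f"grammar exhausted at {len(out)} unique molecules "
            f"(requested {size})")
    return out


def _fixture_smiles(size: int, rng: np.random.Generator) -> List[str]:
    """Decorated variants of the fixed fixture list, deduplicated."""
    seen = set()
    out: List[str] = []
    base = [try_canonical_smiles(s) for s in FIXTURE_SMILES]
    for smi in base:
        if smi is not None and smi not in seen:
            seen.add(smi)
            out.append(smi)
        if len(out) >= size:
            return out[:size]
    attempts = 0
    while len(out) < size and attempts < 200 * size:
        attempts += 1
        smi = FIXTURE_SMILES[int(rng.integers(len(FIXTURE_SMILES)))]
        chain = SIDE_CHAINS[int(rng.integers(len(SIDE_CHAINS)))]
        canon = try_canonical_smiles(chain + smi) or try_canonical_smiles(smi + chain)
        if canon is None or canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    if len(out) < size:
        raise GenerationError(f"fixture list exhausted at {len(out)}")
    return out


def generate_library(spec: LandscapeSpec) -> CompoundDataset:
    """Deterministically generate the library and its potency labels."""
    ss = np.random.SeedSequence(int(spec.seed))
    struct_seed, noise_seed = (int(s) % (2 ** 31)
                               for s in ss.generate_state(2))
    rng = np.random.default_rng(struct_seed)
    if spec.generator == "enumerated_fragments":
        smiles = _enumerate_smiles(spec.library_size, rng)
    else:
        smiles = _fixture_smiles(spec.library_size, rng)
    w = build_signal(spec)
    fps = fingerprint_matrix(smiles, spec.signal_kind).astype(float)
    base = fps @ w + spec.assay_offset
    noise_rng = np.random.default_rng(noise_seed)
    noise = (noise_rng.normal(0.0, spec.noise_sd, size=len(smiles))
             if spec.noise_sd > 0 else np.zeros(len(smiles)))
    potencies = base + noise
    records = [MoleculeRecord(id=f"M{i:04d}", smiles=s, potency=float(p))
               for i, (s, p) in enumerate(zip(smiles, potencies))]
    ds = CompoundDataset(records=records, role="train",
                         name=f"synth-{spec.seed}")
    ds.validate()
    return ds


def generate_split(spec: LandscapeSpec, scaffold_disjoint: bool = False
                   ) -> Tuple[CompoundDataset, CompoundDataset]:
    """80:20 train/test partition of a generated library.

    ``scaffold_disjoint`` assigns whole Murcko scaffold classes to one
    side, approximating the harder character of time-based splits where
    test chemistry is new.
    """
    ds = generate_library(spec)
    split_seed = int(np.random.SeedSequence(
        [int(spec.seed), 202]).generate_state(1)[0]) % (2 ** 31)
    if not scaffold_disjoint:
        return split_dataset(ds, SplitSpec(train_fraction=0.8,
                                           seed=split_seed))
    rng = np.random.default_rng(split_seed)
    groups: dict = {}
    for i, rec in enumerate(ds.records):
        groups.setdefault(murcko_scaffold(rec.smiles).smiles, []).append(i)
    order = list(groups.values())
    rng.shuffle(order)
    n_train_target = int(round(0.8 * len(ds)))
    train_idx: set = set()
    for idx_group in order:
        if len(train_idx) < n_train_target:
            train_idx.update(idx_group)
    train = [r for i, r in enumerate(ds.records) if i in train_idx]
    test = [r for i, r in enumerate(ds.records) if i not in train_idx]
    return (ds.with_records(train, role="train"),
            ds.with_records(test, role="test"))
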