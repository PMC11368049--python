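"""Molecular featurization, scaffolds, and similarity.

Fingerprint kinds are fixed to the three used throughout the package:
Morgan (radius 2, 2048 bits), MACCS keys (167 bits), and hashed atom-pair
fingerprints (2048 bits). Models consume Morgan fingerprints only; MACCS and
atom pairs exist for similarity analyses.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

# Parse failures are reported through return values / exceptions, not stderr spam.
RDLogger.DisableLog("rdApp.error")

#: Fixed bit widths per fingerprint kind.
FP_LENGTHS = {
    "morgan_r2_2048": 2048,
    "maccs": 167,
    "atom_pair": 2048,
}

FP_KINDS = tuple(FP_LENGTHS)

#: Sentinel scaffold class shared by all acyclic molecules.
ACYCLIC_SCAFFOLD = ""


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical RDKit SMILES; chemical identity is defined on this form."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def try_canonical_smiles(smiles: str) -> Optional[str]:
    """Canonical SMILES, or None if the string does not parse."""
    if not isinstance(smiles, str) or not smiles:
        return None
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary feature vector for one molecule."""

    bits: np.ndarray
    kind: str
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in FP_LENGTHS:
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")
        if len(self.bits) != FP_LENGTHS[self.kind]:
            raise ValueError(
                f"{self.kind} fingerprint must have {FP_LENGTHS[self.kind]} bits, "
                f"got {len(self.bits)}"
            )

    @property
    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def to_json_dict(self) -> dict:
        return {"kind": self.kind, "on_bits": self.on_bits.tolist(),
                "source_id": self.source_id}

    @classmethod
    def from_json_dict(cls, d: dict) -> "Fingerprint":
        bits = np.zeros(FP_LENGTHS[d["kind"]], dtype=np.uint8)
        bits[np.asarray(d["on_bits"], dtype=int)] = 1
        return cls(bits=bits, kind=d["kind"], source_id=d.get("source_id"))


@dataclass(frozen=True)
class Scaffold:
    """Bemis-Murcko framework; empty SMILES for acyclic molecules."""

    smiles: str

    @property
    def is_acyclic(self) -> bool:
        return self.smiles == ACYCLIC_SCAFFOLD


@functools.lru_cache(maxsize=None)
def _morgan_generator():
    return rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@functools.lru_cache(maxsize=None)
def _atom_pair_generator():
    return rdFingerprintGenerator.GetAtomPairGenerator(fpSize=2048)


@functools.lru_cache(maxsize=500_000)
def _fingerprint_bits(smiles: str, kind: str) -> np.ndarray:
    """Cached bit vector on the canonical SMILES; read-only array."""
    mol = mol_from_smiles(smiles)
    if kind == "morgan_r2_2048":
        bv = _morgan_generator().GetFingerprint(mol)
    elif kind == "atom_pair":
        bv = _atom_pair_generator().GetFingerprint(mol)
    elif kind == "maccs":
        bv = MACCSkeys.GenMACCSKeys(mol)
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    arr = np.zeros(len(bv), dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(bv, arr)
    # MACCS keys come back as 167 bits (bit 0 unused but kept for width stability)
    arr = arr[: FP_LENGTHS[kind]] if len(arr) > FP_LENGTHS[kind] else arr
    arr.setflags(write=False)
    return arr


def fingerprint(smiles: str, kind: str = "morgan_r2_2048",
                source_id: Optional[str] = None) -> Fingerprint:
    """Deterministic bit-vector fingerprint of a molecule.

    Equal molecules (same canonical form) yield bitwise-identical vectors
    regardless of how the SMILES was written.
    """
    return Fingerprint(bits=_fingerprint_bits(canonical_smiles(smiles), kind),
                       kind=kind, source_id=source_id)


def fingerprint_matrix(smiles_list: Sequence[str],
                       kind: str = "morgan_r2_2048") -> np.ndarray:
    """Stack fingerprints into an (n, n_bits) uint8 matrix, order preserved."""
    n = len(smiles_list)
    out = np.zeros((n, FP_LENGTHS[kind]), dtype=np.uint8)
    for i, smi in enumerate(smiles_list):
        out[i] = _fingerprint_bits(canonical_smiles(smi), kind)
    return out


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| over on-bits.

    Defined as 1.0 when both vectors are all-zero (two featureless molecules
    are treated as identical), which keeps nearest-neighbor maxima NaN-free.
    """
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind} vs {b.kind}")
    inter = int(np.sum((a.bits != 0) & (b.bits != 0)))
    union = int(np.sum((a.bits != 0) | (b.bits != 0)))
    if union == 0:
        return 1.0
    return inter / union


def murcko_scaffold(smiles: str) -> Scaffold:
    """Bemis-Murcko framework: ring systems plus linkers, terminal
    acyclic substituents removed. Acyclic molecules map to the empty
    scaffold sentinel."""
    mol = mol_from_smiles(smiles)
    scaffold_mol = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold_mol is None or scaffold_mol.GetNumAtoms() == 0:
        return Scaffold(ACYCLIC_SCAFFOLD)
    return Scaffold(Chem.MolToSmiles(scaffold_mol))


def _reference_smiles(reference) -> list:
    """Accept a CompoundDataset, records, or plain SMILES strings."""
    out = []
    for item in reference:
        if isinstance(item, str):
            out.append(item)
        else:
            out.append(item.smiles)
    return out


def nearest_neighbor_similarity(query: str, reference,
                                kind: str = "morgan_r2_2048",
                                exclude_self: bool = False) -> float:
    """Max Tanimoto similarity of ``query`` to any molecule in ``reference``.

    With ``exclude_self`` the query's own canonical structure is skipped, so
    a molecule already present in the reference is compared only to the
    *other* molecules.
    """
    ref_smiles = _reference_smiles(reference)
    if not ref_smiles:
        raise ValueError("reference set must be non-empty")
    q_canon = canonical_smiles(query)
    q_fp = fingerprint(q_canon, kind)
    best = None
    for smi in ref_smiles:
        canon = canonical_smiles(smi)
        if exclude_self and canon == q_canon:
            continue
        sim = tanimoto(q_fp, fingerprint(canon, kind))
        if best is None or sim > best:
            best = sim
    if best is None:
        raise ValueError("reference empty after self-exclusion")
    return best
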