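"""Shared fixtures: all data is generated programmatically at test time."""

import pytest

from activedelta import (CompoundDataset, LandscapeSpec, MoleculeRecord,
                         generate_library, generate_split)


def make_records(potencies, smiles=None, prefix="m"):
    """Hand-built records; default SMILES are simple alkanes (valid but
    chemically uninteresting), fine for logic-only tests."""
    if smiles is None:
        smiles = ["C" * (i + 1) for i in range(len(potencies))]
    return [MoleculeRecord(id=f"{prefix}{i}", smiles=s, potency=float(p))
            for i, (s, p) in enumerate(zip(smiles, potencies))]


def make_dataset(potencies, smiles=None, name="toy"):
    return CompoundDataset(records=make_records(potencies, smiles), name=name)


@pytest.fixture(scope="session")
def landscape_split():
    """The standard synthetic study conditions: 300 molecules, noise 0.3."""
    spec = LandscapeSpec(library_size=300, noise_sd=0.3, seed=0)
    return generate_split(spec)


@pytest.fixture(scope="session")
def small_library():
    """A 60-molecule noisy library for fast end-to-end checks."""
    return generate_library(LandscapeSpec(library_size=60, noise_sd=0.3,
                                          seed=3))


@pytest.fixture(scope="session")
def tiny_library():
    """Smallest legal generated library (30 molecules)."""
    return generate_library(LandscapeSpec(library_size=30, noise_sd=0.2,
                                          seed=11))
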