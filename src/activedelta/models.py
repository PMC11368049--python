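"""Uniform regressor interface over single-molecule and paired (delta) modes.

Families
--------
``gradient_boosted_trees``
    XGBoost regression on Morgan fingerprints (library defaults, seeded).
``random_forest``
    scikit-learn RandomForestRegressor on Morgan fingerprints (defaults).
``dmpnn_adapter``
    Optional plug-in for the two-molecule directed message-passing network
    (Chemprop). Only the adapter surface and its published settings live
    here (paired: 5 epochs; single: 50 epochs; aggregation="sum"); the
    network itself is an external dependency.
``oracle_perfect`` / ``oracle_noisy``
    Test oracles that read the true labels (optionally with fixed
    per-molecule Gaussian noise). They exist to verify acquisition logic,
    never to benchmark.

In ``single`` mode a model maps one molecule's fingerprint to a potency
estimate; in ``paired`` mode it maps a concatenated two-molecule
fingerprint to a potency *difference* (second minus first). Models are
always refit from scratch — the active-learning protocol retrains on the
grown set every round, so no warm starts exist to preserve.
"""

from __future__ import annotations

import pickle
import time
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .chem import fingerprint_matrix
from .dataio import CompoundDataset, InsufficientDataError, MoleculeRecord
from .pairing import (PairExample, anchor_pairs, pair_deltas,
                      paired_fingerprint_matrix)

FAMILIES = ("gradient_boosted_trees", "random_forest", "dmpnn_adapter",
            "oracle_perfect", "oracle_noisy")
MODES = ("single", "paired")

#: Feature kind consumed by the fingerprint families (evaluation-only kinds
#: are never used as model inputs).
MODEL_FP_KIND = "morgan_r2_2048"

#: Published adapter settings for the optional two-molecule network.
DMPNN_DEFAULTS = {
    "paired": {"epochs": 5, "aggregation": "sum", "number_of_molecules": 2},
    "single": {"epochs": 50, "aggregation": "sum", "number_of_molecules": 1},
}

MODEL_ARCHIVE_VERSION = 1


class ModeMismatchError(ValueError):
    """A single-mode model was used in a paired context or vice versa."""


@dataclass(frozen=True)
class RegressorSpec:
    family: str = "gradient_boosted_trees"
    mode: str = "single"
    hyperparams: tuple = ()  # frozen as sorted (key, value) items
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if isinstance(self.hyperparams, dict):  # allow dict at construction
            object.__setattr__(self, "hyperparams",
                               tuple(sorted(self.hyperparams.items())))

    @property
    def params(self) -> Dict:
        return dict(self.hyperparams)

    def with_mode(self, mode: str) -> "RegressorSpec":
        return replace(self, mode=mode)

    def with_seed(self, seed: int) -> "RegressorSpec":
        return replace(self, seed=int(seed))


def _stable_noise(record_id: str, seed: int, sd: float) -> float:
    """Fixed per-molecule assay noise: deterministic across calls."""
    key = zlib.crc32(record_id.encode("utf8")) & 0x7FFFFFFF
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, key])
    return float(rng.normal(0.0, sd))


class _Oracle:
    """Label-reading estimator; ``sd == 0`` is the perfect oracle."""

    def __init__(self, sd: float, seed: int):
        self.sd = float(sd)
        self.seed = int(seed)

    def potency(self, rec: MoleculeRecord) -> float:
        if self.sd == 0.0:
            return rec.potency
        return rec.potency + _stable_noise(rec.id, self.seed, self.sd)


def _make_estimator(spec: RegressorSpec):
    params = spec.params
    if spec.family == "gradient_boosted_trees":
        from xgboost import XGBRegressor
        defaults = dict(random_state=spec.seed, n_jobs=1)
        defaults.update(params)
        return XGBRegressor(**defaults)
    if spec.family == "random_forest":
        from sklearn.ensemble import RandomForestRegressor
        defaults = dict(random_state=spec.seed, n_jobs=1)
        defaults.update(params)
        return RandomForestRegressor(**defaults)
    if spec.family in ("oracle_perfect", "oracle_noisy"):
        sd = params.get("noise_sd", 0.1) if spec.family == "oracle_noisy" else 0.0
        return _Oracle(sd=sd, seed=spec.seed)
    if spec.family == "dmpnn_adapter":
        return _DmpnnAdapter(spec)
    raise ValueError(spec.family)


class _DmpnnAdapter:
    """Thin adapter for the optional two-molecule message-passing network.

    Carries the published training settings; fitting requires the external
    ``chemprop`` package and raises a clear error when it is absent.
    """

    def __init__(self, spec: RegressorSpec):
        self.spec = spec
        self.settings = dict(DMPNN_DEFAULTS[spec.mode])
        self.settings.update(spec.params)
        self._backend = None

    def fit(self, smiles_cols, targets):
        try:
            import chemprop  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the dmpnn_adapter family needs the optional 'chemprop' "
                "package; install it or use a tree family"
            ) from exc
        raise NotImplementedError(
            "chemprop backend wiring is intentionally external; "
            "see DMPNN_DEFAULTS for the recorded settings"
        )


@dataclass
class FittedModel:
    """A trained regressor plus provenance for reproducibility."""

    spec: RegressorSpec
    estimator: object
    training_fingerprint_kind: str = MODEL_FP_KIND
    fit_report: Dict = field(default_factory=dict)

    def save(self, path) -> None:
        payload = {"version": MODEL_ARCHIVE_VERSION, "spec": self.spec,
                   "estimator": self.estimator,
                   "training_fingerprint_kind": self.training_fingerprint_kind,
                   "fit_report": self.fit_report}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != MODEL_ARCHIVE_VERSION:
            raise ValueError(f"unsupported model archive version: "
                             f"{payload.get('version')}")
        return cls(spec=payload["spec"], estimator=payload["estimator"],
                   training_fingerprint_kind=payload["training_fingerprint_kind"],
                   fit_report=payload["fit_report"])


def _params_snapshot(estimator) -> Dict:
    get_params = getattr(estimator, "get_params", None)
    if get_params is None:
        return {}
    return {k: v for k, v in get_params().items()
            if isinstance(v, (int, float, str, bool, type(None)))}


def fit_single(spec: RegressorSpec, train: CompoundDataset) -> FittedModel:
    """Fit a single-molecule potency regressor on the training set."""
    if spec.mode != "single":
        raise ModeMismatchError("fit_single requires mode='single'")
    if len(train) < 2:
        raise InsufficientDataError(
            f"single-molecule fit needs >= 2 records, got {len(train)}")
    t0 = time.perf_counter()
    est = _make_estimator(spec)
    if isinstance(est, _Oracle):
        pass  # oracles never fit
    else:
        X = fingerprint_matrix(train.smiles, MODEL_FP_KIND)
        est.fit(X, train.potencies)
    report = {"training_size": len(train), "pair_count": 0,
              "wall_time_s": time.perf_counter() - t0,
              "params": _params_snapshot(est)}
    return FittedModel(spec=spec, estimator=est, fit_report=report)


def fit_delta(spec: RegressorSpec, pairs: Sequence[PairExample]) -> FittedModel:
    """Fit a paired regressor on cross-merged difference-labeled pairs."""
    if spec.mode != "paired":
        raise ModeMismatchError("fit_delta requires mode='paired'")
    if len(pairs) == 0:
        raise ValueError("fit_delta requires a non-empty pair collection")
    t0 = time.perf_counter()
    est = _make_estimator(spec)
    if isinstance(est, _Oracle):
        pass
    else:
        X = paired_fingerprint_matrix(pairs, MODEL_FP_KIND)
        y = pair_deltas(pairs)
        est.fit(X, y)
    n_train = len({p.first.id for p in pairs})
    report = {"training_size": n_train, "pair_count": len(pairs),
              "wall_time_s": time.perf_counter() - t0,
              "params": _params_snapshot(est)}
    return FittedModel(spec=spec, estimator=est, fit_report=report)


def predict_single(model: FittedModel, pool: CompoundDataset) -> np.ndarray:
    """Per-molecule potency estimates, pool order preserved."""
    if model.spec.mode != "single":
        raise ModeMismatchError("predict_single requires a single-mode model")
    est = model.estimator
    if isinstance(est, _Oracle):
        return np.array([est.potency(r) for r in pool.records], dtype=float)
    X = fingerprint_matrix(pool.smiles, model.training_fingerprint_kind)
    return np.asarray(est.predict(X), dtype=float)


def predict_improvement(model: FittedModel, anchor: MoleculeRecord,
                        pool: CompoundDataset) -> np.ndarray:
    """Predicted potency improvement of each pool molecule over the anchor."""
    if model.spec.mode != "paired":
        raise ModeMismatchError("predict_improvement requires a paired-mode model")
    est = model.estimator
    if isinstance(est, _Oracle):
        return np.array(
            [est.potency(r) - est.potency(anchor) for r in pool.records],
            dtype=float)
    pairs = anchor_pairs(anchor, pool)
    X = paired_fingerprint_matrix(pairs, model.training_fingerprint_kind)
    return np.asarray(est.predict(X), dtype=float)


def predict_pairs(model: FittedModel, pairs: Sequence[PairExample]) -> np.ndarray:
    """Delta predictions for arbitrary pairs (diagnostics, held-out checks)."""
    if model.spec.mode != "paired":
        raise ModeMismatchError("predict_pairs requires a paired-mode model")
    est = model.estimator
    if isinstance(est, _Oracle):
        return np.array([est.potency(p.second) - est.potency(p.first)
                         for p in pairs], dtype=float)
    X = paired_fingerprint_matrix(pairs, model.training_fingerprint_kind)
    return np.asarray(est.predict(X), dtype=float)
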