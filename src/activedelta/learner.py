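"""The exploitative active-learning loop.

One compound is acquired per iteration. The three policies:

``activedelta``
    Train a paired delta regressor on the cross-merged training set, pair
    the current best training compound (the anchor) against every pool
    molecule, and acquire the candidate with the highest predicted
    improvement over the anchor.
``single_exploit``
    Train a single-molecule regressor on the training set and acquire the
    pool molecule with the highest predicted potency.
``random``
    Uniform draw from the pool under the repeat's seed stream.

True pool labels are hidden from the policies: predictions use only the
candidates' structures, and a compound's potency enters the training data
only after it has been acquired. Models are refit from scratch each round.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dataio import CompoundDataset, MoleculeRecord, cold_start
from .models import (FittedModel, RegressorSpec, fit_delta, fit_single,
                     predict_improvement, predict_single)
from .pairing import best_in_train, cross_merge

POLICIES = ("activedelta", "single_exploit", "random")


class PoolExhaustedError(RuntimeError):
    """The learning pool has no molecules left to acquire."""


class BudgetError(ValueError):
    """The iteration budget exceeds what the dataset can supply."""


def derive_repeat_seeds(base_seed: int, repeats: int) -> Tuple[int, ...]:
    """One independent seed per repeat from a single base seed.

    Uses a seed sequence so the repeats have non-overlapping streams; every
    derived seed stays below 2**31.
    """
    state = np.random.SeedSequence(int(base_seed)).generate_state(repeats)
    return tuple(int(s) % (2 ** 31) for s in state)


def _stage_seeds(repeat_seed: int) -> Tuple[int, int, int]:
    """Per-repeat (cold_start, policy_stream, model) seeds."""
    state = np.random.SeedSequence(int(repeat_seed)).generate_state(3)
    return tuple(int(s) % (2 ** 31) for s in state)


@dataclass(frozen=True)
class PolicyConfig:
    """Which policy, which regressor, and the run geometry.

    ``seeds`` holds one integer per repeat; when omitted they are derived
    from ``base_seed``. The regressor mode is coerced to match the policy
    (paired for activedelta, single otherwise).
    """

    policy: str = "activedelta"
    regressor: RegressorSpec = field(default_factory=RegressorSpec)
    iterations: int = 100
    repeats: int = 3
    seeds: Optional[Tuple[int, ...]] = None
    base_seed: int = 0
    include_self_pairs: bool = True

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be positive")
        wanted_mode = "paired" if self.policy == "activedelta" else "single"
        if self.regressor.mode != wanted_mode:
            object.__setattr__(self, "regressor",
                               self.regressor.with_mode(wanted_mode))
        if self.seeds is None:
            object.__setattr__(
                self, "seeds", derive_repeat_seeds(self.base_seed, self.repeats))
        elif len(self.seeds) != self.repeats:
            raise ValueError("need exactly one seed per repeat")
        else:
            object.__setattr__(self, "seeds", tuple(int(s) for s in self.seeds))


@dataclass(frozen=True)
class AcquisitionStep:
    iteration: int  # 1-based
    record: MoleculeRecord
    score: float
    anchor_id: Optional[str]
    train_size_before: int


@dataclass
class ALTrajectory:
    """Ordered log of one active-learning run.

    The training set at iteration t (before the t-th acquisition) is the
    cold start plus the first t-1 acquisitions, so its size is 2 + (t-1);
    after the final iteration the terminal training set holds
    2 + iterations records.
    """

    policy: str
    seed: int
    repeat_index: int
    cold_start_records: List[MoleculeRecord]
    steps: List[AcquisitionStep] = field(default_factory=list)
    dataset_name: str = "dataset"

    @property
    def iterations(self) -> int:
        return len(self.steps)

    @property
    def acquired_records(self) -> List[MoleculeRecord]:
        return [s.record for s in self.steps]

    @property
    def acquired_ids(self) -> List[str]:
        return [s.record.id for s in self.steps]

    def training_records(self, budget: Optional[int] = None,
                         include_cold_start: bool = True
                         ) -> List[MoleculeRecord]:
        """Cold start plus the first ``budget`` acquisitions (default all)."""
        budget = self.iterations if budget is None else budget
        if budget > self.iterations:
            raise ValueError(
                f"budget {budget} exceeds trajectory length {self.iterations}")
        recs = list(self.cold_start_records) if include_cold_start else []
        recs.extend(s.record for s in self.steps[:budget])
        return recs

    def training_dataset(self, budget: Optional[int] = None,
                         include_cold_start: bool = True) -> CompoundDataset:
        return CompoundDataset(
            records=self.training_records(budget, include_cold_start),
            role="train", name=f"{self.dataset_name}-acquired")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": [s.iteration for s in self.steps],
            "chosen_id": [s.record.id for s in self.steps],
            "chosen_smiles": [s.record.smiles for s in self.steps],
            "chosen_potency": [s.record.potency for s in self.steps],
            "score": [s.score for s in self.steps],
            "anchor_id": [s.anchor_id for s in self.steps],
            "train_size_before": [s.train_size_before for s in self.steps],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> str:
        pot = [s.record.potency for s in self.steps]
        lines = [
            f"policy={self.policy} repeat={self.repeat_index} seed={self.seed}",
            f"iterations={self.iterations} terminal_train_size="
            f"{2 + self.iterations}",
        ]
        if pot:
            lines.append(f"best_acquired_potency={max(pot):.4g} "
                         f"mean_acquired_potency={float(np.mean(pot)):.4g}")
        return "\n".join(lines)


def _fit_policy_model(config: PolicyConfig, train: CompoundDataset,
                      model_seed: int) -> Optional[FittedModel]:
    spec = config.regressor.with_seed(model_seed)
    if config.policy == "activedelta":
        pairs = cross_merge(train, include_self_pairs=config.include_self_pairs)
        return fit_delta(spec, pairs)
    if config.policy == "single_exploit":
        return fit_single(spec, train)
    return None  # random policy fits nothing


def _argmax_first(scores: np.ndarray) -> int:
    """Index of the maximum; ties break to the earliest pool position."""
    return int(np.argmax(scores))


def acquire_next(config: PolicyConfig, train: CompoundDataset,
                 pool: CompoundDataset, rng: Optional[np.random.Generator] = None,
                 model_seed: Optional[int] = None
                 ) -> Tuple[MoleculeRecord, float, Optional[MoleculeRecord]]:
    """Select the next compound to acquire from the pool.

    Returns (chosen record, its selection score, anchor used — None unless
    the policy is activedelta). The chosen compound's true potency plays no
    role in the selection; it is revealed only once the caller moves the
    record into the training set.
    """
    if len(pool) == 0:
        raise PoolExhaustedError("learning pool is empty")
    if config.policy == "random":
        rng = rng if rng is not None else np.random.default_rng(config.base_seed)
        idx = int(rng.integers(len(pool)))
        return pool.records[idx], float("nan"), None
    seed = model_seed if model_seed is not None else config.regressor.seed
    model = _fit_policy_model(config, train, seed)
    if config.policy == "activedelta":
        anchor = best_in_train(train)
        scores = predict_improvement(model, anchor, pool)
        idx = _argmax_first(scores)
        return pool.records[idx], float(scores[idx]), anchor
    scores = predict_single(model, pool)
    idx = _argmax_first(scores)
    return pool.records[idx], float(scores[idx]), None


def run_active_learning(config: PolicyConfig, ds_train: CompoundDataset,
                        repeat_index: int = 0) -> ALTrajectory:
    """Run one full repeat: cold start, then iterate refit + acquire-one.

    Fully determined by (config, dataset, repeat seed) for deterministic
    model families. Acquired molecules leave the pool permanently.
    """
    if not 0 <= repeat_index < config.repeats:
        raise ValueError(f"repeat_index {repeat_index} out of range")
    if config.iterations > len(ds_train) - 2:
        raise BudgetError(
            f"iterations={config.iterations} exceeds |dataset|-2="
            f"{len(ds_train) - 2}")
    repeat_seed = config.seeds[repeat_index]
    cold_seed, policy_seed, model_seed = _stage_seeds(repeat_seed)
    train, pool = cold_start(ds_train, cold_seed)
    rng = np.random.default_rng(policy_seed)

    traj = ALTrajectory(policy=config.policy, seed=repeat_seed,
                        repeat_index=repeat_index,
                        cold_start_records=list(train.records),
                        dataset_name=ds_train.name)
    for t in range(1, config.iterations + 1):
        chosen, score, anchor = acquire_next(config, train, pool, rng=rng,
                                             model_seed=model_seed)
        traj.steps.append(AcquisitionStep(
            iteration=t, record=chosen, score=score,
            anchor_id=None if anchor is None else anchor.id,
            train_size_before=len(train)))
        train = train.with_records(train.records + [chosen])
        pool = pool.with_records([r for r in pool.records if r.id != chosen.id])
    return traj


def run_repeats(config: PolicyConfig, ds_train: CompoundDataset
                ) -> List[ALTrajectory]:
    """All repeats of one policy, each with its own starting pair."""
    return [run_active_learning(config, ds_train, i)
            for i in range(config.repeats)]


def evaluate_on_test(config: PolicyConfig, trajectory: ALTrajectory,
                     test: CompoundDataset, budget: int,
                     include_cold_start: bool = True) -> np.ndarray:
    """Score external test molecules with a model trained on the acquired set.

    Refits the policy's regressor on the cold start plus the first
    ``budget`` acquisitions. Under activedelta the test molecules are
    ranked by predicted improvement over the final training-set best (the
    external-data anchor is not otherwise defined); under the other
    policies by predicted potency. Random-policy runs are scored with a
    single-molecule model of the configured family, since random selection
    itself carries no model. The returned vector supports top-decile
    ranking of the test set.
    """
    if budget > trajectory.iterations:
        raise ValueError(f"budget {budget} exceeds trajectory length "
                         f"{trajectory.iterations}")
    train = trajectory.training_dataset(budget, include_cold_start)
    _, _, model_seed = _stage_seeds(trajectory.seed)
    if config.policy == "activedelta":
        spec = config.regressor.with_mode("paired").with_seed(model_seed)
        model = fit_delta(spec, cross_merge(
            train, include_self_pairs=config.include_self_pairs))
        anchor = best_in_train(train)
        return predict_improvement(model, anchor, test)
    spec = config.regressor.with_mode("single").with_seed(model_seed)
    model = fit_single(spec, train)
    return predict_single(model, test)
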