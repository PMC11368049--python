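"""Evaluation suite: hit retrieval, scaffold diversity, similarity windows,
chemical-space embedding with jump/stay counts, and paired significance
tests.

A "hit" is a compound in the top ten percentile of most potent molecules of
a reference set (hit-set size ceil(0.1 N), threshold ties broken by dataset
position so the size is exact). Retrieval curves report the fraction of
hits held after each acquisition, counting cold-start hits at t = 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .chem import (ACYCLIC_SCAFFOLD, FP_KINDS, fingerprint_matrix,
                   murcko_scaffold, nearest_neighbor_similarity)
from .dataio import CompoundDataset, MoleculeRecord
from .learner import ALTrajectory

#: Iteration windows used for the early-phase similarity analysis.
DEFAULT_SIMILARITY_WINDOWS = ((1, 15), (16, 30), (31, 45))

#: Fixed, manifest-recorded clustering parameters for jump/stay analysis.
CLUSTERING_PARAMS = {"method": "dbscan", "eps": 5.0, "min_samples": 4}

#: Fixed t-SNE settings (qualitative use only; the embedding is stochastic
#: across seeds by nature).
TSNE_PARAMS = {"perplexity": 30.0, "max_iter": 1000, "init": "pca"}

PCA_COMPONENTS = 50


@dataclass(frozen=True)
class HitSet:
    """Top-ten-percentile most potent molecules of a reference dataset."""

    ids: Tuple[str, ...]
    threshold: float

    def __contains__(self, mol_id: str) -> bool:
        return mol_id in set(self.ids)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class RetrievalCurve:
    """Fraction of the hit set held after t acquisitions, t = 0..T."""

    values: np.ndarray  # length T+1, values[0] = cold-start fraction

    def at(self, t: int) -> float:
        return float(self.values[t])

    def final(self) -> float:
        return float(self.values[-1])


@dataclass
class TrajectoryEmbedding:
    """2-D chemical-space coordinates plus cluster labels, by molecule id."""

    coords: Dict[str, np.ndarray]
    clusters: Dict[str, int] = field(default_factory=dict)
    params: Dict = field(default_factory=dict)


@dataclass
class ComparisonResult:
    """Paired two-strategy comparison across datasets."""

    statistic: float
    p_value: float
    mean_difference: float
    sd_difference: float
    se_difference: float
    n: int
    degenerate: bool = False

    def summary(self) -> str:
        tag = " (degenerate: all paired differences zero)" if self.degenerate else ""
        return (f"Wilcoxon signed-rank W={self.statistic:.4g}, "
                f"p={self.p_value:.3g}, mean diff={self.mean_difference:.4g} "
                f"± {self.sd_difference:.4g} (SD), SE={self.se_difference:.4g}, "
                f"n={self.n}{tag}")


def top_decile(ds: CompoundDataset) -> HitSet:
    """The ceil(0.1 N) most potent molecules; threshold ties break to the
    earliest dataset position so the set size is exact."""
    n = len(ds)
    if n < 10:
        raise ValueError(f"top decile needs >= 10 records, got {n}")
    k = math.ceil(0.1 * n)
    # stable sort on descending potency keeps dataset order within ties
    order = np.argsort(-ds.potencies, kind="stable")[:k]
    members = [ds.records[int(i)] for i in order]
    threshold = min(m.potency for m in members)
    return HitSet(ids=tuple(m.id for m in members), threshold=threshold)


def retrieval_curve(trajectory: ALTrajectory, hits: HitSet) -> RetrievalCurve:
    """Per-iteration hit-retrieval fractions, cold-start hits at t = 0."""
    hit_ids = set(hits.ids)
    held = {r.id for r in trajectory.cold_start_records} & hit_ids
    values = [len(held) / len(hit_ids)]
    for step in trajectory.steps:
        if step.record.id in hit_ids:
            held.add(step.record.id)
        values.append(len(held) / len(hit_ids))
    return RetrievalCurve(values=np.asarray(values, dtype=float))


def _scaffold_key(smiles: str) -> str:
    scaf = murcko_scaffold(smiles)
    return scaf.smiles if not scaf.is_acyclic else ACYCLIC_SCAFFOLD


def scaffold_diversity(selected: Sequence[MoleculeRecord],
                       hits: Optional[HitSet] = None,
                       reference: Optional[CompoundDataset] = None
                       ) -> Tuple[int, float]:
    """Unique Murcko scaffolds among selected molecules.

    With ``hits`` given, only selected molecules that are hits count, and
    the fraction is relative to the unique scaffolds among *all* hits in
    ``reference`` (which must then be supplied). Without ``hits`` the count
    covers all selected molecules and the fraction is NaN. Acyclic
    molecules share one sentinel scaffold class.
    """
    if hits is not None:
        hit_ids = set(hits.ids)
        chosen = [r for r in selected if r.id in hit_ids]
        count = len({_scaffold_key(r.smiles) for r in chosen}) if chosen else 0
        if reference is None:
            return count, float("nan")
        all_hits = [r for r in reference.records if r.id in hit_ids]
        denom = len({_scaffold_key(r.smiles) for r in all_hits})
        return count, (count / denom if denom else float("nan"))
    count = len({_scaffold_key(r.smiles) for r in selected}) if selected else 0
    return count, float("nan")


def similarity_windows(trajectory: ALTrajectory,
                       windows: Sequence[Tuple[int, int]] = DEFAULT_SIMILARITY_WINDOWS,
                       kinds: Sequence[str] = FP_KINDS) -> pd.DataFrame:
    """Mean nearest-neighbor similarity of each acquisition to the training
    set as it stood at acquisition time (the acquisition itself excluded),
    averaged within iteration windows, per fingerprint kind.

    Returns a tidy frame (window, kind, mean_similarity, n_iterations).
    """
    max_needed = max(hi for _, hi in windows)
    if trajectory.iterations < max_needed:
        raise ValueError(f"trajectory has {trajectory.iterations} iterations; "
                         f"windows need {max_needed}")
    # training set before iteration t = cold start + acquisitions < t
    rows = []
    for lo, hi in windows:
        sims: Dict[str, List[float]] = {k: [] for k in kinds}
        for t in range(lo, hi + 1):
            train_before = (trajectory.cold_start_records
                            + [s.record for s in trajectory.steps[: t - 1]])
            acquired = trajectory.steps[t - 1].record
            # the training snapshot predates the acquisition, so the
            # acquired molecule can never be its own neighbor here
            for kind in kinds:
                sims[kind].append(nearest_neighbor_similarity(
                    acquired.smiles, train_before, kind=kind))
        for kind in kinds:
            rows.append({"window": f"{lo}-{hi}", "kind": kind,
                         "mean_similarity": float(np.mean(sims[kind])),
                         "n_iterations": hi - lo + 1})
    return pd.DataFrame(rows)


def embed_chemical_space(molecules: CompoundDataset, seed: int,
                         cluster: bool = True) -> TrajectoryEmbedding:
    """Morgan fingerprints -> 50 principal components -> 2-D t-SNE map,
    with optional density-based cluster labels for jump/stay analysis.

    Datasets of 50 molecules or fewer skip the PCA stage (warned): there
    are not enough samples to support 50 components.
    """
    from sklearn.cluster import DBSCAN
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    n = len(molecules)
    X = fingerprint_matrix(molecules.smiles, "morgan_r2_2048").astype(float)
    params = {"pca_components": PCA_COMPONENTS, "seed": int(seed),
              **TSNE_PARAMS, "clustering": CLUSTERING_PARAMS}
    if n > PCA_COMPONENTS:
        X = PCA(n_components=PCA_COMPONENTS,
                random_state=seed).fit_transform(X)
    else:
        warnings.warn(f"{n} molecules <= {PCA_COMPONENTS}: skipping PCA stage")
        params["pca_components"] = None
    perplexity = min(TSNE_PARAMS["perplexity"], max(2.0, (n - 1) / 3.0))
    coords = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                  max_iter=TSNE_PARAMS["max_iter"],
                  init=TSNE_PARAMS["init"]).fit_transform(X)
    params["perplexity"] = perplexity
    emb = TrajectoryEmbedding(
        coords={mid: coords[i] for i, mid in enumerate(molecules.ids)},
        params=params)
    if cluster:
        labels = DBSCAN(eps=CLUSTERING_PARAMS["eps"],
                        min_samples=CLUSTERING_PARAMS["min_samples"]
                        ).fit_predict(coords)
        # noise points become singleton clusters so every molecule is labeled
        next_label = int(labels.max()) + 1 if labels.size else 0
        final = []
        for lab in labels:
            if lab == -1:
                final.append(next_label)
                next_label += 1
            else:
                final.append(int(lab))
        emb.clusters = {mid: final[i] for i, mid in enumerate(molecules.ids)}
    return emb


def jump_stay(embedding: TrajectoryEmbedding, trajectory: ALTrajectory,
              window: Tuple[int, int]) -> Tuple[int, int]:
    """Count cluster jumps vs stays over consecutive acquisitions in the
    window (1-based, inclusive). jumps + stays = window length - 1."""
    lo, hi = window
    if not 1 <= lo <= hi <= trajectory.iterations:
        raise ValueError(f"window {window} outside trajectory "
                         f"(1..{trajectory.iterations})")
    ids = [trajectory.steps[t - 1].record.id for t in range(lo, hi + 1)]
    try:
        labels = [embedding.clusters[i] for i in ids]
    except KeyError as exc:
        raise ValueError(f"molecule {exc} has no cluster label") from exc
    jumps = sum(1 for a, b in zip(labels, labels[1:]) if a != b)
    stays = len(labels) - 1 - jumps
    return jumps, stays


def compare_strategies(per_dataset_a: Sequence[float],
                       per_dataset_b: Sequence[float]) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-dataset values,
    plus the mean ± SD and SE of the differences (a - b). Zero differences
    are dropped per the standard convention; an all-zero comparison is
    degenerate and reported with p = 1."""
    a = np.asarray(per_dataset_a, dtype=float)
    b = np.asarray(per_dataset_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = a - b
    n = len(diffs)
    mean = float(np.mean(diffs)) if n else float("nan")
    sd = float(np.std(diffs, ddof=1)) if n > 1 else 0.0
    se = sd / math.sqrt(n) if n else float("nan")
    if np.all(diffs == 0):
        return ComparisonResult(statistic=0.0, p_value=1.0, mean_difference=mean,
                                sd_difference=sd, se_difference=se, n=n,
                                degenerate=True)
    stat, p = stats.wilcoxon(a, b, zero_method="wilcox",
                             alternative="two-sided")
    return ComparisonResult(statistic=float(stat), p_value=float(p),
                            mean_difference=mean, sd_difference=sd,
                            se_difference=se, n=n)


def evaluation_report(trajectories: Dict[str, Sequence[ALTrajectory]],
                      reference: CompoundDataset,
                      checkpoints: Sequence[int] = (50,)) -> pd.DataFrame:
    """Tidy cross-policy report: one row per policy x repeat x metric.

    Metrics: hit-retrieval fraction at each checkpoint, unique hit
    scaffolds and their fraction, and unique scaffolds over all selected
    molecules.
    """
    hits = top_decile(reference)
    rows = []
    for policy, trajs in trajectories.items():
        for traj in trajs:
            curve = retrieval_curve(traj, hits)
            selected = traj.training_records()
            n_scaf_hits, frac_scaf = scaffold_diversity(selected, hits,
                                                        reference)
            n_scaf_all, _ = scaffold_diversity(selected)
            for t in checkpoints:
                rows.append({"policy": policy, "repeat": traj.repeat_index,
                             "metric": f"hit_fraction@{t}",
                             "value": curve.at(min(t, traj.iterations))})
            rows.append({"policy": policy, "repeat": traj.repeat_index,
                         "metric": "hit_scaffolds", "value": n_scaf_hits})
            rows.append({"policy": policy, "repeat": traj.repeat_index,
                         "metric": "hit_scaffold_fraction", "value": frac_scaf})
            rows.append({"policy": policy, "repeat": traj.repeat_index,
                         "metric": "selected_scaffolds", "value": n_scaf_all})
    return pd.DataFrame(rows)
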