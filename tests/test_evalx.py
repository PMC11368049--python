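"""Evaluation metrics against brute-force and closed-form oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from activedelta import (HitSet, compare_strategies, embed_chemical_space,
                         jump_stay, retrieval_curve, run_active_learning,
                         scaffold_diversity, similarity_windows, top_decile,
                         nearest_neighbor_similarity, PolicyConfig,
                         RegressorSpec)
from activedelta.evalx import TrajectoryEmbedding
from activedelta.learner import ALTrajectory, AcquisitionStep

from conftest import make_dataset, make_records


def brute_force_top_decile_ids(ds):
    k = math.ceil(0.1 * len(ds))
    ranked = sorted(range(len(ds)),
                    key=lambda i: (-ds.records[i].potency, i))
    return [ds.records[i].id for i in ranked[:k]]


def exact_signed_rank_p(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns
    (valid for tie-free, zero-free differences)."""
    d = np.asarray(diffs, dtype=float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = np.array([0.0])
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    p_le = np.mean(sums <= w_obs)
    p_ge = np.mean(sums >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def make_trajectory(cold, steps_potencies, policy="random"):
    cold_records = make_records(cold, prefix="c")
    step_records = make_records(steps_potencies, prefix="s")
    steps = [AcquisitionStep(iteration=t + 1, record=r, score=float("nan"),
                             anchor_id=None, train_size_before=2 + t)
             for t, r in enumerate(step_records)]
    return ALTrajectory(policy=policy, seed=0, repeat_index=0,
                        cold_start_records=cold_records, steps=steps)


class TestTopDecile:
    @pytest.mark.parametrize("n,expected", [(100, 10), (95, 10), (10, 1)])
    def test_hit_set_size_is_ceil_ten_percent(self, n, expected):
        ds = make_dataset(np.arange(n))
        assert len(top_decile(ds)) == expected

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(5)
        for n in (10, 17, 50, 123, 500):
            ds = make_dataset(rng.normal(size=n))
            assert sorted(top_decile(ds).ids) == \
                sorted(brute_force_top_decile_ids(ds))

    def test_threshold_ties_break_by_position(self):
        # three-way tie at the threshold; only the earliest fills the set
        ds = make_dataset([9, 5, 5, 5] + [1] * 16)
        hits = top_decile(ds)
        assert list(hits.ids) == ["m0", "m1"]

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            top_decile(make_dataset(range(9)))


class TestRetrievalCurve:
    def test_cold_start_hits_count_at_t0(self):
        traj = make_trajectory([10.0, 0.0], [1.0, 2.0])
        hits = HitSet(ids=("c0", "s1"), threshold=2.0)
        curve = retrieval_curve(traj, hits)
        np.testing.assert_allclose(curve.values, [0.5, 0.5, 1.0])

    def test_exhaustion_reaches_one(self, tiny_library):
        cfg = PolicyConfig(policy="random",
                           regressor=RegressorSpec(family="oracle_perfect"),
                           iterations=len(tiny_library) - 2, base_seed=0)
        traj = run_active_learning(cfg, tiny_library, 0)
        curve = retrieval_curve(traj, top_decile(tiny_library))
        assert curve.final() == 1.0

    def test_monotone_and_bounded(self, tiny_library):
        for policy in ("random", "activedelta"):
            cfg = PolicyConfig(policy=policy,
                               regressor=RegressorSpec(
                                   family="oracle_noisy",
                                   hyperparams={"noise_sd": 2.0}),
                               iterations=20, base_seed=8)
            curve = retrieval_curve(
                run_active_learning(cfg, tiny_library, 0),
                top_decile(tiny_library))
            assert np.all(np.diff(curve.values) >= 0)
            assert np.all((curve.values >= 0) & (curve.values <= 1))


class TestScaffoldDiversity:
    def test_analog_series_counts_one_scaffold(self):
        analogs = make_records([1, 2, 3],
                               smiles=["Cc1ccccc1", "CCc1ccccc1",
                                       "CCCc1ccccc1"])
        count, _ = scaffold_diversity(analogs)
        assert count == 1

    def test_selecting_all_hits_gives_fraction_one(self, tiny_library):
        hits = top_decile(tiny_library)
        selected = [r for r in tiny_library if r.id in set(hits.ids)]
        count, frac = scaffold_diversity(selected, hits, tiny_library)
        assert frac == 1.0

    def test_hand_enumerated_toy(self):
        smiles = ["Cc1ccccc1", "CCc1ccccc1",          # benzene x2
                  "Cc1ccncc1",                        # pyridine
                  "CCO", "CCCO",                      # acyclic (one class)
                  "C1CCCCC1", "CC1CCCCC1",            # cyclohexane x2
                  "c1ccc2ccccc2c1"]                   # naphthalene
        recs = make_records(range(8), smiles=smiles)
        count, _ = scaffold_diversity(recs)
        assert count == 5  # benzene, pyridine, acyclic, cyclohexane, naphthalene

    def test_count_monotone_in_selection(self, tiny_library):
        counts = [scaffold_diversity(tiny_library.records[:k])[0]
                  for k in range(1, len(tiny_library) + 1)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestSimilarityWindows:
    def test_duplicate_acquisitions_score_one(self):
        cold = make_records([1.0, 2.0], smiles=["CCO", "CCN"])
        # acquisitions structurally identical to a training compound
        steps = make_records([3.0] * 6, smiles=["OCC"] * 6, prefix="s")
        traj = ALTrajectory(
            policy="random", seed=0, repeat_index=0,
            cold_start_records=cold,
            steps=[AcquisitionStep(iteration=t + 1, record=r, score=0.0,
                                   anchor_id=None, train_size_before=2 + t)
                   for t, r in enumerate(steps)])
        tab = similarity_windows(traj, windows=[(1, 3), (4, 6)],
                                 kinds=["morgan_r2_2048"])
        np.testing.assert_allclose(tab["mean_similarity"], 1.0)
        assert set(tab["n_iterations"]) == {3}

    def test_matches_brute_force_recomputation(self, tiny_library):
        cfg = PolicyConfig(policy="random",
                           regressor=RegressorSpec(family="oracle_perfect"),
                           iterations=10, base_seed=2)
        traj = run_active_learning(cfg, tiny_library, 0)
        tab = similarity_windows(traj, windows=[(1, 10)],
                                 kinds=["morgan_r2_2048"])
        sims = []
        train = [r.smiles for r in traj.cold_start_records]
        for step in traj.steps:
            sims.append(nearest_neighbor_similarity(step.record.smiles,
                                                    train))
            train.append(step.record.smiles)
        assert tab["mean_similarity"].iloc[0] == pytest.approx(np.mean(sims))

    def test_window_beyond_trajectory_rejected(self, tiny_library):
        cfg = PolicyConfig(policy="random",
                           regressor=RegressorSpec(family="oracle_perfect"),
                           iterations=5, base_seed=2)
        traj = run_active_learning(cfg, tiny_library, 0)
        with pytest.raises(ValueError):
            similarity_windows(traj, windows=[(1, 15)])


class TestEmbedding:
    def test_two_coordinates_deterministic_and_duplicates_coincide(
            self, small_library):
        emb1 = embed_chemical_space(small_library, seed=0)
        emb2 = embed_chemical_space(small_library, seed=0)
        assert all(v.shape == (2,) for v in emb1.coords.values())
        for mid in small_library.ids:
            np.testing.assert_array_equal(emb1.coords[mid], emb2.coords[mid])
        assert set(emb1.clusters) == set(small_library.ids)

    def test_small_dataset_skips_pca_with_warning(self, tiny_library):
        with pytest.warns(UserWarning, match="skipping PCA"):
            emb = embed_chemical_space(tiny_library, seed=1)
        assert emb.params["pca_components"] is None


class TestJumpStay:
    def _embedding_with_labels(self, labels):
        return TrajectoryEmbedding(
            coords={f"s{i}": np.zeros(2) for i in range(len(labels))},
            clusters={f"s{i}": lab for i, lab in enumerate(labels)})

    def test_direct_count(self):
        traj = make_trajectory([0, 0], [1, 2, 3, 4, 5])
        emb = self._embedding_with_labels([1, 1, 2, 2, 3])
        assert jump_stay(emb, traj, (1, 5)) == (2, 2)

    def test_all_same_cluster(self):
        traj = make_trajectory([0, 0], [1] * 7)
        emb = self._embedding_with_labels([4] * 7)
        assert jump_stay(emb, traj, (1, 7)) == (0, 6)

    def test_conservation_under_random_labels(self):
        rng = np.random.default_rng(3)
        k = 200
        traj = make_trajectory([0, 0], list(range(k)))
        labels = rng.integers(0, 2, size=k).tolist()
        emb = self._embedding_with_labels(labels)
        jumps, stays = jump_stay(emb, traj, (1, k))
        assert jumps + stays == k - 1
        # two equiprobable clusters: jumps ~ Binomial(k-1, 1/2)
        assert abs(jumps - (k - 1) / 2) < 4 * math.sqrt((k - 1) / 4)

    def test_unlabeled_molecule_rejected(self):
        traj = make_trajectory([0, 0], [1, 2])
        emb = self._embedding_with_labels([1])
        with pytest.raises(ValueError, match="cluster label"):
            jump_stay(emb, traj, (1, 2))


class TestCompareStrategies:
    def test_identical_vectors_degenerate(self):
        res = compare_strategies([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0

    def test_hand_computed_n6_statistic(self):
        # diffs = [1, -2, 3, -4, 5, 6]; |d| ranks are 1..6
        # W+ = 1+3+5+6 = 15, W- = 2+4 = 6; reported statistic = min = 6
        a = np.array([1.0, 0.0, 3.0, 0.0, 5.0, 6.0])
        b = np.array([0.0, 2.0, 0.0, 4.0, 0.0, 0.0])
        res = compare_strategies(a, b)
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(exact_signed_rank_p(a - b))

    def test_uniform_dominance_matches_exact_tail(self):
        # every difference positive with distinct magnitudes: the most
        # extreme signed-rank table; two-sided p is twice the single
        # sign-pattern mass 2^-n
        n = 20
        b = np.linspace(0, 1, n)
        shifts = 1.0 + np.arange(n) / 100.0
        res = compare_strategies(b + shifts, b)
        assert res.p_value == pytest.approx(2 * 0.5 ** n, rel=1e-6)
        assert res.mean_difference == pytest.approx(float(np.mean(shifts)))

    @pytest.mark.parametrize("n", [4, 7, 10, 12])
    def test_matches_exact_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        res = compare_strategies(a, b)
        assert res.p_value == pytest.approx(exact_signed_rank_p(a - b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_strategies([1.0], [1.0, 2.0])
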