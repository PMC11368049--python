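# activedelta

Exploitative active learning on molecular pairs, for computational
chemists benchmarking compound-prioritization strategies in the low-data
regime of early drug-discovery projects.

## What it does

Greedy (exploitative) active learning trains a potency regressor on the
few compounds labeled so far and acquires the pool compound with the
highest predicted potency — which tends to exploit analogs of the best
compound already found. The paired strategy implemented here instead:

1. **cross-merges** the n training compounds into all n² ordered pairs
   (i, j), labeled with the potency difference Δy = y_j − y_i, and trains
   a regressor on concatenated pair fingerprints to predict Δy — a
   combinatorial expansion of tiny training sets in which constant assay
   offsets cancel exactly;
2. **acquires by predicted improvement**: the current best training
   compound (the anchor) is paired with every pool candidate, and the
   candidate with the largest predicted improvement over the anchor is
   acquired, one compound per iteration, retraining from scratch each
   round.

The package provides this policy plus single-molecule and random
baselines over a uniform regressor interface (XGBoost and random-forest
on Morgan fingerprints, test oracles, and an optional adapter slot for a
two-molecule message-passing network), the active-learning driver with a
two-compound cold start and fully seeded repeats, and an evaluation suite:
top-decile hit retrieval, Bemis–Murcko scaffold diversity,
nearest-neighbor similarity windows, PCA→t-SNE chemical-space trajectories
with cluster jump/stay counts, and paired Wilcoxon signed-rank
comparisons. A fragment-grammar simulator generates valid, scaffold-diverse
SMILES libraries with a learnable linear-in-fingerprint potency landscape
so everything is testable offline; real compound CSVs (SMILES + K_i or
pK_i, optionally with fixed train/test splits) load directly.

## Worked example

```python
import numpy as np
from activedelta import (LandscapeSpec, PolicyConfig, RegressorSpec,
                         generate_split, retrieval_curve,
                         run_active_learning, scaffold_diversity, top_decile)

train, test = generate_split(LandscapeSpec(library_size=150, noise_sd=0.3,
                                           seed=42))
hits = top_decile(train)
print(f"train={len(train)} test={len(test)} hits={len(hits)} "
      f"threshold={hits.threshold:.2f}")
for policy in ("activedelta", "single_exploit", "random"):
    cfg = PolicyConfig(policy=policy,
                       regressor=RegressorSpec(family="gradient_boosted_trees"),
                       iterations=30, repeats=3, base_seed=42)
    fracs, scafs = [], []
    for i in range(3):
        traj = run_active_learning(cfg, train, i)
        fracs.append(retrieval_curve(traj, hits).final())
        scafs.append(scaffold_diversity(traj.training_records(), hits,
                                        train)[0])
    print(f"{policy:>14}: hit fraction @30 = {np.mean(fracs):.3f} "
          f"(repeats: {', '.join(f'{f:.2f}' for f in fracs)}), "
          f"hit scaffolds = {np.mean(scafs):.1f}")
```

prints

```
train=120 test=30 hits=12 threshold=8.17
   activedelta: hit fraction @30 = 0.556 (repeats: 0.50, 0.50, 0.67), hit scaffolds = 6.0
single_exploit: hit fraction @30 = 0.611 (repeats: 0.58, 0.50, 0.75), hit scaffolds = 6.0
        random: hit fraction @30 = 0.361 (repeats: 0.33, 0.33, 0.42), hit scaffolds = 4.3
```

Each line is the fraction of the training pool's top-decile hits (12 of
120 compounds, pK-like threshold 8.17) acquired after 30 iterations,
averaged over three repeats with distinct random starting pairs, plus the
number of distinct Murcko scaffolds among the acquired hits. Both
model-guided policies leave random selection far behind; at this very
small budget the single-molecule baseline can still edge out the paired
policy, which needs a few more iterations of pair data before its
combinatorial expansion pays off (at 50 iterations on the standard
300-molecule conditions the paired policy leads — see the reproduction
script below).

The same run from a shell:

```sh
activedelta simulate --size 150 --seed 42 --out fixture.csv
activedelta run --dataset fixture.csv --policy activedelta --family gbt \
    --iterations 30 --repeats 3 --seed 42 --out runs/
activedelta evaluate --runs runs/ --dataset fixture.csv --checkpoints 30
```

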