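#!/usr/bin/env python
"""Re-run the hit-retrieval comparison on an external benchmark collection.

Given a directory of compound CSVs (one dataset per file, columns SMILES /
potency, optionally a split column marking the fixed train/test partition),
this harness runs paired (activedelta) and single-molecule exploitative
active learning with the gradient-boosted-tree family on every dataset,
records per-dataset hit-retrieval fractions at the chosen iteration count,
and reports the paired Wilcoxon signed-rank comparison. The qualitative
expectation is that the paired policy retrieves at least as many hits as
the single-molecule baseline at 100 iterations.

This is a long-running batch tool intended for the public K_i benchmark
collection; nothing in the package's test suite depends on it.

Usage:
    python scripts/benchmark_external.py --data-dir <dir> \
        [--iterations 100] [--repeats 3] [--seed 0] [--out results.csv] \
        [--log-transform]
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from activedelta import (PolicyConfig, RegressorSpec, compare_strategies,
                         load_dataset, load_precomputed_split,
                         retrieval_curve, run_active_learning, top_decile)


def run_dataset(path: Path, args) -> dict:
    try:
        train, _ = load_precomputed_split(path, smiles_col=args.smiles_col,
                                          potency_col=args.potency_col,
                                          log_transform=args.log_transform)
    except KeyError:
        train = load_dataset(path, smiles_col=args.smiles_col,
                             potency_col=args.potency_col,
                             log_transform=args.log_transform)
    iters = min(args.iterations, len(train) - 2)
    if iters < 1 or len(train) < 10:
        return {}
    hits = top_decile(train)
    row = {"dataset": path.stem, "n_train": len(train),
           "iterations": iters}
    for label, policy in (("activedelta", "activedelta"),
                          ("single", "single_exploit")):
        cfg = PolicyConfig(policy=policy,
                           regressor=RegressorSpec(
                               family="gradient_boosted_trees"),
                           iterations=iters, repeats=args.repeats,
                           base_seed=args.seed)
        fracs = [retrieval_curve(run_active_learning(cfg, train, i),
                                 hits).final()
                 for i in range(args.repeats)]
        row[f"{label}_hit_fraction"] = float(np.mean(fracs))
    return row


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        description=__doc__,
        formatter_class=argparse.RawDescriptionHelpFormatter)
    parser.add_argument("--data-dir", required=True,
                        help="directory of per-dataset compound CSVs")
    parser.add_argument("--iterations", type=int, default=100)
    parser.add_argument("--repeats", type=int, default=3)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--smiles-col", default="SMILES")
    parser.add_argument("--potency-col", default="potency")
    parser.add_argument("--log-transform", action="store_true",
                        help="treat potency values as raw K_i")
    parser.add_argument("--out", default="external_benchmark.csv")
    args = parser.parse_args(argv)

    rows = []
    for path in sorted(Path(args.data_dir).glob("*.csv")):
        row = run_dataset(path, args)
        if row:
            rows.append(row)
            print(f"{row['dataset']}: activedelta="
                  f"{row['activedelta_hit_fraction']:.3f} single="
                  f"{row['single_hit_fraction']:.3f}")
    if not rows:
        print("no usable datasets found")
        return 1
    df = pd.DataFrame(rows)
    df.to_csv(args.out, index=False)
    res = compare_strategies(df["activedelta_hit_fraction"],
                             df["single_hit_fraction"])
    print(res.summary())
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
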