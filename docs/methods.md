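# Methods

## The problem and the approach

Exploitative active learning for potency optimization iterates: train a
regressor on the labeled compounds collected so far, score every unlabeled
compound in the learning pool, acquire the single best-scoring one, reveal
its label, retrain. In early project stages the training set is tiny (here
it starts at two compounds), which starves conventional single-molecule
models and biases greedy selection toward analogs of the best compound
found so far.

The paired (delta) strategy implemented here changes both the training
representation and the acquisition rule:

1. **Cross-merge.** The n training compounds are expanded into all n²
   ordered pairs (i, j), each labeled with the potency difference
   Δy = y_j − y_i. Training on pairs grows the training data
   quadratically and makes the learning target a *difference*, so any
   constant assay offset cancels exactly (the package asserts this
   bitwise for exactly representable potencies).
2. **Anchor acquisition.** At each iteration the most potent training
   compound (the anchor, ties to the earliest training position) is
   paired against every pool compound; the delta model predicts each
   candidate's improvement over the anchor, and the candidate with the
   largest predicted improvement is acquired.

The single-molecule baseline trains on individual fingerprints and
acquires the argmax of predicted absolute potency; the random baseline
draws uniformly from the pool.

## Conventions and assumptions

- **Potency orientation.** Larger value = more potent throughout. The
  loader's `log_transform` maps raw binding constants K_i to
  pK_i = −log10(K_i); log-scale modeling is the default recommendation
  since potency differences are most meaningful on the log scale.
- **Chemical identity** is the RDKit canonical SMILES; duplicate removal,
  self-pair detection and nearest-neighbor self-exclusion all operate on
  the canonical form. Duplicates keep the first occurrence.
- **Pair direction** is fixed as (first = reference, second = candidate),
  delta = second − first, shared by training and prediction; there is no
  post-hoc symmetrization of (a, b) and (b, a) predictions.
- **Self-pairs are included** in the cross-merge (n² pairs, not n(n−1)),
  providing exact zero-delta anchoring examples; `include_self_pairs=False`
  is available for ablation.
- **Model features** are Morgan fingerprints (radius 2, 2048 bits);
  paired mode concatenates the two fingerprints (4096 features). MACCS
  keys (167 bits) and hashed atom-pair fingerprints (2048 bits) are used
  only in similarity analyses.
- **Models are refit from scratch each iteration** — the protocol
  retrains on the grown set every round, so no warm starting.
- **Tree families use library defaults** (XGBoost and scikit-learn
  random-forest regressors, seeded, single-threaded); resolved parameters
  are snapshotted into each fit report. The two-molecule message-passing
  network is an optional adapter that records its published settings
  (paired: 5 epochs, single: 50 epochs, aggregation "sum") and requires
  the external `chemprop` package.
- **Acquisition is strictly label-blind:** a compound's potency enters
  the system only after acquisition. A dedicated test corrupts the labels
  of never-acquired molecules and asserts the trajectory is unchanged.
- **Ties at the acquisition argmax** break to the earliest pool position;
  acquired compounds leave the pool permanently; exactly one compound is
  acquired per iteration (no batching).
- **Anchor update** recomputes the best training compound every iteration,
  so a newly acquired compound can dethrone the previous anchor.
- **Test-set scoring** after an active-learning run refits on the cold
  start plus the first `budget` acquisitions. For the paired policy, test
  molecules are ranked by predicted improvement over the *final*
  training-set best; the anchor for external data is otherwise undefined,
  and this choice is deliberately conservative (a single fixed reference).
  Whether the cold-start pair counts toward the training budget is a flag
  (`include_cold_start`, default true).

## Evaluation suite

- **Hits** are the top ten percentile of most potent compounds of a
  reference set; the set size is ceil(0.1 N) with threshold ties broken
  by dataset position so the size is exact. Retrieval curves report the
  fraction of hits held after each acquisition, with cold-start hits
  counted at t = 0; they are nondecreasing, bounded in [0, 1], and reach
  1 under pool exhaustion.
- **Scaffold diversity** counts unique Bemis–Murcko frameworks
  (atom-typed, not carbon-skeleton), either among selected hits (fraction
  relative to scaffolds over all hits) or among all selected compounds.
  All acyclic molecules share a single sentinel scaffold class.
- **Similarity windows** average, over iteration windows 1–15, 16–30 and
  31–45, the Tanimoto similarity of each acquisition to its nearest
  neighbor in the training set *as it stood at acquisition time* (the
  acquisition itself cannot be its own neighbor by construction). The
  all-zero/all-zero Tanimoto is defined as 1.0 to keep nearest-neighbor
  maxima NaN-free.
- **Chemical-space embedding** reduces Morgan fingerprints by PCA to 50
  components, then t-SNE to 2 (perplexity 30 capped at (n−1)/3, 1000
  iterations, PCA initialization, seeded). Libraries of ≤ 50 molecules
  skip the PCA stage with a warning. Coordinates are for qualitative
  trajectory analysis only. Jump/stay counts need cluster labels, which
  no published definition fixes; DBSCAN (eps 5.0, min_samples 4) on the
  embedding is used with parameters recorded in the embedding metadata,
  noise points become singleton clusters, and only the conservation
  property (jumps + stays = transitions) is treated as a hard invariant.
- **Strategy comparisons** use the two-sided Wilcoxon signed-rank test on
  per-dataset paired values (zero differences dropped; an all-zero
  comparison is degenerate with p = 1), reported with the mean ± SD and
  the SE of the differences. The test suite checks the p-values against
  an independent exact enumeration of all 2^n sign patterns for n ≤ 12.

## Synthetic landscape

The generator assembles molecules from a fixed fragment grammar (16 ring
templates × side chains, ring substituents, and prefix chains), which
guarantees valid canonical SMILES and, by construction, tens of distinct
Murcko scaffolds per 300-molecule library. Potency is

    y(m) = w · fp(m) + assay_offset + Normal(0, noise_sd)

with a sparse weight vector w (120 random Morgan bits, weights
N(0, 0.35²)) drawn once per seed. `hit_skew` (default 1.5) adds weight to
the fingerprint bits of three designated core scaffolds (pyrimidine,
naphthalene and quinoline series), producing a separated top tail spread
over several scaffold classes — a skewed pK_i-like distribution (typical
range ≈ 5–9 around `assay_offset` = 6). Defaults: 300 molecules,
noise_sd 0.3, 80:20 train/test split; a scaffold-disjoint split mode
assigns whole scaffold classes to one side to approximate the character
of time-based splits. `hard_mode` attaches the signal to atom-pair bits
while models consume Morgan bits, for graceful-degradation studies.

What the generator does **not** emulate: congeneric medicinal-chemistry
series with matched pairs, activity cliffs, assay heteroscedasticity, or
temporal drift. Passing tests on this landscape demonstrate that the
pairing and acquisition machinery is correct and that the paired policy
can exploit a learnable structure–activity signal; they do not certify
performance margins on real benchmark collections.

## Seeds and determinism

One base seed drives everything: a seed sequence derives one seed per
repeat (the three-repeat protocol with unique starting pairs comes from a
single flag), and each repeat seed is split into cold-start, policy-stream
and model seeds. All derived seeds stay below 2³¹. Trajectories are fully
deterministic given (config, dataset, seed) for the tree and oracle
families; t-SNE coordinates are deterministic per seed but are never used
in quantitative assertions.

## Problem sizes used in the shipped checks

The standard benchmark conditions used by the test suite and the
acceptance script are: 300-molecule library, noise SD 0.3, 3 repeats of
50 iterations for the model policies; 30-molecule fixtures for the
oracle-equivalence enumeration (20 seeds); a 100-molecule pool with 10
hits and 25 acquisitions for the random-screening calibration (hundreds
of seeds, compared against the closed-form hypergeometric mean kH/N).
These sizes keep a complete verification pass at desk scale while
exercising every code path at realistic dimensionality (2048/4096-bit
features).

## Known limitations

- Tree models on binary fingerprints extrapolate poorly to structurally
  novel molecules; the delta model's accuracy claims are therefore stated
  for held-out *pairs* of molecules seen in training (interpolation of
  the difference function), which is what acquisition-time scoring against
  a known anchor needs most.
- Exhaustive n² pairing is quadratic in training-set size; it is intended
  for the low-data regime (hundreds of compounds). Subsampled pairing is
  out of scope.
- The external-data anchor choice (final training best) and the DBSCAN
  clustering of the embedding are package conventions where no published
  definition exists; both are recorded in outputs so alternatives can be
  compared.
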