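# Methods

This note documents the models and procedures implemented in `cpanntox`,
the conventions chosen where standard practice leaves room, and what the
synthetic data generator does and does not emulate.

## Counter-propagation network

A CPANN is a rectangular, non-toroidal grid of neurons with two weight
layers of identical grid shape: a Kohonen layer with one weight per input
descriptor, and an output (Grossberg) layer with one weight per target.
Training presents one object per iteration `t` (1-based; `t_max = epochs ×
objects-per-epoch`):

1. the winning neuron is the one with the smallest Euclidean distance
   between its Kohonen weights and the object's descriptors — targets never
   participate in the winner search; ties break to the smallest row-major
   index so training is deterministic;
2. both layers move toward the object (Kohonen toward the descriptors,
   output toward the 0/1 target) by the fraction `η(t) · a(c, j, t)`.

The learning rate decays linearly, `η(t) = v_min + (v_max − v_min)(t_max −
t)/(t_max − 1)`, from `v_max` (default 0.5) to `v_min` (default 0.01); a
one-iteration schedule is defined as `v_max`. The neighborhood is
triangular on the Chebyshev grid distance `d`: `a = max(0, 1 − d/(r(t)+1))`
with the radius shrinking linearly from the maximum grid distance to 0 at
`t_max`, so only the winner is corrected at the end of training. Chebyshev
distance, the linear radius schedule, and uniform-random weight
initialization in [0, 1) are conventions — standard SOM practice chosen for
reproducibility, not unique mathematical necessities. Because targets are
0/1 and every update is a convex combination, output weights remain in
[0, 1] and act as class scores: class 1 (toxic) iff score ≥ 0.5, with the
boundary assigned to the toxic class (conservative for a toxicity
endpoint). A two-output one-hot mode with arg-max decision is available but
the scalar-target mode is the default.

### Imbalance handling

Two training regimes:

- `full_epoch` — every training object once per epoch (classical);
- `balanced_subsample` — before each epoch a fresh subsample is drawn
  consisting of all minority-class objects plus an equally sized
  without-replacement uniform draw from the majority class; the epoch then
  presents each subsample member exactly once (so `t_max = epochs × 2 ×
  minority count`). Majority objects all remain in play across the run but
  are individually used less often.

Object order is reshuffled every epoch in both regimes. With the canonical
imbalanced composition of 108 toxic / 296 non-toxic training compounds, the
per-epoch subsample has exactly 216 members, 108 per class.

## Model quality and selection

Quality is summarized by sensitivity `TP/(TP+FN)`, specificity
`TN/(TN+FP)` and the Matthews correlation coefficient; an MCC with any zero
marginal is defined as 0 so that ranking stays total. The genetic algorithm
maximizes one of three criteria, each damped by the descriptor-count
penalty `f = 1 − p(Nselected − 1)/Ndescriptors` (`p ≥ 0` chosen per run;
`f = 1` for single-descriptor models): OC1 = min(sens, spec) on the first
test set × f; OC2 = MCC(TE1) × f; OC3 = MCC(TR) × MCC(TE1) × f.

A chromosome is a descriptor mask (≥ 1 bit set, enforced by a one-random-
bit repair after crossover/mutation) plus the two learning-rate genes with
`0 < v_max ≤ 1`, `0 ≤ v_min ≤ v_max`. Since no canonical operator set
exists for this kind of wrapper selection, the simplest scheme consistent
with the usual narrative is used: seeded random initial population; parents
drawn uniformly from the top `n_crossover_parents` by criterion; uniform
crossover on masks with a single arithmetic blend coefficient for both
genes; per-bit flip mutation plus clipped Gaussian perturbation of genes
(σ = 0.05); one elite chromosome carried over *with its evaluation*, which
makes the best-so-far criterion non-decreasing — a property the tests rely
on. Each chromosome evaluation derives its training seed from the run seed,
generation and slot, so whole searches are bit-reproducible.

Acceptance of models is two-staged:

1. every evaluated model with sensitivity and specificity ≥ 0.7 and
   MCC ≥ 0.5 on TR, TE1 and TE2 (all inclusive) is a candidate; in
   addition, when the history spans ≥ 20 generations, the three
   best-of-generation rank slots are averaged over the final 20
   generations, and if any slot averages sensitivity and specificity ≥ 0.7
   on all three sets, the final generation's best three chromosomes are
   candidates too. The window rule is interpreted per rank slot (1st, 2nd,
   3rd of each generation), not per persistent chromosome identity — the
   most direct reading of a "best three over the last 20 generations"
   requirement, since chromosome identities are not stable across
   generations.
2. each candidate is retrained `n_retrains` times (default 100) with fixed
   descriptors and hyper-parameters under fresh seeded object orders (and
   fresh subsample draws in `balanced_subsample` mode); it is finally
   accepted iff mean sensitivity and mean specificity stay ≥ 0.7 on all
   three sets. The report carries means and standard deviations per set.

## Data preparation

- **Filtering.** A descriptor is near-constant when its most frequent value
  covers strictly more than 70% of rows. Correlation pruning keeps the
  earlier column of any pair with |Pearson r| ≥ 0.95, scanning in column
  order — a deterministic greedy rule (which member of a correlated pair to
  keep is otherwise arbitrary); the survivor set has all pairwise
  |r| < 0.95 and the filter is idempotent. Every removal is logged with its
  reason.
- **Normalization.** z-scores with training-set statistics; the sample
  (n−1) standard-deviation convention is used, so the column (1, 2, 3)
  transforms exactly to (−1, 0, 1). Zero-variance columns raise an error
  naming the column.
- **Descriptor reduction.** The transposed (z-scored) matrix is mapped on a
  SOM — descriptors are the objects, compounds the variables. Per occupied
  neuron the nearest and the farthest descriptor are kept (one if the
  neuron holds a single descriptor), so a `g × g` map yields at most
  `2g²` descriptors: exactly 50 for a fully occupied 5×5 map, 98 for 7×7,
  under 200 for a partially occupied 10×10.
- **Splitting.** Compounds are mapped on a SOM and assigned to training
  (TR), two test sets (TE1, TE2) and external validation (VA) under exact
  per-class quotas that must partition the class totals. Manual,
  judgment-based map reading is common in this workflow; it is replaced here by a deterministic
  seeded heuristic: VA is drawn uniformly over compounds per class (which
  spreads it across neurons in proportion to occupancy); post-VA neurons
  with ≤ 2 objects are reserved for TR; TE1 and TE2 fill round-robin, one
  compound per multiply-occupied neuron per pass, falling back to the
  reserve only if the map runs dry; the remainder is TR. Infeasible quotas
  raise an error naming the shortfall.

Two canonical set layouts are bundled: layout `a` (imbalanced TR of
108/296 with 20/20 test and validation sets) and layout `b` (balanced TR of
108/108 with the surplus negatives in the test and validation sets); both
partition 168 positives and 356 negatives.

## Consensus, applicability domain, importance

Consensus is a majority vote of the accepted models, each applying its own
descriptor subset and normalization; ties go to the toxic class. The
applicability-domain check is deliberately simple: a query is inside a
model's domain iff its distance to the winning neuron is ≤ a percentile
(default 100, i.e. the maximum, boundary inclusive) of the training
distances recorded at that neuron, pooled over all neurons for neurons
unseen in training. With the default percentile the flag rarely excludes
anything — matching the observation that consensus calls tend not to change
when the domain filter is switched on.

Descriptor importance is `I_d = (1/nm) Σ s·(a/n)` over accepted models
(`nm` = models whose candidate pool contains the descriptor, `s` ∈ {0, 1}
selection, `a` pool size, `n` selected count). The printed form of this
statistic in the source literature is typographically garbled; the
implementation follows the prose definitions of its variables. Descriptors
selected fewer than 4 times are removed before reporting, and the report
keeps `I_d ≥ 2`, both bounds inclusive.

## Synthetic data

The generator emulates the *shape* of a curated hepatotoxicity descriptor
table: exact class counts at roughly 1:3 imbalance, a few hundred numeric
descriptor columns with block correlation, a minority of informative
columns shifted by `effect_size` (in within-class SD units) for the
positive class, and optional activity cliffs (copies of positive compounds
with 1% descriptor noise and a negative label). Each column mixes its
primary block factor with one random second block (uniform mixing weight),
producing a correlated continuum rather than tight clusters — this makes
SOM occupancy on the transposed matrix behave like a real descriptor set
(fully occupied 5×5 maps, partially occupied 10×10 maps) while keeping all
pairwise correlations well below the 0.95 filter by construction.

What it does **not** emulate: real descriptor marginals (Dragon-style
counts, heavy tails, discreteness), nonlinear structure-activity
relationships, scaffold clustering, or label noise. Passing tests therefore
demonstrate correctness and the imbalance-handling mechanism, not expected
performance on real chemistry.

The study-scale bundle (`study_shape_fixture`) draws 524 compounds
(168/356) with 600 clean descriptors, splits them to both layouts on a
10×10 compound map and reduces descriptors on 5×5/7×7/10×10 maps of the
non-validation compounds, using 5 SOM epochs throughout — enough for stable
maps at this size while keeping the full pipeline in seconds.

## Numerical and scale choices

- All randomness flows through `numpy.random.default_rng` /
  `SeedSequence`; derived seeds are reduced mod 2³¹. Identical seeds give
  bit-identical models, splits and CLI outputs.
- Winner ties break to the smallest row-major index; the class-score
  boundary goes to the toxic class; the AD boundary is inclusive.
- Default test and acceptance problem sizes (grids 4×4–6×6, 8–30 epochs,
  populations ≤ 12, 20-seed comparisons) are chosen so each property is
  demonstrated at the smallest scale where it is stable; full-scale GA
  campaigns of several thousand optimizations are a matter of scale, not
  mechanism, and are not replicated.

## Known limitations

- The GA operators, radius schedule and weight initialization are declared
  conventions; other choices could change which models are found (not the
  contracts tested here).
- The applicability-domain rule is a distance-percentile simplification of
  more elaborate published schemes.
- `stability_check` retrains serially; at full scale (100 retrains
  × many candidates) users should expect minutes, not seconds.
- Single binary endpoint only; no multi-class or regression counter-
  propagation.
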