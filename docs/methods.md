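# Methods

## The model

A screening corpus pairs each compound with ~1400 numeric molecular
descriptors, a potency label pIC50 ∈ [0, 10], and five binary ADMET labels
(Caco-2, CYP3A4, hERG, HOB, MN; 1 = favorable).  The workflow has four
stages:

1. **Cleaning.**  Descriptor columns whose fraction of literal zeros is at
   least 0.9 are removed (on raw values, where "zero" is unambiguous), the
   survivors are min-max scaled to [0, 1] per column, and pIC50 is kept as
   the only activity annotation (IC50 is its deterministic transform).
   The per-column (min, max) pairs are retained so optimized candidates can
   be reported in real units.
2. **Screening.**  A regression random forest on pIC50 scores every
   descriptor by normalized mean impurity decrease; the top k = 224 become
   the operating variables.  Ties break lexicographically, and the forest is
   fit on a column-sorted view, so the ranking is reproducible and
   independent of input column order.
3. **Surrogates.**  One quantitative regressor ψ(X) for pIC50 and five
   binary classifiers ϕₚ(X), all sharing a lightweight 1-D convolutional
   backbone: the selected descriptors enter as a one-channel sequence and
   pass through depthwise-separable inverted-residual blocks with
   squeeze-excitation and hard-swish, then a global-average pool and a dense
   head emit one scalar (plus a sigmoid for the classifiers).  Training uses
   Adam under a single-cycle cosine-annealed learning rate, mean-square error
   for the regressor, binary cross entropy for the classifiers, and
   seeded minority oversampling to class parity on the training split only.
4. **Search.**  Candidates maximize F(X) = Ψ(X) + Φ(X), where Ψ zeroes
   predictions outside [0, 10] and Φ zeroes ADMET mark sums below three,
   subject to 0 ≤ xᵢ ≤ 1.  A binary-coded genetic algorithm (20-bit genes,
   decode value = integer/(2²⁰−1)) encodes part of its initial population
   from corpus rows, selects parents by roulette, applies single-point
   crossover and per-gene mutation, and carries one elite unchanged, making
   the best-so-far trace monotone.  Whether the best candidate also clears
   the corpus-maximum potency (pIC50_target ≥ pIC50_source) is reported as a
   feasibility flag, not folded into the fitness; a hard-filter mode exists
   for sensitivity runs.

## Default parameters

| parameter | default | note |
|---|---|---|
| sparse-column threshold | 0.9 zero fraction | "mostly zero" reading, configurable |
| forest | 500 trees, regression on pIC50 | ranking stability |
| selected variables k | 224 | decision-vector dimension |
| epochs / batch / lr ceiling | 100 / 10 / 1e-4 | cosine-annealed to 0 over one cycle |
| split | 80 / 15 / 5 | train / test / validation rows; sizes round(n·f), remainder to validation |
| classifier threshold | 0.5 | favorable mark when ϕₚ ≥ 0.5 |
| GA | pop 2000, 500 generations, crossover 0.6, mutation 0.1, elite 1 | full-scale protocol |

The `desk` profile keeps the pipeline identical but shrinks the problem so a
complete run takes ~80 s on one CPU: 600 compounds × 120 descriptors
(12 informative), k = 20, a narrower backbone (three blocks, 16-channel
stem, ~12k parameters), 40 epochs at a 3e-3 ceiling (a shorter schedule
needs a larger step to converge), 150-tree forest, and a GA of 150
individuals × 60 generations with 12-bit genes.

## Numerical choices

* **Net engine.**  All layers are float64 numpy with hand-written backward
  passes, checked against central finite differences in the test suite.
  Convolution supports channel groups (depthwise as the special case); batch
  normalization keeps running statistics, and after training those are
  recalibrated by one exact full-training-set pass, since minibatches of 10
  leave noisy estimates.  Regression targets are standardized internally
  (predictions mapped back to pIC50 units) so the freshly initialized head
  starts at the corpus mean instead of zero.
* **Mutation semantics.**  "Mutation rate 0.1" is applied per gene: each of
  the decision variables mutates with probability 0.1, by flipping one
  uniformly chosen bit of its gene (expected coordinate move ≈ 5% of range).
  The alternative per-bit reading (also implemented,
  `mutation_mode="per_bit"`) flips ~10% of all bits of every child, which
  turns each offspring into an effectively random point; a solver behaving
  that way could not produce a converging best-fitness trace ending just
  above the corpus maximum, so the per-gene reading is the default.
* **Degenerate inputs.**  Constant descriptor columns scale to 0 and are
  flagged; MAPE averages over nonzero labels and reports how many were
  excluded; precision/recall are 0 when their denominator is empty; roulette
  selection falls back to uniform when total fitness is 0.
* **Determinism.**  Every stage draws from `numpy` generators seeded from
  one global seed through fixed stream offsets; two runs with the same
  config produce byte-identical artifacts.

## What the synthetic generator emulates — and what it does not

The generator reproduces the corpus *shape*: heavy-tailed per-column scales
(lognormal, spanning orders of magnitude), a configurable fraction of
≥90%-zero columns, uniform and lognormal marginals, pIC50 in [0, 10] from a
known clipped-linear function of an informative descriptor subset plus
Gaussian noise (sd 0.5), and ADMET labels drawn from logistic rules over the
same informative pool — so that changing operating variables moves potency
and ADMET jointly — with intercepts calibrated by root finding to hit the
configured positive rates (HOB at 0.10, deliberately the most imbalanced).
Labels are reproducible bit-for-bit from the stored ground truth and seed.

It does not emulate real structure–activity relationships: descriptors are
statistically independent (real descriptor families are strongly
correlated), the activity map is linear-plus-clip rather than the unknown
real landscape, and no chemistry constrains which descriptor combinations
are realizable.  Passing recovery tests therefore demonstrates that the
pipeline machinery — cleaning, screening, training, search, unit round-trips
— behaves correctly under known ground truth, not that the surrogates would
achieve any particular accuracy on laboratory data.

## Known limitations

* The convolutional backbone treats descriptors as a sequence with arbitrary
  adjacency.  Its decision boundaries away from the data manifold are less
  reliable than those of models matched to tabular structure, and an
  optimizer maximizing the surrogate composite is drawn precisely to regions
  where the surrogates err upward — the classical winner's curse of
  surrogate-assisted search.  The ground-truth value of the returned
  candidate can therefore fall below the corpus best even while its
  surrogate value exceeds it.  The end-to-end recovery check in
  `tests/test_acceptance.py` measures exactly this and is expected to expose
  the limitation at desk scale.
* Min-max parameters come from the corpus, so optimized "real unit" values
  cannot leave the observed per-descriptor ranges.
* The full published protocol (1974 × 1361, 500 forest trees, six 100-epoch
  trainings, a 2000 × 500 GA) is hours of CPU; tests and the acceptance
  script run the desk profile.
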