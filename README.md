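# qsaropt

Inverse-QSAR optimization of drug-candidate properties: clean a
molecular-descriptor table, train surrogate models for inhibitory activity
(pIC50) and five binary ADMET properties, then search descriptor space with a
binary-coded genetic algorithm for candidates that maximize a composite
clinical objective.

## The problem

In ligand-based drug design, each candidate compound is described by a large
vector of numeric molecular descriptors (lipophilicity, topological surface
area, atom-type electrotopological states, ...).  Two kinds of models are fit
on a screening corpus:

* a **quantitative** model ψ(X) predicting potency as pIC50 = −log₁₀ IC50,
  treated as bounded in [0, 10] (higher = more potent), and
* five **qualitative** models ϕₚ(X), one per ADMET property — Caco-2
  permeability, CYP3A4 metabolism, hERG cardiotoxicity, human oral
  bioavailability (HOB), and micronucleus genotoxicity (MN) — each binarized
  with 1 meaning "favorable".

The design question is then inverted: *which descriptor vector X would an
ideal candidate have?*  With the decision vector X = (x₁, …, x₂₂₄) of
selected, min-max-normalized descriptors, the composite objective is

    Φ(X) = Σₚ ϕₚ(X)   if the sum ≥ 3, else 0          (ADMET acceptability)
    Ψ(X) = ψ(X)       if 0 ≤ ψ(X) ≤ 10, else 0       (valid-potency clip)
    F(X) = Ψ(X) + Φ(X),   maximized s.t. 0 ≤ xᵢ ≤ 1

so F ∈ [0, 15], with the additional recorded constraint that the optimized
potency should not fall below the corpus maximum
(10 ≥ pIC50_target ≥ pIC50_source ≥ 0).

## What the package provides

| stage | module | summary |
|---|---|---|
| synthetic corpus | `qsaropt.datagen` | seeded generator emulating a 1974 × 1361 screening corpus with known ground truth |
| cleaning | `qsaropt.preprocess` | sparse-column removal, min-max scaling with invertible per-column params, pIC50-only labeling |
| screening | `qsaropt.feature_select` | random-forest importance ranking, top-k (default 224) selection; packaged published ranking fixture |
| surrogates | `qsaropt.surrogates` | 1-D depthwise-separable conv backbone (inverted residuals, squeeze-excitation, hard-swish) for regression and binary heads; minority oversampling; MSE/MAPE/MAE and accuracy/precision/recall/F1 |
| net engine | `qsaropt.nn` | numpy layers with hand-written backprop, Adam, cosine-annealed learning rate |
| objective | `qsaropt.objective` | Φ, Ψ, F and the constraint report |
| search | `qsaropt.ga` | binary-coded GA: 20-bit genes, data-seeded initialization, roulette selection, single-point crossover, per-gene mutation, elitism |
| orchestration | `qsaropt.pipeline`, `qsaropt.cli` | profiles, artifacts, `qsaropt` command line |

Preprocessing and the surrogates follow scikit-learn estimator conventions
(`fit`/`transform`/`predict`, fitted attributes with trailing underscores),
so they compose with sklearn pipelines and model selection.

## Worked example

```bash
qsaropt -v run-all --profile desk --seed 1 --outdir out/
```

runs the full workflow on a desk-scale synthetic corpus (600 compounds ×
120 descriptors) and prints:

```
best fitness F = 10.7205
  Psi = 6.7205, Phi = 4, marks = {'Caco2': 1, 'CYP3A4': 1, 'hERG': 1, 'HOB': 0, 'MN': 1}
  corpus max pIC50 = 5.6157, activity-feasible: True
reports in out/
```

Reading: the optimizer found a candidate whose surrogate-predicted potency is
6.72 pIC50 units and for which four of the five predicted ADMET marks are
favorable (oral bioavailability is not), so F = 6.72 + 4 = 10.72.  Its
predicted potency exceeds the corpus maximum of 5.62, so the
potency-dominance constraint is also met.  `out/` holds the corpus, the cleaning report, the
importance ranking, activity/ADMET metric tables computed on the held-out
validation slice, the per-generation best-fitness trace, and the best
candidate with each descriptor in normalized and real units.

At full scale, `--profile paper` uses the published protocol: a
1974-compound corpus, 224 operating variables, 100 training epochs (batch 10,
Adam, cosine-annealed learning rate capped at 1e-4, 80/15/5 split), and a
population of 2000 evolved for 500 generations.

## Scope

The package does not compute molecular descriptors from chemical structures
(no SMILES/SDF input) and does not attempt to reproduce metric values that
depend on a non-public screening corpus; the synthetic generator exists
precisely so that every stage is testable against a known ground truth.
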