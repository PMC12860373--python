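# Methods

## The screening problem

A poorly soluble active needs a small hydrophilic partner (a coformer)
that co-assembles with it through non-covalent interactions. Screening
candidates experimentally is slow, so the package treats partner selection
as supervised learning plus inverse design: learn a binary *suitability*
classifier from a small labeled library of candidate molecules, then
search a candidate space for the molecule the classifier scores highest,
subject to physicochemical and bioactivity constraints.

Five predictive variables describe a candidate: molecular weight (MW,
g/mol), hydrogen-bond-donor count (HBD; N/O atoms bearing ≥ 1 H),
topological polar surface area (TPSA, Å², Ertl fragment-additive scheme),
a tyrosinase-inhibitory potential score scaled to [0, 1] (an experimental
bioactivity annotation, never computed from structure), and the molecular
structure itself via its SMILES string. MW/HBD/TPSA are computed with
RDKit when absent from the input table.

### SMILES encoding

A raw string cannot feed a numeric network, so the structure feature is
realized as a fixed-length count vector: the molecule is canonicalized,
its circular substructure environments of radius ≤ 2 are enumerated with
multiplicity (Morgan enumeration), and each fragment identifier is hashed
into one of k buckets (default k = 32, seed-remixable). The encoding is
invariant to how the SMILES was written and deterministic per
(molecule, k, seed). This is one defensible concrete realization of a
"structure feature" for very small sample sizes; nothing downstream
depends on the specific choice, and `CoformerFeaturizer(features=...)`
drops it entirely if desired.

### Normalization

Features are z-scored with the *training* mean and sample standard
deviation (n − 1); constant columns map to zero. The fitted
`CoformerFeaturizer` carries these parameters so prediction-time inputs
are scaled identically.

## Feature ranking

`rank_features_rf` fits a Random Forest (100 trees, √p features per
split, bootstrap, seed-pinned — scikit-learn's implementation) and
reports mean-decrease-impurity importances, normalized to sum to 1 and
sorted descending with ties broken toward the lower input column index.
The per-bucket encoding columns are summed into a single `smiles_enc`
entry so the ranking speaks the five-variable vocabulary of the screen.
Summed MDI over a 32-column block is a *total* contribution; a block of
pure-noise columns can therefore out-rank a single informative scalar.
The ranking is a reduction/diagnostic stage, not a gatekeeper: the
workflow's default selection keeps all five variables.

## The suitability classifier

`BPClassifier` is a feed-forward network written out explicitly — one
hidden layer of 16 logistic units (configurable), a single sigmoid output,
mean cross-entropy loss — trained by error back-propagation with
mini-batch stochastic gradient descent plus classical momentum.
With ~10² labeled examples, deeper architectures are not supportable;
every hyperparameter is a constructor argument:

| parameter | default | notes |
|---|---|---|
| hidden_layer_sizes | (16,) | logistic activations |
| learning_rate | 0.05 | fixed step size |
| momentum | 0.9 | classical momentum |
| epochs | 2000 | full passes over the training set |
| batch_size | 16 | reshuffled per epoch from the estimator's RNG |
| patience | None | early stopping off by default |
| validation_fraction | 0.1 | held out when patience is set |
| threshold | 0.5 | decision threshold on probability |
| random_state | 0 | initialization, shuffling, validation split |

Numerical choices: hidden weights use uniform Glorot initialization; the
output layer starts at exactly zero so an untrained model predicts 0.5
(the first update activates it); the sigmoid is evaluated in the
numerically stable split form; training aborts with the loss trace
attached if the loss becomes non-finite. Full-batch training
(`batch_size=None`) is available but converges markedly slower at these
learning rates. The gradient computation is exposed as `bp_loss_and_grad`
precisely so it can be validated against central finite differences; the
agreement metric is the standard norm ratio ‖g − fd‖ / max(‖g‖, ‖fd‖),
which is well-posed when individual gradient entries pass through zero.

Early stopping, when enabled, holds out `validation_fraction` of the
training rows, tracks validation loss per epoch, stops after `patience`
epochs without improvement and restores the best snapshot
(`best_validation_loss_` equals the minimum of `validation_curve_`).

Evaluation (`evaluate`) produces the 2×2 confusion matrix; accuracy,
sensitivity and specificity are reported in percent rounded half-up to one
decimal (so 34 agreements on 39 entries reports 87.2 %).

## GA inverse design

Fitness of a candidate is its predicted suitability probability minus
λ · Σ(constraint violations), each violation normalized by its bound's
span (λ default 1), so a feasible candidate scores exactly its
probability. Penalties rather than hard rejection keep the signal
informative in small populations. Among everything evaluated, a feasible
individual is always preferred over any infeasible one.

Defaults: population 50, crossover rate 0.8, mutation rate 0.1,
100 generations, elitism 2, tournament selection of size 3. Two
representations:

* **discrete** — the chromosome is the bit string of an index into an
  enumerated pool. Crossover is one-point on the bits; mutation flips each
  bit at the configured per-gene rate; indices ≥ pool size are repaired by
  a uniform re-draw. Pool fitnesses are cached once per run.
* **continuous** — the chromosome is a raw descriptor vector inside a
  box. Crossover is BLX-α blending (α = 0.5); mutation is per-gene
  Gaussian with sd = 10 % of the gene's box span; children are clipped to
  the box. `map_to_candidate` maps a continuous optimum to the nearest
  real pool molecule (Euclidean distance in z-scored feature space, ties
  to the lexicographically smallest id).

**No-duplicates policy (discrete mode).** Pool indices carry no
neighborhood structure, so selection and crossover cannot exploit any
fitness gradient over the index space; neutral genetic drift then
collapses the population onto a few indices and the run re-evaluates the
same candidates while covering only half the pool. The search therefore
re-draws any child whose index has already been evaluated (up to 20
tries) — the classic duplicate-avoidance diversity mechanism. With it,
a 100-generation run covers essentially the whole of a 1000-candidate
pool and reliably returns the exact exhaustive-search optimum, which is
the behavior an inverse-design user needs on enumerable pools. On spaces
larger than the evaluation budget the policy is a no-op in the limit and
the GA behaves as an ordinary elitist search.

Elitism makes the per-generation best fitness non-decreasing.
`detect_convergence` reports the first generation opening a window
(default 10 generations) whose best-fitness spread is ≤ tol (default
1e-4); this plateau definition is a package convention. A trained
classifier typically scores many deep-in-range candidates near
probability 1, so the best-fitness curve often starts at its plateau and
convergence is reported at generation 0 even though the search keeps
refining *which* candidate is best.

## Synthetic study conditions

The generator emulates a small screening library of hydrophilic
small-molecule candidates. Defaults are the package's study conditions:

* n = 159 records, split 120 train / 39 test (stratified by default);
* descriptor ranges MW 75–400 g/mol, HBD 0–6 (integer), TPSA 0–150 Å²,
  tyrosinase score uniform [0, 1];
* planted suitability rule (closed bounds): HBD ∈ [1, 4], TPSA ∈ [20, 90]
  Å², MW ≤ 250 g/mol, tyrosinase score ≥ 0.5; the continuous rule score is
  the sum of per-descriptor margins, each normalized by its sampling span;
* label noise 0.1: each rule label flips independently with this
  probability;
* class balance ≈ 0.5, achieved by drawing half the records inside the
  rule box;
* candidate pools are unlabeled and contain exactly one planted optimum
  profiled on tranexamic acid (MW 157.21, HBD 2, TPSA 63.32, score 0.98;
  RDKit values for its SMILES) whose rule score exceeds every other pool
  record's by ≥ 0.05 (enforced by bounded re-drawing).

Records carry real small-molecule SMILES from a bundled pool (amino
acids, organic acids, phenolics, sugars, common actives) so the encoder
runs on genuine structures, but the tabulated descriptors are *sampled*,
not recomputed from the structure: the planted rule is the ground truth.
Two consequences matter for interpreting results. First, the SMILES
encoding is label-independent noise under these conditions, so including
it (the faithful five-variable default) costs held-out accuracy at
n = 120 relative to the four scalar descriptors alone. Second, with 10 %
label noise the achievable test accuracy is bounded near 90 % regardless
of the model. Passing tests on this generator demonstrate that each stage
does what it claims against a known ground truth — not that the specific
accuracy figures transfer to any real screening library, whose label
definition, feature correlations and noise structure are unknown.

## Degenerate inputs and conventions

* CSV interchange: comma-separated UTF-8 with mandatory header and fixed
  column order `id, smiles, mw, hbd, tpsa, tyr_inhib, label`; floats are
  parsed with pandas' round-trip parser so write→read is value-exact.
* Unlabeled records are permitted only in candidate pools; training
  operations fail fast on them.
* Stratified splitting apportions the training size across classes by
  largest remainder, so train-class fractions match the library's within
  1/train_size.
* Permeation: the aliquot volume S defaults to 1 mL per sampling; the
  receiver volume has no sensible universal default and is a required
  input. Series with any negative concentration are rejected; Q_s is
  exactly equivariant in the diffusion area.
* Viability outside [0, 100] % is reported as-is with a warning, never
  clipped.
* IC estimation interpolates linearly in log10 concentration (dose series
  are geometric; a linear mode is exposed), returns exact hits as-is, uses
  the first crossing from above on non-monotone curves, and raises rather
  than extrapolates when the target is never bracketed.

## Known limitations

* The classifier is a deliberately small network; it underfits sharp
  axis-aligned boundaries relative to tree ensembles at very small n
  (at n = 159 with 10 % noise, held-out accuracy in the 60–80 % range is
  typical under the default synthetic conditions; with noiseless labels
  and n = 1000 it exceeds 95 %).
* Whether the bioactivity score's [0, 1] scaling, the hashed-fragment
  structure encoding, and the planted-rule label definition resemble any
  particular experimental library is unknowable from public data; they
  are package conventions, stated here so they can be replaced wholesale
  when real training data are available.
* The GA's continuous mode requires a model trained on scalar features
  only (a fragment-count vector has no meaningful box interior).
* No probability calibration, hyperparameter search, or multi-objective
  optimization; single-objective penalized fitness only.
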