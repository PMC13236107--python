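# Methods

## Statevector engine

All circuits are simulated exactly on a little-endian statevector backend:
qubit 0 is the least significant bit of the amplitude index, and a k-qubit
gate matrix is little-endian within its `target_qubits` list. Gates are
applied by tensor reshaping rather than by materializing full 2^n × 2^n
matrices; controlled gates act on the subspace where every control qubit is
|1⟩. Unitarity of every supplied matrix and norm conservation after every
application are enforced at 1e-10. Registers are capped at 24 qubits (2^24
complex amplitudes, 256 MB); wider circuits raise a resource error before
any allocation, which is also how configurations that are width-calculable
but not simulable (e.g. the 56-qubit ensemble settings) are handled.

## Amplitude encoding

A nonnegative feature vector of length f is zero-padded to the next power of
two *before* normalization, then written into the amplitudes of
ceil(log2 f) qubits. The all-zero vector and negative entries are rejected
(features reach the encoder min-max scaled to [0, 1]). The vector is divided
by its maximum before computing the norm so that encoding cannot underflow
for very small magnitudes.

## The cosine weak learner (QCC)

Registers: train data (m = log2 f qubits), label (1 qubit, basis-encoded),
test data (m qubits), prediction ancilla — 4 qubits at f = 2. The circuit is
a swap test (H on the ancilla, qubit-wise controlled-SWAP between the data
registers, H) followed by a CNOT from the label qubit to the ancilla. The
swap test leaves the ancilla in |0⟩ with probability 1/2 + D²/2, D being the
cosine similarity of the encoded vectors (real and nonnegative here); the
label CNOT converts this into

    Pr(ancilla = 1) = 1/2 + D²/2  if y_train = 1,
                      1/2 − D²/2  if y_train = 0,

i.e. Pr(ŷ = y_train) = 1/2 + D²/2. Predictions threshold at 0.5 with ties
going to class 1. A standalone QCC draws its single training sample
uniformly at random from the training split (seeded). The measured output is
exact by default; a finite-shot estimate (default budget 8192) is a seeded
binomial draw on the exact probability. Note the quantity D is sometimes
called a cosine *distance*, but the monotonicity of the classifier —
probability grows with similarity — makes it a similarity; that convention
is used throughout.

## The superposition ensemble (QEC / QECRU)

Layout (low to high): n_train data subregisters of m qubits, n_train label
qubits, the test register, d control qubits, one prediction ancilla — width
n_train·(m+1) + m + d + 1. This layout gives 7 qubits at
(d=1, n_train=2, f=2), 56 at (2, 8, 32), 47 at (2, 8, 16), and 23 at the
maximum of the random-unitary grid (3, 4, 8).

State preparation amplitude-encodes every training sample and the test
sample, basis-encodes the labels, and applies a Walsh–Hadamard to the
control register. For each control qubit i two random transformations
U_{i,1}, U_{i,2} are drawn; the circuit applies controlled-U_{i,1} (control
|1⟩), X, controlled-U_{i,2}, X, so branch bitstring b applies U_{i,1} where
b_i = 1 and U_{i,2} where b_i = 0. After d steps the register holds 2^d
entangled trajectories; the QCC interference block then runs between the
slot-0 data register and the test register, with the slot-0 label driving
the ancilla.

Because the control branches are mutually orthogonal and untouched after
their Hadamards, the ancilla probability is exactly the arithmetic mean of
the per-branch weak-learner probabilities. The package ships an independent
classical oracle (`enumerate_trajectories`) that recomputes each branch
without the circuit: for the swap variant it composes the slot permutation
and evaluates the closed form on whichever sample lands in slot 0; for the
Haar variant it composes the branch unitary on the product-encoded data
block, reduces to the slot-0 density matrix ρ, and uses the mixed-state swap
test identity Pr(accept) = (1 + ⟨t|ρ|t⟩)/2. Circuit and oracle agree to
1e-8 on randomized configurations — this is the package's core correctness
test.

Transformation families:

- **swap**: each U_{i,j} is a product of n_swap uniformly drawn sample-slot
  transpositions (pairs drawn with replacement across the n_swap draws);
  a transposition moves a data subregister and its label qubit together, so
  each branch remains a valid relabelled training configuration.
  n_swap composes *within* each transformation.
- **haar**: each U_{i,j} is a Haar-random unitary on the joint data
  subregisters (n_train·m qubits), sampled by QR decomposition of a complex
  standard-normal matrix with the orthogonal factor's columns
  phase-normalized by the diagonal of R. Labels are left untouched — the
  minimal reading that keeps branch labels well-defined. Haar supports are
  capped at 12 qubits (QR on a 4096² complex matrix is the practical
  limit for a workstation); larger requests fail fast.

## Variational weak learners

A learner on n = ceil(log2 f) qubits applies amplitude embedding, one
RZ-RY-RZ rotation per qubit (3 parameters each), a linear CNOT chain
(i → i+1, present whenever n > 1), a second rotation layer, and reads
p(y = 1) as the probability of measuring qubit 0 in |1⟩ — 6n trainable
parameters, 18 at the largest feature size (8) used here. Training is
mini-batch gradient descent with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8 —
standard constants) on binary cross entropy with probabilities clipped at
1e-12; batches are drawn without replacement per epoch from a seeded
shuffle. Gradients are analytic: every parameter drives a Pauli-generator/2
rotation, so dp/dθ = [p(θ+π/2) − p(θ−π/2)]/2 exactly, chained through the
loss. The default epoch budget is 30 with no early stopping; statevector
probabilities are used during training, shot sampling is optional at
inference.

Hyperparameters are searched on a grid of 3 learning rates
{1e-3, 1e-2, 1e-1} × 5 batch sizes {1, 2, 4, 8, 16} × 7 ensemble sizes
{1..7} (105 configurations) under stratified 4-fold cross-validation,
ranking configurations by median fold accuracy.

## Ensemble aggregation

- **Soft voting**: every learner trains on the full training set; the
  ensemble probability is the unweighted mean (1/K)Σ p_k(y=1). An ensemble
  of ℓ n-qubit learners can be instantiated as one tensor-product circuit of
  n·ℓ qubits (how its hardware footprint is sized: 4 three-qubit learners →
  12 qubits).
- **Bagging**: the training set is shuffled (seeded) and partitioned into k
  disjoint near-equal subsets (sizes differ by at most 1, remainder to the
  earliest subsets); learner k trains only on subset k; inference is a
  weighted mean with uniform default weights (the weighting is exposed as a
  hook).
- **Boosting**: AdaBoost-style. Weights start at 1/N; each round trains a
  learner on ⌊N/k⌋ samples drawn without replacement proportionally to the
  weights, measures its error ε on the full set (clipped to
  [1e-6, 1−1e-6]), assigns coefficient α = ½ ln((1−ε)/ε), multiplies
  misclassified weights by e^{2α} and renormalizes. A round with ε ≥ 0.5
  stops the ensemble early with a warning, keeping completed rounds (a lone
  failing first round is kept with zero weight so prediction stays defined).
  Aggregation is the α-weighted mean of member probabilities.

## Synthetic benchmarks

- **Gaussian blobs**: 18 configurations (cluster_std ∈ {0.3, 0.5} ×
  p1, p2 ∈ {0.3, 0.5, 1.0}), class-0 center (p1, p2), class-1 center
  (p2, p1), 100 samples drawn 50/50. Features are generated in the domain
  [−0.85, 2.55]² and mapped onto [0, 1] by the fixed affine map of that
  domain; sampling is not truncated, the rare outlier is clipped. Each
  dataset gets 10 stratified 80/20 train/test splits (stratification keeps
  both classes present in 20-sample test sets).
- **Synthetic expression cohort**: a stand-in for a controlled-access
  immunotherapy-response cohort, simulated directly on the
  variance-stabilized log scale that count normalization would produce
  (count-level simulation is deliberately out of scope): 150 samples ×
  n_genes (default 2000, standing in for a full transcriptome), gene
  baselines μ_g ~ N(6, 2), dispersions σ_g ~ U(0.5, 1.5), responder
  fraction 0.35 (a typical response rate; the real cohort's fraction is not
  public), and 8 planted informative genes shifted by effect_size·σ_g in
  responders (default effect 1.0 SD — a strong but realistic biomarker).
  The generator returns the planted gene identities so recovery can be
  tested: at effect 2.0 a plain class-mean-difference statistic ranks the
  planted genes in the top decile in ≥95% of seeds. The generator does not
  emulate count noise, gene–gene correlation, or batch structure, so
  passing tests speak to the pipeline's correctness, not to performance on
  real cohorts.
- **Preprocessing**: min-max scaling is fit on the training split only, with
  out-of-range test values clipped to [0, 1] (conservative leakage
  handling); constant features map to 0. PCA (top f components by variance)
  is fit on the training split and its output re-min-max-scaled for
  amplitude encoding.

## Evaluation protocol

Per split: accuracy, support-weighted F1 (undefined per-class F1 counts as
0), Brier score S = ⟨(p_i − y_i)²⟩ on the class-1 probabilities. Per
classifier configuration: mean and standard error (SD/√n) over splits; per
classifier family the configuration with the best mean is reported
(max-mean; min for Brier). Families are compared by a one-sided paired
t-test over common split ids; zero-variance differences degenerate to p ∈
{0, 0.5, 1}. The significance threshold is 0.05, one-sided, without
multiplicity correction — a deliberate match to common practice in this
literature and a known limitation. Splits where a classifier emits a single
predicted class are flagged: on unbalanced data that pathology can look
accurate while carrying no information.

Classical baselines: random forest tuned with RandomizedSearchCV
(n_estimators 100..1000 step 100, max_depth 5..20, min_samples_split 2..10,
min_samples_leaf 1..5, max_features {sqrt, log2}; 50 candidates, 4-fold
internal CV — the candidate count and fold number are this package's
choices) and XGBoost tuned with an exhaustive GridSearchCV over
n_estimators {100, 200} × max_depth {3, 5, 7} × learning_rate
{0.01, 0.1, 0.2} × subsample {0.7, 0.8, 1.0} × colsample_bytree
{0.7, 0.8, 1.0} × min_child_weight {1, 3, 5} = 486 combinations. Baselines
skip PCA reduction (they have no register-width constraint).

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale:
oracle equivalence on circuits of ≤ 16 qubits (d ≤ 3), learnability on the
well-separated blob configuration with three 1-qubit soft-voting learners
(batch 4, lr 1e-1, 30 epochs, 4-fold CV), expression recovery over 20 seeds
at 500 genes. Ties at p = 0.5 classify as 1 everywhere. All randomness
descends from explicit integer seeds through `numpy.random.Generator`, so
every run — including the trajectory draws shared between circuit and
oracle — is bit-reproducible.

## Known limitations

- No noise model, transpilation, or hardware execution: all results are
  noise-free statevector values, and circuit *depth* is never reported
  (it is toolchain-dependent).
- The variational ensembles process one sample per circuit evaluation;
  the parameter-shift loop costs 2·6n circuit evaluations per sample and
  step, which bounds practical ensemble and batch sizes in pure simulation.
- The expression generator's independence assumptions make its recovery
  tests necessary but not sufficient evidence for performance on real
  transcriptomes.
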