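# Methods

This note documents the measures the package computes, the estimators it
trains, the benchmark distributions it generates, and the numerical and
design choices behind them.

## Exact measures

### Undirected: the Cohesion family

For discrete variables `X_1..X_n` with subset entropies `H(X_A)`, the
Cohesion measure at order `k` is

    C(k) = binom(n-1, k-1)^{-1} * Σ_{|A|=k} H(X_A) - H(X_{1:n}),

a normalized average of size-`k` subset entropies minus the joint entropy.
`C(1)` is the total correlation `Σ_i H(X_i) - H(X_{1:n})`; `C(n) = 0`; and
`C(k)` is monotone decreasing in `k`. The local differences

    C(k-1||k) = C(k-1) - C(k) >= 0

therefore split the total correlation into `n-1` non-negative
contributions, attributed to the growth from size-(k-1) to size-k subsets.
Distributions whose dependence is purely high-order (parity, MDS codes)
concentrate the entire profile in the last differences.

Two independent computational paths are implemented and cross-checked:

* the *difference form* above (averages of subset entropies), and
* the *conditional form*, obtained by averaging the entropy chain rule
  `H(X_A) = H(X_i | X_{A\i}) + H(X_{A\i})` over the `k` choices of `i`:

      C(k-1||k) = (1/k) binom(n-1,k-2)^{-1} Σ_{|B|=k-1} H(X_B)
                - (1/k) binom(n-1,k-1)^{-1} Σ_i Σ_{|B|=k-1, i∉B} H(X_i|X_B).

Unrolling the same recursion down to `k = 1` gives the cumulative form
implemented in `cumulative_differences`: writing
`T_m = binom(n-1,m-1)^{-1} Σ_{|A|=m} H(X_A)` and
`G_m = binom(n-1,m-1)^{-1} Σ_{|B|=m-1} Σ_{i∉B} H(X_i|X_B)`, the chain rule
gives `m T_m = (m-1) T_{m-1} + G_m`, hence

    Σ_{l=1}^{k} C(l||l+1) = (k/(k+1)) Σ_i H(X_i)
                          - (1/(k+1)) Σ_{l=2}^{k+1} G_l / 1
                          = C(1) - C(k+1).

The package derives this identity from scratch (the index placement
matters: the partial sum through `C(k||k+1)` needs conditional-entropy
terms through context size `k`, i.e. `G_2..G_{k+1}`); the test suite checks
it against the telescoping oracle on random joints to 1e-9.

### Directed: order-k information about a target

With a designated target `Y` and `n` *source* variables (the joint then
holds `n+1` variables),

    C_Y(k-1||k) = binom(n,k-1)^{-1} Σ_{|B|=k-1} H(Y|X_B)
                - binom(n,k)^{-1}   Σ_{|A|=k}   H(Y|X_A),

the average reduction in conditional entropy of `Y` when source contexts
grow by one variable. Non-negativity follows because each size-k subset
contains k size-(k-1) subsets and conditioning never increases entropy.
The convention at `k = 1` uses `H(Y | X_∅) = H(Y)`, so `C_Y(0||1)` equals
the mean over sources of `I(Y; X_i)` — it captures *all* first-order
information, confounding redundant and unique contributions (a deliberate
price of a decomposition with only `n` terms). Consecutive averages
telescope, so `Σ_k C_Y(k-1||k) = I(Y : X_{1:n})` exactly.

### Numerical choices

* Internal unit is nats; conversion to bits happens only at reporting
  surfaces. The canonical gate profiles are conventionally quoted in bits
  and the parity/MDS profiles in nats; every report carries a unit tag.
* `0 log 0 = 0`; masses below 1e-15 are treated as exact zeros.
* Subset enumeration is exhaustive with memoized marginal entropies
  (`EntropyCache`); caps on `Π q_i` (default 2^24 states) and on `n`
  (default 20) raise clear errors instead of silently subsampling.
* Equality contracts are asserted at 1e-9 absolute.
* Variables are 0-based internally; reports use 1-based labels
  (`C(1||2)`, `x1`, ...).
* Joint tables may be built from sample matrices by plug-in (empirical
  frequency) estimation, flagged `is_plugin_estimate`, with no bias
  correction: exact tables are used for all ground truths, and plug-in
  entropies are downward-biased by roughly `(S-1)/2M` nats.

## Benchmark generators

* **Parity(n)** — `n-1` iid uniform bits plus their XOR; uniform over the
  `2^{n-1}` even-parity states. Every proper-subset marginal is uniform,
  so the exact profile is `(0, ..., 0, ln 2)`.
* **MDS(n, k, q)** — uniform over the `q^k` codewords of a Reed–Solomon
  code: draw `k` field coefficients, evaluate the polynomial at points
  `0..n-1` in the prime field of size `q` (default `q = n`; `n = 7` and
  `n = 11` are prime). Reed–Solomon is chosen because it realizes the
  defining property exactly — any `k` symbols are jointly uniform and
  independent and determine the rest — giving analytic subset entropies
  `min(m, k) ln q`. The closed-form profile generator uses these directly,
  providing an enumeration-free second path.
* **Canonical gates** — XOR/AND/Redundant in bivariate and trivariate
  form, plus the sum gate (`Y = X1+X2+X3`) and the copy gate. Sources are
  iid uniform bits except the Redundant gates, where a single uniform bit
  is copied to every source and the target. The copy gate's three pairwise
  copies jointly determine the full source state, so `Y` is encoded as an
  8-letter categorical equal to `(X1, X2, X3)`; this reproduces the
  `(1, 1, 1)`-bit directed profile. The Unique, Redundant-XOR and XOR-AND
  test cases from the bivariate comparison literature are *not* generated:
  their generating processes are defined in external references and a
  naive reconstruction does not reproduce the quoted values, so they are
  excluded from the catalogue rather than guessed at.
* Default sample size is 100,000 with a deterministic seeded 70/30
  train/validation split. The canned benchmark runs in `nid.benchmarks`
  use 20,000 samples: parity-5 has 16 support states and MDS(7,3) has
  343, so empirical frequencies are already estimated to well under one
  percent and larger M only adds run time.

What sampled data do not emulate: real populations (e.g. binarized spike
trains) have heterogeneous marginals, autocorrelation in time, and mixed
interaction orders. Passing the benchmark suite shows the estimators
recover *pure, stationary, uniform-marginal* higher-order structure; it
does not certify behavior under temporal dependence or rate
inhomogeneity. The I/O path accepts arbitrary integer matrices so such
data can be analyzed, but no claims are tested against them.

## The neural estimator

Exact profiles need a combinatorial number of subset entropies, which is
hopeless beyond small `n`. The neural estimator replaces the average over
size-l contexts with a single learned context representation per variable:

* `phi_{-i}(0)` is a learned per-variable bias; a *layer-0 head* on it
  estimates the marginal `H(X_i)`.
* Layer `l` computes candidate statistics
  `psi_j(l) = f_l(phi_{-i}(l-1), X_j)` for every `j != i` through a shared
  2-layer feedforward map (per-variable value embeddings, relu hidden,
  linear output), then pools them: `phi_{-i}(l) = mean_j psi_j(l)` (max
  pooling is available as an option).
* A linear categorical head per (layer, variable) yields
  `log p(X_i | phi_{-i}(l))`.

The training loss is the uniform-weight average over layers of the summed
per-variable NLL (weights configurable). Because averaging over contexts
upper-bounds the minimum, each layer's validation NLL is an upper bound on
the corresponding averaged conditional entropy, and the whole objective is
a lower-bound surrogate for the cumulative local differences. Drops in
validation NLL between consecutive layers (`deltas`) are reported as
estimates of `C(l||l+1)`; negative drops are estimation noise and are
clipped to zero in reports (raw values retained). Mean pooling is linear,
not information-limiting, so structure can surface one or two layers
before the true order — observed on parity, where the drop concentrates
in layers 2–3 rather than 4 — and the one-to-one layer/order
correspondence is qualitative, not exact.

Choices left open by the construction, resolved as follows:

* psi networks are shared across target variables within a layer and
  separate across layers; heads are per (layer, variable).
* Layerwise NLLs are reported on the validation split.
* Optimizer Adam (lr 5e-3), statistic width 32, hidden width 64, embed
  width 8, batch 512, up to 120 epochs with patience-25 early stopping on
  the final-layer validation NLL, gradient-norm clipping at 5 (deep
  stacks are otherwise prone to unstable dynamics; 5 layers is the
  default). The MDS benchmark uses wider nets (48/96, embed 12) for its
  7-letter alphabets. Divergence (non-finite loss) raises immediately.
* Minibatches are collapsed to unique rows with multiplicity weights — an
  exact rewrite of the weighted loss that exploits the small support of
  the benchmark families.
* Determinism: all randomness flows from numpy generators seeded by the
  config; identical config and seed give identical runs on one machine.

### The frozen-model probe

To distinguish learning from memorization, the trained model is frozen
and a small feedforward head predicts each `X_i` from (a) the frozen
final-layer log-probabilities of *all* variables and (b) the raw values
of the *other* variables — never raw `X_i` (a leakage audit verifies this
before training). If the generating function was learned for even one
variable, extending it to the rest is a near-linear task (for parity,
XOR-ing one frozen prediction with the other raw bits), so the probe
converges immediately; a model that merely memorized provides nothing the
probe can use. The probe is deliberately tiny (hidden width 16, 25
epochs, lr 1e-2 for binary data; 64 units and 80 epochs for the 7-ary
code): at this scale it cannot learn the higher-order function from raw
inputs within its budget, which the randomly-initialized-frozen-model
control in the test suite confirms (on 5-parity the control stays above
half the `n ln 2` noise floor while the trained-model probe reaches
~1e-3 nats — a three-orders-of-magnitude separation).

## The masked autoregressive baseline

A MADE-style network — one feedforward net whose weight masks enforce an
autoregressive factorization over a variable ordering — is the standard
density-estimation baseline. One-hot inputs, two relu hidden layers
(64 units each), categorical output heads, degree-based masks. Variants:

* fixed single ordering (`made_nll`); on parity only the last variable in
  the ordering is informative, so its validation NLL is the figure of
  merit (0 if the parity map is learned, ln 2 if not);
* a pool of `n` random orderings sharing one network, resampled per batch
  (`made_s`) — the multi-ordering variant that keeps parameter count
  constant; the one-network-per-ordering alternative is omitted as
  parameter-inefficient;
* a sliding-window variant restricting each variable's context to the
  `k` previous positions — the "model only a linear number of size-k
  subsets" baseline. Window masks use dedicated hidden blocks per output
  position, since degree-based masks cannot express bounded windows.
  On data whose dependence order exceeds the window it correctly reports
  the noise floor.

A connectivity audit (finite perturbation of every non-predecessor) runs
before training and on demand.

## Scope and limitations

* Exact computation is bounded by the state cap; it is meant for ground
  truths and small systems, not for high-dimensional data — that is the
  estimator's job.
* No lattice-based partial information decomposition (redundancy /
  unique / synergy atoms) is computed; the directed profile is a
  deliberately coarser, tractable `n`-term decomposition. Published
  lattice values for the same gates are quoted in docs for comparison
  only. On those gates `C_Y(0||1)` coincides with classical redundancy
  measures except where unique information exists, and the synergy of
  maximum-entropy 3-variable decompositions is often equal to
  `C_Y(1||2) + C_Y(2||3)`; both observations are documented, not asserted
  as invariants.
* Entropy estimation from samples is plug-in only; no bias-corrected or
  continuous-variable estimators.
* The layer-difference estimates inherit the pooling caveat above: they
  localize information order only approximately.
* Neural results are stochastic; the benchmark checks use seed-averaged
  means with the tolerances stated alongside each published band.
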