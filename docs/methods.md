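# Methods

## Problem and model

The package searches chemical space for molecules with a prescribed
photophysical character: strong S0→S1 absorption, an emissive S1 minimum,
and a large absorption-to-emission shift. The search state is a partial
SMILES string; actions are tokens; a complete string is validated as a
molecule and sent to a photophysics evaluator; the resulting profile
(a_w, a_i, f_w, f_i) is scored by a bounded four-component reward and the
score is backpropagated through the search tree.

### Reward

Each wavelength contributes a Gaussian band exp(−(x−T)²/2σ²) centred on its
target; each oscillator strength contributes tanh((log10(x+ε) − log10 T)²).
Defaults (all configurable through `RewardParams`):

| parameter | default | units | role |
|---|---|---|---|
| T_aw / T_fw | 700 / 1200 | nm | wavelength targets (near-IR bioimaging window) |
| T_ai / T_fi | 0.01 / 0.01 | — | oscillator-strength thresholds |
| W_aw, W_ai, W_fw, W_fi | 0.4, 0.1, 0.4, 0.1 | — | component weights (sum to 1) |
| σ_a / σ_f | 150 / 150 | nm | Gaussian band widths |
| ε | 1e-8 | — | log floor so OS = 0 is finite |
| C | 4 | — | exploration constant of the tree search |

Because the weights sum to 1 and every component lies in [0, 1], the total
reward is bounded in [0, 1]; a failed evaluation scores exactly 0.

The tanh-of-squared-log form is symmetric in the log distance from the
threshold, so it scores an OS far *below* threshold as high as one far
above. We keep it as the default (`literal_squared`) because it is the
form the reward was originally specified in, and provide a
`signed_monotone` variant — max(0, tanh(log10(x+ε) − log10 T)) — for users
who want intensity strictly rewarded. Note that tanh saturates to exactly
1.0 in double precision once the squared log distance exceeds ~19, so the
analytic open bound [0, 1) is closed at machine precision.

### Selection with virtual loss

Children are scored by S_i = R_i/(v_i+w_i) + C·P_i·√(v_p+w_p)/(1+v_i+w_i).
Choices that were genuinely open and how we fixed them:

* **Square root.** The exploration numerator is read as √(v_p+w_p), the
  standard PUCT form.
* **Unvisited nodes.** At v_i+w_i = 0 the exploitation term is defined as
  0 (not ∞), so first visits are driven by the prior and the parent count;
  this also keeps the virtual-loss bookkeeping divide-by-zero free.
* **Virtual loss magnitude.** One unit per in-flight path, applied to every
  node on the selected path atomically with selection and removed at
  backpropagation. After quiescence every w_i is 0 (tested).
* **Ties.** Broken toward the lowest vocabulary index, deterministically.
* **Budget accounting.** `budget` counts oracle evaluations of *new valid*
  molecules — the expensive quantity in real deployments. Invalid strings
  and duplicates still backpropagate (reward 0 and the cached reward,
  respectively) so the tree learns from them, but do not consume budget.
  A rollout cap (default 20× budget) guarantees termination when the
  reachable unique-molecule space is smaller than the budget.
* **Parallelism contract.** The coordinator owns the tree: selection with
  virtual-loss application, completion sampling, deduplication and
  backpropagation are serialized; only evaluator calls run on a thread
  pool (up to `n_workers` in flight). Any concurrency mechanism honoring
  this single-writer contract is conformant; single-worker runs are
  bit-reproducible from (config, seed, corpus), and run manifests contain
  no wall-clock fields so artifacts are byte-stable.

### Language-model prior

The prior is a contract — a conditional next-token distribution plus a
seeded sampler — not a fixed architecture; search correctness does not
depend on prior quality. Two trainable implementations ship:

* `RecurrentPrior`: a single-layer Elman RNN (16-d embeddings, 32-d hidden
  state) over the corpus token alphabet, trained by full backpropagation
  through time with Adam (lr 5e-3, gradient-norm clip 5). It fits the
  bundled corpora in seconds on one CPU and is the default for `train`.
* `NGramPrior`: an interpolated back-off n-gram (order 3, mixing weight
  0.8 per observed context level, uniform base). Deterministic, trains by
  counting, and is the fast choice for tests and small runs.

Tokenization is longest-match: bracket atoms (`[nH]`), two-letter halogens
and `%NN` ring closures are single tokens, so arbitrary corpora load even
though the default element filter restricts molecules to H/C/N/O. Rollouts
default to 82 tokens maximum; a truncated (unterminated) sample is treated
as invalid.

## Oracles

`surrogate_evaluate` is a deterministic closed form over three structural
descriptors (conjugate length L, aromatic ring count A, nitrogen count N):
a_w = 150 + 55L + 15A nm, a_i = 1 − e^(−0.15(L+1)), f_w = a_w + 40 + 10N nm,
f_i = a_i·e^(−0.1A). It emulates the qualitative regularities of excited-
state calculations — conjugation elongation red-shifts and brightens
absorption, every molecule is Stokes-shifted — while being exact and
instantaneous, which is what makes search-vs-enumeration tests possible.
It does **not** emulate evaluation failures, excited-state character
changes, steric effects, or any of the quantum-mechanical subtlety that
makes real fluorophore design hard: a passing test shows the machinery is
correct, not that the surrogate's chemistry is.

The TD-DFT adapter writes input decks (default route `B3LYP/3-21G*` with
`TD(NStates=10)`; the S1 stage adds `Root=1` + `Opt`) from a deterministic
ETKDG embedding seeded by the canonical SMILES, and parses excited-state
announcement lines (index, energy, `f=` oscillator strength) from engine
logs. Wavelengths are recomputed from energies via hc = 1239.84193 eV·nm
rather than trusting printed roundings; when an optimization repeats the
TD block, only the final block is used. Absorption is taken from state 1
of the S0-geometry run and fluorescence from state 1 of the S1-optimized
run; state reordering along the optimization is out of scope. The engine
itself is never executed here — it plugs in behind the same evaluator
callable, wrapped in `CachedEvaluator` so duplicates are never recomputed
and failures degrade to a zero-reward profile.

## Structural descriptors

* **Aromatic rings**: SSSR rings whose bonds are all aromatic, under
  RDKit's aromaticity perception (which, e.g., treats the 2-pyranone ring
  of coumarin as aromatic).
* **Conjugate length**: molecules are kekulized (one kekulé structure,
  fixed by canonicalization), then every simple path with strictly
  alternating single/double bonds is enumerated exhaustively and the
  maximum number of double bonds on such a path is reported. A lone C=C
  is 1; kekulized benzene is 3; triple bonds do not participate. The
  "longest chain" reading (rather than a global sum of alternation units)
  was an open choice; we picked it because a length should measure a path
  extent, and it reproduces the intuition for benzene. Exhaustive DFS is
  affordable because generated molecules have tens of heavy atoms.

## Screening and statistics

The filter requires a_i > 0.1, f_w > 400 nm, f_i > 0.01 and
f_w − a_w > 100 nm. "Greater than" is strict by default; a `strict=False`
flag makes boundaries inclusive, so edge cases are decided explicitly,
never silently. Pass percentages are rounded half-up to two decimals.
The median generation index uses the lower median for even counts.
Pearson correlations are computed from centered sums; zero variance raises
rather than returning NaN.

## Problem sizes and test design

The suite runs on one CPU in well under a minute. The search-vs-oracle
checks use a four-token grammar ({C, O, =} + end, ≤ 6 tokens), whose 129
unique valid molecules can be enumerated and scored exactly; single-worker
search with budget 300 must hit the global optimum in ≥ 9 of 10 seeds, and
the (timing-stochastic) 4-worker run must reach the top percentile over a
best-of-3-seeds replication. Prior-training checks use the bundled
138-molecule corpus (resampled to 500 strings for the held-out-likelihood
check). These sizes are the package's chosen desk-scale study conditions;
campaign-scale deployments differ only in budget, corpus, and oracle.

## Known limitations

* The surrogate's linear structure–property map is far simpler than real
  photophysics; correlation-recovery tests are parameter-recovery checks
  on the surrogate, not chemical findings.
* The RNN prior is intentionally small; it is not a reimplementation of
  any published SMILES generator and makes no claim of sample quality on
  large corpora.
* Multi-worker searches are not bit-reproducible (completion order depends
  on thread timing); all ledger invariants still hold.
* No conformer search: one deterministic embedding per canonical SMILES
  feeds the deck writer. Stereochemistry is not handled.
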