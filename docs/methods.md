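# Methods

## Model and likelihood

`markorder` treats a subject's event directions as realizations of a
stationary two-state Markov chain of unknown order n ∈ {0, 1, 2, 3}. The
parameterization is by switch probabilities: for each of the 2ⁿ history
words w (oldest symbol first, most recent last), ε_w = Pr(next symbol ≠
last symbol of w). This is equivalent to, and more economical than, the
full conditional table: relabeling the data L↔R permutes the ε vector but
never changes its values, which makes the relabeling invariance of all
downstream quantities easy to state and test.

Order-n chains are handled as first-order chains in word space. Words are
indexed lexicographically with L=0, R=1 and the oldest symbol as the most
significant bit; the successor of word i under appended symbol s is
`((i & (2^(n-1)-1)) << 1) | s`. Each row of the 2ⁿ×2ⁿ word transition
matrix has exactly two nonzero entries (switch/stay); all other entries
are exact structural zeros. The stationary distribution π(ε) is the left
Perron–Frobenius eigenvector normalized to sum 1.

The exact log-likelihood of pooled trials is

    Σ_trials log π(initial word) + Σ_i [c_i log ε_i + c̄_i log(1−ε_i)]

with per-word switch counts c_i and stay counts c̄_i. For n = 0 the
initial word is empty and the counts are the symbol totals over *all*
symbols (no symbols are set aside for a prefactor). Counts and initial
words are a sufficient statistic; pooling adds counts and concatenates
initial words. The 0·log 0 = 0 convention applies, so boundary parameters
conflicting with observed counts yield −∞, not an exception.

## Evidence computation

The evidence of order n is the likelihood integrated against a flat prior
on (0,1)^(2ⁿ). Three routes:

* **Analytic (uniform initial words).** Weighting every initial word by
  2⁻ⁿ separates the integral into Beta functions:
  log E = −nT log 2 + Σ_i log B(c_i+1, c̄_i+1), T = pooled trials.
  Exact at order 0. Adequate for long sequences only; at 20–50 symbols
  the prefactor choice visibly moves the evidence, which is the reason
  for the exact treatment.
* **Midpoint grid (default, orders ≤ 2).** G equidistant midpoint nodes
  (k−½)/G per dimension (G = 100 for orders 0–1; G = 30 at order 2,
  i.e. 8.1·10⁵ nodes in 4 dimensions), with π(ε) evaluated at every
  node and the cell-volume-weighted log-sum-exp of the log-likelihood.
  Midpoint nodes never touch 0 or 1 (asserted), so π is always defined.
  Grids beyond 10⁷ nodes are refused with a pointer to Monte Carlo.
* **Monte Carlo (default at order 3).** ε drawn uniformly on the open
  hypercube with a caller-supplied seed; log E = log-sum-exp(ll) − log N
  with N = 10⁵ samples, and a delta-method standard error
  se(log Ê) ≈ sd(w)/(√N · mean(w)) on shifted weights w. The standard
  error is surfaced so the selector can warn when a parsimony decision
  sits within ±3 se of the threshold.

Everything is accumulated in log space; raw products of trial
probabilities underflow for pooled subjects.

Stationary distributions inside the integral are computed for whole node
batches at once by solving (Mᵀ−I)π = 0 with the last equation replaced by
normalization — mathematically identical to the eigen-route used by the
single-model API (a test asserts agreement to 1e-10) but vectorizable
with stacked LAPACK solves, which makes the order-2 grid a sub-second
operation instead of minutes. Independent cross-checks in the test suite:
the closed forms π_L = ε_R/(ε_L+ε_R) at order 1 and
(π_LL, π_LR, π_RL, π_RR) ∝ ((1−ε_RL)/ε_LL, 1, 1, (1−ε_LR)/ε_RR) at
order 2, a brute-force enumeration showing likelihoods of all length-8
sequences sum to 1, and a 10×-resolution Simpson quadrature of the
order-1 evidence.

### Numerical accuracy of the midpoint rule

For trial-like statistics (every word observed switching and staying a
few times) the integrand vanishes to high order at the hypercube
boundary, the Euler–Maclaurin boundary terms cancel, and the 100-point
midpoint rule is accurate far beyond its nominal O(G⁻²): relative errors
against the Beta-product closed form are below 1e-10. The rule degrades
when the integrand concentrates mass *at* the boundary — a word with
c_i ≤ 1 switches against ~30 stays gives relative errors up to ~1e-2.
Pooled multi-trial data rarely produces such counts, but single extreme
trials can; raising G (configurable) restores accuracy quadratically.

## Order selection

DB_k = 10·log₁₀(E_k/E_0) decibans against the order-0 null (DB_0 ≡ 0),
labeled on the Jeffreys scale with configurable band edges at
0/5/10/15/20 dB. Nesting means data of true order k also produce
DB_{k+1} > 0; selection therefore takes the smallest order within a
parsimony margin (default 5 dB — one Jeffreys interpretation band, a
visible and configurable reading of "equivalent strength") of the maximal
DB. Margin 0 reduces to argmax with lowest-order tie-breaking; if no
order beats the null by the margin the null is selected. Pairwise
comparisons between adjacent orders are derivable from the stored log
evidences.

## Simulator and synthetic fixtures

The simulator generates the validation conditions: random transition
matrices with iid Uniform(0,1) switch probabilities (the flat prior's own
law — the natural choice absent any other stated distribution), 30,000
burn-in iterates before emitting symbols (initial word uniform over
words; a test verifies the burn-in erases it), and sequence lengths of
20–50 symbols, ~30 trials per synthetic subject — the shape of per-trial
direction sequences in a fixation experiment. The benchmark dataset
default is 532 sequences per order split evenly over 19 random models
(28 each). An optional exclusion band redraws parameters within h of 0.5,
since near-chance parameters are unidentifiable at these lengths.

A master seed derives per-(order, model, sequence) child seeds through
`SeedSequence` spawn keys, so datasets are byte-identical across runs and
any single sequence is reproducible in isolation.

What the fixtures deliberately do not emulate: inter-event times, eye
position or microsaccade waveforms, amplitude/displacement covariates,
and inter-trial parameter drift. Passing the recovery benchmark shows the
estimator identifies memory length from direction statistics alone; it
says nothing about detection or direction-assignment errors upstream of
the symbol sequences.

### Identifiability limits of the recovery benchmark

The per-parameter exclusion band bounds each ε_i away from chance but not
parameter *combinations* equivalent to a lower order: an order-1 chain
with ε_L + ε_R = 1 is exactly an iid coin, and an order-2 chain whose
switch probabilities depend only on the last symbol is exactly
first-order. Under iid Uniform draws with h = 0.2, roughly a quarter of
"order-1" models fall close enough to the iid manifold that, at 30×40
symbols, the order-0 model genuinely attains higher evidence — and the
estimator, correctly, selects 0. Replicated recovery rates are therefore
~75% for true order 1 (100% for order 0, ~85% for order 2) when
"correct" is scored against the generator's label rather than against
the statistically supportable order. This is a property of the benchmark
labeling, not an estimator error.

## Degenerate inputs and edge cases

* Switch probabilities exactly 0 or 1 are rejected by stationary
  computations (non-unique invariant measure) but permitted in MLE
  matrices; integration nodes and samples are always interior.
* Words never observed get an undefined (NaN-flagged) MLE entry, never
  an imputed 0.
* Trials shorter than order+1 symbols raise by default; a policy flag
  drops them with a logged warning instead.
* Zero-length data gives log E = 0 for every order and method (the prior
  integrates to 1), keeping evidences comparable.

## Problem sizes

Defaults were chosen so a full four-order estimate of one subject runs in
about a second (order-2 grid G = 30; order-3 Monte Carlo N = 10⁵,
se(log E) ≈ 1 dB-scale unit on typical fixtures) and the 150-replicate
recovery experiment in ~2 minutes on one CPU; all sizes are configurable
upward where more precision is wanted.
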