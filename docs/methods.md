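# Methods

## Model

Observed data are per-sample reaction abundances over a reaction catalog.
Each reaction is a hyper-edge from a non-empty substrate compound set to a
non-empty product compound set; it is decomposed into the full Cartesian
product of substrate × product *pairs*. The Cartesian expansion is the
decomposition consistent with a fixed per-reaction pair count J and with
pairs being coupled only through a shared subnetwork label; an optional
`reversible` flag appends the reversed pairs. A compound may appear on
both sides (intermediary compounds). One occurrence of reaction *i* in
sample *n* is a *token*; abundance m means m independently labelled

tokens.

Generative process, with C compounds, K metabosystems, L subnetworks:

* θ_n ~ Dir_K(α_θ) per sample; φ_k ~ Dir_L(α_φ) per metabosystem;
  δ_l, γ_l ~ Dir_C(α_δ), Dir_C(α_γ) per subnetwork.
* Token: Z ~ Cat(θ_n), Y ~ Cat(φ_Z); each of its J pairs draws a substrate
  from δ_Y and a product from γ_Y, conditionally iid given Y.

All four concentrations default to 0.01. Small values push each sample
onto few metabosystems, each metabosystem onto few subnetworks and each
subnetwork onto few compounds, which is what makes the decomposition
interpretable; they are independently settable (`--alpha-theta` etc.).

## Inference

Collapsed Gibbs sampling over the joint per-token labels (Z, Y); θ, φ, δ,
γ are integrated out analytically. The per-token conditional (README shows
the formula) uses the *exclude-self* convention — the token's full
contribution (one θ- and one φ-level count, J substrate and J product
slots) is removed before evaluation — and the ascending-factorial
Dirichlet-multinomial predictive across the token's slots, with
within-token repeat offsets a_j. A naive product of singleton predictives
would be wrong whenever a token repeats a compound; the enumeration oracle
in the test suite distinguishes the two.

Implementation choices:

* Labels are drawn jointly over the flattened K×L table with a single
  inverse-CDF uniform per token per sweep, so seeded runs are bit-for-bit
  reproducible regardless of the surrounding vectorisation. Visit order is
  sample index then token index; an explicit `order` argument exists (used
  by the reversed-order stationarity test).
* Initialisation is uniform-random labels (the symmetric prior makes any
  fixed start arbitrary); α = 0 is rejected at validation, so
  zero-probability table entries cannot occur.
* The inner loop is a numba kernel; tokens with more than 32 pairs switch
  to a log-space evaluation of the same quantity to avoid underflow of
  long predictive products. A pure-NumPy reference (`conditional_table`)
  implements both paths and is tested against the compiled kernel and
  against a brute-force gamma-function oracle to 1e-10 relative error.
* Schedule defaults follow the published protocol: 100 burn-in sweeps,
  then 500 retained draws at lag 20.

Posterior estimates: θ and φ per retained draw are unsmoothed assignment
frequencies (the estimator the protocol describes), averaged over draws;
an empty metabosystem yields a uniform φ row plus a warning. δ, γ and the
per-subnetwork reaction profile are *prior-smoothed* frequencies
((count + α)/(total + Cα)), so every compound and reaction keeps positive
mass and downstream JSD is defined on full support. The per-subnetwork
reaction profile (smoothed frequency of tokens of each reaction among a
subnetwork's tokens, smoothing α_r = α_δ by default) is this package's
reconstruction of the published per-reaction mixing probabilities, whose
exact construction is not specified in the primary text.

Within-chain label switching is not corrected — sparse priors keep modes
well separated — but a diagnostic counts consecutive-draw φ permutation
mismatches and warns when any occur. Cross-run/label coordination is done
downstream by optimal assignment (Hungarian) on composition JSD or L1;
compositions rather than φ are compared because subnetwork spaces differ
across L.

## Analysis layer

* Reaction composition of metabosystem k: φ_k-weighted mixture of the
  subnetwork reaction profiles.
* JSD uses base-2 logs (maximum 1, heat-map friendly); the membership
  score |log(φ_kl / max_{k'≠k} φ_k'l)| uses natural logs. Neither base is
  dictated by the source protocol; both are configurable. Scores floor φ
  entries at 1e-12 before the ratio.
* Principal subnetworks: strict φ_kl > 2/L (strict per the published
  wording); principal reactions: inclusive profile ≥ 2/R (the filter
  removes "< 2/R"), with R the number of distinct reactions in the
  dataset. Boundary behaviour is tested.
* Discriminatory (threshold ln 2 ≈ 2-fold, configurable): a principal
  subnetwork whose membership in k *exceeds every other metabosystem's*
  and whose score clears the threshold. The directionality condition is
  deliberate: the score is an absolute value, and without the condition a
  subnetwork would also flag the metabosystems it is depleted in.
* Core: membership > 2/L in every metabosystem and discriminatory for
  none; core ∩ discriminatory = ∅ by construction. The numeric
  discriminatory threshold and the core definition are reconstructions of
  criteria whose exact published form lives in supplementary material.

## Synthetic data

The generator replays the generative process exactly and is the package's
validation bed. Defaults are one cell of the published simulation design:
N = 40 samples, C = 100 compounds, K = 3, L = 10, per-sample token count ~
Poisson(1000) (zero draws resampled: a sample must contain a token), pair
count J ~ Poisson(2)+1, generating α = 0.10 at the θ and φ levels (grid
levels {0.05, 0.10, 0.20}; `simulation_grid()` enumerates the full
4×3×2×3×3 = 216-cell factorial with distinct seeds). The compound-level
generating concentrations are not specified in the published design; the
default 0.05 gives sparse subnetworks, matching the model's stated intent.

A simulated reaction's identity is the (sorted substrate multiset, sorted
product multiset) of a token's draws, interned into the catalog on first
occurrence; identical tokens within a sample accumulate abundance. The
exact drawn slot multisets are preserved in memory via explicit pair
lists; writing such a catalog to TSV and re-reading collapses repeated
draws to compound *sets* (file round-trips are exact on sets, which is the
contract of the file format).

What the generator does **not** emulate: read-level noise, EC-annotation
error, count scaling or sequencing-depth variation. A green recovery test
therefore establishes correctness of the inference machinery on data the
model describes, not robustness to upstream processing of real
metagenomes.

## Validation and numerical checks

* **Exact-posterior agreement**: on an enumerable instance (4 tokens,
  K = L = 2, C = 4) the chain's empirical distribution over full label
  configurations is within total variation 0.01 of the posterior computed
  by brute-force enumeration of collapsed joint probabilities
  (gamma-function oracle, written independently of the sampler). Moderate
  concentrations (0.5) are used there so the chain mixes across the whole
  256-configuration support and the 200k-draw noise floor (≈ Σ√p·√(2/πn)/2
  ≈ 0.006) sits below the band; draws are thinned (lag 10) to approach
  that iid floor. The same check runs under a reversed token visit order.
* **Parameter recovery**: simulate at generating α ∈ {0.05, 0.10, 0.20},
  fit with all concentrations at 0.01; after Hungarian matching the mean
  per-sample L1 between estimated and true θ must be ≤ 0.15 (observed
  ≈ 0.006–0.036). The retained-draw schedule is thinned to 100 draws at
  lag 5 (instead of 500 at lag 20) to fit a CI budget; burn-in is
  unchanged.
* **Geweke-style prior consistency**: forward simulation from the prior
  vs. a successive-conditional chain (package label updates alternating
  with slot-wise data redraws) agree on count-statistic means within 3
  standard errors.
* **Conservation**: all count tables are integer-conserved after every
  sweep; every output row (θ, φ, δ, γ, profiles, compositions) sums to 1
  within 1e-9.

## Known limitations

* Single-chain semantics; run multiple chains with distinct seeds and
  coordinate with `match_components`.
* K and L are fixed inputs; choosing them is the user's (heuristic) task,
  supported by the JSD-across-L heat-map workflow.
* No hyper-priors on the concentrations; no variational alternative.
* Raw-read processing (reads → EC numbers → reaction counts) is out of
  scope; inputs are reaction abundances.
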