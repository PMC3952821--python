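# Methods

## The model

`mphmm` implements mixed pair hidden Markov models (MPHs): generative
models of a *pair* of sequences — a continuous stimulus sequence
`X = x_1..x_Tx` (embedded window vectors of dimension `d`) and a discrete
binned spike response `R = r_1..r_Tr` (`r ∈ {0..V−1}`, `V = 2` throughout
the supported experiments).  A hidden Markov chain walks over three kinds of
states:

* **M (match)** states emit a (stimulus, response) pair with density
  `e_s(x, r) = P(r | s) · p(x | s, r)`, where each `p(x | s, r)` is a
  Gaussian mixture.  An M-state advances both sequences — a diagonal step in
  the alignment matrix.
* **X** states emit only a stimulus vector (Gaussian mixture; horizontal
  step).
* **R** states emit only a response symbol (categorical; vertical step).

A hidden path is thus a monotone lattice path from `(0, 0)` to `(Tx, Tr)`;
the difference `j − i` at a matching step is the momentary lag between a
spike and the stimulus it is matched to.  X/R excursions change the lag, so
spike-time jitter and slowly varying response latencies become properties
of the path distribution rather than violations of the model.  Multiple
M-states express state-dependent codes: each carries its own
spike-conditioned mean (receptive field), and the transition matrix carries
the switching dynamics.

Parameters: transitions `a(s, s′)`, initial probabilities `ρ`, final
probabilities `τ`, and the per-state emission parameters.  We adopt the
convention `Σ_s′ a(s, s′) + τ(s) = 1` per state, so the model is a proper
distribution over finite paths and the forward termination
`P(X, R) = Σ_s α(Tx, Tr, s) τ(s)` is well defined.  `τ` is re-estimated in
the M-step from terminal occupancies, symmetric to the `ρ` update.

## Inference

Generalized forward, backward, and Viterbi recursions run over the banded
alignment tensor `(i, j, s)` with `|i − j| ≤ W`; `W` (the band width, in
bins) caps the lag the model may consider and reduces complexity from
`O(Tx · Tr · N²)` to `O((Tx + Tr) · W · N²)`.  All recursions are in the
log domain (log-sum-exp); sequences of 10⁴ bins at `d = 40` pose no
underflow risk.  Banding is exact whenever all path mass lies within the
band, and in particular for `W ≥ max(Tx, Tr)`.  The inner loops are
compiled with numba; an untouched pure-Python fallback keeps the package
functional (slowly) without it.

Posteriors are `γ(i, j, s) = α(i, j, s) β(i, j, s) / P(X, R)`.  The
**alignment kernel** — the model's estimate of the jitter/latency
distribution — is the posterior-weighted histogram of lags `j − i` over
M-state cells whose response symbol is a spike, normalized to sum to one.
Negative lags mean the spike precedes its matched stimulus.  By default
only M-state posteriors enter the sum (in the supported architectures
R-states never emit spikes); a flag includes spiking R-states for models
that use them.

A brute-force path enumerator (exponential time, exact linear-domain
arithmetic) serves as an independent oracle; the test suite certifies the
DP quantities against it on ~100 random small instances at 1e-9.

### Per-state lag bounds

`MPHModel.lag_bounds` optionally restricts individual states to a lag
interval inside the band.  Its purpose is internal: rewriting an M-state
into an X→R chain (below) sends paths through an intermediate cell one lag
below the original diagonal cell, so the rewritten model needs band
`W + 1` for that one state only.  Bounding the branch X-states to
`[−W−1, W−1]` and everything else to `[−W, W]` makes banded inference in
the rewritten model *exactly* equal to the original (tested to 1e-9 over
random models); without the bounds the wider band would admit X/R
excursions the original model truncates.

## Learning

Fitting is by EM.  The E-step computes `γ` and expected transition counts
`ξ` per pair; the M-step renormalizes statistics pooled over all pairs:
transitions and `τ` from `ξ` and terminal occupancies, `ρ` from start
occupancies, discrete emissions from symbol-split occupancies, and Gaussian
mixture components from responsibility-weighted moments (for M-states,
summed only over positions whose consumed response symbol matches the
conditional being updated).

Constraint flags are honored after the free update: `mean_mode ∈
{fixed_zero, fixed_value, free}` and `covariance_mode ∈ {identity,
fixed_shared, free}` per emission.  Templates:

* `build_mxr_template` — one M-, one X-, one R-state; all covariances fixed
  (identity or a supplied shared matrix), X/no-spike means fixed to the
  ensemble mean, R-state never spikes; free: the spike-conditioned M mean
  (the RF), the M spike marginal, and the transition structure.
* `build_mn_template(n)` — `n` M-states, no X/R; free: the `n` RFs, spike
  marginals, transitions.  `n = 1` is the minimal matching model.

Numerical choices: freshly estimated free covariances get an eigenvalue
floor of 1e-6 × their mean diagonal; a mixture component with zero
responsibility keeps its parameters and gets weight 0 with a warning; an
unused state keeps its old transition row.  Initialization for restarts
draws Dirichlet jitter around the template's transition rows and starts
free spike-conditioned means at the spike-triggered mean plus Gaussian
noise (breaking symmetry between multiple M-states).  Stopping: relative
log-likelihood change below 1e-6 (default) or 200 iterations; with
restarts the highest-likelihood fit wins.  The training log-likelihood is
non-decreasing (tested to 1e-8 across 50 seeded fits).

## Encoding and the LNP bridge

For a single M-state with shared covariance `Σ`, spike prior `p₁`, and
conditional means `μ₀, μ₁`, the posterior spike probability is exactly

    P(spike | x) = sigmoid(w·x + c),   w = Σ⁻¹(μ₁ − μ₀),
    c = log(p₁/p₀) − ½(μ₁ᵀΣ⁻¹μ₁ − μ₀ᵀΣ⁻¹μ₀)

— a one-dimensional LNP cascade whose filter is the reverse-correlation
(whitened spike-triggered average) solution; with white stimuli and one EM
iteration the fitted spike mean *is* the STA.  `baselines.lnp_from_mmph`
exposes the closed form; the package-level inference path reproduces it to
machine precision.

General response-probability inference rewrites each M-state into two
branch chains `x_v → r_v` (v = no-spike / spike) with incoming transitions
split by the spike marginal, and splits stochastic R-states likewise; the
rewritten model assigns identical pair probabilities.  Forward-backward
with the response marginalized (deterministic R emissions contribute 1)
then yields `P(r_j = 1 | X)` as the posterior mass of spike-branch states
at position `j`, normalized over all response-consuming states.  The
normalization equals 1 analytically; dividing explicitly guards rounding.
This route is certified against brute-force marginalization over all `2^Tr`
response sequences on small instances.

`encode_map` extends Viterbi to maximize jointly over (path, response):
each response-consuming cell takes the symbol with maximal emission, and
backtracking recovers both sequences.  `Tr` defaults to `Tx` at prediction
time.

The **cascade** estimates an output nonlinearity `g(p)` on the posterior
spike probability by histogram division — spike-coincident counts over
total counts in 25 equal-width probability bins, empty bins filled by
linear interpolation, application by linear interpolation between bin
centers, clipped to [0, 1].  On data generated by the model itself the
mapping calibrates to the identity (count-weighted mean |g(p) − p| ≈ 0.004
at 10⁵ bins); on data whose true nonlinearity is steeper than the implied
sigmoid it corrects the operating curve and improves validation CC.

## Synthetic experiments and what they show

The generators emulate the reference designs: white-noise stimuli
(i.i.d. standard normal channels), a correlated Gaussian stand-in for
natural stimuli (AR(1) in time, squared-exponential channel mixing),
Bernoulli LNP spiking with a sigmoid nonlinearity whose offset is solved by
bisection to hit a target mean rate, i.i.d. spike jitter from a discretized
log-normal pmf (continuous mean placed at lag 0; increasingly right-skewed
with variance), and a symmetric Markov switching process over two LNP
models (stay probability 0.98 — dwell times of order 100 bins).
Jittered spikes falling outside the sequence are dropped; coincident
spikes collapse to one (binary trains).

Experiment scales (chosen once as the package defaults): the jitter
experiment uses 20 000 bins at `d = 20` (2 channels × 10-bin window), rate
0.015 spikes/bin (~300 spikes), jitter variances {0, 2, 6} bins², 16
training / 4 validation sequences of 1000 bins, band `W = 8`; the
switching experiment uses 10 000 bins at `d = 21`, rate 0.044, rotation
angles {60°, 120°, 180°}; the cascade calibration uses 10⁵ bins.  These
sizes keep several hundred spikes — the regime where the comparisons are
meaningful — while a full run takes minutes on one core.

Baselines: STA (spike-bin mean minus ensemble mean; its rate predictor is
the single-M-state sigmoid with moments set from the data), reverse
correlation (regularized-covariance solve; the trace-preserving shrinkage
`(1−λ)C + λ(tr C / d) I`, default λ = 0.1, keeps rank-deficient solves
conditioned), STC (eigenvectors of the spike-triggered minus ensemble
covariance, ranked by |eigenvalue|; its rate predictor is a subspace
histogram), and a sampling upper bound on attainable CC (mean pairwise CC
among independently re-jittered ideal trains).  Rates are smoothed with a
Gaussian kernel (σ = 2 bins) before correlating.

**Reference-lag degeneracy.**  The (RF, alignment kernel) pair is
identified only jointly up to an integer time shift: delaying the RF by one
window bin and shifting the kernel by the opposite lag leaves the
likelihood essentially unchanged, and with asymmetric jitter the fitted
optimum often sits at the jitter mode rather than at lag 0.  RF similarity
is therefore reported as the shift-invariant cosine (maximum over integer
within-window shifts), and the estimated kernel is translated by the RF's
best-match shift before comparison with the generating pmf.  Plain cosines
are reported alongside.

What passing tests do and do not show: the synthetic data are Gaussian,
stationary, and exactly LNP/Markov-generated, with jitter i.i.d. per spike.
Real recordings violate all of these (non-Gaussian stimuli, nonstationary
rates, correlated jitter, spike sorting noise); the experiments certify
the estimation machinery and its relative advantages under the generating
assumptions, not performance on any particular dataset.

## Known limitations

* Binary responses only for rewriting/encoding (`V = 2`); larger alphabets
  are supported by the DP and EM but untested beyond construction.
* No linear-memory checkpointed DP: tensors are held densely over the band
  (fine for 10⁵-bin sequences at small band widths).
* Viterbi training, discriminative criteria, and stimulus decoding are out
  of scope.
* The cascade mapping is a raw histogram ratio; no isotonic smoothing is
  applied by default.
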