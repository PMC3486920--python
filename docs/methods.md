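# Methods

This note documents the models, the synthetic-experiment generator, the
numerical choices behind the fits, and the limits of what the simulated
results can show.

## Task and staircase

Each simulated block is 80 two-alternative forced-choice trials. The
percent difference Δ between the two tone frequencies is controlled by a
transformed up-down (3-down-1-up) staircase: after every third
consecutive correct response Δ decreases by the current step, after any
error it increases by the current step, steps are applied additively in
percent space (20 → 15.5 after a 4.5% down-step), and Δ is clamped at
0.1% from below. Δ starts at 20%; the step sizes are 4.5, 2, 1, 0.5 and
0.1%, advancing one position after every four reversals and staying on
the last value. A *reversal* is a move whose direction differs from the
previous non-null direction; the Δ in force on the reversal trial is
logged, and the staircase JND is the mean of the last six logged values.
This rule drives any observer whose probability of a correct response
increases continuously with Δ to the level where `p³ = ½`, i.e.
`p ≈ 0.794`, which is also the criterion at which psychometric-based
JNDs are read off.

Exclusions mirror standard practice for this paradigm: blocks that do
not reach 65% correct over their final 40 trials are dropped, and the
first 15 trials of kept blocks (where Δ is still far from threshold) are
flagged ineligible for analysis while still feeding observers' memory
and the lagged regressors.

## Stimulus generators

*Experiment 1*: base frequency `f ~ U(800, 1200)` Hz; the comparison is
`f·(1 ± Δ/100)` with equal probability, and the pair is assigned to
(tone 1, tone 2) in random order. The multiplicative construction keeps
Δ a ratio measure, consistent with reporting JNDs in percent.

*Experiment 2*: the pair's ln-mean is `m ~ N(6.908, 0.115)` (centred on
1000 Hz) and the two log-frequencies are `m ± δ/2` with
`δ = ln(1 + Δ/100)`, so the pair's log-mean equals `m` exactly. The
difference is defined in log space; the alternative ratio-on-linear
reading differs only at second order in Δ and is not separately
implemented. The tone *order* is biased: in the Bias+ condition the
second tone is the higher one with probability 0.9 when `m > ln 1000`
and the lower one with probability 0.9 when `m < ln 1000`; the Bias−
condition mirrors the rule. The 0.9 default reproduces a roughly 9:1
ratio of Bias+ to Bias− region trials within a condition and is
configurable (`BlockDesign.bias_prob`). The same 3-down-1-up controller
and step schedule governs δ in both experiments.

One master seed yields per-block child generators through
`numpy.random.SeedSequence.spawn`, so every trial table is reproducible
bit for bit and blocks are independent.

## Observer models

All computation is in natural-log frequency space; psychometrics relate
choices to `l1 − l2 = ln(f1/f2)`.

**Naive probit.** `P("tone 1 higher") = Φ((l1 − l2)/σ)`. σ is the
effective decision-noise SD in ln units; σ = 0.1 corresponds to an
analytic 79.4%-correct threshold of `100·(exp(0.8202·σ) − 1) ≈ 8.5%`,
inside the range reported for untrained listeners on this task.

**Implicit memory.** A single scalar trace `H` replaces the first tone:
on each trial `H ← γ·H + (1 − γ)·(l1 + ε)`, `ε ~ N(0, σ²)` i.i.d., and
the model reports "tone 1 higher" iff `H > l2` (exact ties, a
probability-zero event in simulation, are broken by a fair coin).
Iterating the update gives the closed form
`H_t = (1−γ)·Σ_k γ^k (l1_{t−k} + ε_{t−k}) + γ^t·H0`, which the test
suite verifies against the recursion to 1e-10. Noise is applied to tone
1 only, because noise on `l2` is equivalent at decision time to a larger
trace noise. The trace is initialized at the first trial's noisy `l1`;
with the 15-trial burn-in excluded from every analysis, the
initialization is immaterial (remnant weight `γ^15 < 5·10⁻⁴` at
γ = 0.6).

For fitting, the choice probability conditions on the noise-free
trace `S_t` and treats the accumulated noise as Gaussian with its
steady-state SD `σ_N = σ·√((1−γ)/(1+γ))` (the exponentially weighted
noise sum's limit variance): `P_t = Φ((S_t − l2)/σ_N)`. The finite-t
correction to `σ_N` decays like `γ^{2t}` and is negligible past the
burn-in. At γ = 0 this collapses exactly onto the naive model.

**Bayesian ideal detector.** The two tones are encoded as
`x_i = l_i + η_i`, `η_i ~ N(0, σ_i²)`, with `σ1 ≥ σ2` expected because
tone 1 must be held in memory across the inter-stimulus interval. The
observer knows the stimulus marginal, moment-matched by a Gaussian
prior: for Experiment 1 the exact moments of `ln U(800, 1200)`
(mean 6.9011 ln-Hz = ln 997.3, SD 0.1155), for Experiment 2
`N(6.908, 0.115)`. Posterior means `w_i·x_i + (1−w_i)·μ_p` with
`w_i = σ_p²/(σ_p² + σ_i²)` are compared, giving the closed form
`P = Φ((w1·l1 − w2·l2 + (w2 − w1)·μ_p)/√(w1²σ1² + w2²σ2²))`, verified
against brute-force sampling of the generative observer. Because
`w1 < w2`, tone 1 is contracted more, reproducing the contraction bias.
The posterior-mean comparison with a Gaussian prior is the reference
interpretation implemented here; comparisons of full posteriors under
this Gaussian model reduce to the same rule.

## Fitting

Every fit minimizes the **mean squared error** between the model's
per-trial probability vector and the 0/1 response vector — not the
likelihood — so flat-probability models are penalized the same way the
descriptive analyses are scored.

*LN history kernel.* Decision variable
`x_t = a·l1_t + b·l2_t + Σ_{k=1..K} c_k·l1_{t−k} + Σ_k d_k·l2_{t−k} +
e·ln f̄_t`, `P_t = Φ(x_t)`, with no intercept; `ln f̄_t` is the running
mean of the log-frequencies of *both* tones over all strictly previous
trials of the block (exclusive reading; regressors are raw ln-Hz, with
an optional centering flag for sensitivity checks). At K = 3 this is 9
free parameters. Optimization is L-BFGS-B with the analytic gradient
from 10 seeded starts (zeros plus small random perturbations); response
rows are eligible trials with at least K within-block predecessors, and
fits with fewer than 10 rows per parameter, or with constant responses
(complete separation), raise. 68% CIs — one-SD-equivalent bands — come
from a nonparametric bootstrap over blocks (default 1,000 resamples,
each refit started from the point estimate). Cross-validation is
leave-one-block-out with parameters pooled over training blocks; the
five nested variants keep {current tones}, {+ global mean}, {+ both lag
families}, {+ past-l1 lags only}, {+ past-l2 lags only}, and per-block
held-out MSEs are compared by Wilcoxon signed-rank tests.

*Implicit-memory and Bayesian per-block fits.* Coarse grids
(γ ∈ {0, 0.05, …, 0.95} × 16 log-spaced σ; 14×14 log-spaced (σ1, σ2))
followed by bounded L-BFGS-B refinement, γ capped at 0.99. Blocks must
supply at least 30 eligible trials. On 200 synthetic blocks at
(σ = 0.08, γ = 0.6) the median recovered parameters land within ±0.1 of
γ and ±25% of σ; σ is recovered with a mild downward bias because the
fitted probability conditions away the trial-to-trial correlation that
the shared trace noise induces.

*Psychometric JND.* Single free slope `a` in `P = Φ(a·(l1 − l2))`, no
bias term, fit by a log-spaced grid scan plus bounded Brent; the JND in
percent is `100·(exp(Φ⁻¹(0.794)/a) − 1)` (within 4% relative of the
simpler `100·Φ⁻¹(0.794)/a` at observed JND scales). Perfect separation
drives the slope to the search ceiling (500 per ln-ratio); such fits are
flagged `capped` rather than reported infinite, and capped or
under-populated region fits are dropped (with counts) from JND medians.

## Permutation tests

The null hypothesis — performance depends only on the frequency ratio —
is exchangeable under swapping the within-trial tone labels. Each
permutation therefore swaps each trial's labels independently with
probability ½ (whole-vector permutation would break the within-trial
pairing). A swap flips the trial's region (Bias+ ↔ Bias−, straddle
fixed) and simultaneously negates the psychometric regressor and flips
the response, which leaves each trial's correctness and squared-error
contribution invariant — so in practice only region membership is
re-randomized. Statistics: accuracy(Bias+) − accuracy(Bias−), and the
across-block median JND(Bias−) − median JND(Bias+). One-sided p-values
use the add-one estimator `p = (1 + #{perm ≥ obs})/(1 + n_perm)`, which
is never zero and is calibrated (p-values uniform under a history-free
null, checked by KS over 200 replicate simulations). Defaults are 10⁶
permutations for accuracy and 10⁵ for the JND statistic, both
configurable; the JND test refits two psychometric curves per block per
permutation, so analysis drivers and tests use reduced permutation
counts.

Trials with a tone exactly at the 1000 Hz median are classified
straddle by the strict inequalities; this is measure-zero in simulation
and documented for real-data edge cases. Accuracy maps use 10×10
log-spaced bins spanning the 2.5th–97.5th percentiles of pooled tone
frequencies by default, masking bins with fewer than 50 trials.

## Default study conditions and problem sizes

The generator defaults are the deployed protocol: 80-trial blocks,
staircase constants as above, Experiment-2 order-bias probability 0.9.
Simulated populations use σ = 0.08, γ = 0.6 for the implicit-memory
observer (the regime where the contraction is strong and parameter
recovery is well conditioned), σ = 0.1 for the naive observer, and
(σ1, σ2) = (0.15, 0.05) for the Bayesian population. Recovery and
calibration analyses use 200 blocks; cross-validation uses 30 blocks;
null-calibration uses 200 replicate datasets of 8 blocks at 2,000
permutations each; the acceptance computation uses 250 blocks. These
sizes give standard errors comfortably inside the assertion tolerances
while keeping every analysis a matter of seconds to minutes on one CPU.

## What the synthetic data do and do not show

The generator emulates the stimulus statistics, staircase dynamics,
exclusion rules and history-dependent choice processes of the task, so
passing tests demonstrate that the estimators recover the generative
truth and that the analysis pipeline detects (and correctly signs) the
contraction bias, the recency kernel, and the rigidity of the bias
under order-biased statistics. They do not reproduce human
participant-level numbers: real listeners show attention lapses,
learning and fatigue within blocks, heterogeneous (σ, γ) across
individuals and possibly within a block, and response-time structure,
none of which are modelled. With γ = 0.6 the simulated bias
(99% vs 51% region accuracies) is stronger than typically observed in
humans (~88% vs ~63%); directions and orderings, not magnitudes, are
the claims the simulations support.

## Known limitations

* The implicit-memory fit uses the steady-state noise SD and ignores
  across-trial correlation of the trace noise; σ estimates are
  consequently biased low by ~10–20% at 65-trial blocks (γ is
  essentially unbiased).
* MSE-based probit fitting with raw, highly collinear regressors (the
  lagged tones and the running mean all hover near ln 1000) yields wide
  bootstrap CIs on the history coefficients at small block counts.
* `permutation_test_jnd` is expensive (two psychometric refits per
  block per permutation) and is intended for reduced permutation counts
  in interactive use.
* The Bayesian observer is restricted to Gaussian priors over the two
  tone log-frequencies; mixture priors and joint (f1, f2) priors are out
  of scope.
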