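# tonebias

Simulation and analysis of history-dependent two-tone frequency
discrimination.

In the classic 2AFC tone task a listener hears two brief pure tones,
`f1` then `f2`, and reports which was higher. Performance is usually
summarized by a single just-noticeable difference (JND), implicitly
assuming the probability of a correct response depends only on the
frequency ratio `f1/f2`. It does not: listeners show a **contraction
bias** — the remembered first tone is pulled toward the centre of the
recent stimulus distribution — so accuracy is high when the pull helps
the comparison (both tones above the median with `f1 < f2`, or both
below with `f1 > f2`; the *Bias+* region) and poor in the mirrored
*Bias−* region, and the influence of previous trials decays over just a
few trials (a **recency effect**).

This package provides, for simulated experiments:

* **Experiment simulators** — adaptive 3-down-1-up staircase (initial
  difference 20%, floor 0.1%, steps 4.5/2/1/0.5/0.1% shrinking every
  four reversals, converging to the level where
  `p_correct^3 = 1/2 ⇒ p ≈ 0.794`), with Experiment-1 stimuli
  (`f ~ U(800, 1200)` Hz, random tone order) and Experiment-2 stimuli
  (pair ln-mean `~ N(6.908, 0.115)`, tone *order* biased conditional on
  the pair being above/below 1000 Hz), plus the standard exclusion rules
  (non-converged blocks, 15-trial burn-in).
* **Observer models**, each usable for simulation and for per-trial
  choice probabilities:
  * *naive*: `P("f1 higher") = Φ((ln f1 − ln f2)/σ)`;
  * *implicit memory*: a scalar trace
    `H_t = γ·H_{t−1} + (1−γ)(ln f1_t + ε_t)`, `ε_t ~ N(0, σ²)`, compared
    directly with `ln f2` — equivalently an exponentially weighted sum of
    current and past first tones;
  * *Bayesian ideal detector*: noisy encodings of both tones
    (`σ1 ≥ σ2`) shrunk toward a Gaussian prior with weights
    `w_i = σ_p²/(σ_p² + σ_i²)`; posterior means are compared.
* **Model fitting** by probit-MSE: the linear–nonlinear history kernel
  `P_t = Φ(a·l1_t + b·l2_t + Σ_k c_k·l1_{t−k} + Σ_k d_k·l2_{t−k} +
  e·ln f̄_t)` (9 parameters at lag depth K = 3) with block-bootstrap
  CIs and leave-one-block-out comparison of its nested variants;
  per-block `(σ, γ)` and `(σ1, σ2)` fits; single-slope psychometric
  curves with `JND% = 100·(exp(Φ⁻¹(0.794)/a) − 1)`; reversal-based
  staircase JNDs.
* **Bias analyses**: Bias+/Bias−/straddle region classification, binned
  `(f1, f2)` accuracy maps, and Monte Carlo permutation tests that
  randomly swap the within-trial tone labels.

## Worked example

Simulate a population of implicit-memory listeners in Experiment 1 and
quantify their contraction bias:

```sh
python analysis/01_simulate_experiments.py
python analysis/03_contraction_bias.py
```

which prints (seeds fixed in the scripts):

```
                 n  frac_correct     sem
bias_plus   2112.0        0.9920  0.0019
bias_minus  2137.0        0.5063  0.0108
straddle    2186.0        0.9218  0.0057
Fisher exact p (Bias+ vs Bias-): 0
accuracy difference 0.486, permutation p = 1.00e-05 (100000 permutations)
```

A listener with memory weight γ = 0.6 is near ceiling when the
contraction helps (99.2% correct in Bias+) and at chance when it hurts
(50.6% in Bias−); the tone-label permutation test puts the accuracy
difference far outside the null. `analysis/04_recency_kernel.py` then
recovers the exponentially decaying kernel from the choices alone
(positive, decreasing weights on past first tones; weights on past
second tones indistinguishable from zero), and its cross-validation
shows the past-`f1`-only model predicting as well as the full model —
the signature separating the implicit-memory account from a fixed-prior
Bayesian one. `analysis/06_rigidity_exp2.py` reproduces the rigidity
result: the same population has a mean JND of ~2.9% in the Bias+
condition but ~18% in the Bias− condition, and simply switching its
memory off (γ = 0) in Bias− would lower the JND to ~6.9%.

The analysis drivers are numbered in dependency order; 03 and 04 read
the trial tables written by 01 into `results/`.

A `tonebias` CLI exposes the same steps
(`tonebias simulate|fit|analyze|report|recover`, see `--help`).

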