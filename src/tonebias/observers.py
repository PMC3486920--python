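"""Generative choice models for the two-tone discrimination task.

Three observers are implemented, each usable both to simulate responses
trial by trial and to evaluate per-trial choice probabilities for fitting:

* **naive** — a history-free probit detector: the probability of reporting
  "tone 1 higher" is Phi((l1 - l2) / sigma), where l1, l2 are the two tone
  log-frequencies and sigma is the internal-noise SD in ln units.
* **implicit memory** — the first tone is not compared directly; instead a
  single scalar memory trace H, an exponentially weighted running average
  of noisy first-tone log-frequencies, is compared with the second tone.
  Two parameters: encoding-noise SD sigma and memory weight gamma.
* **Bayesian ideal detector** — both tones are encoded with Gaussian noise
  (SDs sigma1 >= sigma2, reflecting the memory cost of holding tone 1),
  combined with a Gaussian prior over log-frequency, and the two posterior
  means are compared. The asymmetric shrinkage toward the prior mean
  produces the contraction bias.

All computation is in natural-log frequency space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .stimuli import (
    EXP1_HIGH_HZ,
    EXP1_LOW_HZ,
    EXP2_LN_MEAN,
    EXP2_LN_SD,
    BlockDesign,
    TrialStimuli,
)

__all__ = [
    "NaiveParams",
    "ImplicitMemoryParams",
    "MemoryTrace",
    "BayesParams",
    "naive_choice_prob",
    "imm_update",
    "imm_closed_form",
    "imm_respond",
    "imm_signal",
    "imm_noise_sd",
    "imm_choice_prob",
    "bayes_choice_prob",
    "log_uniform_moments",
    "prior_for_design",
    "Observer",
    "NaiveObserver",
    "ImplicitMemoryObserver",
    "BayesianObserver",
    "AlwaysCorrectObserver",
    "make_observer",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class NaiveParams:
    """History-free probit detector: decision-noise SD in ln units."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class ImplicitMemoryParams:
    """Encoding-noise SD (ln units) and memory weight gamma in [0, 1)."""

    sigma: float
    gamma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")


@dataclass(frozen=True)
class MemoryTrace:
    """Scalar memory trace H (ln-Hz) after t tone-1 presentations."""

    H: float
    t: int = 0


@dataclass(frozen=True)
class BayesParams:
    """Representation-noise SDs of the two tones plus the Gaussian prior."""

    sigma1: float
    sigma2: float
    prior_mean: float
    prior_sd: float

    def __post_init__(self) -> None:
        if min(self.sigma1, self.sigma2, self.prior_sd) <= 0:
            raise ValueError("all standard deviations must be positive")


# ---------------------------------------------------------------------------
# choice probabilities and memory-trace algebra


def naive_choice_prob(l1: float, l2: float, params: NaiveParams) -> float:
    """P("tone 1 higher") = Phi((l1 - l2) / sigma)."""
    return float(stats.norm.cdf((l1 - l2) / params.sigma))


def imm_update(
    trace: MemoryTrace,
    l1: float,
    params: ImplicitMemoryParams,
    noise: float = 0.0,
) -> MemoryTrace:
    """One memory-trace update: H' = gamma*H + (1-gamma)*(l1 + noise)."""
    g = params.gamma
    return MemoryTrace(H=g * trace.H + (1.0 - g) * (l1 + noise), t=trace.t + 1)


def imm_closed_form(
    l1_history: Sequence[float],
    noises: Sequence[float],
    gamma: float,
    H0: float,
) -> float:
    """Closed form of the iterated trace update.

    After t updates the trace equals the exponentially weighted sum
    (1-gamma) * sum_k gamma**k * (l1[t-k] + eps[t-k]) plus the
    initialization remnant gamma**t * H0. Must agree with iterating
    :func:`imm_update` to float precision.
    """
    l1_history = np.asarray(l1_history, dtype=float)
    noises = np.asarray(noises, dtype=float)
    if l1_history.shape != noises.shape:
        raise ValueError("l1_history and noises must have equal length")
    t = l1_history.size
    if t < 1:
        raise ValueError("history must contain at least one trial")
    k = np.arange(t)  # k = 0 is the most recent trial
    weights = (1.0 - gamma) * gamma**k
    total = float(weights @ (l1_history[::-1] + noises[::-1]))
    return total + gamma**t * H0


def imm_respond(
    trace: MemoryTrace, l2: float, rng: np.random.Generator
) -> int:
    """Report "tone 1 higher" iff H > l2; exact ties broken by fair coin."""
    if trace.H > l2:
        return 1
    if trace.H < l2:
        return 0
    return int(rng.random() < 0.5)


def imm_signal(l1_seq: Sequence[float], gamma: float) -> np.ndarray:
    """Noise-free memory trace after each trial of a block.

    The trace is initialized at the first trial's tone 1 and thereafter
    follows the convex recursion S_t = gamma*S_{t-1} + (1-gamma)*l1_t.
    """
    l1_seq = np.asarray(l1_seq, dtype=float)
    if l1_seq.size == 0:
        raise ValueError("empty tone-1 history")
    out = np.empty_like(l1_seq)
    out[0] = l1_seq[0]
    for i in range(1, l1_seq.size):
        out[i] = gamma * out[i - 1] + (1.0 - gamma) * l1_seq[i]
    return out


def imm_noise_sd(sigma: float, gamma: float) -> float:
    """Steady-state SD of the accumulated encoding noise in the trace.

    The exponentially weighted sum of i.i.d. N(0, sigma^2) noises has
    variance sigma^2 * (1-gamma)^2 * sum_k gamma^(2k)
    = sigma^2 * (1-gamma)/(1+gamma) in the long-run limit.
    """
    return sigma * math.sqrt((1.0 - gamma) / (1.0 + gamma))


def imm_choice_prob(
    l1_history: Sequence[float], l2: float, params: ImplicitMemoryParams
) -> float:
    """P("tone 1 higher") for the last trial of ``l1_history``.

    Uses the noise-free trace as the signal and the steady-state
    accumulated-noise SD; exact in the long-history limit, and the
    15-trial burn-in discarded from analyses makes the finite-t error
    negligible.
    """
    if params.gamma >= 1.0:
        raise ValueError("gamma must be < 1")
    s = imm_signal(l1_history, params.gamma)[-1]
    sd = imm_noise_sd(params.sigma, params.gamma)
    return float(stats.norm.cdf((s - l2) / sd))


def bayes_choice_prob(l1: float, l2: float, params: BayesParams) -> float:
    """P("tone 1 higher") for the Bayesian posterior-mean comparison.

    With shrinkage weights w_i = sp^2 / (sp^2 + s_i^2) the posterior mean
    of tone i is w_i*x_i + (1-w_i)*mu_p, where x_i is the noisy encoding.
    The model reports "tone 1 higher" when posterior mean 1 exceeds
    posterior mean 2, which happens with probability
    Phi((w1*l1 - w2*l2 + (w2-w1)*mu_p) / sqrt(w1^2 s1^2 + w2^2 s2^2)).
    """
    sp2 = params.prior_sd**2
    w1 = sp2 / (sp2 + params.sigma1**2)
    w2 = sp2 / (sp2 + params.sigma2**2)
    num = w1 * l1 - w2 * l2 + (w2 - w1) * params.prior_mean
    den = math.hypot(w1 * params.sigma1, w2 * params.sigma2)
    return float(stats.norm.cdf(num / den))


def log_uniform_moments(low: float, high: float) -> tuple[float, float]:
    """Exact mean and SD of ln(X) for X ~ Uniform(low, high)."""

    def antideriv_ln(x: float) -> float:
        return x * math.log(x) - x

    def antideriv_ln2(x: float) -> float:
        lx = math.log(x)
        return x * (lx * lx - 2.0 * lx + 2.0)

    width = high - low
    mean = (antideriv_ln(high) - antideriv_ln(low)) / width
    second = (antideriv_ln2(high) - antideriv_ln2(low)) / width
    return mean, math.sqrt(second - mean * mean)


def prior_for_design(design: BlockDesign) -> tuple[float, float]:
    """(mean, SD) in ln-Hz of the base-frequency marginal of a design.

    Experiment 1 draws the base frequency uniformly on 800-1200 Hz;
    Experiment 2 draws the pair's ln-mean from N(6.908, 0.115). The
    Bayesian observer treats this marginal, moment-matched by a Gaussian,
    as its known prior.
    """
    if design.experiment == "exp1":
        return log_uniform_moments(EXP1_LOW_HZ, EXP1_HIGH_HZ)
    return EXP2_LN_MEAN, EXP2_LN_SD


# ---------------------------------------------------------------------------
# simulation-side observers


class Observer:
    """Base class: stateful trial-by-trial response generation."""

    def start_block(self) -> None:
        """Reset any internal state at the start of a block."""

    def respond(self, stim: TrialStimuli, rng: np.random.Generator) -> int:
        """Return 1 for "tone 1 higher", 0 otherwise."""
        raise NotImplementedError


class NaiveObserver(Observer):
    def __init__(self, params: NaiveParams):
        self.params = params

    def respond(self, stim: TrialStimuli, rng: np.random.Generator) -> int:
        z = rng.normal(0.0, self.params.sigma)
        return int(stim.l1 - stim.l2 + z > 0)


class AlwaysCorrectObserver(Observer):
    """Deterministic oracle observer, for exercising the staircase."""

    def respond(self, stim: TrialStimuli, rng: np.random.Generator) -> int:
        return int(stim.l1 > stim.l2)


class ImplicitMemoryObserver(Observer):
    """Simulates the scalar-memory heuristic.

    Noise is applied only to the encoding of tone 1: noise on tone 2 is
    mathematically equivalent to larger trace noise at decision time. The
    trace starts at the first trial's noisy tone-1 log-frequency.
    """

    def __init__(self, params: ImplicitMemoryParams):
        self.params = params
        self.trace: MemoryTrace | None = None

    def start_block(self) -> None:
        self.trace = None

    def respond(self, stim: TrialStimuli, rng: np.random.Generator) -> int:
        noisy = stim.l1 + rng.normal(0.0, self.params.sigma)
        if self.trace is None:
            self.trace = MemoryTrace(H=noisy, t=1)
        else:
            g = self.params.gamma
            self.trace = MemoryTrace(
                H=g * self.trace.H + (1.0 - g) * noisy, t=self.trace.t + 1
            )
        return imm_respond(self.trace, stim.l2, rng)


class BayesianObserver(Observer):
    def __init__(self, params: BayesParams):
        self.params = params

    def respond(self, stim: TrialStimuli, rng: np.random.Generator) -> int:
        p = self.params
        x1 = stim.l1 + rng.normal(0.0, p.sigma1)
        x2 = stim.l2 + rng.normal(0.0, p.sigma2)
        sp2 = p.prior_sd**2
        w1 = sp2 / (sp2 + p.sigma1**2)
        w2 = sp2 / (sp2 + p.sigma2**2)
        m1 = w1 * x1 + (1.0 - w1) * p.prior_mean
        m2 = w2 * x2 + (1.0 - w2) * p.prior_mean
        if m1 > m2:
            return 1
        if m1 < m2:
            return 0
        return int(rng.random() < 0.5)


def make_observer(spec: dict, design: BlockDesign | None = None) -> Observer:
    """Build an observer from a config mapping.

    ``spec`` holds ``type`` in {"naive", "imm", "bayes", "oracle"} plus the
    model's parameters. For the Bayesian observer, a missing prior defaults
    to the design's true stimulus marginal.
    """
    kind = spec.get("type")
    if kind == "naive":
        return NaiveObserver(NaiveParams(sigma=float(spec["sigma"])))
    if kind == "imm":
        return ImplicitMemoryObserver(
            ImplicitMemoryParams(
                sigma=float(spec["sigma"]), gamma=float(spec["gamma"])
            )
        )
    if kind == "bayes":
        if "prior_mean" in spec:
            mean, sd = float(spec["prior_mean"]), float(spec["prior_sd"])
        else:
            if design is None:
                raise ValueError("bayes observer needs a prior or a design")
            mean, sd = prior_for_design(design)
        return BayesianObserver(
            BayesParams(
                sigma1=float(spec["sigma1"]),
                sigma2=float(spec["sigma2"]),
                prior_mean=mean,
                prior_sd=sd,
            )
        )
    if kind == "oracle":
        return AlwaysCorrectObserver()
    raise ValueError(f"unknown observer type {kind!r}")
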