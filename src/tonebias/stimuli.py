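"""Stimulus generation for the two frequency-discrimination experiments.

Experiment 1 draws a base frequency uniformly from 800-1200 Hz and offsets
the comparison tone multiplicatively by the staircase-controlled percent
difference, with random tone order. Experiment 2 draws the ln-mean of the
pair from N(6.908, 0.115) (i.e. centred on 1000 Hz), places the two tones
symmetrically around it in log space, and biases the *order* of the tones
conditional on whether the pair sits above or below the 1000 Hz median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .staircase import StaircaseState

#: Median of both experiments' frequency distributions, Hz.
MEDIAN_HZ = 1000.0
LN_MEDIAN = math.log(MEDIAN_HZ)

EXP1_LOW_HZ = 800.0
EXP1_HIGH_HZ = 1200.0

EXP2_LN_MEAN = 6.908
EXP2_LN_SD = 0.115


@dataclass(frozen=True)
class TrialStimuli:
    """The two tones of one trial, in Hz and ln-Hz."""

    f1_hz: float
    f2_hz: float
    l1: float
    l2: float

    @classmethod
    def from_frequencies(cls, f1_hz: float, f2_hz: float) -> "TrialStimuli":
        if f1_hz <= 0 or f2_hz <= 0:
            raise ValueError("frequencies must be positive")
        return cls(f1_hz, f2_hz, math.log(f1_hz), math.log(f2_hz))

    @classmethod
    def from_log_frequencies(cls, l1: float, l2: float) -> "TrialStimuli":
        return cls(math.exp(l1), math.exp(l2), l1, l2)


@dataclass(frozen=True)
class BlockDesign:
    """Design of one 80-trial block.

    ``bias_prob`` is the probability that the tone order follows the
    condition's rule in Experiment 2 (the deployed conditions used ~0.9,
    matching the published Bias+ region trial-count ratio).
    """

    experiment: str = "exp1"  # {"exp1", "exp2"}
    condition: str = "none"  # {"none", "bias_plus", "bias_minus"}
    n_trials: int = 80
    bias_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.condition not in ("none", "bias_plus", "bias_minus"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.experiment == "exp1" and self.condition != "none":
            raise ValueError("exp1 blocks have no order-bias condition")
        if self.experiment == "exp2" and self.condition == "none":
            raise ValueError("exp2 blocks require bias_plus or bias_minus")
        if not 0.5 < self.bias_prob <= 1.0:
            raise ValueError("bias_prob must lie in (0.5, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")


def draw_exp1_stimuli(
    state: StaircaseState, rng: np.random.Generator
) -> TrialStimuli:
    """Draw one Experiment-1 stimulus pair.

    A base frequency f ~ Uniform(800, 1200) Hz; the comparison tone is
    f*(1 + delta/100) or f*(1 - delta/100) with equal probability; the two
    frequencies are assigned to (tone 1, tone 2) in random order.
    """
    f = rng.uniform(EXP1_LOW_HZ, EXP1_HIGH_HZ)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    other = f * (1.0 + sign * state.delta_pct / 100.0)
    if rng.random() < 0.5:
        f1, f2 = f, other
    else:
        f1, f2 = other, f
    return TrialStimuli.from_frequencies(f1, f2)


def draw_exp2_stimuli(
    state: StaircaseState, design: BlockDesign, rng: np.random.Generator
) -> TrialStimuli:
    """Draw one Experiment-2 stimulus pair.

    The pair's ln-mean m ~ N(6.908, 0.115); the two log-frequencies are
    m +/- d/2 with d = ln(1 + delta/100), so their log-mean equals m
    exactly. In the bias_plus condition the 2nd tone is the higher one
    with probability ``bias_prob`` when m > ln(1000) and the lower one
    with probability ``bias_prob`` when m < ln(1000); bias_minus mirrors
    the rule.
    """
    if design.experiment != "exp2" or design.condition == "none":
        raise ValueError("draw_exp2_stimuli requires an exp2 biased design")
    m = rng.normal(EXP2_LN_MEAN, EXP2_LN_SD)
    half = 0.5 * math.log1p(state.delta_pct / 100.0)

    if m > LN_MEDIAN:
        prefer_second_higher = design.condition == "bias_plus"
    elif m < LN_MEDIAN:
        prefer_second_higher = design.condition == "bias_minus"
    else:  # measure-zero tie: unbiased order
        prefer_second_higher = rng.random() < 0.5
    second_higher = (
        prefer_second_higher
        if rng.random() < design.bias_prob
        else not prefer_second_higher
    )
    l2 = m + half if second_higher else m - half
    l1 = 2.0 * m - l2
    return TrialStimuli.from_log_frequencies(l1, l2)
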