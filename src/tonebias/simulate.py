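"""Block simulation and exclusion rules.

A block is 80 staircase-controlled trials driven by a pluggable observer.
Blocks that fail to converge (< 65% correct over the last 40 trials) are
excluded, and the first 15 trials of kept blocks are flagged ineligible
for analysis, mirroring the behavioural protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .observers import Observer
from .staircase import StaircaseState, staircase_update
from .stimuli import BlockDesign, TrialStimuli, draw_exp1_stimuli, draw_exp2_stimuli

#: Trials at the start of each block excluded from analysis (staircase
#: burn-in: the frequency ratio is still far from threshold).
BURN_IN_TRIALS = 15

#: Convergence rule: minimum fraction correct over the final window.
CONVERGENCE_WINDOW = 40
CONVERGENCE_MIN_FRAC = 0.65


@dataclass(frozen=True)
class TrialRecord:
    """One 2AFC trial."""

    block_id: int
    trial_index: int  # 1-based within block
    stimuli: TrialStimuli
    response_first_higher: int
    correct: int
    analysis_eligible: bool
    condition: str = "none"


@dataclass
class Block:
    """Simulated block: design, trials and the final staircase state."""

    block_id: int
    design: BlockDesign
    trials: list[TrialRecord]
    staircase: StaircaseState
    rng_seed: int | None = None

    @property
    def reversal_deltas(self) -> tuple[float, ...]:
        return self.staircase.reversal_deltas

    def fraction_correct(self, last: int | None = None) -> float:
        trials = self.trials if last is None else self.trials[-last:]
        return float(np.mean([t.correct for t in trials]))


@dataclass
class ExclusionReport:
    n_total: int
    n_kept: int
    n_dropped: int
    dropped_block_ids: list[int] = field(default_factory=list)


def simulate_block(
    design: BlockDesign,
    observer: Observer,
    rng: np.random.Generator,
    block_id: int = 0,
    rng_seed: int | None = None,
) -> Block:
    """Run one block: staircase from 20%, observer state evolving throughout."""
    state = StaircaseState()
    observer.start_block()
    trials: list[TrialRecord] = []
    for t in range(1, design.n_trials + 1):
        if design.experiment == "exp1":
            stim = draw_exp1_stimuli(state, rng)
        else:
            stim = draw_exp2_stimuli(state, design, rng)
        response = observer.respond(stim, rng)
        correct = int(response == int(stim.l1 > stim.l2))
        trials.append(
            TrialRecord(
                block_id=block_id,
                trial_index=t,
                stimuli=stim,
                response_first_higher=response,
                correct=correct,
                analysis_eligible=t > BURN_IN_TRIALS,
                condition=design.condition,
            )
        )
        state = staircase_update(state, bool(correct))
    return Block(block_id, design, trials, state, rng_seed)


def simulate_blocks(
    design: BlockDesign,
    observer_factory: Callable[[], Observer],
    n_blocks: int,
    seed: int,
) -> list[Block]:
    """Simulate independent blocks with per-block child seeds.

    Child generators are spawned deterministically from one master seed,
    so the full trial table is reproducible bit for bit. Each block gets a
    fresh observer (fresh memory trace), as for separate participants.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be positive")
    seqs = np.random.SeedSequence(seed).spawn(n_blocks)
    blocks = []
    for i, seq in enumerate(seqs):
        rng = np.random.Generator(np.random.PCG64(seq))
        blocks.append(
            simulate_block(design, observer_factory(), rng, block_id=i)
        )
    return blocks


def apply_exclusions(
    blocks: Iterable[Block],
) -> tuple[list[Block], ExclusionReport]:
    """Drop non-converged blocks; flag burn-in trials in kept blocks.

    A block is kept when it reached at least 65% correct over its final 40
    trials. Raises on blocks shorter than the convergence window.
    """
    blocks = list(blocks)
    kept, dropped_ids = [], []
    for block in blocks:
        if len(block.trials) < CONVERGENCE_WINDOW:
            raise ValueError(
                f"block {block.block_id} has {len(block.trials)} trials; "
                f"need at least {CONVERGENCE_WINDOW}"
            )
        if block.fraction_correct(last=CONVERGENCE_WINDOW) >= CONVERGENCE_MIN_FRAC:
            kept.append(block)
        else:
            dropped_ids.append(block.block_id)
    report = ExclusionReport(
        n_total=len(blocks),
        n_kept=len(kept),
        n_dropped=len(dropped_ids),
        dropped_block_ids=dropped_ids,
    )
    return kept, report


def blocks_to_frame(blocks: Sequence[Block]) -> pd.DataFrame:
    """Flatten blocks into the canonical trial table."""
    rows = []
    for block in blocks:
        for t in block.trials:
            rows.append(
                (
                    t.block_id,
                    t.trial_index,
                    t.stimuli.f1_hz,
                    t.stimuli.f2_hz,
                    t.response_first_higher,
                    t.correct,
                    t.analysis_eligible,
                    t.condition,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "block_id",
            "trial_index",
            "f1_hz",
            "f2_hz",
            "response_first_higher",
            "correct",
            "analysis_eligible",
            "condition",
        ],
    )
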