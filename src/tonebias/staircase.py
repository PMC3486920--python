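"""Adaptive 3-down-1-up staircase controller.

The staircase controls the percent frequency difference between the two
tones of a trial. Difficulty decreases (smaller difference) after every
third consecutive correct response and increases after any error. This
transformed up-down rule converges to the stimulus level at which the
probability of a correct response p satisfies p**3 = 1/2, i.e.
p = 0.794 (Levitt's asymptote).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

#: Step magnitudes in percent; the schedule advances one step every four
#: reversals and stays on the last step thereafter.
DEFAULT_STEP_SIZES: tuple[float, ...] = (4.5, 2.0, 1.0, 0.5, 0.1)

#: Lower clamp on the percent difference between the two tones.
DELTA_FLOOR_PCT = 0.1

#: Percent difference at the start of every block.
INITIAL_DELTA_PCT = 20.0

#: Number of reversals after which the step size shrinks.
REVERSALS_PER_STEP = 4

#: Correct responses in a row required for a down (harder) step.
DOWN_RULE = 3


@dataclass(frozen=True)
class StaircaseState:
    """State of the 3-down-1-up controller.

    Attributes
    ----------
    delta_pct:
        Current frequency difference as percent of the base frequency;
        never drops below :data:`DELTA_FLOOR_PCT`.
    step_sizes:
        Ordered step magnitudes in percent.
    step_index:
        Position in ``step_sizes``; advances by one after every
        :data:`REVERSALS_PER_STEP` reversals, capped at the last index.
    reversal_count:
        Total direction reversals so far (non-decreasing).
    consecutive_correct:
        Correct responses since the last staircase move.
    last_direction:
        ``"up"``, ``"down"`` or ``"none"`` (no move yet this block).
    reversal_deltas:
        ``delta_pct`` in force on each trial that triggered a reversal.
    """

    delta_pct: float = INITIAL_DELTA_PCT
    step_sizes: tuple[float, ...] = DEFAULT_STEP_SIZES
    step_index: int = 0
    reversal_count: int = 0
    consecutive_correct: int = 0
    last_direction: str = "none"
    reversal_deltas: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.delta_pct < DELTA_FLOOR_PCT:
            raise ValueError(
                f"delta_pct={self.delta_pct} below floor {DELTA_FLOOR_PCT}"
            )
        if not 0 <= self.step_index < len(self.step_sizes):
            raise ValueError("step_index out of range")

    @property
    def current_step(self) -> float:
        return self.step_sizes[self.step_index]


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one trial outcome.

    After every third consecutive correct response ``delta_pct`` decreases
    by the current step; after any error it increases by the current step
    and the run counter resets. A move whose direction differs from the
    previous (non-null) direction is logged as a reversal, recording the
    pre-move ``delta_pct``. Every :data:`REVERSALS_PER_STEP` reversals the
    step size advances. ``delta_pct`` is clamped at the floor.
    """
    if correct:
        run = state.consecutive_correct + 1
        if run < DOWN_RULE:
            return replace(state, consecutive_correct=run)
        direction = "down"
        new_delta = state.delta_pct - state.current_step
    else:
        direction = "up"
        new_delta = state.delta_pct + state.current_step

    new_delta = max(new_delta, DELTA_FLOOR_PCT)

    reversal = state.last_direction not in ("none", direction)
    reversal_count = state.reversal_count + int(reversal)
    reversal_deltas = state.reversal_deltas
    if reversal:
        reversal_deltas = reversal_deltas + (state.delta_pct,)
    step_index = min(
        reversal_count // REVERSALS_PER_STEP, len(state.step_sizes) - 1
    )
    return replace(
        state,
        delta_pct=new_delta,
        step_index=step_index,
        reversal_count=reversal_count,
        consecutive_correct=0,
        last_direction=direction,
        reversal_deltas=reversal_deltas,
    )
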