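"""Three-down/one-up adaptive staircase for contrast thresholds.

The protocol: probe contrast starts at 40%; after three consecutive correct
responses the contrast steps down, after a single incorrect response it
steps up.  Steps are 12% until the second reversal, then 3%.  The run
terminates after 30 trials and the threshold estimate is the mean of the
last five contrast values selected by the procedure.  A 3-down/1-up rule
converges near the 79.4%-correct point of the observer's psychometric
function (0.5^(1/3)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StaircaseProtocol", "StaircaseResult", "run_staircase"]


@dataclass(frozen=True)
class StaircaseProtocol:
    start_contrast: float = 40.0
    step_coarse: float = 12.0
    step_fine: float = 3.0
    reversals_to_fine: int = 2
    n_down: int = 3
    n_trials: int = 30
    n_average: int = 5
    floor: float = 0.0
    ceiling: float = 100.0


@dataclass
class StaircaseResult:
    threshold: float
    contrasts: np.ndarray           # contrast presented on each trial
    responses: np.ndarray           # correct (True) / incorrect per trial
    reversals: int
    clipped_trials: int             # floor/ceiling clipping events
    protocol: StaircaseProtocol = field(repr=False, default_factory=StaircaseProtocol)


def run_staircase(
    observer,
    protocol: StaircaseProtocol | None = None,
    rng: np.random.Generator | int | None = None,
) -> StaircaseResult:
    """Run one staircase against a trial oracle.

    ``observer(contrast, rng)`` returns True for a correct response.  The
    ``rng`` is passed through so seeded observers yield identical trial logs
    on rerun.
    """
    protocol = protocol or StaircaseProtocol()
    rng = np.random.default_rng(rng)
    contrast = protocol.start_contrast
    contrasts, responses = [], []
    correct_streak = 0
    reversals = 0
    clipped = 0
    last_direction = 0  # +1 up, -1 down
    for _ in range(protocol.n_trials):
        contrasts.append(contrast)
        correct = bool(observer(contrast, rng))
        responses.append(correct)
        move = 0
        if correct:
            correct_streak += 1
            if correct_streak >= protocol.n_down:
                move = -1
                correct_streak = 0
        else:
            move = +1
            correct_streak = 0
        if move != 0:
            if last_direction != 0 and move != last_direction:
                reversals += 1
            last_direction = move
            step = (
                protocol.step_coarse
                if reversals < protocol.reversals_to_fine
                else protocol.step_fine
            )
            new_contrast = contrast + move * step
            if new_contrast < protocol.floor or new_contrast > protocol.ceiling:
                clipped += 1
                new_contrast = min(max(new_contrast, protocol.floor), protocol.ceiling)
            contrast = new_contrast
    tail = contrasts[-protocol.n_average :]
    return StaircaseResult(
        threshold=float(np.mean(tail)),
        contrasts=np.array(contrasts),
        responses=np.array(responses),
        reversals=reversals,
        clipped_trials=clipped,
        protocol=protocol,
    )
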