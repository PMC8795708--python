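"""Block designs of the two tasks.

Picture naming: 12 active blocks; each block shows 5 pictures for 4 s with a
1 s inter-stimulus interval (the trailing ISI is kept inside the block, so
an active block spans 25 s) followed by a 24 s rest.

Landmark: a landmark condition (LM, judge whether a pre-bisected line is
bisected at its midpoint) and a control condition (LMC), 6 blocks each,
alternating. A block is a 4 s instruction then 12 trials of 1.6 s stimulus
plus 200 ms ISI — 21.6 s of task — followed by a rest drawn uniformly from
{15, 16, 17} s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PICTURE_NAMING = "picture_naming"
LANDMARK = "landmark"


@dataclass(frozen=True)
class Trial:
    onset_s: float
    duration_s: float
    condition: str


@dataclass(frozen=True)
class Block:
    index: int
    condition: str
    onset_s: float          # onset of the active (stimulation) period
    duration_s: float
    instruction_s: float = 0.0  # instruction period immediately before onset
    trials: tuple[Trial, ...] = ()

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class BlockDesign:
    task: str
    conditions: tuple[str, ...]
    blocks: tuple[Block, ...]
    total_duration_s: float

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for b in self.blocks:
            if b.onset_s - b.instruction_s < prev_end:
                raise ValueError(f"blocks overlap at block {b.index}")
            prev_end = b.end_s
        if self.blocks and self.total_duration_s < self.blocks[-1].end_s:
            raise ValueError("total duration shorter than last block")

    def blocks_of(self, condition: str) -> list[Block]:
        return [b for b in self.blocks if b.condition == condition]

    def onsets(self, condition: str | None = None) -> np.ndarray:
        return np.array(
            [b.onset_s for b in self.blocks if condition in (None, b.condition)]
        )


def make_block_design(
    task: str,
    *,
    n_blocks: int | None = None,
    n_trials: int | None = None,
    stimulus_s: float | None = None,
    isi_s: float | None = None,
    rest_s: float | None = None,
    instruction_s: float = 4.0,
    lead_in_s: float = 15.0,
    lead_out_s: float = 45.0,
    seed: int | None = 0,
) -> BlockDesign:
    """Build a fully timed design for one task, defaulting to the published
    protocol. ``lead_out_s`` pads the recording so the final −4..+40 s epoch
    fits. The landmark rest durations are drawn from {15, 16, 17} s with
    ``seed``; all other timing is deterministic.
    """
    if task == PICTURE_NAMING:
        n_blocks = 12 if n_blocks is None else n_blocks
        n_trials = 5 if n_trials is None else n_trials
        stimulus_s = 4.0 if stimulus_s is None else stimulus_s
        isi_s = 1.0 if isi_s is None else isi_s
        rest_s = 24.0 if rest_s is None else rest_s
        _check_positive(n_blocks=n_blocks, n_trials=n_trials,
                        stimulus_s=stimulus_s, isi_s=isi_s, rest_s=rest_s)
        blocks = []
        t = lead_in_s
        active = n_trials * (stimulus_s + isi_s)
        for i in range(n_blocks):
            trials = tuple(
                Trial(t + k * (stimulus_s + isi_s), stimulus_s, "LP")
                for k in range(n_trials)
            )
            blocks.append(Block(i, "LP", t, active, 0.0, trials))
            t += active + rest_s
        return BlockDesign(task, ("LP",), tuple(blocks), t + lead_out_s - rest_s)

    if task == LANDMARK:
        n_blocks = 6 if n_blocks is None else n_blocks  # per condition
        n_trials = 12 if n_trials is None else n_trials
        stimulus_s = 1.6 if stimulus_s is None else stimulus_s
        isi_s = 0.2 if isi_s is None else isi_s
        _check_positive(n_blocks=n_blocks, n_trials=n_trials,
                        stimulus_s=stimulus_s, isi_s=isi_s,
                        instruction_s=instruction_s)
        rng = np.random.default_rng(seed)
        active = n_trials * (stimulus_s + isi_s)
        blocks = []
        t = lead_in_s
        order = ["LM", "LMC"] * n_blocks
        for i, cond in enumerate(order):
            onset = t + instruction_s
            trials = tuple(
                Trial(onset + k * (stimulus_s + isi_s), stimulus_s, cond)
                for k in range(n_trials)
            )
            blocks.append(Block(i, cond, onset, active, instruction_s, trials))
            rest = float(rng.choice([15, 16, 17])) if rest_s is None else rest_s
            t = onset + active + rest
        return BlockDesign(task, ("LM", "LMC"), tuple(blocks),
                           blocks[-1].end_s + lead_out_s)

    raise ValueError(f"unknown task {task!r}")


def _check_positive(**kw: float) -> None:
    for key, value in kw.items():
        if value <= 0:
            raise ValueError(f"{key} must be positive, got {value}")
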