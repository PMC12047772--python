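"""Balanced trial-design generator for the three urgency experiments.

Each participant runs ``n_sessions`` sessions of ``blocks_per_session``
blocks. Within every block the full factorial of balancing units (see
:class:`~tachometry.stimuli.StimulusSet`) x gap duration x fixation
duration occurs equally often, in an order randomized per block. Under the
default parameters that is 5 sessions x 1188 trials = 5940 main trials per
participant, preceded by 132 practice trials, with 11 gap levels
(0, 100, ..., 900, 950 ms) and fixation durations of 350/400/500 ms.

For the numerical Stroop task the four side/size variants of each digit
pair rotate cyclically over blocks with a per-cell phase, which keeps
congruency and the side of the larger digit exactly balanced within every
session (exact four-way balance is impossible in 1188 trials).

Randomness is drawn from one master seed; each participant's design
shuffle uses an independent spawned substream, so adding participants
never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import StimulusSet, build_stimulus_set
from .trials import DEFAULT_DEADLINE_MS, TrialTable

DEFAULT_GAPS_MS = (0, 100, 200, 300, 400, 500, 600, 700, 800, 900, 950)
DEFAULT_FIXATIONS_MS = (350, 400, 500)

_TASK_BLOCKS = {"spatial_stroop": (9, 132), "simon": (9, 132), "numerical_stroop": (3, 396)}


@dataclass
class DesignSpec:
    """Parameters of one experiment's trial design."""

    task: str
    n_participants: int = 1
    n_sessions: int = 5
    blocks_per_session: int | None = None
    trials_per_block: int | None = None
    gap_levels_ms: tuple[int, ...] = DEFAULT_GAPS_MS
    fixation_levels_ms: tuple[int, ...] = DEFAULT_FIXATIONS_MS
    n_practice: int = 132
    deadline_ms: int = DEFAULT_DEADLINE_MS
    seed: int = 0
    simon_color_map: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.task not in _TASK_BLOCKS:
            raise ValueError(f"unknown task {self.task!r}")
        defaults = _TASK_BLOCKS[self.task]
        if self.blocks_per_session is None:
            self.blocks_per_session = defaults[0]
        if self.trials_per_block is None:
            self.trials_per_block = defaults[1]

    @property
    def trials_per_session(self) -> int:
        return self.blocks_per_session * self.trials_per_block

    @property
    def main_trials_per_participant(self) -> int:
        return self.n_sessions * self.trials_per_session


def _block_cells(stimset: StimulusSet, spec: DesignSpec) -> list[tuple[str, int, int]]:
    """The factorial cells crossed exactly within each block."""
    return [
        (unit, gap, fix)
        for unit in stimset.units
        for gap in spec.gap_levels_ms
        for fix in spec.fixation_levels_ms
    ]


def generate_design(spec: DesignSpec) -> TrialTable:
    """Generate the full (unsimulated) trial design for all participants.

    Response fields are left empty (``response_side = none``, RT missing);
    :func:`tachometry.behavior.simulate_experiment` fills them in. The same
    spec and seed always yield an identical table.

    Raises
    ------
    ValueError
        If the factorial of units x gaps x fixations does not divide the
        block length, i.e. blocks cannot be balanced exactly.
    """
    stimset = build_stimulus_set(spec.task, spec.simon_color_map)
    cells = _block_cells(stimset, spec)
    n_cells = len(cells)
    if spec.trials_per_block % n_cells:
        raise ValueError(
            f"trials_per_block={spec.trials_per_block} must be a multiple of the "
            f"design factorial {stimset.n_units} units x {len(spec.gap_levels_ms)} "
            f"gaps x {len(spec.fixation_levels_ms)} fixations = {n_cells}"
        )
    reps_per_block = spec.trials_per_block // n_cells
    unit_variants = {u: items for u, items in stimset.units.items()}

    master = np.random.SeedSequence(spec.seed)
    part_seeds = master.spawn(spec.n_participants)

    cols: dict[str, list] = {c: [] for c in (
        "participant_id", "session", "block", "trial_index", "is_practice",
        "fixation_ms", "gap_ms", "congruency", "stim_desc", "correct_side")}

    def emit(pid, session, block, index, practice, stim, gap, fix):
        cols["participant_id"].append(pid)
        cols["session"].append(session)
        cols["block"].append(block)
        cols["trial_index"].append(index)
        cols["is_practice"].append(practice)
        cols["fixation_ms"].append(fix)
        cols["gap_ms"].append(gap)
        cols["congruency"].append(stim.congruency)
        cols["stim_desc"].append(stim.descriptor)
        cols["correct_side"].append(stim.correct_side)

    for p in range(spec.n_participants):
        pid = f"P{p + 1:02d}"
        rng = np.random.default_rng(part_seeds[p])
        index = 0
        # practice: one shuffled pass through the factorial, truncated;
        # variants drawn at random (practice is discarded by the filter)
        n_rep = -(-spec.n_practice // n_cells)  # ceil
        order = rng.permutation(n_cells * n_rep) % n_cells
        for j in order[: spec.n_practice]:
            unit, gap, fix = cells[j]
            variants = unit_variants[unit]
            stim = variants[rng.integers(len(variants))]
            index += 1
            emit(pid, 1, 1, index, True, stim, gap, fix)
        g = 0  # global block counter drives the variant rotation
        for session in range(1, spec.n_sessions + 1):
            for block in range(1, spec.blocks_per_session + 1):
                trials = []
                for r in range(reps_per_block):
                    for j, (unit, gap, fix) in enumerate(cells):
                        variants = unit_variants[unit]
                        v = (j + g * reps_per_block + r) % len(variants)
                        trials.append((variants[v], gap, fix))
                for t in rng.permutation(len(trials)):
                    stim, gap, fix = trials[t]
                    index += 1
                    emit(pid, session, block, index, False, stim, gap, fix)
                g += 1

    df = pd.DataFrame(cols)
    df["experiment"] = spec.task
    df["response_side"] = "none"
    df["rt_ms"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return TrialTable(df, experiment=spec.task, deadline_ms=spec.deadline_ms)
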