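"""Stimulus sets of the three conflict tasks and their congruency rules.

spatial_stroop
    German direction words LINKS/RECHTS shown left or right of fixation;
    respond to the word's *meaning*. Congruent iff meaning equals position.
simon
    A green or blue dot shown left or right; respond to the *color* via a
    fixed color-to-button mapping (green->left by default). Congruent iff
    the mapped response side equals the stimulus side.
numerical_stroop
    Two digits, one per side, differing in numerical and physical (font)
    size; respond on the side of the *numerically* larger digit. Congruent
    iff the numerically larger digit is also the physically larger one.
    The digit pairs span numerical distances 1, 2 and 5, four pairs each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .trials import EXPERIMENTS

#: Numerical Stroop digit pairs by numerical distance.
NUMBER_PAIRS: dict[int, tuple[tuple[int, int], ...]] = {
    1: ((1, 2), (3, 4), (6, 7), (8, 9)),
    2: ((1, 3), (2, 4), (6, 8), (7, 9)),
    5: ((1, 6), (2, 7), (3, 8), (4, 9)),
}

DEFAULT_SIMON_COLOR_MAP = {"green": "left", "blue": "right"}


@dataclass(frozen=True)
class Stimulus:
    """One presentable stimulus: a descriptor plus its derived task labels."""

    descriptor: str
    congruency: str  # "congruent" | "incongruent"
    correct_side: str  # "left" | "right"
    #: balancing unit this stimulus belongs to (see StimulusSet.units)
    unit: str


@dataclass
class StimulusSet:
    """The complete stimulus inventory of one task.

    ``units`` are the groups that the design crosses exactly with gap and
    fixation within each block. For the word and Simon tasks every stimulus
    is its own unit (4 units of 1). For the numerical Stroop task the unit
    is the digit pair (12 units of 4 variants: larger digit left/right x
    physical size congruent/incongruent); the 4 variants of a pair are
    counterbalanced across blocks by rotation, because 12*4 variants do not
    fit a 396-trial block crossed with 11 gaps and 3 fixations.
    """

    task: str
    items: list[Stimulus]
    units: dict[str, list[Stimulus]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.units:
            self.units = {}
            for s in self.items:
                self.units.setdefault(s.unit, []).append(s)

    @property
    def n_units(self) -> int:
        return len(self.units)


def _spatial_stroop_items() -> list[Stimulus]:
    items = []
    for word, meaning in (("LINKS", "left"), ("RECHTS", "right")):
        for side in ("left", "right"):
            cong = "congruent" if meaning == side else "incongruent"
            desc = f"word={word};side={side}"
            items.append(Stimulus(desc, cong, meaning, unit=desc))
    return items


def _simon_items(color_map: dict[str, str]) -> list[Stimulus]:
    items = []
    for color, resp in color_map.items():
        for side in ("left", "right"):
            cong = "congruent" if resp == side else "incongruent"
            desc = f"color={color};side={side}"
            items.append(Stimulus(desc, cong, resp, unit=desc))
    return items


def _numerical_stroop_items() -> list[Stimulus]:
    items = []
    for distance, pairs in NUMBER_PAIRS.items():
        for small, large in pairs:
            unit = f"pair={small}-{large}"
            # variant order matters: the block-rotation scheme in design.py
            # relies on congruency alternating (c, i, c, i) so that any 3
            # consecutive variants contain both congruencies.
            for larger_side in ("left", "right"):
                for size_rel in ("congruent", "incongruent"):
                    desc = (
                        f"{unit};dist={distance};larger={larger_side};"
                        f"size={size_rel}"
                    )
                    items.append(Stimulus(desc, size_rel, larger_side, unit=unit))
    return items


def build_stimulus_set(
    task: str, simon_color_map: dict[str, str] | None = None
) -> StimulusSet:
    """Build the full stimulus inventory for one of the three tasks.

    Parameters
    ----------
    task:
        ``"spatial_stroop"``, ``"numerical_stroop"`` or ``"simon"``.
    simon_color_map:
        Color-to-response-side mapping for the Simon task (default
        green->left, blue->right; the assignment is a counterbalancing
        choice and does not affect the congruency structure).
    """
    if task == "spatial_stroop":
        return StimulusSet(task, _spatial_stroop_items())
    if task == "simon":
        cmap = dict(simon_color_map or DEFAULT_SIMON_COLOR_MAP)
        if sorted(cmap.values()) != ["left", "right"]:
            raise ValueError("simon color map must assign one color per side")
        return StimulusSet(task, _simon_items(cmap))
    if task == "numerical_stroop":
        return StimulusSet(task, _numerical_stroop_items())
    raise ValueError(f"unknown task {task!r}; expected one of {EXPERIMENTS}")
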