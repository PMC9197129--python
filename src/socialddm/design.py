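"""Factorial stimulus design for the joint-evaluation charity task.

Each trial shows a 2x2 table: two charity options (columns A, B), with the
number of ingroup and outgroup donors (rows) who already chose each option.
Columns fill to 100, so the outgroup count of an option is 100 minus its
ingroup count.  Three stimulus types vary how strongly the ingroup favours
one option, via the canonical ingroup-count ranges

* type 1: option A in [92, 98], option B in [12, 18]  (easy to follow ingroup)
* type 2: option A in [92, 98], option B in [52, 58]  (ingroup vs equality)
* type 3: option A in [52, 58], option B in [12, 18]  (hard, ambiguous)

Crossing the 7 x 7 count grids gives 49 canonical stimuli per type; each is
also presented mirrored (columns swapped), for 3 x 49 x 2 = 294 presentation
stimuli per session.

Two per-stimulus codings drive the analysis: the *compliant* option is the
one with the larger ingroup/outgroup donor ratio; the *equality* option is
the one whose ingroup and outgroup counts differ least.  They coincide on
type 3 and conflict on type 2, which is what separates the two behavioural
strategies downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusTable",
    "SessionPlan",
    "TYPE_RANGES",
    "CHARITY_CATEGORIES",
    "generate_stimuli",
    "code_compliance",
    "code_equality",
    "build_session",
    "stimuli_frame",
    "session_frame",
]

# canonical ingroup-count ranges (inclusive) per stimulus type: (option A, option B)
TYPE_RANGES: dict[int, tuple[tuple[int, int], tuple[int, int]]] = {
    1: ((92, 98), (12, 18)),
    2: ((92, 98), (52, 58)),
    3: ((52, 58), (12, 18)),
}

COLUMN_TOTAL = 100

CHARITY_CATEGORIES: tuple[str, ...] = (
    "cancer charities",
    "disabled charities",
    "poverty charities",
    "medical charities",
    "elderly charities",
    "children's health charities",
)

TRIALS_PER_BLOCK = 49
N_BLOCKS = 6
INTER_TRIAL_DELAYS = (0.2, 0.4, 0.6)
RESPONSE_WINDOW = 5.0


class TieError(ValueError):
    """Raised when a stimulus coding is undefined because of a tie."""


@dataclass(frozen=True)
class StimulusTable:
    """One 2x2 trial table plus derived codings.

    ``ingroup_A``/``outgroup_A`` are the donor counts shown for option A
    (likewise B); columns sum to 100.  ``mirrored`` flags that the canonical
    orientation's columns were swapped for presentation — coding labels swap
    with them, so ``compliant_option`` and ``equality_option`` always refer
    to the columns as presented.
    """

    ingroup_A: int
    ingroup_B: int
    stim_type: int
    mirrored: bool = False
    outgroup_A: int = field(init=False)
    outgroup_B: int = field(init=False)
    compliant_option: str = field(init=False)
    equality_option: str = field(init=False)

    def __post_init__(self) -> None:
        if self.stim_type not in TYPE_RANGES:
            raise ValueError(f"stim_type must be 1, 2 or 3, got {self.stim_type}")
        for c in (self.ingroup_A, self.ingroup_B):
            if not 0 < c < COLUMN_TOTAL:
                raise ValueError(f"ingroup counts must lie in (0, 100), got {c}")
        object.__setattr__(self, "outgroup_A", COLUMN_TOTAL - self.ingroup_A)
        object.__setattr__(self, "outgroup_B", COLUMN_TOTAL - self.ingroup_B)
        object.__setattr__(self, "compliant_option", code_compliance(self))
        object.__setattr__(self, "equality_option", code_equality(self))

    def cell(self, group: str, option: str) -> int:
        """Donor count for ('ingroup'|'outgroup', 'A'|'B')."""
        return getattr(self, f"{group}_{option}")

    def mirror(self) -> "StimulusTable":
        """Swap the option columns (left/right presentation side)."""
        return StimulusTable(
            ingroup_A=self.ingroup_B,
            ingroup_B=self.ingroup_A,
            stim_type=self.stim_type,
            mirrored=not self.mirrored,
        )


def code_compliance(s: StimulusTable | "StimulusTable") -> str:
    """Option with the strictly larger ingroup/outgroup donor ratio.

    Choosing this option is the ingroup-compliant response.  Outgroup counts
    are never zero in the canonical design (ingroup counts stay below 100),
    so the ratios are finite.
    """
    ig_a, ig_b = s.ingroup_A, s.ingroup_B
    og_a, og_b = COLUMN_TOTAL - ig_a, COLUMN_TOTAL - ig_b
    # compare ig_a/og_a vs ig_b/og_b without division
    lhs = ig_a * og_b
    rhs = ig_b * og_a
    if lhs == rhs:
        raise TieError(
            f"equal ingroup/outgroup ratios ({ig_a}/{og_a} vs {ig_b}/{og_b}): "
            "compliance coding undefined"
        )
    return "A" if lhs > rhs else "B"


def code_equality(s: StimulusTable) -> str:
    """Option with the smaller |ingroup - outgroup| donor-count difference.

    Choosing this option is the equality-driven response.
    """
    d_a = abs(s.ingroup_A - (COLUMN_TOTAL - s.ingroup_A))
    d_b = abs(s.ingroup_B - (COLUMN_TOTAL - s.ingroup_B))
    if d_a == d_b:
        raise TieError(
            f"equal ingroup-outgroup imbalance (|{2 * s.ingroup_A - 100}| vs "
            f"|{2 * s.ingroup_B - 100}|): equality coding undefined"
        )
    return "A" if d_a < d_b else "B"


def generate_stimuli() -> list[StimulusTable]:
    """The full fixed design: 294 presentation stimuli.

    For each of the three types, every combination of the 7 option-A and 7
    option-B ingroup counts (49 canonical stimuli), each emitted twice —
    canonical and mirrored.
    """
    out: list[StimulusTable] = []
    for stim_type, ((a_lo, a_hi), (b_lo, b_hi)) in TYPE_RANGES.items():
        for ig_a, ig_b in itertools.product(
            range(a_lo, a_hi + 1), range(b_lo, b_hi + 1)
        ):
            canonical = StimulusTable(ingroup_A=ig_a, ingroup_B=ig_b, stim_type=stim_type)
            out.append(canonical)
            out.append(canonical.mirror())
    return out


@dataclass(frozen=True)
class SessionPlan:
    """One participant session: ordered trials, block structure, timing."""

    trials: tuple[StimulusTable, ...]
    block_labels: tuple[str, ...]  # one label per block, len N_BLOCKS
    delays: tuple[float, ...]  # inter-trial delay per trial, seconds
    response_window: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.trials) != N_BLOCKS * TRIALS_PER_BLOCK:
            raise ValueError(
                f"session must contain {N_BLOCKS * TRIALS_PER_BLOCK} trials, "
                f"got {len(self.trials)}"
            )
        if len(self.block_labels) != N_BLOCKS:
            raise ValueError(f"expected {N_BLOCKS} block labels")
        if len(self.delays) != len(self.trials):
            raise ValueError("one inter-trial delay per trial required")

    def block_of(self, trial_index: int) -> int:
        return trial_index // TRIALS_PER_BLOCK

    def __iter__(self) -> Iterator[StimulusTable]:
        return iter(self.trials)


def build_session(seed: int, response_window: float = RESPONSE_WINDOW) -> SessionPlan:
    """Assemble a randomized session from the fixed 294-stimulus design.

    Stimuli are shuffled across the whole session (the three types were
    interleaved for participants) and cut into six 49-trial blocks; the six
    charity-category labels are shuffled over blocks; each trial gets an
    inter-trial delay drawn uniformly from {0.2, 0.4, 0.6} s.  Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    stimuli = generate_stimuli()
    order = rng.permutation(len(stimuli))
    trials = tuple(stimuli[i] for i in order)
    labels = tuple(np.array(CHARITY_CATEGORIES)[rng.permutation(N_BLOCKS)])
    delays = tuple(rng.choice(INTER_TRIAL_DELAYS, size=len(trials)))
    return SessionPlan(
        trials=trials,
        block_labels=labels,
        delays=delays,
        response_window=response_window,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# serialization

def stimuli_frame(stimuli: Sequence[StimulusTable]) -> pd.DataFrame:
    """Stimulus list as a flat table (one row per presentation stimulus)."""
    return pd.DataFrame(
        {
            "stim_type": [s.stim_type for s in stimuli],
            "mirrored": [int(s.mirrored) for s in stimuli],
            "ingroup_A": [s.ingroup_A for s in stimuli],
            "ingroup_B": [s.ingroup_B for s in stimuli],
            "outgroup_A": [s.outgroup_A for s in stimuli],
            "outgroup_B": [s.outgroup_B for s in stimuli],
            "compliant_option": [s.compliant_option for s in stimuli],
            "equality_option": [s.equality_option for s in stimuli],
        }
    )


def session_frame(plan: SessionPlan) -> pd.DataFrame:
    """Session plan as a flat table (one row per trial, 0-based index)."""
    df = stimuli_frame(plan.trials)
    df.insert(0, "trial", np.arange(len(plan.trials)))
    df.insert(1, "block", [plan.block_of(i) for i in range(len(plan.trials))])
    df["block_label"] = [plan.block_labels[plan.block_of(i)] for i in range(len(plan.trials))]
    df["delay"] = plan.delays
    df["response_window"] = plan.response_window
    return df
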