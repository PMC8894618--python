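"""Controlled vocabularies shared across the pipeline."""

from __future__ import annotations

from enum import Enum


class Direction(str, Enum):
    """Direction of an expression change relative to the most recent
    common ancestor (or, for a human gene, relative to its normal level)."""

    UP = "UP"
    DOWN = "DOWN"

    @property
    def opposite(self) -> "Direction":
        return Direction.DOWN if self is Direction.UP else Direction.UP


class Effect(str, Enum):
    """Annotated effect of an expression change on human reproductive
    potential: the capacity for population growth absent limiting factors."""

    DECREASE = "DECREASE"
    INCREASE = "INCREASE"
    UNKNOWN = "UNKNOWN"


class Lineage(str, Enum):
    """Which branch of the domestic/wild species pair a divergence call
    refers to.  The tame line of a tame-vs-aggressive selection experiment
    is treated as the domestic branch."""

    DOMESTIC = "DOMESTIC"
    WILD = "WILD"


class ZeroPolicy(str, Enum):
    """What to do with a differential-expression record whose log2 fold
    change is exactly zero: no divergence polarity is inferable from it."""

    EXCLUDE = "exclude"
    ERROR = "error"
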