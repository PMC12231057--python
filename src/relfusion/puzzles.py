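"""Latin Square Task puzzle-set bookkeeping.

The task presents 4x4 Sudoku-like grids at three levels of relational
complexity (Binary, Ternary, Quaternary).  Each complexity level comprises a
fixed number of unique puzzle designs, and each design is shown several times
as rotated variants ("rotations") whose brain responses are later averaged.
This module only tracks that combinatorial structure; it renders no stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered complexity levels: 1 = Binary, 2 = Ternary, 3 = Quaternary.
COMPLEXITY_LABELS = {1: "binary", 2: "ternary", 3: "quaternary"}


@dataclass(frozen=True)
class PuzzleSet:
    """The puzzle inventory of one experiment.

    Attributes
    ----------
    puzzle_id : (n_puzzles,) int array, 1-based consecutive ids.
    complexity : (n_puzzles,) int array, ordinal level in 1..n_levels.
    design_id : (n_puzzles,) int array, unique design within a level.
    rotation_ids : dict puzzle_id -> tuple of replicate identifiers.
    """

    puzzle_id: np.ndarray
    complexity: np.ndarray
    design_id: np.ndarray
    rotation_ids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.puzzle_id.shape != self.complexity.shape:
            raise ValueError("puzzle_id and complexity must align")
        levels, counts = np.unique(self.complexity, return_counts=True)
        if len(set(counts.tolist())) != 1:
            raise ValueError("unbalanced design: unequal puzzles per level")
        for pid in self.puzzle_id:
            if len(self.rotation_ids.get(int(pid), ())) < 1:
                raise ValueError(f"puzzle {pid} has no rotation replicate")

    @property
    def n_puzzles(self) -> int:
        return len(self.puzzle_id)

    @property
    def n_levels(self) -> int:
        return int(len(np.unique(self.complexity)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "puzzle_id": self.puzzle_id,
                "complexity": self.complexity,
                "design_id": self.design_id,
                "n_rotations": [
                    len(self.rotation_ids[int(p)]) for p in self.puzzle_id
                ],
            }
        )


def make_puzzle_set(
    n_designs: int = 12,
    n_levels: int = 3,
    n_rotations: int = 3,
    seed: int | None = None,
) -> PuzzleSet:
    """Build the puzzle inventory: ``n_designs`` designs per complexity level,
    each replicated as ``n_rotations`` rotated presentations.

    The default (12, 3, 3) reproduces the fMRI arm: 36 unique puzzles shown
    three times each (108 trials), later averaged back to 36.  The EEG arm
    used four presentations per design.  ``seed`` is accepted for interface
    symmetry; the inventory itself is deterministic.
    """
    if n_designs < 1 or n_levels < 2 or n_rotations < 1:
        raise ValueError(
            "need n_designs >= 1, n_levels >= 2, n_rotations >= 1; got "
            f"({n_designs}, {n_levels}, {n_rotations})"
        )
    n_puzzles = n_designs * n_levels
    puzzle_id = np.arange(1, n_puzzles + 1)
    complexity = np.repeat(np.arange(1, n_levels + 1), n_designs)
    design_id = np.tile(np.arange(1, n_designs + 1), n_levels)
    rotation_ids = {
        int(pid): tuple(range(1, n_rotations + 1)) for pid in puzzle_id
    }
    return PuzzleSet(puzzle_id, complexity, design_id, rotation_ids)
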