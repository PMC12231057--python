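"""Candidate representational models.

Two model RDMs are compared with the brain data:

* the relational-complexity (RC) model — a theoretical matrix in which
  puzzles of the same complexity level are identical (distance 0) and
  between-level distances grow with the ordinal gap, so Binary and Quaternary
  puzzles are maximally distant;
* the cognitive-effort (CE) model — a data-driven matrix built from each
  puzzle's behavioural difficulty: the Euclidean distance between puzzles'
  (error rate, response time) feature vectors, averaged across participants
  (and, when both study arms are supplied, across the two arms with equal
  weight).

Because downstream comparisons are rank correlations, any strictly monotone
re-coding of the RC gradation is equivalent; the default codes are 0/1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Rdm
from .puzzles import PuzzleSet
from .stats import spearman_no_tie_correction


@dataclass
class ModelRdm(Rdm):
    kind: str = ""


def build_rc_model(puzzles: PuzzleSet) -> ModelRdm:
    """RC model RDM: entry (i, j) = |complexity_i - complexity_j|."""
    lev = np.asarray(puzzles.complexity, dtype=float)
    if np.any(~np.isfinite(lev)):
        raise ValueError("puzzles have missing complexity levels")
    d = np.abs(lev[:, None] - lev[None, :])
    return ModelRdm(d, puzzles.puzzle_id, tag="model:RC", kind="RC")


def build_ce_model(behaviour: pd.DataFrame,
                   behaviour_second: pd.DataFrame | None = None,
                   standardize: bool = True) -> ModelRdm:
    """CE model RDM from per-puzzle behavioural difficulty.

    Per puzzle, the feature vector is (error rate, response time) averaged
    across participants; when a second behaviour table is given (the other
    study arm), the two arm means receive equal weight.  Features are
    z-scored across puzzles by default (error rate and RT have incommensurate
    units); set ``standardize=False`` for raw units.  The entry (i, j) is the
    Euclidean distance between puzzle feature vectors.
    """
    feats = _puzzle_features(behaviour)
    if behaviour_second is not None:
        feats2 = _puzzle_features(behaviour_second)
        if not feats.index.equals(feats2.index):
            raise ValueError("the two behaviour tables cover different puzzles")
        feats = (feats + feats2) / 2.0
    x = feats.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        if np.any(sd == 0):
            sd = np.where(sd == 0, 1.0, sd)
        x = (x - x.mean(axis=0)) / sd
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    return ModelRdm(d, feats.index.to_numpy(), tag="model:CE", kind="CE")


def _puzzle_features(behaviour: pd.DataFrame) -> pd.DataFrame:
    req = {"puzzle_id", "accuracy", "rt"}
    missing = req - set(behaviour.columns)
    if missing:
        raise ValueError(f"behaviour table lacks columns {sorted(missing)}")
    counts = behaviour.groupby("puzzle_id").size()
    if (counts < 1).any():
        raise ValueError("every puzzle needs at least one behavioural record")
    g = behaviour.groupby("puzzle_id")[["accuracy", "rt"]].mean()
    out = pd.DataFrame({"error_rate": 1.0 - g["accuracy"], "rt": g["rt"]})
    return out.sort_index()


def model_model_correlation(a: Rdm, b: Rdm) -> float:
    """Spearman correlation (no tie correction) between the vectorized upper
    triangles of two model RDMs."""
    if a.n != b.n or not np.array_equal(np.asarray(a.puzzle_ids),
                                        np.asarray(b.puzzle_ids)):
        raise ValueError("model RDMs must share puzzle ids and order")
    return spearman_no_tie_correction(a.upper(), b.upper())
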