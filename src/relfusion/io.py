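"""On-disk formats.

Dense arrays (patterns, epochs, RDMs) are stored as ``.npy`` files with a
JSON metadata sidecar (``<name>.json``) describing dimension names, units and
acquisition metadata; tabular data (behaviour, results) are TSV.  Readers
validate the sidecar schema and name the offending field on mismatch.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EegDataset, PatternMatrix, Rdm


class InvalidFormatError(ValueError):
    pass


def _write_sidecar(path: Path, meta: dict) -> None:
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _read_sidecar(path: Path, required: tuple) -> dict:
    side = path.with_suffix(".json")
    if not side.exists():
        raise InvalidFormatError(f"missing sidecar {side.name}")
    meta = json.loads(side.read_text())
    for key in required:
        if key not in meta:
            raise InvalidFormatError(f"sidecar {side.name} lacks field {key!r}")
    return meta


def write_patterns(path, p: PatternMatrix, units: str = "beta (a.u.)") -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), p.values)
    _write_sidecar(path, {
        "kind": "pattern_matrix",
        "dims": ["puzzle", "feature"],
        "units": units,
        "puzzle_ids": [int(x) for x in p.puzzle_ids],
        "shape": list(p.values.shape),
    })


def read_patterns(path) -> PatternMatrix:
    path = Path(path)
    meta = _read_sidecar(path, ("kind", "dims", "puzzle_ids", "shape"))
    values = np.load(path.with_suffix(".npy"))
    if list(values.shape) != meta["shape"]:
        raise InvalidFormatError(
            f"array shape {values.shape} does not match sidecar field 'shape'"
        )
    return PatternMatrix(values, np.asarray(meta["puzzle_ids"]))


def write_epochs(path, e: EegDataset, units: str = "uV") -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), e.epochs)
    _write_sidecar(path, {
        "kind": "eeg_epochs",
        "dims": ["puzzle", "sensor", "sample"],
        "units": units,
        "participant_id": int(e.participant_id),
        "puzzle_ids": [int(x) for x in e.puzzle_ids],
        "sample_rate": e.sample_rate,
        "t_start": e.t_start,
        "t_end": e.t_end,
        "shape": list(e.epochs.shape),
    })


def read_epochs(path) -> EegDataset:
    path = Path(path)
    meta = _read_sidecar(path, ("kind", "participant_id", "puzzle_ids",
                                "sample_rate", "t_start", "t_end", "shape"))
    values = np.load(path.with_suffix(".npy"))
    if list(values.shape) != meta["shape"]:
        raise InvalidFormatError(
            f"array shape {values.shape} does not match sidecar field 'shape'"
        )
    return EegDataset(meta["participant_id"], values,
                      np.asarray(meta["puzzle_ids"]),
                      meta["sample_rate"], meta["t_start"], meta["t_end"])


def write_rdm(path, r: Rdm) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), r.values)
    _write_sidecar(path, {
        "kind": "rdm",
        "tag": r.tag,
        "puzzle_ids": [int(x) for x in r.puzzle_ids],
        "shape": list(r.values.shape),
    })


def read_rdm(path) -> Rdm:
    path = Path(path)
    meta = _read_sidecar(path, ("kind", "tag", "puzzle_ids", "shape"))
    values = np.load(path.with_suffix(".npy"))
    if list(values.shape) != meta["shape"]:
        raise InvalidFormatError(
            f"array shape {values.shape} does not match sidecar field 'shape'"
        )
    return Rdm(values, np.asarray(meta["puzzle_ids"]), tag=meta["tag"])


def rdm_to_long_tsv(path, r: Rdm) -> None:
    """Long-format export: puzzle_i, puzzle_j, dissimilarity (i < j)."""
    iu, ju = np.triu_indices(r.n, k=1)
    pd.DataFrame({
        "puzzle_i": np.asarray(r.puzzle_ids)[iu],
        "puzzle_j": np.asarray(r.puzzle_ids)[ju],
        "dissimilarity": r.values[iu, ju],
    }).to_csv(path, sep="\t", index=False)


def write_behaviour(path, behaviour: pd.DataFrame) -> None:
    cols = ["participant_id", "puzzle_id", "complexity", "accuracy", "rt"]
    behaviour[cols].to_csv(path, sep="\t", index=False)


def read_behaviour(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"participant_id", "puzzle_id", "accuracy", "rt"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidFormatError(f"behaviour TSV lacks columns {sorted(missing)}")
    return df


def read_patterns_tsv(path) -> PatternMatrix:
    """Pattern matrix from a TSV with a ``puzzle_id`` column followed by one
    column per feature."""
    df = pd.read_csv(path, sep="\t")
    if "puzzle_id" not in df.columns:
        raise InvalidFormatError("pattern TSV lacks column 'puzzle_id'")
    ids = df["puzzle_id"].to_numpy()
    values = df.drop(columns="puzzle_id").to_numpy(dtype=float)
    return PatternMatrix(values, ids)
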