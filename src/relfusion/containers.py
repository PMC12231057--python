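"""In-memory containers shared across the pipeline.

Everything is built on plain numpy arrays with light dataclass wrappers that
enforce the invariants the analysis relies on (RDM symmetry, epoch grid
consistency, pattern/puzzle alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical EEG frequency bands (Hz).
BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with low/high cutoffs in Hz."""

    label: str
    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band {self.label}: {self.low}-{self.high} Hz")

    @classmethod
    def named(cls, label: str) -> "BandSpec":
        if label not in BANDS:
            raise ValueError(f"unknown band {label!r}; choose from {sorted(BANDS)}")
        lo, hi = BANDS[label]
        return cls(label, lo, hi)


@dataclass
class PatternMatrix:
    """A puzzle x feature activation matrix (fMRI vertices/voxels, or EEG
    sensors at one time point)."""

    values: np.ndarray
    puzzle_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.puzzle_ids = np.asarray(self.puzzle_ids)
        if self.values.ndim != 2:
            raise ValueError("pattern must be 2-D (puzzle x feature)")
        if self.values.shape[0] != self.puzzle_ids.size:
            raise ValueError("row count must match puzzle_ids")
        if self.values.shape[1] < 1:
            raise ValueError("need at least one feature")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("pattern contains missing/non-finite values")

    @property
    def n_puzzles(self) -> int:
        return self.values.shape[0]


@dataclass
class Rdm:
    """A puzzle x puzzle dissimilarity matrix.

    Symmetry, zero diagonal and non-negativity are asserted on construction
    (tiny negative round-off is clipped to zero).
    """

    values: np.ndarray
    puzzle_ids: np.ndarray
    tag: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        self.puzzle_ids = np.asarray(self.puzzle_ids)
        n = self.puzzle_ids.size
        if v.shape != (n, n):
            raise ValueError("RDM must be square and match puzzle_ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if np.any(v < -1e-10):
            raise ValueError("RDM entries must be non-negative")
        v = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper(self) -> np.ndarray:
        """Upper triangle, row-major (i < j)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class RdmSeries:
    """Time-binned RDMs for one frequency band.

    ``values`` is (n_bins, n_puzzles, n_puzzles); bin centers are in seconds
    relative to stimulus onset and strictly increasing with uniform width.
    """

    values: np.ndarray
    puzzle_ids: np.ndarray
    bin_centers: np.ndarray
    bin_width: float
    band: str = "broadband"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != self.bin_centers.size:
            raise ValueError("values must be (n_bins, n, n) matching bin_centers")
        d = np.diff(self.bin_centers)
        if self.bin_centers.size > 1 and (
            np.any(d <= 0) or not np.allclose(d, d[0], atol=1e-9)
        ):
            raise ValueError("bin centers must be strictly increasing and uniform")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, k: int) -> Rdm:
        return Rdm(self.values[k], self.puzzle_ids,
                   tag=f"{self.band}@{self.bin_centers[k]:.3f}s")


@dataclass
class EegDataset:
    """Sensor-level epochs for one participant.

    ``epochs`` is (n_puzzles, n_sensors, n_samples) in microvolt-like units on
    the half-open grid t = t_start + k/fs, k = 0..N-1 with
    N = round((t_end - t_start) * fs); the defaults (-0.4 to 4.5 s at 250 Hz)
    give 1225 samples.
    """

    participant_id: int
    epochs: np.ndarray
    puzzle_ids: np.ndarray
    sample_rate: float = 250.0
    t_start: float = -0.4
    t_end: float = 4.5

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.puzzle_ids = np.asarray(self.puzzle_ids)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (puzzle, sensor, sample)")
        if self.epochs.shape[0] != self.puzzle_ids.size:
            raise ValueError("first axis must match puzzle_ids")
        if self.epochs.shape[1] < 2:
            raise ValueError("need at least 2 sensors")
        n_expected = int(round((self.t_end - self.t_start) * self.sample_rate))
        if self.epochs.shape[2] != n_expected:
            raise ValueError(
                f"expected {n_expected} samples for "
                f"[{self.t_start}, {self.t_end}) at {self.sample_rate} Hz, "
                f"got {self.epochs.shape[2]}"
            )

    @property
    def times(self) -> np.ndarray:
        n = self.epochs.shape[2]
        return self.t_start + np.arange(n) / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]


@dataclass
class FmriDataset:
    """Region-wise beta patterns for one participant.

    ``patterns`` maps region_id -> (n_rows, n_features) array; with rotation
    replicates present, n_rows = n_puzzles * n_rotations and ``row_puzzle_ids``
    labels each row's puzzle.
    """

    participant_id: int
    patterns: dict
    row_puzzle_ids: np.ndarray
    region_to_network: dict = field(default_factory=dict)

    def __post_init__(self):
        self.row_puzzle_ids = np.asarray(self.row_puzzle_ids)
        for rid, pat in self.patterns.items():
            pat = np.asarray(pat, dtype=float)
            if pat.shape[0] != self.row_puzzle_ids.size:
                raise ValueError(f"region {rid}: row count mismatch")
            if pat.shape[1] < 2:
                raise ValueError(f"region {rid}: need >= 2 features")
            self.patterns[rid] = pat
        for rid in self.patterns:
            if rid not in self.region_to_network:
                raise ValueError(f"region {rid} has no network assignment")

    @property
    def n_regions(self) -> int:
        return len(self.patterns)
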