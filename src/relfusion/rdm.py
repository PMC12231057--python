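"""From activity patterns to representational dissimilarity matrices.

Spatial RDMs: each brain region's puzzle x feature beta pattern (rotations
averaged, features z-scored across puzzles) is turned into a 36 x 36 squared
Euclidean distance matrix, then averaged region-wise into functional networks.

Temporal RDMs: per time point, the puzzle x sensor EEG pattern yields one RDM;
per-time-point RDMs are averaged element-wise within consecutive 100 ms bins.
Band-limited variants first pass the epochs through a zero-phase band-pass
filter and re-apply pre-stimulus baseline correction.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal
from scipy.spatial.distance import squareform, pdist

from .containers import BandSpec, EegDataset, PatternMatrix, Rdm, RdmSeries

logger = logging.getLogger(__name__)


def average_rotations(values: np.ndarray, row_puzzle_ids, puzzle_order=None
                      ) -> PatternMatrix:
    """Average rotation-replicate rows into one row per puzzle.

    ``values`` is (n_rows, n_features) with ``row_puzzle_ids`` labelling each
    row's puzzle; the output has one row per unique puzzle (in
    ``puzzle_order`` if given, else sorted order of appearance).
    """
    values = np.asarray(values, dtype=float)
    row_ids = np.asarray(row_puzzle_ids)
    if values.shape[0] != row_ids.size:
        raise ValueError("row_puzzle_ids must label every row")
    if puzzle_order is None:
        puzzle_order = np.unique(row_ids)
    puzzle_order = np.asarray(puzzle_order)
    out = np.empty((puzzle_order.size, values.shape[1]))
    for k, pid in enumerate(puzzle_order):
        mask = row_ids == pid
        if not mask.any():
            raise ValueError(f"puzzle {pid} has no replicate rows")
        out[k] = values[mask].mean(axis=0)
    return PatternMatrix(out, puzzle_order)


def zscore_patterns(p: PatternMatrix) -> PatternMatrix:
    """Standardize each feature column across puzzles (mean 0, sd 1).

    Constant features carry no pattern information and are dropped with a
    logged count.
    """
    if p.n_puzzles < 2:
        raise ValueError("need at least 2 puzzles to z-score")
    v = p.values
    sd = v.std(axis=0, ddof=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d constant feature column(s)", n_dropped)
        v = v[:, keep]
        sd = sd[keep]
        if v.shape[1] == 0:
            raise ValueError("all feature columns are constant")
    z = (v - v.mean(axis=0)) / sd
    return PatternMatrix(z, p.puzzle_ids)


def squared_euclidean_rdm(p: PatternMatrix, tag: str = "") -> Rdm:
    """Puzzle x puzzle squared Euclidean distance matrix."""
    if p.n_puzzles < 2:
        raise ValueError("need at least 2 puzzles")
    d = squareform(pdist(p.values, metric="sqeuclidean"))
    return Rdm(d, p.puzzle_ids, tag=tag)


def bandpass_zero_phase(e: EegDataset, band: BandSpec, order: int = 4
                        ) -> EegDataset:
    """Zero-phase band-pass filter (forward-backward Butterworth).

    Filtering is applied along the sample axis for every trial and sensor;
    the forward-backward pass cancels group delay (no phase shift).
    """
    nyq = e.sample_rate / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.label} upper cutoff {band.high} Hz >= Nyquist {nyq} Hz"
        )
    sos = signal.butter(order, [band.low, band.high], btype="bandpass",
                        fs=e.sample_rate, output="sos")
    # default sosfiltfilt padlen for this order
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if e.n_samples <= padlen:
        raise ValueError(
            f"epoch too short ({e.n_samples} samples) for zero-phase "
            f"filtering (needs > {padlen})"
        )
    filtered = signal.sosfiltfilt(sos, e.epochs, axis=-1)
    return EegDataset(e.participant_id, filtered, e.puzzle_ids,
                      e.sample_rate, e.t_start, e.t_end)


def baseline_correct(e: EegDataset) -> EegDataset:
    """Subtract each trial x sensor's mean pre-stimulus (t < 0) signal from
    the whole epoch."""
    pre = e.times < 0
    if not pre.any():
        raise ValueError("no pre-stimulus samples (t_start must be < 0)")
    baseline = e.epochs[:, :, pre].mean(axis=-1, keepdims=True)
    return EegDataset(e.participant_id, e.epochs - baseline, e.puzzle_ids,
                      e.sample_rate, e.t_start, e.t_end)


def temporal_rdm_series(e: EegDataset, bin_width: float = 0.1,
                        band: str = "broadband") -> RdmSeries:
    """Per-time-point puzzle x sensor RDMs, averaged within consecutive bins.

    Squared Euclidean RDMs are computed at every sample and then averaged
    element-wise within bins of ``bin_width`` seconds.  The trailing partial
    bin is dropped: the default grid (1225 samples, 100 ms bins at 250 Hz)
    yields floor(1225 / 25) = 49 bins.
    """
    spb_f = bin_width * e.sample_rate
    spb = int(round(spb_f))
    if spb < 1:
        raise ValueError("bin_width must cover at least one sample")
    if abs(spb_f - spb) > 1e-9:
        raise ValueError("bin_width must be an integer multiple of the sample period")
    x = e.epochs  # (P, S, T)
    sq = np.einsum("pst,pst->pt", x, x)
    gram = np.einsum("ist,jst->ijt", x, x)
    d = sq[:, None, :] + sq[None, :, :] - 2.0 * gram  # (P, P, T)
    n_bins = x.shape[2] // spb
    if n_bins < 1:
        raise ValueError("epoch shorter than one bin")
    d = d[:, :, : n_bins * spb].reshape(x.shape[0], x.shape[0], n_bins, spb)
    binned = np.clip(d.mean(axis=-1), 0.0, None)  # (P, P, n_bins)
    binned = np.moveaxis(binned, -1, 0)
    binned = (binned + binned.transpose(0, 2, 1)) / 2.0
    for k in range(n_bins):
        np.fill_diagonal(binned[k], 0.0)
    centers = e.t_start + (np.arange(n_bins) + 0.5) * bin_width
    return RdmSeries(binned, e.puzzle_ids, centers, bin_width, band=band)


def network_average_rdms(region_rdms: dict, region_to_network: dict) -> dict:
    """Element-wise average of member-region RDMs per functional network.

    Returns ``{network_label: Rdm}``; networks with no member regions are
    skipped with a warning.
    """
    members: dict = {}
    for rid, rdm in region_rdms.items():
        net = region_to_network.get(rid)
        if net is None:
            raise ValueError(f"region {rid} has no network assignment")
        members.setdefault(net, []).append(rdm)
    networks = set(region_to_network.values())
    out = {}
    for net in sorted(networks):
        if net not in members:
            logger.warning("network %s has no regions; skipped", net)
            continue
        rdms = members[net]
        vals = np.mean([r.values for r in rdms], axis=0)
        out[net] = Rdm(vals, rdms[0].puzzle_ids, tag=f"network:{net}")
    return out
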