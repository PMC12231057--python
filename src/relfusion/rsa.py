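"""End-to-end RSA drivers: spatial (fMRI) and temporal (EEG) analyses.

Spatial: per participant and brain region, the rotation-averaged, z-scored
beta pattern yields a 36 x 36 squared Euclidean RDM; region RDMs are averaged
into 13 functional networks; per unit, the coding strength is the Spearman
correlation (no tie correction) between the empirical and model RDM upper
triangles, Fisher z-transformed and tested against zero across participants
with FDR control.

Temporal: per participant and frequency band, baseline-corrected (and
band-pass filtered) epochs yield a time series of RDMs in 100 ms bins; per
bin, coding strengths are computed and tested the same way across
participants, with FDR across bins.

Data are generated (or supplied) per participant and reduced immediately, so
the full study never has to sit in memory at once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BandSpec, EegDataset, FmriDataset, Rdm, RdmSeries
from .rdm import (average_rotations, bandpass_zero_phase, baseline_correct,
                  network_average_rdms, squared_euclidean_rdm,
                  temporal_rdm_series, zscore_patterns)
from .stats import fdr_adjust, fisher_z, group_onesample_t, \
    spearman_no_tie_matrix, uncorrected_null_mean
from .synth import GeneratorConfig, simulate_eeg_epochs, simulate_fmri_patterns


def participant_region_rdms(fmri: FmriDataset, puzzle_order=None) -> dict:
    """Region -> Rdm for one participant (rotations averaged, features
    z-scored across puzzles, squared Euclidean distances)."""
    out = {}
    for rid, pat in fmri.patterns.items():
        pm = average_rotations(pat, fmri.row_puzzle_ids, puzzle_order)
        pm = zscore_patterns(pm)
        out[rid] = squared_euclidean_rdm(pm, tag=f"region:{rid}")
    return out


def participant_band_series(e: EegDataset, band: str = "broadband",
                            bin_width: float = 0.1) -> RdmSeries:
    """Time-binned RDM series for one participant and band.

    Epochs are baseline-corrected against the pre-stimulus window, band-pass
    filtered (zero-phase) unless ``band == 'broadband'``, and reduced to
    per-bin squared-Euclidean RDMs over the puzzle x sensor patterns.
    """
    e = baseline_correct(e)
    if band != "broadband":
        e = bandpass_zero_phase(e, BandSpec.named(band))
    return temporal_rdm_series(e, bin_width=bin_width, band=band)


def _group_table(unit_labels, unit_kind, model_kind, rho_matrix,
                 alternative="greater", fdr_method="by", alpha=0.05,
                 null_mean: float = 0.0) -> pd.DataFrame:
    """Group inference over units: rho (participant x unit) -> tidy table.

    ``null_mean`` is the expected value of the uncorrected Spearman
    estimator under pure noise for this model's tie structure; coding
    strengths are centred on it (on the Fisher-z scale) before the t-test,
    so the null hypothesis is genuinely "no model correspondence".
    """
    z = fisher_z(np.clip(rho_matrix, -1 + 1e-15, 1 - 1e-15)) - fisher_z(null_mean)
    rows = []
    for j, unit in enumerate(unit_labels):
        g = group_onesample_t(z[:, j], alternative=alternative,
                              unit=unit, model=model_kind)
        rows.append(g)
    p_adj, sig = fdr_adjust([g.p for g in rows], alpha=alpha,
                            method=fdr_method)
    return pd.DataFrame(
        {
            "unit": unit_labels,
            "unit_kind": unit_kind,
            "model": model_kind,
            "mean_z": [g.mean_z for g in rows],
            "t": [g.t for g in rows],
            "df": [g.df for g in rows],
            "p": [g.p for g in rows],
            "p_fdr": p_adj,
            "significant": sig,
        }
    )


def spatial_rsa(puzzles, behaviour, cfg: GeneratorConfig, model_rdms: dict,
                participants=None, datasets=None, alternative="greater",
                fdr_method="by", alpha=0.05):
    """Region- and network-level model coding in the fMRI arm.

    ``model_rdms`` maps model kind (e.g. "RC", "CE") to a model Rdm.  When
    ``datasets`` is None, each participant's data are generated on the fly
    from ``cfg``.  Returns ``(results_table, mean_network_rdms)`` where the
    table has one row per unit x model and ``mean_network_rdms`` are the
    participant-averaged network RDMs used later by the fusion stage.
    """
    if participants is None:
        participants = list(range(1, cfg.n_participants_fmri + 1))
    model_vecs = {kind: m.upper() for kind, m in model_rdms.items()}
    null_means = {kind: uncorrected_null_mean(v) for kind, v in model_vecs.items()}

    region_rhos = {kind: [] for kind in model_rdms}
    network_rhos = {kind: [] for kind in model_rdms}
    net_sum = None
    region_ids = network_ids = None
    region_to_network = None
    for k, pid in enumerate(participants):
        if datasets is not None:
            ds = datasets[k]
        else:
            ds = simulate_fmri_patterns(puzzles, behaviour, cfg,
                                        participants=[pid])[0]
        rdms = participant_region_rdms(ds, puzzle_order=puzzles.puzzle_id)
        nets = network_average_rdms(rdms, ds.region_to_network)
        if region_ids is None:
            region_ids = sorted(rdms.keys())
            network_ids = sorted(nets.keys())
            region_to_network = dict(ds.region_to_network)
            net_sum = {n: np.zeros_like(nets[n].values) for n in network_ids}
        reg_mat = np.stack([rdms[r].upper() for r in region_ids])
        net_mat = np.stack([nets[n].upper() for n in network_ids])
        for n in network_ids:
            net_sum[n] += nets[n].values
        for kind, vec in model_vecs.items():
            region_rhos[kind].append(spearman_no_tie_matrix(reg_mat, vec))
            network_rhos[kind].append(spearman_no_tie_matrix(net_mat, vec))

    tables = []
    for kind in model_rdms:
        tables.append(_group_table(region_ids, "region", kind,
                                   np.stack(region_rhos[kind]),
                                   alternative, fdr_method, alpha,
                                   null_mean=null_means[kind]))
        tables.append(_group_table(network_ids, "network", kind,
                                   np.stack(network_rhos[kind]),
                                   alternative, fdr_method, alpha,
                                   null_mean=null_means[kind]))
    mean_nets = {
        n: Rdm(net_sum[n] / len(participants), puzzles.puzzle_id,
               tag=f"group-network:{n}")
        for n in network_ids
    }
    results = pd.concat(tables, ignore_index=True)
    results.attrs["region_to_network"] = region_to_network
    return results, mean_nets


def temporal_rsa(puzzles, behaviour, cfg: GeneratorConfig, model_rdms: dict,
                 bands=("broadband", "theta", "alpha", "beta", "gamma"),
                 bin_width: float = 0.1, participants=None, datasets=None,
                 alternative="greater", fdr_method="by", alpha=0.05):
    """Time-resolved model coding in the EEG arm, per frequency band.

    Returns ``(results_table, group_series)``: the table has one row per
    band x time bin x model (FDR across bins within band x model), and
    ``group_series`` maps band -> participant-averaged RdmSeries (the EEG
    side of the fusion stage).
    """
    if participants is None:
        participants = list(range(1, cfg.n_participants_eeg + 1))
    model_vecs = {kind: m.upper() for kind, m in model_rdms.items()}
    null_means = {kind: uncorrected_null_mean(v) for kind, v in model_vecs.items()}

    rhos = {(b, kind): [] for b in bands for kind in model_rdms}
    series_sum = {}
    centers = {}
    iu = None
    for k, pid in enumerate(participants):
        if datasets is not None:
            e = datasets[k]
        else:
            e = simulate_eeg_epochs(puzzles, behaviour, cfg,
                                    participants=[pid])[0]
        for b in bands:
            series = participant_band_series(e, band=b, bin_width=bin_width)
            if iu is None:
                iu = np.triu_indices(series.values.shape[1], k=1)
            vecs = series.values[:, iu[0], iu[1]]  # (n_bins, n_pairs)
            if b not in series_sum:
                series_sum[b] = np.zeros_like(series.values)
                centers[b] = series.bin_centers
            series_sum[b] += series.values
            for kind, mvec in model_vecs.items():
                rhos[(b, kind)].append(spearman_no_tie_matrix(vecs, mvec))

    tables = []
    for b in bands:
        for kind in model_rdms:
            tab = _group_table(
                [f"{c:.3f}" for c in centers[b]], "time_bin", kind,
                np.stack(rhos[(b, kind)]), alternative, fdr_method, alpha,
                null_mean=null_means[kind])
            tab.insert(0, "band", b)
            tab["bin_center_s"] = centers[b]
            tables.append(tab)
    group_series = {
        b: RdmSeries(series_sum[b] / len(participants), puzzles.puzzle_id,
                     centers[b], bin_width, band=b)
        for b in bands
    }
    return pd.concat(tables, ignore_index=True), group_series
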