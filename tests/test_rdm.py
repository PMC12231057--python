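"""RDM construction: rotation averaging, z-scoring, distances, filtering,
baselining, time binning and network averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relfusion.containers import BandSpec, EegDataset, PatternMatrix, Rdm
from relfusion.rdm import (average_rotations, bandpass_zero_phase,
                           baseline_correct, network_average_rdms,
                           squared_euclidean_rdm, temporal_rdm_series,
                           zscore_patterns)


def _epochs(values, fs=250.0, t_start=-0.4, t_end=4.5, pid=1):
    n = values.shape[0]
    return EegDataset(pid, values, np.arange(1, n + 1), fs, t_start, t_end)


# ---------------------------------------------------------------- averaging

def test_average_rotations_means_replicates():
    vals = np.array([[1.0, 1.0], [3.0, 3.0], [5.0, 7.0]])
    out = average_rotations(vals, [1, 1, 2])
    assert np.allclose(out.values, [[2.0, 2.0], [5.0, 7.0]])


def test_average_rotations_single_replicate_is_identity(rng):
    vals = rng.normal(size=(4, 3))
    out = average_rotations(vals, [1, 2, 3, 4])
    assert np.allclose(out.values, vals)


def test_average_rotations_study_shape(rng):
    vals = rng.normal(size=(36 * 3, 5))
    ids = np.tile(np.arange(1, 37), 3)
    out = average_rotations(vals, ids, np.arange(1, 37))
    assert out.values.shape == (36, 5)


def test_average_rotations_missing_puzzle_errors(rng):
    with pytest.raises(ValueError, match="no replicate"):
        average_rotations(rng.normal(size=(2, 2)), [1, 1], puzzle_order=[1, 2])


# ---------------------------------------------------------------- z-scoring

def test_zscore_standardizes_columns(rng):
    p = PatternMatrix(rng.normal(2.0, 3.0, size=(36, 20)), np.arange(36))
    z = zscore_patterns(p)
    assert np.abs(z.values.mean(axis=0)).max() < 1e-12
    assert np.abs(z.values.std(axis=0) - 1).max() < 1e-12


def test_zscore_idempotent_on_standardized(rng):
    p = zscore_patterns(PatternMatrix(rng.normal(size=(10, 4)), np.arange(10)))
    z = zscore_patterns(p)
    assert np.allclose(z.values, p.values, atol=1e-12)


def test_zscore_drops_constant_columns(rng, caplog):
    vals = rng.normal(size=(8, 3))
    vals[:, 1] = 7.0
    with caplog.at_level("WARNING"):
        z = zscore_patterns(PatternMatrix(vals, np.arange(8)))
    assert z.values.shape == (8, 2)
    assert "constant feature" in caplog.text


# ---------------------------------------------------------------- distances

def test_squared_euclidean_345_triangle():
    p = PatternMatrix(np.array([[0.0, 0.0], [3.0, 4.0]]), np.arange(2))
    rdm = squared_euclidean_rdm(p)
    assert rdm.values[0, 1] == pytest.approx(25.0)


def test_squared_euclidean_identical_rows_zero():
    p = PatternMatrix(np.ones((4, 3)), np.arange(4))
    assert np.allclose(squared_euclidean_rdm(p).values, 0.0)


def test_squared_euclidean_matches_bruteforce(rng):
    """Vectorized distances equal an explicit double loop on 1000 random
    instances."""
    for _ in range(1000):
        n, f = rng.integers(2, 9), rng.integers(2, 6)
        x = rng.normal(size=(n, f))
        rdm = squared_euclidean_rdm(PatternMatrix(x, np.arange(n)))
        for i in range(n):
            for j in range(n):
                expect = np.sum((x[i] - x[j]) ** 2)
                assert abs(rdm.values[i, j] - expect) < 1e-12


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_rdm_invariants_hold_for_random_patterns(seed):
    """Every constructed RDM is symmetric, zero-diagonal, non-negative."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(rng.integers(2, 12), rng.integers(2, 6)))
    rdm = squared_euclidean_rdm(PatternMatrix(x, np.arange(x.shape[0])))
    assert np.allclose(rdm.values, rdm.values.T)
    assert np.all(np.diag(rdm.values) == 0)
    assert np.all(rdm.values >= 0)


# ---------------------------------------------------------------- filtering

def _tone(freq, fs=250.0, t_start=-0.4, t_end=4.5):
    n = int(round((t_end - t_start) * fs))
    t = t_start + np.arange(n) / fs
    return np.sin(2 * np.pi * freq * t)


def test_beta_filter_passes_20hz_tone():
    sig = _tone(20.0)
    e = _epochs(np.tile(sig, (2, 2, 1)))
    out = bandpass_zero_phase(e, BandSpec.named("beta"))
    mid = slice(300, 900)  # avoid edges
    ratio = out.epochs[0, 0, mid].std() / e.epochs[0, 0, mid].std()
    assert ratio >= 0.9


def test_alpha_filter_attenuates_20hz_tone():
    sig = _tone(20.0)
    e = _epochs(np.tile(sig, (2, 2, 1)))
    out = bandpass_zero_phase(e, BandSpec.named("alpha"))
    mid = slice(300, 900)
    ratio = out.epochs[0, 0, mid].std() / e.epochs[0, 0, mid].std()
    assert 20 * np.log10(1 / ratio) >= 20.0


def test_zero_phase_no_lag():
    sig = _tone(20.0)
    e = _epochs(np.tile(sig, (1, 2, 1)))
    out = bandpass_zero_phase(e, BandSpec.named("beta"))
    a = e.epochs[0, 0, 300:900]
    b = out.epochs[0, 0, 300:900]
    lags = range(-5, 6)
    xc = [np.dot(a, np.roll(b, k)) for k in lags]
    assert list(lags)[int(np.argmax(xc))] == 0


def test_stopband_power_reduced_20db(rng):
    """White noise: power outside the passband is >= 20 dB below power
    inside, per band."""
    noise = rng.normal(size=(1, 2, 1225))
    e = _epochs(noise)
    from scipy.signal import welch
    for label in ("theta", "alpha", "beta", "gamma"):
        band = BandSpec.named(label)
        out = bandpass_zero_phase(e, band)
        f, p = welch(out.epochs[0, 0], fs=250.0, nperseg=512)
        inside = (f >= band.low) & (f <= band.high)
        stop = (f < band.low * 0.5) | (f > min(band.high * 2.0, 124.0))
        assert 10 * np.log10(p[inside].mean() / p[stop].mean()) >= 20.0


def test_band_above_nyquist_rejected():
    e = _epochs(np.zeros((1, 2, 1225)))
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass_zero_phase(e, BandSpec("ultra", 100.0, 130.0))


def test_short_epoch_rejected():
    e = EegDataset(1, np.zeros((1, 2, 25)), [1], 250.0, 0.0, 0.1)
    with pytest.raises(ValueError, match="too short"):
        bandpass_zero_phase(e, BandSpec.named("alpha"))


# ---------------------------------------------------------------- baseline

def test_baseline_constant_epoch_goes_to_zero():
    e = _epochs(np.full((2, 2, 1225), 3.7))
    assert np.allclose(baseline_correct(e).epochs, 0.0)


def test_baseline_subtracts_prestim_mean():
    vals = np.zeros((1, 2, 1225))
    vals[:, :, :100] = 2.0
    vals[:, :, 100:] = 5.0
    out = baseline_correct(_epochs(vals))
    assert out.epochs[0, 0, -1] == pytest.approx(3.0)


def test_baseline_zeroes_prestim_means(rng):
    e = _epochs(rng.normal(size=(3, 4, 1225)))
    out = baseline_correct(e)
    pre = out.times < 0
    assert np.abs(out.epochs[:, :, pre].mean(axis=-1)).max() < 1e-12


def test_baseline_requires_prestim_window():
    e = EegDataset(1, np.zeros((1, 2, 250)), [1], 250.0, 0.0, 1.0)
    with pytest.raises(ValueError, match="pre-stimulus"):
        baseline_correct(e)


# ---------------------------------------------------------------- binning

def test_default_grid_gives_49_bins(rng):
    e = _epochs(rng.normal(size=(4, 3, 1225)))
    series = temporal_rdm_series(e, bin_width=0.1)
    assert series.n_bins == 49  # floor(1225 / 25); trailing partial dropped
    assert series.bin_centers[0] == pytest.approx(-0.35)
    assert series.bin_centers[-1] == pytest.approx(4.45)


def test_constant_in_time_epochs_give_identical_bins(rng):
    pattern = rng.normal(size=(5, 4, 1))
    e = _epochs(np.repeat(pattern, 1225, axis=2))
    series = temporal_rdm_series(e)
    assert np.allclose(series.values, series.values[0][None])


def test_bin_narrower_than_sample_rejected(rng):
    e = _epochs(rng.normal(size=(2, 2, 1225)))
    with pytest.raises(ValueError):
        temporal_rdm_series(e, bin_width=0.001)


def test_time_shuffling_destroys_window_localization(puzzles, behaviour):
    """Shuffling samples in time spreads the implant across all bins: the
    out-of-window bins gain RDM magnitude they never had."""
    from relfusion.synth import GeneratorConfig, simulate_eeg_epochs
    cfg = GeneratorConfig(seed=5, n_sensors=8, eeg_noise_sd=1e-6)
    e = simulate_eeg_epochs(puzzles, behaviour, cfg, participants=[1])[0]
    series = temporal_rdm_series(e)
    rng = np.random.default_rng(0)
    shuffled = e.epochs[:, :, rng.permutation(e.n_samples)]
    series_sh = temporal_rdm_series(_epochs(shuffled, pid=1))
    mags = series.values.mean(axis=(1, 2))
    mags_sh = series_sh.values.mean(axis=(1, 2))
    outside = (series.bin_centers < 2.5) | (series.bin_centers > 4.1)
    assert mags[outside].max() < 1e-6 * mags.max()
    assert mags_sh[outside].max() > 0.1 * mags_sh.max()


# ------------------------------------------------------- network averaging

def test_network_average_single_region_unchanged(rng):
    x = rng.normal(size=(4, 3))
    rdm = squared_euclidean_rdm(PatternMatrix(x, np.arange(4)))
    out = network_average_rdms({1: rdm}, {1: "frontoparietal"})
    assert np.allclose(out["frontoparietal"].values, rdm.values)


def test_network_average_is_elementwise_mean():
    ids = np.arange(3)
    a = Rdm(np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float), ids)
    b = Rdm(np.array([[0, 4, 4], [4, 0, 4], [4, 4, 0]], float), ids)
    out = network_average_rdms({1: a, 2: b}, {1: "net", 2: "net"})
    assert out["net"].values[0, 1] == pytest.approx(3.0)


def test_network_average_default_parcellation(puzzles, behaviour):
    from relfusion.rsa import participant_region_rdms
    from relfusion.synth import GeneratorConfig, simulate_fmri_patterns
    cfg = GeneratorConfig(seed=0, n_regions=26)
    ds = simulate_fmri_patterns(puzzles, behaviour, cfg, participants=[1])[0]
    rdms = participant_region_rdms(ds, puzzles.puzzle_id)
    nets = network_average_rdms(rdms, ds.region_to_network)
    assert len(nets) == 13


def test_empty_network_skipped_with_warning(rng, caplog):
    x = rng.normal(size=(4, 3))
    rdm = squared_euclidean_rdm(PatternMatrix(x, np.arange(4)))
    with caplog.at_level("WARNING"):
        out = network_average_rdms({1: rdm}, {1: "a", 2: "b"})
    assert "b" not in out and "no regions" in caplog.text
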