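"""Welch spectra with a simplified aperiodic/periodic decomposition.

The power spectral density of the late task window (default 2.1-4.2 s
post-stimulus) is estimated with Welch's method (500-sample Hann segments,
50% overlap, 2-45 Hz) and averaged over trials and channels.  The spectrum
is then split into an aperiodic 1/f component — a robust linear fit of
log10(power) on log10(frequency) in "fixed" mode (offset and exponent, no
knee), iteratively down-weighting positive outliers so narrowband peaks do
not bias the slope — and a periodic component: a single Gaussian fitted to
the residual inside a requested band (e.g. beta, 13-30 Hz), yielding the
band's peak frequency and power above the aperiodic background.

This is a single-band, single-pass decomposition, not the full iterative
multi-peak spectral parameterization algorithm; range, fixed mode, minimum
peak height 0.0 and peak width limits (0.5-12 Hz) follow the analysis
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from .containers import BandSpec, EegDataset


@dataclass
class PsdSpectrum:
    """Trial- and channel-averaged power spectral density."""

    frequencies: np.ndarray
    power: np.ndarray
    window: tuple
    n_trials: int
    n_channels: int

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class AperiodicFit:
    """Fixed-mode aperiodic parameters: log10 power ~ offset - exponent * log10 f."""

    offset: float
    exponent: float
    r_squared: float
    fmin: float
    fmax: float

    def predict_log10(self, frequencies) -> np.ndarray:
        f = np.asarray(frequencies, dtype=float)
        return self.offset - self.exponent * np.log10(f)


@dataclass
class PeakEstimate:
    """Periodic peak within one band, measured above the aperiodic fit."""

    band: str
    frequency: float
    power: float          # log10 units above the aperiodic component
    found: bool


def welch_psd(e: EegDataset, window: tuple = (2.1, 4.2), nperseg: int = 500,
              overlap: float = 0.5, fmin: float = 2.0, fmax: float = 45.0
              ) -> PsdSpectrum:
    """Welch PSD of a time window, averaged over trials and channels.

    Hann-tapered segments of ``nperseg`` samples with fractional ``overlap``;
    the frequency grid is restricted to [fmin, fmax].
    """
    t0, t1 = window
    if not (e.t_start <= t0 < t1 <= e.t_end):
        raise ValueError("analysis window must lie within the epoch")
    sel = (e.times >= t0) & (e.times < t1)
    n_sel = int(sel.sum())
    if n_sel < nperseg:
        raise ValueError(
            f"window has {n_sel} samples, shorter than one {nperseg}-sample segment"
        )
    data = e.epochs[:, :, sel]
    freqs, pxx = signal.welch(
        data, fs=e.sample_rate, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), axis=-1,
    )
    keep = (freqs >= fmin) & (freqs <= fmax)
    power = pxx[..., keep].mean(axis=(0, 1))
    return PsdSpectrum(freqs[keep], power, (t0, t1),
                       n_trials=data.shape[0], n_channels=data.shape[1])


def fit_aperiodic_fixed(s: PsdSpectrum, n_iter: int = 5,
                        drop_fraction: float = 0.25) -> AperiodicFit:
    """Robust fixed-mode (no-knee) aperiodic fit.

    An ordinary least-squares line is fit to log10(power) vs log10(f); on
    each pass the ``drop_fraction`` largest *positive* residuals (likely peak
    regions — peaks only add power) are discarded and the line refit, for up
    to ``n_iter`` passes.  A peak-free power law is recovered exactly on the
    first pass.
    """
    if s.frequencies.size < 5:
        raise ValueError("need at least 5 frequency points")
    if np.any(s.power <= 0):
        raise ValueError("aperiodic fit requires strictly positive power")
    lx = np.log10(s.frequencies)
    ly = np.log10(s.power)
    mask = np.ones(lx.size, dtype=bool)
    slope = intercept = 0.0
    for _ in range(n_iter):
        slope, intercept = np.polyfit(lx[mask], ly[mask], 1)
        resid = ly - (intercept + slope * lx)
        pos = resid[mask & (resid > 0)]
        if pos.size == 0:
            break
        thresh = np.percentile(pos, 100.0 * (1.0 - drop_fraction))
        new_mask = mask & (resid <= max(thresh, 0.0))
        if new_mask.sum() < 5 or np.array_equal(new_mask, mask):
            break
        mask = new_mask
    fit_line = intercept + slope * lx
    ss_res = np.sum((ly - fit_line) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AperiodicFit(offset=float(intercept), exponent=float(-slope),
                        r_squared=float(r2),
                        fmin=float(s.frequencies[0]),
                        fmax=float(s.frequencies[-1]))


def _gaussian(f, height, center, width):
    return height * np.exp(-0.5 * ((f - center) / width) ** 2)


def extract_band_peak(s: PsdSpectrum, fit: AperiodicFit, band: BandSpec,
                      min_height: float = 0.0,
                      width_limits: tuple = (0.5, 12.0)) -> PeakEstimate:
    """Periodic peak inside ``band``: a Gaussian fitted to the flattened
    spectrum (log10 power minus the aperiodic fit) around the in-band
    residual maximum.

    ``found`` is False when the in-band residual maximum is below
    ``min_height`` (log10 units; default 0.0).
    """
    in_band = (s.frequencies >= band.low) & (s.frequencies <= band.high)
    if not in_band.any():
        raise ValueError(f"band {band.label} lies outside the spectrum range")
    resid = np.log10(s.power) - fit.predict_log10(s.frequencies)
    band_idx = np.where(in_band)[0]
    k = band_idx[int(np.argmax(resid[in_band]))]
    f0, h0 = float(s.frequencies[k]), float(resid[k])
    if h0 < min_height:
        return PeakEstimate(band.label, np.nan, np.nan, False)
    # a maximum sitting on the band edge with the residual still rising just
    # beyond it is the tail of a neighbouring band's peak, not an in-band one
    if (k == band_idx[0] and k > 0 and resid[k - 1] > h0) or \
            (k == band_idx[-1] and k + 1 < resid.size and resid[k + 1] > h0):
        return PeakEstimate(band.label, np.nan, np.nan, False)
    # fit the Gaussian on a neighbourhood around the maximum, using the full
    # flattened spectrum so shoulders outside the band edge still constrain it
    near = np.abs(s.frequencies - f0) <= max(2.0 * width_limits[0], 4.0)
    try:
        popt, _ = curve_fit(
            _gaussian, s.frequencies[near], resid[near],
            p0=[max(h0, 1e-3), f0, 1.0],
            bounds=([0.0, band.low, width_limits[0] / 2.0],
                    [np.inf, band.high, width_limits[1] / 2.0]),
            maxfev=2000,
        )
        height, center, _ = popt
    except RuntimeError:
        height, center = h0, f0
    return PeakEstimate(band.label, float(center), float(height), True)


def condition_band_peaks(datasets_by_condition: dict, band: BandSpec,
                         window: tuple = (2.1, 4.2), **welch_kwargs):
    """Per-condition peak estimates for one participant's epochs.

    ``datasets_by_condition`` maps condition label -> EegDataset (that
    condition's trials only).  Returns {condition: PeakEstimate}.  Group
    comparisons should exclude participants for whom ``found`` is False in
    any condition (no defined peak across all conditions).
    """
    out = {}
    for cond, ds in datasets_by_condition.items():
        spec = welch_psd(ds, window=window, **welch_kwargs)
        fit = fit_aperiodic_fixed(spec)
        out[cond] = extract_band_peak(spec, fit, band)
    return out
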