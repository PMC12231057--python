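"""Model-based EEG-fMRI fusion through commonality analysis.

For every brain network j and EEG time bin t, the shared representational
variance between the time-resolved EEG RDM (X_t) and the network fMRI RDM
(Y_j) is split between two candidate models, relational complexity (A) and
cognitive effort (B), using squared Spearman semi-partial correlations:

    C(A) = R2(X_t, Y_j . B) - R2(X_t, Y_j . A, B)

i.e. the variance shared between EEG and fMRI once everything except the
model of interest has been partialled out of fMRI, minus the share that
survives partialling out every model.  Ranks are computed once per RDM
(mid-rank over the vectorized upper triangle) and the residualization is
ordinary least squares on ranks.  Commonality coefficients can be negative
(suppression) and are never clipped.

Significance is assessed with a permutation null that re-labels the puzzles
of the EEG RDMs (rows and columns shuffled together); by default one
permutation per iteration is shared across all time bins so the null
preserves the temporal dependence of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import Rdm, RdmSeries
from .stats import DegenerateInputError, fdr_adjust


def rank_vectorize(r: Rdm) -> np.ndarray:
    """Mid-ranked upper-triangle vector (row-major, i < j) of an RDM."""
    return sps.rankdata(r.upper())


def _residualize(y: np.ndarray, controls) -> np.ndarray:
    """Residual of y after least-squares regression on controls + intercept."""
    n = y.size
    cols = [np.ones(n)] + [np.asarray(c, dtype=float) for c in controls]
    Z = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta


def semipartial_r2(x, y, controls=()) -> float:
    """Squared correlation between x and (y residualized on controls).

    With rank-transformed inputs this realizes the squared Spearman
    semi-partial correlation; with no controls it is the plain squared
    correlation of x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input")
    resid = _residualize(y, controls)
    if np.allclose(resid, 0.0, atol=1e-12 * max(1.0, np.abs(y).max())):
        raise DegenerateInputError(
            "controls explain y exactly; semi-partial undefined"
        )
    r = np.corrcoef(x, resid)[0, 1]
    return float(r * r)


def commonality_coefficient(x, y, a, b) -> float:
    """Variance uniquely shared through model-of-interest ``a``:
    ``R2(x, y.b) - R2(x, y.{a,b})``.  May be negative (suppression)."""
    return semipartial_r2(x, y, (b,)) - semipartial_r2(x, y, (a, b))


@dataclass
class CommonalityTimecourse:
    """Fusion results for one network x band."""

    network: str
    band: str
    bin_centers: np.ndarray
    total_r2: np.ndarray
    c_rc: np.ndarray
    c_ce: np.ndarray
    p_rc: np.ndarray | None = None
    p_ce: np.ndarray | None = None
    p_fdr_rc: np.ndarray | None = None
    p_fdr_ce: np.ndarray | None = None
    sig_rc: np.ndarray | None = None
    sig_ce: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "network": self.network,
            "band": self.band,
            "bin_center_s": self.bin_centers,
            "total_R2": self.total_r2,
            "C_RC": self.c_rc,
            "C_CE": self.c_ce,
        }
        for name in ("p_rc", "p_ce", "p_fdr_rc", "p_fdr_ce",
                     "sig_rc", "sig_ce"):
            v = getattr(self, name)
            if v is not None:
                d[name.replace("rc", "RC").replace("ce", "CE")] = v
        return pd.DataFrame(d)


def _pair_permutation_index(n: int, perm: np.ndarray) -> np.ndarray:
    """Index array mapping the upper-triangle vector of an RDM to the
    upper-triangle vector of the row/column-permuted RDM.

    ``out[k]`` is the source index such that ``vec_permuted = vec[out]``.
    """
    iu, ju = np.triu_indices(n, k=1)
    flat = np.full((n, n), -1, dtype=int)
    flat[iu, ju] = np.arange(iu.size)
    flat[ju, iu] = flat[iu, ju]
    return flat[perm[iu], perm[ju]]


def _prepare(inputs):
    """Rank-transform all RDMs and precompute fMRI residuals.

    Returns (X ranks per bin, per-network dict of (yr, resid_B, resid_AB,
    resid_A)).
    """
    x_series, fmri_rdms, rc, ce = inputs
    a = sps.rankdata(rc.upper())
    b = sps.rankdata(ce.upper())
    X = np.stack([sps.rankdata(x_series.values[k][np.triu_indices(
        x_series.values.shape[1], k=1)]) for k in range(x_series.n_bins)])
    pre = {}
    for net, y in fmri_rdms.items():
        yr = sps.rankdata(y.upper())
        pre[net] = {
            "resid_b": _residualize(yr, (b,)),       # for C(RC)
            "resid_a": _residualize(yr, (a,)),       # for C(CE)
            "resid_ab": _residualize(yr, (a, b)),
            "yr": yr,
        }
    return X, pre, a, b


def _corr2_rows(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each row of X with v."""
    Xc = X - X.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    num = Xc @ vc
    den = np.sqrt((Xc * Xc).sum(axis=1) * (vc @ vc))
    r = num / den
    return r * r


@dataclass
class FusionInputs:
    """EEG RDM time series (one band), per-network fMRI RDMs, and the two
    model RDMs (all sharing puzzle ids and order)."""

    eeg: RdmSeries
    fmri: dict
    rc: Rdm
    ce: Rdm

    def __post_init__(self):
        pids = np.asarray(self.eeg.puzzle_ids)
        for r in list(self.fmri.values()) + [self.rc, self.ce]:
            if not np.array_equal(np.asarray(r.puzzle_ids), pids):
                raise ValueError("all fusion RDMs must share puzzle ids/order")
        if pids.size < 3:
            raise ValueError("need at least 3 puzzles")


def fusion_timecourses(inputs: FusionInputs) -> dict:
    """Observed total R2 and commonality coefficients per network x bin
    (no inference).  Returns {network: CommonalityTimecourse}."""
    X, pre, _, _ = _prepare((inputs.eeg, inputs.fmri, inputs.rc, inputs.ce))
    out = {}
    for net, d in pre.items():
        r2_b = _corr2_rows(X, d["resid_b"])
        r2_a = _corr2_rows(X, d["resid_a"])
        r2_ab = _corr2_rows(X, d["resid_ab"])
        total = _corr2_rows(X, d["yr"])
        out[net] = CommonalityTimecourse(
            network=net, band=inputs.eeg.band,
            bin_centers=inputs.eeg.bin_centers.copy(),
            total_r2=total, c_rc=r2_b - r2_ab, c_ce=r2_a - r2_ab,
        )
    return out


def permutation_null(inputs: FusionInputs, n_perm: int = 5000,
                     seed: int | None = None,
                     share_across_bins: bool = True,
                     alpha: float = 0.05,
                     fdr_method: str = "by") -> dict:
    """Permutation inference on the commonality coefficients.

    Each iteration draws one puzzle relabelling and applies it to the rows
    and columns of every EEG RDM (shared across time bins by default, so the
    null retains the temporal dependence of the observed statistic); the
    commonality coefficients are recomputed and
    ``p = (1 + #{null >= observed}) / (n_perm + 1)`` (ties count as
    exceeding).  FDR correction is applied across bins within each
    network x model.  Returns {network: CommonalityTimecourse} with p-values
    and significance flags filled in.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = np.asarray(inputs.eeg.puzzle_ids).size
    if n < 3:
        raise ValueError("need at least 3 puzzles")
    rng = np.random.default_rng(seed)
    X, pre, _, _ = _prepare((inputs.eeg, inputs.fmri, inputs.rc, inputs.ce))
    observed = fusion_timecourses(inputs)
    nets = list(pre.keys())
    n_bins = X.shape[0]

    exceed_rc = {net: np.zeros(n_bins) for net in nets}
    exceed_ce = {net: np.zeros(n_bins) for net in nets}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        idx = _pair_permutation_index(n, perm)
        Xp = X[:, idx]
        if not share_across_bins:
            Xp = np.stack([
                X[k][_pair_permutation_index(n, rng.permutation(n))]
                for k in range(n_bins)
            ])
        for net in nets:
            d = pre[net]
            null_rc = _corr2_rows(Xp, d["resid_b"]) - \
                _corr2_rows(Xp, d["resid_ab"])
            null_ce = _corr2_rows(Xp, d["resid_a"]) - \
                _corr2_rows(Xp, d["resid_ab"])
            exceed_rc[net] += null_rc >= observed[net].c_rc
            exceed_ce[net] += null_ce >= observed[net].c_ce

    for net in nets:
        tc = observed[net]
        tc.p_rc = (1.0 + exceed_rc[net]) / (n_perm + 1.0)
        tc.p_ce = (1.0 + exceed_ce[net]) / (n_perm + 1.0)
        tc.p_fdr_rc, tc.sig_rc = fdr_adjust(tc.p_rc, alpha, fdr_method)
        tc.p_fdr_ce, tc.sig_ce = fdr_adjust(tc.p_ce, alpha, fdr_method)
    return observed


def fusion_pipeline(inputs: FusionInputs, n_perm: int = 5000,
                    seed: int | None = None, **kwargs) -> dict:
    """Full fusion analysis for one band: observed timecourses plus
    permutation p-values and FDR flags.  Deterministic given ``seed``."""
    return permutation_null(inputs, n_perm=n_perm, seed=seed, **kwargs)
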