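"""Group-level RSA statistics.

Model-to-data comparisons use Spearman rank correlation *without* tie
correction: both vectors are mid-ranked, then the classical formula
``rho = 1 - 6 * sum(d^2) / (n * (n^2 - 1))`` is applied even when ties are
present (model dissimilarity matrices are heavily tied, so this deliberately
differs from Pearson-on-ranks).  Per-participant correlations are Fisher
z-transformed and entered into one-sample t-tests, with FDR control across
units (regions, networks, or time bins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class DegenerateInputError(ValueError):
    """Raised when an input is constant/collinear and the statistic is undefined."""


def spearman_no_tie_correction(x, y) -> float:
    """Spearman rho via the uncorrected rank-difference formula.

    Ties receive mid-ranks, but no tie correction term is applied: with ties
    the result differs from ``scipy.stats.spearmanr`` (Pearson on ranks) by
    design.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input: rank correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    d = rx - ry
    return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1.0)))


def spearman_no_tie_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise ``spearman_no_tie_correction(X[i], y)`` (vectorized).

    ``X`` is (m, n); ``y`` is (n,).  Used to correlate many empirical RDM
    vectors against one model RDM vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    rX = sps.rankdata(X, axis=1)
    ry = sps.rankdata(y)
    d = rX - ry[None, :]
    return 1.0 - 6.0 * np.sum(d * d, axis=1) / (n * (n * n - 1.0))


def uncorrected_null_mean(y) -> float:
    """Expected value of the uncorrected Spearman formula against ``y`` when
    the other vector is continuous, independent noise.

    The no-tie-correction formula is positively biased whenever ``y`` has
    ties (tied mid-ranks shrink the rank variance, so the expected rank
    distance falls short of the tie-free value).  For a tie deficit
    ``T = m(m^2-1)/12 - (sum(ry^2) - m(m+1)^2/4)`` the null mean is
    ``6T / (m(m^2-1))``; it is 0 for a tie-free ``y``.  Group inference on
    coding strengths against heavily tied model RDMs must be centred on this
    value rather than zero.
    """
    y = np.asarray(y, dtype=float)
    m = y.size
    ry = sps.rankdata(y)
    s_y = float(np.sum(ry * ry))
    s_full = m * (m + 1) * (2 * m + 1) / 6.0
    return float(1.0 - 6.0 * (s_full + s_y - m * (m + 1) ** 2 / 2.0)
                 / (m * (m * m - 1.0)))


def fisher_z(rho, clip: bool = False):
    """Fisher z-transform (atanh).  ``|rho| = 1`` raises unless ``clip``."""
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(r) == 1):
        if not clip:
            raise ValueError("|rho| = 1 maps to an infinite z (set clip=True)")
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    z = np.arctanh(r)
    return float(z) if np.isscalar(rho) else z


@dataclass
class GroupResult:
    """One-sample t-test summary for one analysis unit."""

    unit: object
    model: str
    mean_z: float
    t: float
    df: int
    p: float
    p_fdr: float | None = None
    significant: bool | None = None


def group_onesample_t(z_values, alternative: str = "greater",
                      unit=None, model: str = "") -> GroupResult:
    """One-sample t-test of Fisher-z coding strengths against zero.

    One-sided (positive) by default: RSA model correspondence is directional.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 participants")
    if np.ptp(z) == 0:
        raise DegenerateInputError("zero variance across participants")
    t, p = sps.ttest_1samp(z, 0.0, alternative=alternative)
    return GroupResult(unit=unit, model=model, mean_z=float(z.mean()),
                       t=float(t), df=z.size - 1, p=float(p))


def fdr_adjust(p_values, alpha: float = 0.05, method: str = "by"):
    """FDR adjustment: Benjamini-Yekutieli by default, BH optional.

    Returns ``(p_adjusted, significant_flags)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"by": "fdr_by", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown FDR method {method!r} (use 'by' or 'bh')")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method=key)
    return p_adj, reject


def coding_behaviour_correlation(coding, accuracy):
    """Spearman correlation (standard, mid-ranks, two-sided p) between
    per-participant coding strengths and task accuracy."""
    c = np.asarray(coding, dtype=float)
    a = np.asarray(accuracy, dtype=float)
    if c.shape != a.shape or c.ndim != 1:
        raise ValueError("coding and accuracy must be matched 1-D vectors")
    if c.size < 3:
        raise ValueError("need at least 3 participants")
    rho, p = sps.spearmanr(c, a)
    return float(rho), float(p)


def rm_anova_oneway(values: np.ndarray):
    """One-way repeated-measures ANOVA on a participant x condition matrix.

    F = MS_condition / MS_error with df1 = k-1, df2 = (k-1)(n-1); no
    sphericity correction is applied.  Returns ``(F, df1, df2, p)``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("expected a participant x condition matrix")
    n, k = v.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 participants and >= 2 conditions")
    if np.any(~np.isfinite(v)):
        raise ValueError("missing cells are not supported")
    grand = v.mean()
    ss_cond = n * np.sum((v.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((v.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((v - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        if ms_cond == 0:
            return 0.0, df1, df2, 1.0
        raise DegenerateInputError("zero error variance")
    F = ms_cond / ms_err
    p = float(sps.f.sf(F, df1, df2))
    return float(F), df1, df2, p
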