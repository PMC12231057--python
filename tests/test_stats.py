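"""Statistical primitives: uncorrected Spearman, Fisher z, group tests,
FDR, brain-behaviour correlation, repeated-measures ANOVA."""

import numpy as np
import pytest
from scipy import stats as sps

from relfusion.stats import (DegenerateInputError,
                             coding_behaviour_correlation, fdr_adjust,
                             fisher_z, group_onesample_t, rm_anova_oneway,
                             spearman_no_tie_correction,
                             spearman_no_tie_matrix, uncorrected_null_mean)


# ------------------------------------------------------ uncorrected Spearman

def test_spearman_perfect_and_reversed():
    x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
    assert spearman_no_tie_correction(x, x) == pytest.approx(1.0)
    order = np.argsort(x)
    y = np.empty_like(x)
    y[order] = np.sort(x)[::-1]
    assert spearman_no_tie_correction(x, y) == pytest.approx(-1.0)


def test_spearman_tied_input_uses_uncorrected_formula():
    """With ties, the uncorrected formula differs from Pearson-on-ranks and
    equals the hand-applied 1 - 6*sum(d^2)/(n(n^2-1))."""
    x = np.array([1.0, 2.0, 2.0, 3.0])
    y = np.array([1.0, 3.0, 2.0, 4.0])
    rx = np.array([1.0, 2.5, 2.5, 4.0])
    ry = np.array([1.0, 3.0, 2.0, 4.0])
    expect = 1.0 - 6.0 * np.sum((rx - ry) ** 2) / (4 * 15)
    got = spearman_no_tie_correction(x, y)
    assert got == pytest.approx(expect, abs=1e-15)
    assert got != pytest.approx(sps.spearmanr(x, y).statistic)


def test_spearman_agrees_with_scipy_when_tie_free(rng):
    for _ in range(50):
        x, y = rng.normal(size=(2, 20))
        assert spearman_no_tie_correction(x, y) == pytest.approx(
            sps.spearmanr(x, y).statistic, abs=1e-12)


def test_spearman_matrix_matches_scalar(rng):
    X = rng.normal(size=(5, 30))
    y = rng.normal(size=30)
    rows = spearman_no_tie_matrix(X, y)
    for i in range(5):
        assert rows[i] == pytest.approx(
            spearman_no_tie_correction(X[i], y), abs=1e-12)


def test_spearman_constant_input_raises():
    with pytest.raises(DegenerateInputError):
        spearman_no_tie_correction(np.ones(5), np.arange(5.0))


def test_uncorrected_null_mean_matches_simulation(rng):
    """The closed-form null mean of the uncorrected estimator against a tied
    vector matches brute-force simulation."""
    y = np.repeat([0.0, 1.0, 2.0], [10, 6, 4])
    mu0 = uncorrected_null_mean(y)
    sims = [spearman_no_tie_correction(rng.normal(size=20), y)
            for _ in range(20000)]
    assert mu0 == pytest.approx(np.mean(sims), abs=4 * np.std(sims) / 140)
    assert uncorrected_null_mean(np.arange(10.0)) == pytest.approx(0.0)


# ----------------------------------------------------------------- Fisher z

def test_fisher_z_values():
    assert fisher_z(0.0) == 0.0
    assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5))
    grid = np.linspace(-0.99, 0.99, 41)
    assert np.allclose(np.tanh(fisher_z(grid)), grid, atol=1e-12)


def test_fisher_z_unit_rho_raises_unless_clipped():
    with pytest.raises(ValueError):
        fisher_z(1.0)
    assert np.isfinite(fisher_z(1.0, clip=True))


# -------------------------------------------------------------- group t-test

def test_group_t_matches_hand_formula():
    z = np.array([0.1, 0.2, 0.3])
    g = group_onesample_t(z, alternative="two-sided")
    se = z.std(ddof=1) / np.sqrt(3)
    assert g.t == pytest.approx(z.mean() / se)
    assert g.df == 2


def test_group_t_zero_variance_raises():
    with pytest.raises(DegenerateInputError):
        group_onesample_t(np.full(10, 0.1))


def test_group_t_type_one_rate(rng):
    """One-sided test at alpha=0.05 rejects ~5% of null samples."""
    n_rep, n = 1000, 40
    rejections = sum(
        group_onesample_t(rng.normal(size=n)).p <= 0.05
        for _ in range(n_rep))
    lo, hi = sps.binom.interval(0.95, n_rep, 0.05)
    assert lo <= rejections <= hi


# --------------------------------------------------------------------- FDR

def _bh_oracle(p):
    """Independent step-up implementation (Benjamini-Hochberg)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def _by_oracle(p):
    c = np.sum(1.0 / np.arange(1, len(p) + 1))
    return np.minimum(_bh_oracle(np.asarray(p) * c), 1.0)


def test_fdr_all_ones_none_significant():
    _, sig = fdr_adjust(np.ones(7))
    assert not sig.any()


def test_fdr_single_small_p_significant():
    adj, sig = fdr_adjust([0.01])
    assert sig[0] and adj[0] == pytest.approx(0.01)


@pytest.mark.parametrize("method,oracle", [("bh", _bh_oracle),
                                           ("by", _by_oracle)])
def test_fdr_matches_stepup_oracle(method, oracle, rng):
    for _ in range(1000):
        p = rng.uniform(size=rng.integers(2, 25))
        adj, sig = fdr_adjust(p, method=method)
        expect = oracle(p)
        assert np.allclose(adj, expect, atol=1e-12)
        assert np.array_equal(sig, expect <= 0.05)


def test_fdr_adjusted_monotone_and_bounded(rng):
    p = rng.uniform(size=30)
    adj, _ = fdr_adjust(p, method="by")
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)
    assert np.all(adj >= p - 1e-15)


def test_fdr_invalid_p_rejected():
    with pytest.raises(ValueError):
        fdr_adjust([0.2, 1.4])


# ----------------------------------------------- brain-behaviour correlation

def test_behaviour_correlation_monotone_pair():
    rho, _ = coding_behaviour_correlation([1, 2, 3, 4], [10, 20, 30, 40])
    assert rho == pytest.approx(1.0)


def test_behaviour_correlation_null_p_uniform(rng):
    """Independent pairs: two-sided p is approximately uniform."""
    ps = []
    for _ in range(1000):
        ps.append(coding_behaviour_correlation(
            rng.normal(size=20), rng.normal(size=20))[1])
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_behaviour_correlation_recovers_inverse_coupling(rng):
    """Participants with lower accuracy get higher coding values (the
    study's direction): recovered rho < 0."""
    acc = rng.uniform(0.5, 1.0, size=40)
    coding = 0.5 - 0.4 * acc + rng.normal(0, 0.05, size=40)
    rho, p = coding_behaviour_correlation(coding, acc)
    assert rho < 0 and p < 0.05


# ------------------------------------------------------------------ RM-ANOVA

def test_rm_anova_identical_columns_f_zero():
    v = np.tile(np.array([[1.0], [2.0], [5.0]]), (1, 3))
    F, df1, df2, p = rm_anova_oneway(v)
    assert F == 0.0 and df1 == 2 and df2 == 4 and p == pytest.approx(1.0)


def test_rm_anova_matches_hand_sums_of_squares():
    v = np.array([[1.0, 2.0, 4.0], [2.0, 3.0, 5.0], [0.0, 4.0, 5.0]])
    grand = v.mean()
    ss_cond = 3 * np.sum((v.mean(0) - grand) ** 2)
    ss_subj = 3 * np.sum((v.mean(1) - grand) ** 2)
    ss_err = np.sum((v - grand) ** 2) - ss_cond - ss_subj
    F_hand = (ss_cond / 2) / (ss_err / 4)
    F, df1, df2, p = rm_anova_oneway(v)
    assert F == pytest.approx(F_hand)
    assert (df1, df2) == (2, 4)


def test_rm_anova_matches_pingouin(rng):
    """Independent cross-check against pingouin's implementation."""
    import pandas as pd
    import pingouin as pg
    v = rng.normal(size=(12, 3)) + np.array([0.0, 0.3, 0.5])
    F, df1, df2, p = rm_anova_oneway(v)
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(12), 3),
        "cond": np.tile(np.arange(3), 12),
        "y": v.ravel(),
    })
    res = pg.rm_anova(data=long, dv="y", within="cond", subject="subject")
    assert F == pytest.approx(res["F"].iloc[0], rel=1e-9)
    assert p == pytest.approx(res["p_unc"].iloc[0], rel=1e-9)
    assert (df1, df2) == (res["ddof1"].iloc[0], res["ddof2"].iloc[0])


def test_rm_anova_type_one_rate(rng):
    n_rep = 1000
    rejections = sum(
        rm_anova_oneway(rng.normal(size=(15, 3)))[3] <= 0.05
        for _ in range(n_rep))
    lo, hi = sps.binom.interval(0.95, n_rep, 0.05)
    assert lo <= rejections <= hi


def test_rm_anova_rejects_missing_cells():
    v = np.ones((3, 3))
    v[0, 0] = np.nan
    with pytest.raises(ValueError):
        rm_anova_oneway(v)
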