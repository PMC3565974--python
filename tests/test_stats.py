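"""Statistics layer: ANOVA, post-hoc, regression, power, VIF, PCA, Ward."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
import scipy.stats as sps

from discmech.stats import (Dendrogram, compute_vif, correlation_circle,
                            dunn_sidak_pairwise, fit_multilinear,
                            natural_division, one_way_anova, regression_power,
                            run_pca, vif_eliminate, ward_cluster)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_anova_identical_groups_degenerate():
    g = [np.array([5.0, 5.0, 5.0])] * 4
    f, p = one_way_anova(g)
    assert (f, p) == (0.0, 1.0)


def test_anova_perfect_separation():
    f, p = one_way_anova([np.array([0.0, 1e-6, -1e-6]),
                          np.array([10.0, 10.0 + 1e-6, 10.0 - 1e-6])])
    assert p < 1e-6


def test_anova_hand_computed_sums_of_squares():
    groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0]),
              np.array([5.0, 5.0, 8.0]), np.array([1.0, 1.0, 1.0])]
    f, p = one_way_anova(groups)
    grand = np.mean(np.concatenate(groups))
    ssb = sum(3 * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f_hand = (ssb / 3) / (ssw / 8)
    assert f == pytest.approx(f_hand, rel=1e-12)
    f_sp, p_sp = sps.f_oneway(*groups)
    assert f == pytest.approx(f_sp, rel=1e-12)
    assert p == pytest.approx(p_sp, rel=1e-12)


def test_anova_shift_and_scale_invariance():
    rng = np.random.default_rng(0)
    groups = [rng.normal(i, 1.0, 10) for i in range(4)]
    f0, _ = one_way_anova(groups)
    f_shift, _ = one_way_anova([g + 7.0 for g in groups])
    f_scale, _ = one_way_anova([g * 3.0 for g in groups])
    assert f_shift == pytest.approx(f0, rel=1e-10)
    assert f_scale == pytest.approx(f0, rel=1e-10)


# ---------------------------------------------------------------------------
# Dunn-Sidak
# ---------------------------------------------------------------------------

def test_sidak_single_comparison_unadjusted():
    rng = np.random.default_rng(1)
    out = dunn_sidak_pairwise([rng.normal(0, 1, 8), rng.normal(1, 1, 8)])
    assert out.p_adj[0] == pytest.approx(out.p_raw[0], rel=1e-12)


def test_sidak_closed_form_adjustment():
    assert 1 - 0.99**6 == pytest.approx(0.058519, abs=1e-6)
    rng = np.random.default_rng(2)
    groups = [rng.normal(i * 0.5, 1.0, 12) for i in range(4)]
    out = dunn_sidak_pairwise(groups)
    assert len(out) == 6
    for _, r in out.iterrows():
        assert r.p_adj == pytest.approx(1 - (1 - r.p_raw) ** 6, abs=1e-12)


def test_sidak_extremes_clip():
    g = [np.array([0.0, 1e-9, -1e-9]), np.array([100.0, 100.0, 100.0 + 1e-9]),
         np.array([0.0, 0.0, 1e-9])]
    out = dunn_sidak_pairwise(g)
    assert ((out.p_adj >= 0) & (out.p_adj <= 1)).all()


# ---------------------------------------------------------------------------
# regression, power, VIF
# ---------------------------------------------------------------------------

def _random_cohort(n=15, seed=3, noise=0.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 5))
    a = np.array([1.0, 0.5, -2.0, 3.0, 0.0, 1.5])
    y = a[0] + x @ a[1:] + noise * rng.normal(size=n)
    df = pd.DataFrame(x, columns=["T1_ms", "T2_ms", "MTR", "ADC", "FA"])
    df["E"] = y
    return df, a


def test_regression_noiseless_exact():
    df, a = _random_cohort()
    res = fit_multilinear(df, "E")
    assert np.allclose(res.coefficients, a, atol=1e-10)
    assert res.r2 == pytest.approx(1.0, abs=1e-12)
    assert res.see == pytest.approx(0.0, abs=1e-10)


def test_regression_equals_normal_equations_oracle():
    df, _ = _random_cohort(noise=1.0)
    res = fit_multilinear(df, "E")
    x = np.column_stack([np.ones(len(df)),
                         df[["T1_ms", "T2_ms", "MTR", "ADC", "FA"]].to_numpy()])
    y = df["E"].to_numpy()
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    assert np.max(np.abs(res.coefficients - beta)) < 1e-10
    sse = np.sum((y - x @ beta) ** 2)
    assert res.see == pytest.approx(np.sqrt(sse / (len(df) - 6)), rel=1e-10)


def test_regression_independent_response_low_r2():
    rng = np.random.default_rng(7)
    df = pd.DataFrame(rng.normal(size=(600, 5)),
                      columns=["T1_ms", "T2_ms", "MTR", "ADC", "FA"])
    df["E"] = rng.normal(size=600)
    res = fit_multilinear(df, "E")
    assert res.r2 < 0.05


def test_regression_r2_invariant_to_predictor_rescaling():
    df, _ = _random_cohort(noise=0.5)
    res0 = fit_multilinear(df, "E")
    df2 = df.copy()
    df2["T1_ms"] = df2["T1_ms"] * 1000.0 + 5.0
    res2 = fit_multilinear(df2, "E")
    assert res2.r2 == pytest.approx(res0.r2, rel=1e-10)
    # SEE carries the response units
    df3 = df.copy()
    df3["E"] = df3["E"] * 10.0
    assert fit_multilinear(df3, "E").see == pytest.approx(10 * res0.see,
                                                          rel=1e-10)


def test_power_null_case_equals_alpha():
    assert regression_power(0.0, 15, 5) == pytest.approx(0.05, abs=1e-12)


def test_power_monotone_limits():
    ps = [regression_power(r, 15, 5) for r in (0.1, 0.3, 0.6, 0.9, 0.999)]
    assert np.all(np.diff(ps) > 0)
    assert ps[-1] > 0.999
    assert regression_power(1.0, 15, 5) == 1.0


def test_power_matches_monte_carlo_oracle():
    """r2=0.70, n=15, p=5: rejection rate of 1e5 noncentral-F draws."""
    r2, n, p, alpha = 0.70, 15, 5, 0.05
    lam = n * r2 / (1 - r2)
    df1, df2 = p, n - p - 1
    rng = np.random.default_rng(42)
    m = 100_000
    draws = (rng.noncentral_chisquare(df1, lam, m) / df1) / (
        rng.chisquare(df2, m) / df2)
    crit = sps.f.isf(alpha, df1, df2)
    mc = np.mean(draws > crit)
    assert regression_power(r2, n, p, alpha) == pytest.approx(mc, abs=0.01)


def test_power_convention_switch():
    a = regression_power(0.5, 15, 5, convention="n*f2")
    b = regression_power(0.5, 15, 5, convention="(n-p-1)*f2")
    assert a > b  # smaller noncentrality multiplier, lower power


def test_vif_orthogonal_predictors_unity():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(30, 3))
    x = x - x.mean(0)
    # Gram-Schmidt on centered columns keeps them centered, so the sample
    # correlations vanish exactly
    for j in range(1, 3):
        for i in range(j):
            x[:, j] -= (x[:, j] @ x[:, i]) / (x[:, i] @ x[:, i]) * x[:, i]
    vif = compute_vif(x)
    assert all(v == pytest.approx(1.0, abs=1e-9) for v in vif.values())


def test_vif_duplicate_column_infinite():
    rng = np.random.default_rng(5)
    a = rng.normal(size=30)
    vif = compute_vif(np.column_stack([a, a, rng.normal(size=30)]))
    assert np.isinf(vif["x0"]) and np.isinf(vif["x1"])


def test_vif_two_predictor_closed_form():
    """Two predictors with sample correlation exactly 0.9: VIF = 1/(1-0.81)."""
    rng = np.random.default_rng(6)
    a = rng.normal(size=200)
    b = rng.normal(size=200)
    # orthonormalize, then mix with exact correlation 0.9
    a = (a - a.mean()) / a.std(ddof=1)
    b = b - b.mean()
    b -= (b @ a) / (a @ a) * a
    b /= b.std(ddof=1)
    y = 0.9 * a + np.sqrt(1 - 0.81) * b
    vif = compute_vif(np.column_stack([a, y]))
    assert vif["x0"] == pytest.approx(1 / (1 - 0.81), rel=1e-9)
    assert vif["x0"] == pytest.approx(5.263, abs=1e-3)


def test_vif_eliminate_collinear_t2():
    """T2 = T1 + tiny noise: one of them is removed first, R^2 barely moves."""
    rng = np.random.default_rng(8)
    n = 60
    t1 = rng.normal(1000, 100, n)
    df = pd.DataFrame({"T1_ms": t1, "T2_ms": t1 + rng.normal(0, 1.0, n),
                       "MTR": rng.normal(0.3, 0.1, n),
                       "ADC": rng.normal(1.5e-3, 1e-4, n),
                       "FA": rng.normal(0.1, 0.03, n)})
    df["E"] = 0.01 + 1e-5 * df.T1_ms + 0.05 * df.MTR + rng.normal(0, 0.01, n)
    res, trace = vif_eliminate(df, "E", threshold=10.0)
    assert trace[0]["removed"] in ("T1_ms", "T2_ms")
    assert abs(trace[0]["delta_r2"]) < 0.02
    assert max(res.vif.values()) <= 10.0


def test_vif_eliminate_identity_below_threshold():
    df, _ = _random_cohort(n=40, noise=0.5)
    res, trace = vif_eliminate(df, "E", threshold=10.0)
    assert trace == []
    assert res.predictors == ("T1_ms", "T2_ms", "MTR", "ADC", "FA")
    _, trace_inf = vif_eliminate(df, "E", threshold=np.inf)
    assert trace_inf == []


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def _pca_fixture(n=40, seed=9):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n, 3))
    x = np.column_stack([base[:, 0], base[:, 0] + 0.3 * rng.normal(size=n),
                         base[:, 1], base[:, 2],
                         base[:, 1] - base[:, 2],
                         rng.normal(size=n)])
    return x


def test_pca_equals_correlation_eigendecomposition_oracle():
    x = _pca_fixture()
    pca = run_pca(x)
    z = (x - x.mean(0)) / x.std(0, ddof=1)
    corr = np.corrcoef(z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    evals = evals[::-1]
    assert np.max(np.abs(pca.eigenvalues - evals)) < 1e-10
    # loadings match up to the fixed sign convention
    for j in range(x.shape[1]):
        v = evecs[:, ::-1][:, j]
        assert min(np.max(np.abs(pca.loadings[:, j] - v)),
                   np.max(np.abs(pca.loadings[:, j] + v))) < 1e-10


def test_pca_matches_sklearn():
    from sklearn.decomposition import PCA as SkPCA
    x = _pca_fixture(seed=10)
    z = (x - x.mean(0)) / x.std(0, ddof=1)
    sk = SkPCA(n_components=6).fit(z)
    pca = run_pca(x)
    # sklearn eigenvalues of the covariance of z equal correlation eigenvalues
    assert np.allclose(pca.eigenvalues, sk.explained_variance_, atol=1e-10)
    for j in range(6):
        v = sk.components_[j]
        assert min(np.max(np.abs(pca.loadings[:, j] - v)),
                   np.max(np.abs(pca.loadings[:, j] + v))) < 1e-8


def test_pca_reconstruction_and_spectrum_sum():
    x = _pca_fixture(seed=11)
    pca = run_pca(x)
    z = (x - x.mean(0)) / x.std(0, ddof=1)
    assert np.max(np.abs(pca.scores @ pca.loadings.T - z)) < 1e-10
    assert pca.eigenvalues.sum() == pytest.approx(x.shape[1], rel=1e-12)
    cov = np.cov(pca.scores, rowvar=False)
    assert np.max(np.abs(cov - np.diag(np.diag(cov)))) < 1e-10


def test_pca_duplicate_column_block_eigenvalue():
    rng = np.random.default_rng(12)
    a = rng.normal(size=50)
    x = np.column_stack([a, a + 1e-9 * rng.normal(size=50),
                         rng.normal(size=(50, 4))])
    pca = run_pca(x)
    assert pca.eigenvalues[0] >= 2.0 - 1e-6


def test_pca_uncorrelated_unit_eigenvalues():
    rng = np.random.default_rng(13)
    pca = run_pca(rng.normal(size=(20000, 6)))
    assert np.allclose(pca.eigenvalues, 1.0, atol=0.05)
    assert pca.cumulative_variability[2] == pytest.approx(0.5, abs=0.02)


def test_pca_constant_column_rejected():
    x = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.raises(ValueError, match="constant"):
        run_pca(pd.DataFrame(x, columns=["c", "v"]))


def test_correlation_circle_is_variable_score_correlation():
    x = _pca_fixture(seed=14)
    pca = run_pca(x)
    cc = correlation_circle(pca)
    z = (x - x.mean(0)) / x.std(0, ddof=1)
    for vi, var in enumerate(pca.variables):
        for k in range(2):
            r = np.corrcoef(z[:, vi], pca.scores[:, k])[0, 1]
            assert cc.iloc[vi, k] == pytest.approx(r, abs=1e-10)
    assert (cc.to_numpy() ** 2).sum(axis=1).max() <= 1.0 + 1e-12


def test_correlation_circle_aligned_variable():
    rng = np.random.default_rng(15)
    a = rng.normal(size=300)
    x = np.column_stack([a, a + 1e-6 * rng.normal(size=300),
                         a - 1e-6 * rng.normal(size=300)])
    cc = correlation_circle(run_pca(x))
    assert abs(cc.iloc[0, 0]) == pytest.approx(1.0, abs=1e-3)
    assert cc.iloc[0, 1] == pytest.approx(0.0, abs=1e-2)


# ---------------------------------------------------------------------------
# Ward clustering and natural division
# ---------------------------------------------------------------------------

def test_ward_three_point_line_hand_computed():
    """(0), (1), (10): merge {0,1} at ESS increment 0.5, then at
    2/3 * (10 - 0.5)^2 = 60.1667."""
    d = ward_cluster(np.array([[0.0], [1.0], [10.0]]))
    (i, j, h1, _), (_, _, h2, _) = d.merges
    assert {i, j} == {0, 1}
    assert h1 == pytest.approx(0.5, rel=1e-12)
    assert h2 == pytest.approx(2.0 / 3.0 * 9.5**2, rel=1e-12)
    assert h2 == pytest.approx(60.1667, abs=1e-3)


def test_ward_heights_monotone_and_sum_to_tss():
    rng = np.random.default_rng(16)
    x = rng.normal(size=(40, 3))
    d = ward_cluster(x)
    h = d.heights
    assert np.all(np.diff(h) >= -1e-12)
    tss = np.sum((x - x.mean(0)) ** 2)
    assert h.sum() == pytest.approx(tss, abs=1e-8)


def test_ward_matches_scipy_linkage():
    """scipy's ward heights are sqrt(2 * ESS increment); topologies agree."""
    rng = np.random.default_rng(17)
    x = rng.normal(size=(25, 3))
    ours = ward_cluster(x)
    sp = sch.linkage(x, method="ward")
    assert np.allclose(np.sort(ours.heights), np.sort(sp[:, 2] ** 2 / 2),
                       rtol=1e-8)
    for k in (2, 3, 5):
        a = ours.cut(k)
        b = sch.fcluster(sp, k, criterion="maxclust")
        # same partition up to label permutation
        assert len({(x_, y_) for x_, y_ in zip(a, b)}) == k


def test_ward_two_blobs_dominant_final_merge():
    rng = np.random.default_rng(18)
    x = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(8, 0.1, (10, 2))])
    d = ward_cluster(x)
    h = d.heights
    assert h[-1] > 50 * h[-2]


def test_natural_division_dominant_gap():
    merges = [(0, 1, 1.0, 5), (5, 2, 1.1, 6), (6, 3, 1.2, 7),
              (7, 4, 10.0, 8)]
    d = Dendrogram(merges=merges, n_leaves=5)
    out = natural_division(d)
    assert out["k"] == 2


def test_natural_division_four_separated_groups():
    rng = np.random.default_rng(19)
    centers = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]])
    x = np.vstack([c + rng.normal(0, 0.3, (12, 3)) for c in centers])
    d = ward_cluster(x)
    out = natural_division(d)
    assert out["k"] == 4
    labels = np.repeat(np.arange(4), 12)
    assert len({(a, b) for a, b in zip(out["assignments"], labels)}) == 4


def test_natural_division_uniform_chain_flagged():
    merges = [(0, 1, 1.0, 4), (4, 2, 1.0, 5), (5, 3, 1.0, 6)]
    d = Dendrogram(merges=merges, n_leaves=4)
    out = natural_division(d)
    assert out["k"] == 1
    assert out["flag"] == "all heights equal"


def test_dendrogram_newick_parses_with_skbio():
    import io as _io
    from skbio import TreeNode
    rng = np.random.default_rng(20)
    d = ward_cluster(rng.normal(size=(8, 2)),
                     leaf_labels=tuple(f"s{i}" for i in range(8)))
    tree = TreeNode.read(_io.StringIO(d.to_newick()))
    assert {t.name for t in tree.tips()} == {f"s{i}" for i in range(8)}
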