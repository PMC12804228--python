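"""Statistical layer: PCA, concentration ellipsoids, Tukey-Kramer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import skintrib as sk
from skintrib.stats import variance_percentages


class TestPCA:
    def test_collinear_data_one_component(self):
        t = np.linspace(0, 1, 20)
        X = np.column_stack([t, 2 * t, -t])
        model = sk.run_pca(X)
        assert model.variance_pct[0] == pytest.approx(100.0)
        assert np.allclose(model.variance_pct[1:], 0.0, atol=1e-10)

    def test_variance_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        model = sk.run_pca(rng.normal(size=(30, 5)))
        assert model.variance_pct.sum() == pytest.approx(100.0)
        assert model.cumulative_pct[-1] == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(model.cumulative_pct) >= -1e-12)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_loadings_orthonormal_and_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6))
        for mode in ("covariance", "correlation"):
            model = sk.run_pca(X, mode=mode)
            V = model.loadings.to_numpy()
            assert np.allclose(V.T @ V, np.eye(6), atol=1e-8)
            assert np.allclose(model.reconstruct(), X, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 4))
        a = sk.run_pca(X)
        b = sk.run_pca(X.copy())
        assert np.array_equal(a.loadings.to_numpy(), b.loadings.to_numpy())
        for col in a.loadings.columns:
            v = a.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_agrees_with_independent_implementation(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 6)) @ np.diag([3, 2, 1, 1, 0.5, 0.2])
        mine = sk.run_pca(X, mode="covariance")
        ref = sklearn_pca(n_components=6).fit(X)
        assert np.allclose(mine.eigenvalues, ref.explained_variance_, rtol=1e-8)
        for j in range(6):  # components agree up to sign
            cos = abs(ref.components_[j] @ mine.loadings.to_numpy()[:, j])
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_constant_variable_named_in_correlation_mode(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5], "c": [0.0, 1, 0]})
        with pytest.raises(sk.ValidationError, match="b"):
            sk.run_pca(X, mode="correlation")

    def test_published_variance_table_consistency(self):
        """A six-component sensory-PCA variance table (reference fixture)
        satisfies variance% = 100*eigenvalue/sum at printed precision."""
        eigenvalues = [23.4764, 12.2912, 12.1340, 6.1666, 2.6346, 1.7059]
        printed_pct = [40.19, 21.04, 20.77, 10.56, 4.51, 2.92]
        printed_cum = [40.19, 61.24, 82.01, 92.57, 97.08, 100.00]
        pct, cum = variance_percentages(eigenvalues)
        assert np.allclose(pct, printed_pct, atol=0.005)
        assert np.allclose(cum, printed_cum, atol=0.015)
        assert cum[2] == pytest.approx(82.01, abs=0.005)


class TestEllipsoid:
    def test_isotropic_radii_match_chi_square(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(20_000, 3))
        e = sk.concentration_ellipsoid(pts, level=0.95, dims=3)
        expected = np.sqrt(sps.chi2.ppf(0.95, 3))
        assert np.allclose(e.radii, expected, rtol=0.05)
        assert not e.degenerate

    def test_identical_points_degenerate(self):
        pts = np.ones((10, 3))
        e = sk.concentration_ellipsoid(pts)
        assert e.degenerate
        assert np.allclose(e.radii, 0.0)

    def test_few_points_flagged(self):
        e = sk.concentration_ellipsoid(np.random.default_rng(0).normal(size=(3, 3)))
        assert e.degenerate

    def test_mean_region_smaller_than_data_ellipse(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(200, 3))
        data = sk.concentration_ellipsoid(pts, scaling="chi2")
        mean = sk.concentration_ellipsoid(pts, scaling="f")
        assert np.all(mean.radii < data.radii)

    def test_two_points_minimum(self):
        with pytest.raises(sk.ValidationError):
            sk.concentration_ellipsoid(np.array([[1.0, 2, 3]]))


class TestTukeyKramer:
    def test_identical_groups_not_significant(self):
        g = {"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]}
        out = sk.tukey_kramer(g)
        row = out.pair("a", "b")
        assert row.q == 0.0
        assert row.p == pytest.approx(1.0)
        assert not row.significant

    def test_separated_means_detected(self):
        rng = np.random.default_rng(8)
        sd = 1.0
        g = {
            "a": rng.normal(0, sd, 30),
            "b": rng.normal(0, sd, 30),
            "c": rng.normal(10 * sd, sd, 30),
        }
        out = sk.tukey_kramer(g)
        assert out.pair("a", "c").significant
        assert out.pair("b", "c").significant
        assert not out.pair("a", "b").significant

    def test_equal_n_reduces_to_hsd(self):
        """Unequal-n standard error reduces to MSE/n for equal groups."""
        rng = np.random.default_rng(9)
        g = {k: rng.normal(loc, 1.0, 12) for k, loc in
             zip("abcd", (0.0, 0.5, 1.0, 2.0))}
        out = sk.tukey_kramer(g)
        vals = list(g.values())
        mse = np.mean([np.var(v, ddof=1) for v in vals])
        for i, a in enumerate("abcd"):
            for b in "abcd"[i + 1:]:
                q_oracle = abs(g[a].mean() - g[b].mean()) / np.sqrt(mse / 12)
                assert out.pair(a, b).q == pytest.approx(q_oracle, abs=1e-8)

    def test_p_values_match_independent_implementation(self):
        rng = np.random.default_rng(10)
        samples = [rng.normal(loc, 1.0, 15) for loc in (0.0, 0.6, 1.5)]
        mine = sk.tukey_kramer(dict(zip("abc", samples)))
        ref = sps.tukey_hsd(*samples)
        for (i, a), (j, b) in [((0, "a"), (1, "b")), ((0, "a"), (2, "c")),
                               ((1, "b"), (2, "c"))]:
            assert mine.pair(a, b).p == pytest.approx(ref.pvalue[i, j],
                                                      abs=1e-6)

    def test_zero_variance_distinct_means_floor_p(self):
        g = {"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]}
        out = sk.tukey_kramer(g)
        row = out.pair("a", "b")
        assert row.significant
        assert row.p <= 1e-300

    def test_degenerate_group_rejected(self):
        with pytest.raises(sk.ValidationError):
            sk.tukey_kramer({"a": [1.0], "b": [1.0, 2.0]})

    def test_null_rejection_rate_near_alpha(self):
        rate = sk.family_wise_error_rate(k=6, n=12, n_replicates=400, seed=12)
        assert 0.02 <= rate <= 0.10


def _planted_tables(seed=13, n_obs=24):
    """Tribology + sensory tables with planted anti-correlation between
    AE RMS and pleasantness."""
    rng = np.random.default_rng(seed)
    idx = pd.MultiIndex.from_product(
        [[f"m{i}" for i in range(4)], [f"P{j}" for j in range(n_obs // 4)]],
        names=["material", "participant"],
    )
    base = rng.normal(size=len(idx))
    trib = pd.DataFrame(
        {
            "static_cof": 0.6 + 0.2 * base + 0.02 * rng.normal(size=len(idx)),
            "dynamic_cof": 0.4 + 0.15 * base + 0.02 * rng.normal(size=len(idx)),
            "static_rms": 1.0 - 0.3 * base + 0.03 * rng.normal(size=len(idx)),
            "dynamic_rms": 0.8 - 0.25 * base + 0.03 * rng.normal(size=len(idx)),
        },
        index=idx,
    )
    sens = pd.DataFrame(
        {a: 5 + rng.normal(size=len(idx)) for a in sk.ATTRIBUTES}, index=idx
    )
    sens["pleasant"] = 5 + 2.0 * base  # anti-correlated with the RMS columns
    return trib, sens


class TestCombinedPCA:
    def test_planted_anticorrelation_recovered(self):
        trib, sens = _planted_tables()
        model, overlays = sk.combined_pca(trib, sens)
        scores = model.scores
        r_rms = np.corrcoef(trib["dynamic_rms"], scores[:, 0])[0, 1]
        r_pleasant = overlays.loc["pleasant", "PC1"]
        assert np.sign(r_pleasant) == -np.sign(r_rms)
        assert abs(r_pleasant) > 0.8

    def test_overlay_aligns_with_matching_active_variable(self):
        """A sensory attribute equal to an active variable points along
        that variable's biplot arrow (loading scaled by sqrt(eigenvalue),
        i.e. its correlation with each component)."""
        trib, sens = _planted_tables()
        sens = sens.copy()
        sens["pleasant"] = trib["dynamic_rms"]  # attribute == active variable
        model, overlays = sk.combined_pca(trib, sens)
        arrow = (model.loadings.loc["dynamic_rms"].to_numpy()
                 * np.sqrt(model.eigenvalues))
        overlay_dir = overlays.loc["pleasant"].to_numpy()
        cos = (arrow @ overlay_dir) / (
            np.linalg.norm(arrow) * np.linalg.norm(overlay_dir))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_row_permutation_invariance(self):
        trib, sens = _planted_tables()
        perm = np.random.default_rng(14).permutation(len(trib))
        m1, o1 = sk.combined_pca(trib, sens)
        m2, o2 = sk.combined_pca(trib.iloc[perm], sens)
        assert np.allclose(m1.eigenvalues, m2.eigenvalues)
        pd.testing.assert_frame_equal(o1, o2)

    def test_key_mismatch_listed(self):
        trib, sens = _planted_tables()
        with pytest.raises(sk.ValidationError, match="mismatch"):
            sk.combined_pca(trib.iloc[:-2], sens)


class TestCorrelationSigns:
    def test_self_and_negated_pairs(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        df["neg"] = -df["x"]
        out = sk.correlation_signs(df, [("x", "x"), ("x", "neg")])
        assert out.r.iloc[0] == pytest.approx(1.0)
        assert out.r.iloc[1] == pytest.approx(-1.0)
        assert list(out.label) == ["positive", "negative"]

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(16)
        n = 200
        x = rng.normal(size=n)
        y = 0.8 * x + np.sqrt(1 - 0.8**2) * rng.normal(size=n)
        out = sk.correlation_signs(pd.DataFrame({"x": x, "y": y}), [("x", "y")])
        assert out.r.iloc[0] == pytest.approx(0.8, abs=0.1)

    def test_unknown_variable_rejected(self):
        with pytest.raises(sk.ParameterError):
            sk.correlation_signs(pd.DataFrame({"x": [1.0, 2]}), [("x", "zz")])
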