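import numpy as np
import pandas as pd
import pytest

import amide3 as a
from amide3.multivariate import SpectralMatrix, elbow_retain


def random_matrix(rng, n=8, p=5):
    X = rng.standard_normal((n, p))
    values = pd.DataFrame(X, index=[f"s{i}" for i in range(n)], columns=np.arange(p, dtype=float))
    return SpectralMatrix(values=values, factors=pd.DataFrame(index=values.index))


@pytest.fixture(scope="module")
def small_cohort():
    """Noiseless low-rank cohort: one dominant spectral contrast."""
    cfg = a.SyntheticConfig(seed=17, n_portions=3, noise_sd=0.0, portion_scale_sd=0.02,
                            baseline_coeffs=(0.0,))
    spectra, factors = a.generate_cohort(config=cfg)
    return spectra, factors


class TestBuildMatrix:
    def test_portion_averaging_row_counts(self, small_cohort):
        spectra, factors = small_cohort
        m_avg = a.build_matrix(spectra, factors=factors)
        m_all = a.build_matrix(spectra, factors=factors, average_portions=False)
        assert m_avg.n_samples == 17
        assert m_all.n_samples == 17 * 3
        assert m_all.factors.shape[0] == 17 * 3

    def test_band_column_count(self, small_cohort):
        spectra, factors = small_cohort
        m = a.build_matrix(spectra, band=(1185.0, 1330.0), factors=factors)
        assert m.values.shape[1] == 291  # 145 cm^-1 at 0.5 cm^-1 step

    def test_inconsistent_grids_rejected(self):
        s1 = a.spectrum_from_table("FYHHH")
        s2 = a.spectrum_from_table("FYHHH", grid=(1185.0, 1330.0, 1.0))
        with pytest.raises(ValueError, match="common grid"):
            a.build_matrix([s1, s2])


class TestRunPCA:
    def test_two_correlated_variables(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        values = pd.DataFrame({0.0: x, 1.0: 2.0 * x + 1.0})
        values.index = [f"s{i}" for i in range(30)]
        pca = a.run_pca(SpectralMatrix(values, pd.DataFrame(index=values.index)))
        assert pca.eigenvalues[0] == pytest.approx(2.0, rel=1e-9)
        assert pca.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)

    def test_svd_identities(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, n=5, p=4)
        pca = a.run_pca(m, scale_unit=False)
        assert pca.explained_pct.sum() == pytest.approx(100.0)
        gram = pca.scores.to_numpy().T @ pca.scores.to_numpy()
        np.testing.assert_allclose(
            np.diag(gram), pca.eigenvalues * (5 - 1), atol=1e-10
        )
        assert np.abs(pca.scores.to_numpy().mean(axis=0)).max() < 1e-10

    def test_eigenvalues_sorted_nonnegative(self):
        pca = a.run_pca(random_matrix(np.random.default_rng(2), 10, 6))
        assert np.all(np.diff(pca.eigenvalues) <= 1e-12)
        assert np.all(pca.eigenvalues >= -1e-12)

    def test_reconstruction_identity(self):
        """Full-rank scores x loadings recovers the data matrix."""
        rng = np.random.default_rng(3)
        m = random_matrix(rng, n=6, p=4)
        for scale in (False, True):
            pca = a.run_pca(m, scale_unit=scale)
            X_hat = (
                pca.scores.to_numpy() @ pca.loadings.to_numpy().T
            ) * pca.column_scales + pca.column_means
            np.testing.assert_allclose(X_hat, m.values.to_numpy(), atol=1e-8)

    def test_matches_sklearn_pca(self):
        """Eigenvalues and explained variance agree with an independent PCA
        implementation on the same centered matrix."""
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(13)
        m = random_matrix(rng, n=12, p=6)
        ours = a.run_pca(m, scale_unit=False)
        ref = SkPCA().fit(m.values.to_numpy())
        np.testing.assert_allclose(ours.eigenvalues, ref.explained_variance_, rtol=1e-10)
        np.testing.assert_allclose(
            ours.explained_pct, 100 * ref.explained_variance_ratio_, rtol=1e-10
        )
        # scores agree up to per-component sign
        sk_scores = ref.transform(m.values.to_numpy())
        for j in range(6):
            col = ours.scores.to_numpy()[:, j]
            assert (
                np.allclose(col, sk_scores[:, j], atol=1e-8)
                or np.allclose(col, -sk_scores[:, j], atol=1e-8)
            )

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.standard_normal((6, 3)), columns=[0.0, 1.0, 2.0])
        values[2.0] = 5.0
        values.index = [f"s{i}" for i in range(6)]
        m = SpectralMatrix(values, pd.DataFrame(index=values.index))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            pca = a.run_pca(m, scale_unit=True)
        assert pca.loadings.shape[0] == 2

    def test_dominant_factor_concentrates_variance(self):
        """Spectra differing through two structured contrasts (overall
        intensity and one component's content) load >90% of the variance on
        the first two PCs."""
        rng = np.random.default_rng(12)
        from amide3.synth import model_sum

        base = a.SyntheticConfig().components
        nu = a.SyntheticConfig().wavenumbers()
        clean = model_sum(base, nu)
        v = next(c for c in base if c.index == "V")
        v_profile = a.gaussian_profile(v, nu) / v.area
        spectra = []
        for i in range(20):
            scale = 1.0 + 0.1 * rng.standard_normal()
            shift = 5.0 * rng.standard_normal()
            y = scale * clean + shift * v_profile
            y = y + 0.001 * clean.max() * rng.standard_normal(nu.size)
            spectra.append(a.Spectrum(nu, y, sample_id=f"s{i}", portion_id=0))
        m = a.build_matrix(spectra)
        pca = a.run_pca(m, scale_unit=False)
        assert pca.cumulative_pct[1] > 90.0


class TestKaiser:
    def test_counts_only_eigenvalues_above_one(self):
        assert a.kaiser_retain(np.array([2.1, 0.9, 0.5])) == 1
        assert a.kaiser_retain(np.array([2.1, 1.4, 0.5])) == 2

    def test_all_below_one_warns(self):
        with pytest.warns(RuntimeWarning, match="scree elbow"):
            assert a.kaiser_retain(np.array([0.8, 0.6])) == 0

    def test_covariance_eigenvalues_warn(self):
        with pytest.warns(RuntimeWarning, match="correlation"):
            a.kaiser_retain(np.array([3.0, 0.2]), scale_unit=False)

    def test_equal_variance_null_expectation(self):
        """For i.i.d. unit-variance variables roughly half the correlation
        eigenvalues exceed 1."""
        rng = np.random.default_rng(5)
        counts = []
        for _ in range(30):
            m = random_matrix(rng, n=60, p=10)
            pca = a.run_pca(m, scale_unit=True)
            counts.append(a.kaiser_retain(pca.eigenvalues))
        assert 3.0 <= np.mean(counts) <= 7.0

    def test_elbow(self):
        assert elbow_retain(np.array([70.0, 25.0, 3.0, 2.0])) == 2


class TestDescribeDimension:
    def test_perfect_separation_r2_one(self):
        scores = pd.DataFrame({"PC1": [-1.0, -1.0, 1.0, 1.0]}, index=list("abcd"))
        pca = _pca_stub(scores)
        factors = pd.DataFrame({"g": ["x", "x", "y", "y"]}, index=list("abcd"))
        assoc = a.describe_dimension(pca, factors, n_pcs=1)
        row = assoc.anova.iloc[0]
        assert row["R2"] == pytest.approx(1.0)
        assert row["p"] < 1e-6 or row["F"] == np.inf

    def test_r2_matches_brute_force_correlation_ratio(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(30)
        labels = rng.choice(["a", "b", "c"], size=30)
        scores = pd.DataFrame({"PC1": y}, index=[f"s{i}" for i in range(30)])
        factors = pd.DataFrame({"g": labels}, index=scores.index)
        assoc = a.describe_dimension(_pca_stub(scores), factors, n_pcs=1)
        # brute-force correlation ratio: SS_between / SS_total over group means
        grand = y.mean()
        ssb = sum(
            (y[labels == lv].size) * (y[labels == lv].mean() - grand) ** 2
            for lv in np.unique(labels)
        )
        sst = np.sum((y - grand) ** 2)
        assert assoc.anova.iloc[0]["R2"] == pytest.approx(ssb / sst, rel=1e-12)

    def test_null_r2_small(self):
        rng = np.random.default_rng(7)
        n = 400
        scores = pd.DataFrame({"PC1": rng.standard_normal(n)},
                              index=[f"s{i}" for i in range(n)])
        factors = pd.DataFrame({"g": rng.choice(["a", "b"], size=n)}, index=scores.index)
        assoc = a.describe_dimension(_pca_stub(scores), factors, n_pcs=1)
        assert assoc.anova.iloc[0]["R2"] < 0.03

    def test_level_estimates_weighted_sum_zero(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(20)
        labels = np.array(["a"] * 12 + ["b"] * 7 + ["c"])
        scores = pd.DataFrame({"PC1": y}, index=[f"s{i}" for i in range(20)])
        factors = pd.DataFrame({"g": labels}, index=scores.index)
        assoc = a.describe_dimension(_pca_stub(scores), factors, n_pcs=1)
        lv = assoc.levels
        weighted = (lv["estimate"] * lv["n"]).sum()
        assert weighted == pytest.approx(0.0, abs=1e-10)

    def test_singleton_level_gets_p_value(self):
        """A factor level observed once still yields a contrast t-test."""
        rng = np.random.default_rng(9)
        y = np.concatenate([rng.standard_normal(10), [8.0]])
        labels = np.array(["h"] * 10 + ["m"])
        scores = pd.DataFrame({"PC1": y}, index=[f"s{i}" for i in range(11)])
        factors = pd.DataFrame({"g": labels}, index=scores.index)
        assoc = a.describe_dimension(_pca_stub(scores), factors, n_pcs=1)
        row = assoc.levels[assoc.levels["level"] == "m"].iloc[0]
        assert row["n"] == 1
        assert np.isfinite(row["t"]) and 0.0 <= row["p"] <= 1.0
        assert row["p"] < 0.05  # the outlier level separates

    def test_single_level_factor_skipped(self):
        scores = pd.DataFrame({"PC1": [0.0, 1.0, 2.0]}, index=list("abc"))
        factors = pd.DataFrame({"g": ["x", "x", "x"]}, index=list("abc"))
        with pytest.warns(RuntimeWarning, match="single level"):
            assoc = a.describe_dimension(_pca_stub(scores), factors, n_pcs=1)
        assert assoc.anova.empty


class TestVTest:
    def test_hand_computed_example(self):
        """values (1,2,3,4), level {3,4}: v = 1 / sqrt(0.625 * 2/3) = 1.549."""
        values = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array(["o", "o", "l", "l"])
        out = a.v_test(values, labels)
        assert out.loc["l", "v"] == pytest.approx(1.549, abs=1e-3)
        assert out.loc["o", "v"] == pytest.approx(-1.549, abs=1e-3)

    def test_whole_sample_level_zero(self):
        values = np.array([1.0, 2.0, 5.0])
        out = a.v_test(values, np.array(["x", "x", "x"]))
        assert out.loc["x", "v"] == 0.0
        assert out.loc["x", "p"] == 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            a.v_test(np.ones(5), np.array(list("aabbb")))

    def test_sign_tracks_direction(self):
        values = np.array([0.0, 0.0, 10.0, 10.0, 10.0, 0.0])
        labels = np.array(["lo", "lo", "hi", "hi", "hi", "lo"])
        out = a.v_test(values, labels)
        assert out.loc["hi", "v"] > 0 > out.loc["lo", "v"]

    def test_matches_permutation_z_score(self):
        """The closed form agrees with a permutation z-score of the level
        mean for moderate n."""
        rng = np.random.default_rng(10)
        values = rng.standard_normal(40)
        labels = np.array(["a"] * 25 + ["b"] * 15)
        out = a.v_test(values, labels)
        sel = labels == "b"
        obs = values[sel].mean()
        perm = np.array([
            rng.permutation(values)[: sel.sum()].mean() for _ in range(4000)
        ])
        z = (obs - perm.mean()) / perm.std()
        assert np.sign(z) == np.sign(out.loc["b", "v"])
        assert abs(z - out.loc["b", "v"]) < 0.35


class TestLevelDistances:
    def test_three_four_five_triangle(self):
        scores = pd.DataFrame({"PC1": [0.0, 3.0], "PC2": [0.0, 4.0]}, index=["s0", "s1"])
        factors = pd.DataFrame({"g": ["a", "b"]}, index=["s0", "s1"])
        table = a.level_distances(_pca_stub(scores), factors, n_pcs=2)
        assert table.between["g"].loc["a", "b"] == pytest.approx(5.0)
        # after centering both singleton levels sit 2.5 from the center
        assert table.to_center["g"]["a"] == pytest.approx(2.5)
        assert table.to_center["g"]["b"] == pytest.approx(2.5)

    def test_metric_properties(self):
        rng = np.random.default_rng(11)
        n = 24
        scores = pd.DataFrame(
            rng.standard_normal((n, 3)), columns=["PC1", "PC2", "PC3"],
            index=[f"s{i}" for i in range(n)],
        )
        factors = pd.DataFrame({"g": rng.choice(list("abcd"), size=n)}, index=scores.index)
        table = a.level_distances(_pca_stub(scores), factors, n_pcs=3)
        D = table.between["g"].to_numpy()
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        assert np.all(np.diag(D) == 0)
        k = D.shape[0]
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    assert D[i, j] <= D[i, l] + D[l, j] + 1e-9

    def test_n_pcs_bound(self):
        scores = pd.DataFrame({"PC1": [0.0, 1.0]}, index=["s0", "s1"])
        factors = pd.DataFrame({"g": ["a", "b"]}, index=scores.index)
        with pytest.raises(ValueError, match="exceeds"):
            a.level_distances(_pca_stub(scores), factors, n_pcs=3)


def _pca_stub(scores: pd.DataFrame) -> a.PCAResult:
    """PCAResult wrapper around externally supplied scores (centered)."""
    centered = scores - scores.mean(axis=0)
    n, k = centered.shape
    ev = (centered**2).sum(axis=0).to_numpy() / max(n - 1, 1)
    return a.PCAResult(
        eigenvalues=ev,
        explained_pct=100 * ev / ev.sum(),
        cumulative_pct=np.cumsum(100 * ev / ev.sum()),
        scores=centered,
        loadings=pd.DataFrame(np.eye(k), columns=centered.columns),
        scaled=False,
        column_means=np.zeros(k),
        column_scales=np.ones(k),
    )
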