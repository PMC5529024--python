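"""Kinship, EMMA REML vs dense brute force, mixed-model scan, ROI rules."""

import numpy as np
import pandas as pd
import pytest
from numpy.linalg import inv, slogdet, solve

from toxqtl import (
    GenotypeMatrix,
    QTLSpec,
    calibrate_roi_width,
    compute_kinship,
    define_roi,
    emma_reml,
    gwa_scan,
    simulate_phenotypes,
    simulate_wild_panel,
)
from toxqtl.gwa_mapping import GwaResult


def _tiny_panel(calls, chrom="I"):
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    markers = pd.DataFrame(
        {
            "marker": [f"m{j}" for j in range(m)],
            "chrom": chrom,
            "pos_bp": (np.arange(m) + 1) * 100,
            "cM": np.arange(m, dtype=float),
        }
    )
    return GenotypeMatrix(
        strains=[f"s{i}" for i in range(n)], markers=markers, calls=calls
    )


def dense_reml_loglik(y, X, K, delta):
    """Independent dense-matrix evaluation of the Harville REML criterion."""
    n, q = X.shape
    H = K + delta * np.eye(n)
    Hi = inv(H)
    XtHiX = X.T @ Hi @ X
    beta = solve(XtHiX, X.T @ Hi @ y)
    r = y - X @ beta
    s2 = (r @ Hi @ r) / (n - q)
    return -0.5 * (
        (n - q) * (np.log(2 * np.pi * s2) + 1)
        + slogdet(H)[1]
        + slogdet(XtHiX)[1]
        - slogdet(X.T @ X)[1]
    )


def brute_force_reml(y, X, K, n_coarse=2001, n_fine=20001):
    """Dense grid maximization over log10(delta) in [-5, 5]."""
    coarse = np.linspace(-5, 5, n_coarse)
    lls = np.array([dense_reml_loglik(y, X, K, 10.0**g) for g in coarse])
    i = int(np.argmax(lls))
    fine = np.linspace(coarse[max(i - 1, 0)], coarse[min(i + 1, n_coarse - 1)], n_fine)
    lls_fine = np.array([dense_reml_loglik(y, X, K, 10.0**g) for g in fine])
    j = int(np.argmax(lls_fine))
    return 10.0 ** fine[j], float(lls_fine[j])


class TestKinship:
    def test_clones_share_diagonal_value(self):
        calls = np.array([[0, 1, 0, 1, 1], [0, 1, 0, 1, 1], [1, 0, 1, 0, 0]])
        K = compute_kinship(_tiny_panel(calls)).to_numpy()
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)
        assert K[0, 1] == pytest.approx(K[1, 1], abs=1e-12)

    def test_hand_computed_three_by_four(self):
        """3 strains x 4 markers: entries match the explicit normalized
        cross-product computed element by element."""
        calls = np.array(
            [[0.0, 1.0, 1.0, 0.0], [1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]]
        )
        K = compute_kinship(_tiny_panel(calls)).to_numpy()
        p = calls.mean(axis=0)
        x = 2 * calls - 1
        xc = x - (2 * p - 1)
        expected = xc @ xc.T / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(K, expected, atol=1e-12)
        np.testing.assert_allclose(K, K.T, atol=1e-12)

    def test_unrelated_strains_off_diagonal_shrinks(self):
        """Independent strains: off-diagonals approach the in-sample
        centering floor of -diag/(n-1) and are small for a large panel."""
        rng = np.random.default_rng(1)
        n = 50
        calls = rng.integers(0, 2, size=(n, 10_000)).astype(float)
        K = compute_kinship(_tiny_panel(calls)).to_numpy()
        off = K[~np.eye(n, dtype=bool)]
        assert np.abs(off).max() < 0.12
        assert off.mean() == pytest.approx(-K.trace() / n / (n - 1), abs=0.01)

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 2, size=(8, 50)).astype(float)
        K1 = compute_kinship(_tiny_panel(calls)).to_numpy()
        K2 = compute_kinship(_tiny_panel(1.0 - calls)).to_numpy()
        np.testing.assert_allclose(K1, K2, atol=1e-10)

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError, match="polymorphic"):
            compute_kinship(_tiny_panel(np.zeros((3, 4))))


class TestEmmaReml:
    def test_identity_kinship_aliasing_recovers_total_variance(self):
        """With K = I only sigma2_g + sigma2_e is identifiable and equals the
        sample residual variance."""
        rng = np.random.default_rng(3)
        n = 40
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        vc = emma_reml(y, X, np.eye(n))
        total = vc.sigma2_g * (1 + vc.delta)
        assert total == pytest.approx(np.var(y, ddof=1), rel=1e-6)

    def test_matches_brute_force_on_toy_instances(self):
        """Eigendecomposition path equals dense-matrix REML on n <= 12."""
        rng = np.random.default_rng(4)
        for n in (6, 9, 12):
            A = rng.normal(size=(n, 2 * n))
            K = A @ A.T / (2 * n)
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = K @ rng.normal(size=n) + rng.normal(size=n)
            vc = emma_reml(y, X, K)
            _, ll_bf = brute_force_reml(y, X, K)
            assert vc.reml_loglik == pytest.approx(ll_bf, abs=1e-6)
            # grid evaluations never exceed the returned optimum
            for g in np.linspace(-5, 5, 101):
                assert dense_reml_loglik(y, X, K, 10.0**g) <= vc.reml_loglik + 1e-9

    def test_parameter_recovery_on_structured_kinship(self):
        """sigma2_g=2, sigma2_e=1, n=300: median estimates within 25%."""
        rng = np.random.default_rng(5)
        n = 300
        A = rng.normal(size=(n, 150))
        K = A @ A.T / 150
        L = np.linalg.cholesky(K + 1e-9 * np.eye(n))
        est_g, est_e = [], []
        for _ in range(30):
            y = np.sqrt(2.0) * (L @ rng.normal(size=n)) + rng.normal(size=n)
            vc = emma_reml(y, np.ones((n, 1)), K)
            est_g.append(vc.sigma2_g)
            est_e.append(vc.sigma2_e)
        assert abs(np.median(est_g) - 2.0) / 2.0 < 0.25
        assert abs(np.median(est_e) - 1.0) / 1.0 < 0.25

    def test_constant_trait_flagged(self):
        vc = emma_reml(np.ones(10), np.ones((10, 1)), np.eye(10))
        assert vc.constant_trait and vc.sigma2_g == 0.0

    def test_non_psd_kinship_rejected(self):
        K = np.eye(5)
        K[0, 0] = -1.0
        with pytest.raises(ValueError, match="PSD"):
            emma_reml(np.arange(5.0), np.ones((5, 1)), K)


class TestGwaScan:
    def test_maf_filter_excludes_rare_marker(self):
        rng = np.random.default_rng(6)
        n = 50
        calls = rng.integers(0, 2, size=(n, 20)).astype(float)
        calls[:, 0] = 0.0
        calls[:2, 0] = 1.0  # MAF 0.04
        panel = _tiny_panel(calls)
        y = pd.Series(rng.normal(size=n), index=panel.strains)
        res = gwa_scan(panel, y, min_maf=0.05)
        assert "m0" not in set(res.markers["marker"])

    def test_null_pvalues_calibrated(self, marker_map):
        """No QTL, structured panel: mixed-model p-values are uniform
        (median-chi2 inflation factor ~= 1)."""
        rng = np.random.default_rng(7)
        from scipy import stats as sps

        lambdas = []
        for rep in range(10):
            panel = simulate_wild_panel(
                80, marker_map, 3, 0.2, seed=100 + rep
            )
            y = simulate_phenotypes(panel, [], polygenic_h2=0.5, seed=200 + rep)
            res = gwa_scan(panel, y)
            p = 10.0 ** (-res.markers["neglog10p"].to_numpy())
            chi2 = sps.chi2.isf(p, df=1)
            lambdas.append(np.median(chi2) / sps.chi2.ppf(0.5, df=1))
        assert abs(np.mean(lambdas) - 1.0) < 0.1

    def test_mixed_model_corrects_population_stratification(self, marker_map):
        """A trait that is purely a subpopulation shift inflates the naive
        correlation scan but not the mixed model."""
        from scipy import stats as sps

        panel = simulate_wild_panel(100, marker_map, 2, 0.3, seed=8)
        rng = np.random.default_rng(9)
        y_vals = panel.subpopulation * 1.0 + 0.5 * rng.normal(size=100)
        y = pd.Series(y_vals, index=panel.strains)
        # naive per-marker correlation p-values
        naive_p = []
        for j in range(panel.n_markers):
            g = panel.calls[:, j]
            if g.std() == 0:
                continue
            naive_p.append(sps.pearsonr(g, y_vals).pvalue)
        naive_lambda = np.median(sps.chi2.isf(naive_p, 1)) / sps.chi2.ppf(0.5, 1)
        res = gwa_scan(panel, y)
        p = 10.0 ** (-res.markers["neglog10p"].to_numpy())
        mm_lambda = np.median(sps.chi2.isf(p, 1)) / sps.chi2.ppf(0.5, 1)
        assert naive_lambda > 2.0
        assert mm_lambda < 1.3

    def test_marker_pvalue_matches_brute_force_gls(self):
        """On a tiny instance the per-marker p equals the dense GLS t-test at
        the brute-force REML optimum."""
        from scipy import stats as sps

        rng = np.random.default_rng(10)
        n, m = 12, 15
        calls = rng.integers(0, 2, size=(n, m)).astype(float)
        panel = _tiny_panel(calls)
        K = compute_kinship(panel).to_numpy()
        y_vals = rng.normal(size=n)
        y = pd.Series(y_vals, index=panel.strains)
        res = gwa_scan(panel, y, K=pd.DataFrame(K, index=panel.strains, columns=panel.strains))
        for _, row in res.markers.iterrows():
            j = panel.marker_index(row["marker"])
            g = calls[:, j]
            X = np.column_stack([np.ones(n), g])
            delta, _ = brute_force_reml(y_vals, X, K)
            H = K + delta * np.eye(n)
            Hi = inv(H)
            XtHiX = X.T @ Hi @ X
            beta = solve(XtHiX, X.T @ Hi @ y_vals)
            resid = y_vals - X @ beta
            s2 = (resid @ Hi @ resid) / (n - 2)
            se = np.sqrt(s2 * inv(XtHiX)[1, 1])
            t = beta[1] / se
            p_oracle = 2 * sps.t.sf(abs(t), df=n - 2)
            assert 10.0 ** (-row["neglog10p"]) == pytest.approx(p_oracle, abs=1e-6)


@pytest.fixture(scope="module")
def small_panel():
    from toxqtl import make_marker_map

    mm = make_marker_map(n_markers_per_chrom=30, chroms=("I", "II"))
    return simulate_wild_panel(60, mm, 2, 0.15, seed=11)


class TestRoiCalibration:
    def test_noiseless_limit_width_zero(self, small_panel):
        assert calibrate_roi_width(small_panel, ve=1.0, seed=12) == 0

    def test_capture_zero_width_zero(self, small_panel):
        assert calibrate_roi_width(small_panel, ve=0.2, capture=0.0, seed=12) == 0

    def test_width_decreases_with_effect_size(self, small_panel):
        widths = [
            calibrate_roi_width(small_panel, ve=v, seed=13) for v in (0.1, 0.2, 0.4)
        ]
        assert widths[0] >= widths[1] >= widths[2]

    def test_deterministic_given_seed(self, small_panel):
        a = calibrate_roi_width(small_panel, ve=0.2, seed=14)
        b = calibrate_roi_width(small_panel, ve=0.2, seed=14)
        assert a == b

    def test_too_few_markers_rejected(self):
        rng = np.random.default_rng(15)
        panel = _tiny_panel(rng.integers(0, 2, size=(30, 5)).astype(float))
        with pytest.raises(ValueError, match="too few markers"):
            calibrate_roi_width(panel, seed=0)


class TestDefineRoi:
    def _result(self, n_markers, sig_ranks, chrom="II"):
        df = pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(n_markers)],
                "chrom": chrom,
                "pos_bp": (np.arange(n_markers) + 1) * 1000,
                "maf": 0.3,
                "effect": 0.0,
                "neglog10p": 1.0,
                "significant": False,
            }
        )
        df.loc[sig_ranks, "significant"] = True
        df.loc[sig_ranks, "neglog10p"] = 8.0
        return df

    def _panel(self, df):
        markers = df[["marker", "chrom", "pos_bp"]].copy()
        markers["cM"] = np.arange(len(df), dtype=float)
        calls = np.zeros((4, len(df)))
        calls[:2] = 1.0
        return GenotypeMatrix(
            strains=["a", "b", "c", "d"], markers=markers, calls=calls
        )

    def test_central_peak_padded_symmetrically(self):
        df = self._result(200, [100])
        res = GwaResult(markers=df, bonferroni_threshold=4.0)
        rois = define_roi(res, self._panel(df), width_in_snvs=50)
        assert len(rois) == 1
        assert (rois[0].left_bp, rois[0].right_bp) == (51 * 1000, 151 * 1000)

    def test_left_edge_clipped_to_chromosome_start(self):
        df = self._result(200, [9])
        res = GwaResult(markers=df, bonferroni_threshold=4.0)
        rois = define_roi(res, self._panel(df), width_in_snvs=50)
        assert rois[0].left_bp == 1000
        assert rois[0].right_bp == 60 * 1000

    def test_nearby_significant_markers_merge(self):
        df = self._result(200, [80, 110])
        res = GwaResult(markers=df, bonferroni_threshold=4.0)
        rois = define_roi(res, self._panel(df), width_in_snvs=50)
        assert len(rois) == 1
        assert (rois[0].left_bp, rois[0].right_bp) == (31 * 1000, 161 * 1000)

    def test_distant_clusters_stay_separate(self):
        df = self._result(300, [20, 250])
        res = GwaResult(markers=df, bonferroni_threshold=4.0)
        rois = define_roi(res, self._panel(df), width_in_snvs=50)
        assert len(rois) == 2

    def test_no_significant_markers_empty(self):
        df = self._result(100, [])
        res = GwaResult(markers=df, bonferroni_threshold=4.0)
        assert define_roi(res, self._panel(df)) == []
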