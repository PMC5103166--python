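import numpy as np
import pytest

import nirseed.chemometrics as chem
from nirseed.io import SpectraSet, WavenumberGrid
from nirseed.preprocess import PreprocessConfig
from nirseed import synthetic as syn
from oracles import brute_force_press, sklearn_pls_predict


class TestPCA:
    def test_collinear_data_one_component(self):
        t = np.linspace(-1, 1, 8)
        X = 2.0 + np.outer(t, np.array([1.0, -2.0, 0.5, 3.0]))
        m = chem.pca_fit(X, 1)
        assert m.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_at_full_rank(self):
        rng = np.random.default_rng(1)
        X = rng.random((6, 4))
        m = chem.pca_fit(X, 4)
        np.testing.assert_allclose(
            m.center + m.scores @ m.loadings, X, atol=1e-10
        )

    def test_explained_fractions_match_covariance_eigenvalues(self):
        rng = np.random.default_rng(2)
        X = rng.random((15, 6))
        m = chem.pca_fit(X, 5)
        # independent oracle: eigenvalues of the scatter matrix
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        np.testing.assert_allclose(
            m.explained_variance_ratio, evals[:5] / evals.sum(), atol=1e-10
        )
        assert np.all(np.diff(m.explained_variance_ratio) <= 1e-12)

    def test_loadings_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(3)
        m = chem.pca_fit(rng.random((10, 5)), 3)
        np.testing.assert_allclose(m.loadings @ m.loadings.T, np.eye(3), atol=1e-10)
        for row in m.loadings:
            assert row[np.abs(row).argmax()] > 0

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            chem.pca_fit(np.random.default_rng(0).random((4, 10)), 4)


class TestPLSFit:
    def test_single_factor_exact_structure(self):
        rng = np.random.default_rng(4)
        direction = rng.standard_normal(6)
        t = rng.standard_normal(10)
        X = np.outer(t, direction)
        y = 2.0 * t + 1.0
        m = chem.pls_fit(X, y, 1)
        np.testing.assert_allclose(m.predict_matrix(X), y, atol=1e-10)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((12, 7))
        y = rng.standard_normal(12)
        m = chem.pls_fit(X, y, 7)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(
            m.predict_matrix(X), Xc @ beta + y.mean(), atol=1e-8
        )

    def test_matches_sklearn_predictions(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 10))
        y = X @ rng.standard_normal(10) + 0.1 * rng.standard_normal(20)
        for k in (1, 2, 4):
            m = chem.pls_fit(X, y, k)
            np.testing.assert_allclose(
                m.predict_matrix(X), sklearn_pls_predict(X, y, X, k), atol=1e-8
            )

    def test_two_component_mixture_recovery(self):
        """Noise-free 2-component spectra: 2 factors recover concentrations."""
        refs, truth = syn.simulate_concentrations(30, seed=7)
        sub = refs.records[refs.records["component"].isin(["oil", "protein"])]
        refs2 = type(refs)(sub.reset_index(drop=True))
        spectra, _ = syn.simulate_spectra(
            refs2, scatter_slope_sd=0.0, scatter_offset_sd=0.0, noise_sd=0.0, seed=8
        )
        y = truth.concentrations["oil"].loc[spectra.sample_ids].to_numpy()
        m = chem.pls_fit(spectra.absorbance, y, 2)
        np.testing.assert_allclose(m.predict_matrix(spectra.absorbance), y, atol=1e-6)

    def test_degenerate_inputs_rejected(self):
        rng = np.random.default_rng(9)
        X = rng.random((6, 4))
        with pytest.raises(ValueError):
            chem.pls_fit(X, np.ones(6), 1)  # zero-variance y
        with pytest.raises(ValueError):
            chem.pls_fit(X, rng.random(6), 6)  # n_factors > min(n-1, p)
        t = rng.standard_normal(6)
        with pytest.raises(ValueError):  # exceeding the X rank
            chem.pls_fit(np.outer(t, rng.random(4)), rng.random(6), 3)


class TestPLSPredict:
    @pytest.fixture
    def calibrated(self, small_study):
        spectra = small_study["spectra"]
        cal = spectra.subset(spectra.sample_ids[:60])
        y = (
            small_study["conc"].concentrations["oil"].loc[cal.sample_ids].to_numpy()
        )
        cfg = PreprocessConfig()
        from nirseed.preprocess import preprocess

        pp, ref = preprocess(cal, cfg)
        model = chem.pls_fit(
            pp.absorbance, y, 4, preprocess_config=cfg, msc_ref=ref,
            training_ids=cal.sample_ids, component="oil",
        )
        return model, cal, y

    def test_duplicated_spectrum_same_prediction(self, calibrated):
        model, cal, _ = calibrated
        dup = SpectraSet(
            cal.grid, np.vstack([cal.absorbance[0], cal.absorbance[0]]), ["a", "b"]
        )
        p = chem.pls_predict(model, dup)
        assert p[0] == p[1]

    def test_msc_makes_prediction_scatter_invariant(self, calibrated):
        model, cal, _ = calibrated
        base = cal.absorbance[3]
        distorted = SpectraSet(
            cal.grid, np.vstack([base, 0.2 + 1.5 * base]), ["a", "b"]
        )
        p = chem.pls_predict(model, distorted)
        assert abs(p[0] - p[1]) < 1e-8

    def test_sec_consistency_with_residual_sd(self, calibrated):
        """SEC and the raw residual RMS differ exactly by the dof factor."""
        model, cal, y = calibrated
        from nirseed.quality import sec

        e = y - chem.pls_predict(model, cal)
        n, k = len(y), model.n_factors
        rms = np.sqrt((e**2).mean())
        assert sec(e, k) * np.sqrt((n - k - 1) / n) == pytest.approx(rms, rel=1e-12)

    def test_grid_mismatch_rejected(self, calibrated):
        model, cal, _ = calibrated
        other = SpectraSet(
            WavenumberGrid(cal.grid.values[:-10] + 4.0),
            cal.absorbance[:, :-10],
            cal.sample_ids,
        )
        with pytest.raises(ValueError):
            chem.pls_predict(model, other)


class TestLooPress:
    def test_exact_one_factor_structure_zero_press(self):
        rng = np.random.default_rng(10)
        direction = rng.standard_normal(12)
        t = rng.standard_normal(8)
        grid = WavenumberGrid(4000.0 + 8.0 * np.arange(12), 8.0)
        spectra = SpectraSet(grid, np.outer(t, direction) + 1.0, [f"s{i}" for i in range(8)])
        curve = chem.loo_press(spectra, 3.0 * t + 5.0, 1, config=None)
        assert curve.press[0] < 1e-8

    def test_matches_brute_force_with_preprocessing(self):
        """PRESS for k=1..3 equals a from-scratch refit loop (independent
        MSC + derivative + window code and sklearn PLS)."""
        rng = np.random.default_rng(11)
        n, p = 8, 40
        grid = WavenumberGrid(4000.0 + 8.0 * np.arange(p), 8.0)
        t = rng.standard_normal((n, 3))
        basis = rng.standard_normal((3, p))
        # dominant shared spectral shape so per-fold MSC slopes stay positive
        common = 0.8 + 0.3 * np.sin(np.linspace(0, 3, p))
        X = common + 0.05 * (t @ basis) + 0.002 * rng.standard_normal((n, p))
        y = t @ np.array([1.0, -0.5, 0.25]) + 0.01 * rng.standard_normal(n)
        spectra = SpectraSet(grid, X, [f"s{i}" for i in range(n)])
        windows = ((4050.0, 4250.0),)
        cfg = PreprocessConfig(segment=3, gap=2, windows=windows)
        curve = chem.loo_press(spectra, y, 3, cfg)
        expect = brute_force_press(X, grid.values, y, 3, 3, 2, windows)
        np.testing.assert_allclose(curve.press, expect, rtol=1e-8)

    def test_permutation_invariance(self, tiny_spectra):
        rng = np.random.default_rng(12)
        y = rng.random(6)
        c1 = chem.loo_press(tiny_spectra, y, 2, config=None)
        perm = [5, 2, 0, 4, 1, 3]
        shuffled = tiny_spectra.subset([tiny_spectra.sample_ids[i] for i in perm])
        c2 = chem.loo_press(shuffled, y[perm], 2, config=None)
        np.testing.assert_allclose(np.sort(c1.press), np.sort(c2.press), rtol=1e-10)
        np.testing.assert_allclose(c1.press, c2.press, rtol=1e-10)


class TestSelectFactors:
    @pytest.mark.parametrize(
        "press, expected",
        [([5.0, 2.0, 2.5], 2), ([3.0, 3.0], 1), ([1.0], 1), ([4.0, 1.0, 1.0], 2)],
    )
    def test_minimum_with_parsimony_ties(self, press, expected):
        # loo_residuals only supply the sample count for the F criterion
        curve = chem.PressCurve(np.array(press), np.zeros((20, len(press))))
        assert chem.select_factors(curve) == expected
        assert chem.select_factors(curve, method="global_min") == int(
            np.argmin(press)
        ) + 1

    def test_f_rule_ignores_subpercent_tail_fluctuations(self):
        press = np.array([300.0, 9.0, 2.9, 2.48, 2.52, 2.49, 2.41])
        curve = chem.PressCurve(press, np.zeros((111, 7)))
        assert chem.select_factors(curve) == 4
        assert chem.select_factors(curve, method="global_min") == 7


class TestSerialization:
    def test_model_round_trip(self, small_study, tmp_path):
        spectra = small_study["spectra"]
        cal = spectra.subset(spectra.sample_ids[:40])
        y = small_study["conc"].concentrations["protein"].loc[cal.sample_ids].to_numpy()
        cfg = PreprocessConfig()
        from nirseed.preprocess import preprocess

        pp, ref = preprocess(cal, cfg)
        model = chem.pls_fit(pp.absorbance, y, 3, preprocess_config=cfg,
                             msc_ref=ref, training_ids=cal.sample_ids,
                             component="protein")
        path = tmp_path / "model.json"
        chem.save_model(model, path)
        back = chem.load_model(path)
        np.testing.assert_allclose(
            chem.pls_predict(back, spectra), chem.pls_predict(model, spectra), atol=1e-12
        )
        assert back.component == "protein"
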