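"""Band detection, correlation PCA, ANOVA on scores, RAD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plastscreen import (
    BandPCA,
    FTIRDegradationAnalyzer,
    Spectrum,
    anova_on_scores,
    band_absorbances,
    degradation_report,
    detect_bands,
    fit_pca,
    generate_film_pair,
    polymer_scenario,
    rad,
    reference_bands,
    score_map,
    select_components,
    standardize_set,
)
from plastscreen.chemometrics import BandMatrix, BandTable
from plastscreen.preprocess import second_derivative_set
from conftest import make_set


def gaussians(grid, centers, amps, fwhm=20.0):
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    y = np.zeros_like(grid)
    for c, a in zip(centers, amps):
        y += a * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    return y


class TestDetectBands:
    GRID = 400.0 + 4.0 * np.arange(901)

    def _detect(self, y, window_pts=13, **kw):
        sset = make_set(self.GRID, np.tile(y, (2, 1)))
        return detect_bands(second_derivative_set(sset, window_pts=window_pts), **kw)

    def test_single_gaussian_at_center(self):
        bands = self._detect(gaussians(self.GRID, [1715.0], [1.0]))
        assert len(bands) == 1
        assert abs(bands.centers[0] - 1715.0) <= 4.0

    def test_flat_noise_yields_nothing(self):
        rng = np.random.default_rng(0)
        bands = self._detect(rng.normal(0, 0.01, self.GRID.size), depth_factor=5.0)
        assert len(bands) == 0

    def test_merge_tolerance_rule(self):
        # FWHM 10 < separation 12 and a 5-point derivative window keep
        # the two minima resolved; the merge tolerance alone then
        # decides one band vs two
        y = gaussians(self.GRID, [1700.0, 1712.0], [1.0, 0.8], fwhm=10.0)
        near = self._detect(y, window_pts=5, merge_tol=4.0)
        far = self._detect(y, window_pts=5, merge_tol=16.0)
        assert len(near) == 2
        assert len(far) == 1
        # merged band keeps the deeper (larger-amplitude) minimum
        assert abs(far.centers[0] - 1700.0) <= 4.0

    def test_centers_sorted_unique(self):
        y = gaussians(self.GRID, [800.0, 1400.0, 2900.0], [0.5, 1.0, 0.8])
        bands = self._detect(y)
        assert np.all(np.diff(bands.centers) > 0)


class TestReferenceBands:
    @pytest.mark.parametrize(
        "polymer,n,probe,label_part",
        [
            ("LDPE", 5, 718.0, "rocking"),
            ("PA", 20, 1631.0, "amide I"),
            ("PET", 11, 1715.0, "CO st"),
            ("PP", 14, 809.0, "backbone"),
            ("PU", 11, 1705.0, "CO st"),
        ],
    )
    def test_band_tables(self, polymer, n, probe, label_part):
        table = reference_bands(polymer)
        assert len(table) == n
        assert table.source == "reference"
        i = int(np.where(table.centers == probe)[0][0])
        assert label_part in table.labels[i]

    def test_unknown_polymer_rejected(self):
        with pytest.raises(ValueError, match="PVC"):
            reference_bands("PVC")


class TestBandAbsorbances:
    GRID = 1000.0 + 4.0 * np.arange(200)

    def test_on_grid_point_exact(self):
        rng = np.random.default_rng(1)
        rows = rng.normal(size=(4, self.GRID.size))
        sset = standardize_set(make_set(self.GRID, rows))
        bands = BandTable(np.array([1200.0]), ("x",))
        m = band_absorbances(sset, bands, group=["control"] * 4)
        j = int(np.where(self.GRID == 1200.0)[0][0])
        assert np.allclose(m.values[:, 0], sset.intensity_matrix()[:, j])

    def test_off_grid_ties_toward_lower_wavenumber(self):
        rng = np.random.default_rng(2)
        sset = standardize_set(make_set(self.GRID, rng.normal(size=(3, self.GRID.size))))
        bands = BandTable(np.array([1202.0]), ("x",))  # midway between 1200 and 1204
        m = band_absorbances(sset, bands, group=["control"] * 3)
        j = int(np.where(self.GRID == 1200.0)[0][0])
        assert np.allclose(m.values[:, 0], sset.intensity_matrix()[:, j])

    def test_band_outside_grid_rejected(self):
        rng = np.random.default_rng(3)
        sset = standardize_set(make_set(self.GRID, rng.normal(size=(3, self.GRID.size))))
        with pytest.raises(ValueError, match="outside grid"):
            band_absorbances(sset, BandTable(np.array([5000.0]), ("x",)), group=["a"] * 3)

    def test_planted_attenuation_lowers_incubated_mean(self):
        scenario = polymer_scenario("LDPE", seed=4).with_attenuation(0.3, centers=[1463.0])
        control, incubated, _ = generate_film_pair(scenario)
        combined = make_set(control.grid, np.vstack([control.intensity_matrix(), incubated.intensity_matrix()]))
        std = standardize_set(combined)
        bands = reference_bands("LDPE")
        group = ["control"] * len(control) + ["incubated"] * len(incubated)
        m = band_absorbances(std, bands, group=group)
        j = int(np.where(bands.centers == 1463.0)[0][0])
        ctrl = np.asarray(group) == "control"
        assert m.values[~ctrl, j].mean() < m.values[ctrl, j].mean()


class TestBandPCA:
    def test_two_perfectly_correlated_bands(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        X = np.column_stack([x, 2.0 * x + 1.0])
        model = BandPCA().fit(X)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)
        assert np.allclose(np.abs(model.loadings_[:, 0]), 1.0)
        assert model.communalities(1)[0] == pytest.approx(1.0)

    def test_explained_sums_to_one_and_communalities_bounded(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 6))
        model = BandPCA().fit(X)
        assert model.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(model.communalities() <= 1.0 + 1e-8)
        assert np.all(model.communalities() >= -1e-8)
        # full communalities are exactly 1 for correlation PCA
        assert np.allclose(model.communalities(), 1.0, atol=1e-8)

    def test_matches_bruteforce_eigendecomposition(self):
        """Oracle: direct eigendecomposition of np.corrcoef, independent
        of the fit path."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            n, p = rng.integers(5, 11), rng.integers(2, 7)
            X = rng.normal(size=(int(n), int(p)))
            model = BandPCA().fit(X)
            corr = np.corrcoef(X, rowvar=False)
            eigval, eigvec = np.linalg.eig(corr)
            order = np.argsort(eigval.real)[::-1]
            eigval = eigval.real[order]
            assert np.allclose(model.eigenvalues_, np.clip(eigval, 0, None), atol=1e-8)
            oracle_loadings = eigvec.real[:, order] * np.sqrt(np.clip(eigval, 0, None))
            for k in range(int(p)):
                a, b = model.loadings_[:, k], oracle_loadings[:, k]
                assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_scores_orthogonal_and_centered(self):
        rng = np.random.default_rng(8)
        model = BandPCA().fit(rng.normal(size=(25, 5)))
        S = model.scores_
        assert np.allclose(S.mean(axis=0), 0.0, atol=1e-10)
        G = S.T @ S
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) <= 1e-6

    def test_sign_convention_reproducible(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 4))
        m1, m2 = BandPCA().fit(X), BandPCA().fit(X.copy())
        assert np.allclose(m1.loadings_, m2.loadings_)
        for k in range(4):
            pivot = np.argmax(np.abs(m1.loadings_[:, k]))
            assert m1.loadings_[pivot, k] >= 0

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError):
            BandPCA().fit(X)


class TestComponentSelection:
    def _model_with_loadings(self, loadings):
        model = BandPCA.__new__(BandPCA)
        model.loadings_ = np.asarray(loadings, dtype=float)
        return model

    def test_all_below_cut_selects_nothing(self):
        model = self._model_with_loadings([[0.49, 0.49], [0.49, -0.49]])
        assert select_components(model, 0.5) == []

    def test_boundary_inclusive(self):
        model = self._model_with_loadings([[0.5, 0.3], [0.2, -0.5]])
        assert select_components(model, 0.5) == [0, 1]

    def test_constructed_three_component_model(self):
        model = self._model_with_loadings(
            [[0.9, 0.1, 0.1], [0.1, 0.6, 0.2], [0.1, 0.1, 0.3]]
        )
        assert select_components(model, 0.5) == [0, 1]


class TestAnovaOnScores:
    def test_two_group_f_equals_t_squared(self):
        scores = np.array([1.0, 1.1, 1.2, 0.7, 0.8, 0.9])[:, None]
        group = ["a"] * 3 + ["b"] * 3
        table = anova_on_scores(scores, group)
        assert table["F"][0] == pytest.approx(13.5, abs=1e-9)
        assert table["p"][0] == pytest.approx(0.021, abs=1e-3)
        t = stats.ttest_ind(scores[:3, 0], scores[3:, 0], equal_var=True)
        assert table["F"][0] == pytest.approx(t.statistic**2, abs=1e-9)
        assert table["p"][0] == pytest.approx(t.pvalue, abs=1e-12)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(10)
        n_sim, rejections = 1000, 0
        group = ["a"] * 10 + ["b"] * 10
        for _ in range(n_sim):
            scores = rng.normal(size=(20, 1))
            rejections += anova_on_scores(scores, group)["p"][0] < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_permuted_labels_near_uniform_p(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(400):
            scores = rng.normal(size=(20, 1))
            labels = rng.permutation(["a"] * 10 + ["b"] * 10)
            ps.append(anova_on_scores(scores, labels)["p"][0])
        # KS against uniform should not reject wildly
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_on_scores(np.zeros((3, 1)), ["a", "a", "b"])


class TestRad:
    def test_arithmetic(self):
        assert rad(1.0, 0.9) == pytest.approx(-10.0)
        assert rad(0.5, 0.5) == 0.0
        assert rad(0.5, 0.55) == pytest.approx(10.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(12)
        before, after = rng.uniform(0.1, 2.0, 2)
        for c in (0.5, 3.0, 100.0):
            assert rad(c * before, c * after) == pytest.approx(rad(before, after))

    def test_zero_before_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rad(0.0, 1.0)


class TestDegradationReport:
    def test_planted_uniform_attenuation_recovered(self):
        scenario = polymer_scenario("LDPE", seed=13).with_attenuation(
            0.15, centers=[2915.0, 1463.0, 718.0]
        )
        control, incubated, _ = generate_film_pair(scenario)
        analyzer = FTIRDegradationAnalyzer().fit(control, incubated)
        res = analyzer.result_
        assert not res.no_signal
        hits = [c for c in res.decreased_bands if any(abs(c - t) <= 4.0 for t in (2915.0, 1463.0, 718.0))]
        assert len(hits) == 3
        for c in hits:
            assert res.rad_pct[c] == pytest.approx(-15.0, abs=3.0)

    def test_null_pair_reports_no_decreased_bands(self):
        """Control vs an identical copy: group means equal, so ANOVA
        F = 0 and nothing is flagged."""
        control, _, _ = generate_film_pair(polymer_scenario("LDPE", seed=14))
        analyzer = FTIRDegradationAnalyzer().fit(control, control)
        assert analyzer.result_.no_signal
        assert analyzer.result_.decreased_bands == ()

    def test_fringe_attack_concentrates_scores_on_fringe(self):
        # attack the amide bands only: attenuating every band equally
        # is invisible after per-spectrum standardization
        scenario = polymer_scenario("PA", seed=15, spatial_pattern="fringe").with_attenuation(
            0.25, centers=[3297.0, 1631.0, 1534.0, 1275.0]
        )
        control, incubated, truth = generate_film_pair(scenario)
        analyzer = FTIRDegradationAnalyzer().fit(control, incubated)
        res = analyzer.result_
        assert res.significant_components
        comp = res.significant_components[0]
        # scores of incubated measurements split fringe vs interior
        n_ctrl = len(control)
        scores = analyzer.pca_.scores_[n_ctrl:, comp]
        mask = truth["attenuation_mask"]
        fringe = np.abs(scores[mask]).mean()
        interior = np.abs(scores[~mask]).mean()
        assert fringe > interior

    def test_missing_raw_matrix_rejected(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(10, 3))
        m = BandMatrix(X, BandTable(np.array([1.0, 2.0, 3.0]), ("a", "b", "c")), ("control",) * 5 + ("incubated",) * 5)
        model = fit_pca(m)
        with pytest.raises(ValueError, match="raw"):
            degradation_report(m, model)


class TestScoreMap:
    def test_grid_shape_and_signs(self):
        scenario = polymer_scenario("LDPE", seed=17).with_attenuation(0.2)
        control, incubated, _ = generate_film_pair(scenario)
        analyzer = FTIRDegradationAnalyzer().fit(control, incubated)
        table = analyzer.score_map(0)
        assert len(table) == 50  # 25 control + 25 incubated positions
        assert set(table.columns) == {"row", "col", "score", "sign"}
        assert np.all((table["sign"] == "+") == (table["score"] >= 0))

    def test_axial_positions(self):
        model = BandPCA.__new__(BandPCA)
        model.scores_ = np.arange(10.0)[:, None]
        table = score_map(model, [(i,) for i in range(10)], 0)
        assert len(table) == 10
        assert (table["col"] == 0).all()
        assert (table["sign"] == "+").all()

    def test_length_mismatch_rejected(self):
        model = BandPCA.__new__(BandPCA)
        model.scores_ = np.arange(4.0)[:, None]
        with pytest.raises(ValueError):
            score_map(model, [(0, 0)], 0)
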