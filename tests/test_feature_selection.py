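import numpy as np
import pytest
from scipy import stats

from ftirmw import (
    LabelledDataset,
    MwScaler,
    SampleLabel,
    WindowConfig,
    pearson_r,
    regression_slope,
    spearman_rho,
    suitability_map,
)
from ftirmw.feature_selection import SuitabilitySelector
from ftirmw.preprocessing import crop_window

from conftest import make_spectrum


class TestSpearman:
    def test_strictly_monotone_series_gives_unity(self):
        x = np.arange(10.0)
        y = np.exp(x)  # nonlinear but strictly increasing
        assert spearman_rho(x, y) == pytest.approx(1.0, abs=1e-15)
        assert spearman_rho(x, y[::-1]) == pytest.approx(-1.0, abs=1e-15)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 1.0, 2.0, 2.0]
        rx = stats.rankdata(x)  # average ranks
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPearson:
    def test_exact_linear_relationships(self):
        x = np.arange(5.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)
        assert pearson_r(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_saturating_trend_understated_relative_to_spearman(self):
        x = np.arange(1.0, 11.0)
        y = x / (1.0 + x)
        assert pearson_r(x, y) < spearman_rho(x, y) == pytest.approx(1.0)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            pearson_r([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestRegressionSlope:
    def test_exact_line(self):
        x = np.linspace(0, 1, 7)
        assert regression_slope(x, 2.0 * x + 0.3) == pytest.approx(2.0, abs=1e-12)

    def test_flat_ratio_pathology_gives_zero_slope(self):
        x = np.linspace(0, 1, 7)
        assert regression_slope(x, np.full(7, 2.0)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_cov_over_var(self, rng):
        x = rng.uniform(0, 1, 50)
        y = rng.normal(0, 1, 50)
        expect = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert regression_slope(x, y) == pytest.approx(expect, abs=1e-12)

    def test_degenerate_x_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            regression_slope([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMwScaler:
    def test_unit_interval_maps_training_range(self):
        sc = MwScaler(4000.0, 780000.0)
        np.testing.assert_allclose(sc.transform([4000.0, 780000.0]), [0.0, 1.0])

    def test_kilodalton_mode(self):
        sc = MwScaler(4000.0, 780000.0, mode="kilodalton")
        assert sc.transform([50000.0])[0] == pytest.approx(50.0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            MwScaler(5.0, 5.0)


class TestSuitabilityMap:
    def test_toy_grid_matches_bruteforce_pair_loop(self, toy_labelled_dataset):
        """Whole-map oracle: every candidate pair equals the scalar ops."""
        cfg = WindowConfig(1500.0, 1800.0, abs_threshold=0.03)
        smap = suitability_map(toy_labelled_dataset, cfg)
        cropped = [crop_window(s, cfg) for s in toy_labelled_dataset.spectra]
        grid = cropped[0].wavenumbers
        mw = np.array(
            [toy_labelled_dataset.labels[s.sample_id].mw_weight_avg for s in cropped]
        )
        X = np.vstack([s.absorbances for s in cropped])
        mw_scaled = smap.scaler.transform(mw)
        ii, jj = np.nonzero(smap.candidate)
        assert ii.size > 0
        checked = 0
        for i, j in zip(ii, jj):
            r = X[:, i] / X[:, j]
            if np.ptp(r) == 0:  # degenerate (diagonal) pair: stats undefined
                assert np.isnan(smap.suitability[i, j])
                assert not smap.selected[i, j]
                continue
            assert smap.spearman[i, j] == pytest.approx(spearman_rho(mw, r), abs=1e-10)
            assert smap.pearson[i, j] == pytest.approx(pearson_r(mw, r), abs=1e-10)
            assert smap.slope[i, j] == pytest.approx(
                regression_slope(mw_scaled, r), abs=1e-10
            )
            checked += 1
        assert checked > 0

    def test_suitability_is_spearman_times_slope(self, toy_labelled_dataset):
        cfg = WindowConfig(1500.0, 1800.0)
        smap = suitability_map(toy_labelled_dataset, cfg)
        c = smap.candidate
        np.testing.assert_allclose(
            smap.suitability[c], (smap.spearman * smap.slope)[c], rtol=1e-12
        )

    def test_negative_trend_yields_positive_suitability(self, toy_labelled_dataset):
        """A decreasing ratio has negative Spearman AND negative slope, so the
        product used for selection stays positive in either orientation."""
        cfg = WindowConfig(1500.0, 1800.0)
        smap = suitability_map(toy_labelled_dataset, cfg)
        up = smap.pair_stats(1800.0, 1750.0)   # planted increasing ratio
        down = smap.pair_stats(1750.0, 1800.0)  # reverse orientation
        assert up["spearman"] > 0 and up["slope"] > 0
        assert down["spearman"] < 0 and down["slope"] < 0
        assert up["suitability"] > 0 and down["suitability"] > 0

    def test_raising_threshold_never_grows_selection(self, toy_labelled_dataset):
        cfg = WindowConfig(1500.0, 1800.0)
        lo = suitability_map(toy_labelled_dataset, cfg, threshold=0.2)
        hi = suitability_map(toy_labelled_dataset, cfg, threshold=0.6)
        assert not np.any(hi.selected & ~lo.selected)
        assert hi.n_selected <= lo.n_selected

    def test_invariant_to_replicate_reordering(self, toy_labelled_dataset):
        cfg = WindowConfig(1500.0, 1800.0)
        a = suitability_map(toy_labelled_dataset, cfg)
        shuffled = LabelledDataset(
            toy_labelled_dataset.spectra[::-1], toy_labelled_dataset.labels
        )
        b = suitability_map(shuffled, cfg)
        np.testing.assert_allclose(
            a.suitability[a.candidate], b.suitability[b.candidate], rtol=1e-12
        )
        np.testing.assert_array_equal(a.selected, b.selected)

    def test_fewer_than_three_levels_rejected(self, rng):
        grid = np.array([1800.0, 1750.0])
        spectra, labels = [], {}
        for sid, mw in (("A", 1e4), ("B", 1e5)):
            labels[sid] = SampleLabel(sid, mw)
            for k in range(3):
                spectra.append(
                    make_spectrum(rng.uniform(0.1, 1, 2), grid, sid, f"r{k}")
                )
        with pytest.raises(ValueError, match="insufficient M_w levels"):
            suitability_map(LabelledDataset(spectra, labels), WindowConfig(1700, 1800))

    def test_export_frame_contains_candidates(self, toy_labelled_dataset):
        smap = suitability_map(toy_labelled_dataset, WindowConfig(1500.0, 1800.0))
        df = smap.to_frame()
        assert set(["nu1", "nu2", "pearson", "spearman", "slope",
                    "suitability", "selected"]) <= set(df.columns)
        assert len(df) == int(smap.candidate.sum())


class TestSuitabilitySelector:
    def test_transform_produces_selected_ratio_features(self, toy_labelled_dataset):
        cfg = WindowConfig(1500.0, 1800.0)
        cropped = [crop_window(s, cfg) for s in toy_labelled_dataset.spectra]
        X = np.vstack([s.absorbances for s in cropped])
        y = np.array(
            [toy_labelled_dataset.labels[s.sample_id].mw_weight_avg for s in cropped]
        )
        sids = [s.sample_id for s in cropped]
        sel = SuitabilitySelector(
            wavenumbers=cropped[0].wavenumbers, max_features=3
        ).fit(X, y, sample_ids=sids)
        F = sel.transform(X)
        assert F.shape == (len(cropped), len(sel.pairs_))
        assert len(sel.pairs_) <= 3
        # every kept pair must be in the thresholded selection
        for p in sel.pairs_:
            assert sel.selection_map_.pair_stats(*p)["selected"]

    def test_no_selected_pair_raises(self, rng):
        # pure noise: nothing correlates with M_w
        grid = np.arange(1800.0, 1795.0, -1.0)
        X = rng.uniform(0.4, 0.6, (12, grid.size))
        y = np.repeat([1e4, 1e5, 1e6], 4)
        sids = [f"S{k}" for k in np.repeat([1, 2, 3], 4)]
        with pytest.raises(ValueError, match="no pair"):
            SuitabilitySelector(wavenumbers=grid, threshold=0.5).fit(
                X, y, sample_ids=sids
            )
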