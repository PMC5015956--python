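import numpy as np
import pandas as pd
import pytest

import colonyscan as cs
from colonyscan.layout import control_mask, control_positions
from colonyscan.normalization import NormalizationError


def make_features(layout, dt_grid, flags_at=()):
    feats = []
    for p in layout.positions():
        f = cs.GrowthFeatures(
            position=p,
            dt_min=float(dt_grid[p.row, p.col]),
            t_at_dt_min=5.0,
            regression_se=0.001,
            cr_fit_rmse=0.01,
            initial_population=2e4,
            doublings=5.0,
            flags=set(["manual"]) if (p.row, p.col) in flags_at else set(),
        )
        feats.append(f)
    return feats


class TestControlOutliers:
    def test_all_equal_none_removed(self, layout96):
        controls = [(p, 2.0) for p in control_positions(layout96)]
        retained, removed = cs.filter_control_outliers(controls)
        assert len(retained) == len(controls)
        assert removed == []

    def test_single_10x_outlier_removed(self, layout96):
        rng = np.random.default_rng(0)
        controls = [
            (p, 2.0 * np.exp(0.02 * rng.standard_normal()))
            for p in control_positions(layout96)
        ]
        bad = controls[7][0]
        controls[7] = (bad, controls[7][1] * 10.0)
        retained, removed = cs.filter_control_outliers(controls)
        assert removed == [bad]
        assert len(retained) == len(controls) - 1

    def test_lognormal_removal_fraction_small(self, layout1536):
        """3 x scaled-MAD keeps essentially all of an iid lognormal sample."""
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            controls = [
                (p, 2.0 * np.exp(0.1 * rng.standard_normal()))
                for p in control_positions(layout1536)
            ]
            _, removed = cs.filter_control_outliers(controls)
            fracs.append(len(removed) / len(controls))
        assert np.mean(fracs) < 0.02

    def test_too_few_controls_rejected(self):
        with pytest.raises(NormalizationError):
            cs.filter_control_outliers([(cs.Position(1, 1), 2.0)] * 5)

    def test_majority_nonfinite_aborts(self, layout96):
        controls = [(p, np.nan) for p in control_positions(layout96)]
        for i in range(10):
            controls[i] = (controls[i][0], 2.0)
        with pytest.raises(NormalizationError):
            cs.filter_control_outliers(controls)


class TestSurface:
    def test_constant_controls_give_constant_surface(self, layout96):
        controls = [(p, 2.0) for p in control_positions(layout96)]
        surf = cs.build_surface(layout96, controls)
        assert np.allclose(surf.expected_dt, 2.0, atol=1e-9)

    def test_linear_gradient_recovered_within_2pct(self, layout384):
        controls = [(p, 2.0 + 0.01 * p.col) for p in control_positions(layout384)]
        surf = cs.build_surface(layout384, controls)
        truth = 2.0 + 0.01 * np.arange(layout384.cols)[None, :]
        assert np.abs(surf.expected_dt / truth - 1).max() < 0.02

    def test_surface_much_smoother_than_checkerboard_noise(self, layout384):
        rng = np.random.default_rng(1)
        controls = [
            (p, 2.0 * np.exp(0.2 * rng.standard_normal()))
            for p in control_positions(layout384)
        ]
        retained, _ = cs.filter_control_outliers(controls)
        surf = cs.build_surface(layout384, retained)
        ctrl_var = np.var(np.log2([v for _, v in retained]))
        surf_var = np.var(np.log2(surf.expected_dt))
        assert surf_var < 0.2 * ctrl_var

    def test_degenerate_geometry_aborts(self, layout96):
        # all controls on one tetrad row
        controls = [(cs.Position(1, 2 * i + 1), 2.0) for i in range(4)] * 3
        with pytest.raises(NormalizationError):
            cs.build_surface(layout96, controls)

    def test_surface_finite_on_control_free_edges(self, layout96):
        rng = np.random.default_rng(2)
        controls = [
            (p, 2.0 * np.exp(0.05 * rng.standard_normal()))
            for p in control_positions(layout96)
        ]
        surf = cs.build_surface(layout96, controls)
        assert np.all(np.isfinite(surf.expected_dt))
        assert np.all(surf.expected_dt > 0)


class TestNormalizePlate:
    def test_observed_equal_surface_gives_zero(self, layout96):
        dt = np.full((8, 12), 2.0)
        feats = make_features(layout96, dt)
        surf = cs.build_surface(layout96, [(p, 2.0) for p in control_positions(layout96)])
        table = cs.normalize_plate(feats, surf)
        assert np.allclose(table.frame["rel_phenotype_log2"], 0.0, atol=1e-9)

    def test_double_dt_scores_minus_one(self, layout96):
        """A colony growing at half rate (doubling time 2x the local
        expectation) is a growth defect: phenotype -1."""
        dt = np.full((8, 12), 2.0)
        dt[0, 2] = 4.0
        feats = make_features(layout96, dt)
        surf = cs.build_surface(layout96, [(p, 2.0) for p in control_positions(layout96)])
        table = cs.normalize_plate(feats, surf)
        fr = table.frame
        val = fr[(fr.row == 0) & (fr.col == 2)]["rel_phenotype_log2"].iloc[0]
        assert val == pytest.approx(-1.0, abs=1e-9)

    def test_flags_propagate_and_nonpositive_dt_flagged(self, layout96):
        dt = np.full((8, 12), 2.0)
        dt[3, 3] = np.nan
        feats = make_features(layout96, dt, flags_at={(2, 2)})
        surf = cs.build_surface(layout96, [(p, 2.0) for p in control_positions(layout96)])
        fr = cs.normalize_plate(feats, surf).frame
        assert "manual" in fr[(fr.row == 2) & (fr.col == 2)]["flags"].iloc[0]
        bad = fr[(fr.row == 3) & (fr.col == 3)]
        assert "nonpositive-dt" in bad["flags"].iloc[0]
        assert np.isnan(bad["rel_phenotype_log2"].iloc[0])


class TestBetweenPlates:
    def _plate(self, layout, dt_grid, plate_id):
        feats = make_features(layout, dt_grid)
        surf = cs.surface_from_features(layout, feats)
        return cs.normalize_plate(feats, surf, plate_id=plate_id)

    def test_identical_plates_zero_shift(self, layout96):
        rng = np.random.default_rng(3)
        dt = 2.0 * np.exp(0.05 * rng.standard_normal((8, 12)))
        plates = [self._plate(layout96, dt, f"p{i}") for i in range(3)]
        _, shifts = cs.normalize_between_plates(layout96, plates)
        assert all(abs(s) < 1e-12 for s in shifts.values())

    def test_constructed_offset_recovered(self, layout96):
        rng = np.random.default_rng(4)
        dt = 2.0 * np.exp(0.05 * rng.standard_normal((8, 12)))
        p1 = self._plate(layout96, dt, "a")
        p2 = self._plate(layout96, dt * 2.0**0.3, "b")
        _, shifts = cs.normalize_between_plates(layout96, [p1, p2])
        assert shifts["b"] - shifts["a"] == pytest.approx(-0.3, abs=1e-9)

    def test_grand_control_mean_invariant(self, layout96):
        rng = np.random.default_rng(5)
        plates = [
            self._plate(layout96, 2.0 * np.exp(0.1 * rng.standard_normal((8, 12))), f"p{i}")
            for i in range(4)
        ]
        cmask = control_mask(layout96)

        def grand_mean(tables):
            vals = []
            for t in tables:
                fr = t.frame
                is_ctl = cmask[fr["row"].to_numpy(int), fr["col"].to_numpy(int)]
                vals.append(np.log2(fr.loc[is_ctl, "dt_min_hr"].to_numpy(float)))
            return np.mean(np.concatenate(vals))

        before = grand_mean(plates)
        adjusted, _ = cs.normalize_between_plates(layout96, plates)
        assert grand_mean(adjusted) == pytest.approx(before, abs=1e-12)
        # and every adjusted plate's control mean equals the grand mean
        for t in adjusted:
            fr = t.frame
            is_ctl = cmask[fr["row"].to_numpy(int), fr["col"].to_numpy(int)]
            m = np.mean(np.log2(fr.loc[is_ctl, "dt_min_hr"].to_numpy(float)))
            assert m == pytest.approx(before, abs=1e-9)


class TestConditionDifference:
    def _table(self, layout, rel, plate_id, condition):
        rows = []
        for p in layout.positions():
            rows.append(
                {
                    "plate": plate_id,
                    "row": p.row,
                    "col": p.col,
                    "strain": f"s{p.row}_{p.col}",
                    "dt_min_hr": 2.0,
                    "rel_phenotype_log2": rel[p.row, p.col],
                    "flags": "",
                }
            )
        return cs.PhenotypeTable(pd.DataFrame(rows), plate_id, condition)

    def test_equal_tables_give_zero(self, layout96):
        rng = np.random.default_rng(6)
        rel = 0.1 * rng.standard_normal((8, 12))
        out = cs.condition_difference(
            self._table(layout96, rel, "s", "stress"),
            self._table(layout96, rel, "b", "basal"),
        )
        assert np.allclose(out["condition_effect_log2"], 0.0)

    def test_subtraction_arithmetic(self, layout96):
        basal = np.full((8, 12), -0.2)
        stress = np.full((8, 12), -0.5)
        out = cs.condition_difference(
            self._table(layout96, stress, "s", "stress"),
            self._table(layout96, basal, "b", "basal"),
        )
        assert np.allclose(out["condition_effect_log2"], -0.3)

    def test_condition_effect_independent_of_basal(self, layout1536):
        """With independent basal and condition effects, the recovered
        condition effect decorrelates from the basal phenotype."""
        rng = np.random.default_rng(7)
        shape = (layout1536.rows, layout1536.cols)
        basal_eff = 0.3 * rng.standard_normal(shape)
        cond_eff = 0.3 * rng.standard_normal(shape)
        noise = lambda: 0.03 * rng.standard_normal(shape)
        basal = basal_eff + noise()
        stress = basal_eff + cond_eff + noise()
        out = cs.condition_difference(
            self._table(layout1536, stress, "s", "stress"),
            self._table(layout1536, basal, "b", "basal"),
        )
        sub = out.iloc[:1000]
        r = np.corrcoef(sub["condition_effect_log2"], sub["rel_phenotype_log2_basal"])[0, 1]
        assert abs(r) < 0.1

    def test_mismatched_strains_dropped(self, layout96):
        rng = np.random.default_rng(8)
        rel = 0.1 * rng.standard_normal((8, 12))
        a = self._table(layout96, rel, "s", "stress")
        b = self._table(layout96, rel, "b", "basal")
        b.frame.loc[0, "strain"] = "other"
        out = cs.condition_difference(a, b)
        assert len(out) == layout96.n_positions - 1
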