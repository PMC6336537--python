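"""Planted model, per-unit cell simulation and image rendering."""

import math

import numpy as np
import pandas as pd
import pytest

import toposcreen as ts
from toposcreen.library import Primitive, TopoUnitDesign
from toposcreen.screen_sim import (
    PlantedModel,
    PlantedRule,
    eval_predicate,
    default_planted_model,
    simulate_unit,
    write_stack,
    read_stack,
)


class TestPredicates:
    def test_comparison_and_boolean_nodes(self):
        dv = {"fcp": 0.3, "line_len": 10.0}
        assert eval_predicate(["fcp", ">=", 0.256], dv)
        assert not eval_predicate(["fcp", "<", 0.256], dv)
        assert eval_predicate({"all": [["fcp", ">", 0.1], ["line_len", "<", 12]]}, dv)
        assert eval_predicate({"any": [["fcp", ">", 0.9], ["line_len", "<", 12]]}, dv)

    def test_absent_value_is_false(self):
        assert not eval_predicate(["line_len", "<", 15.849], {"line_len": None})
        assert not eval_predicate(["rot_sd", ">=", 40.0], {"rot_sd": float("nan")})
        assert not eval_predicate(["fcp", ">", 0.0], {})

    def test_default_model_rule_routing(self):
        model = default_planted_model()
        # high coverage + large circles -> round stimulating rule
        p, morph, idx = model.match({"fcp": 0.3, "circ_diam": 10.0})
        assert (p, morph, idx) == (0.5, "round", 0)
        # low coverage + short lines + irregular -> spread rule
        p, morph, idx = model.match(
            {"fcp": 0.1, "line_len": 10.0, "rot_sd": 50.0, "fcpn01": 0.5})
        assert (p, morph, idx) == (0.45, "spread", 1)
        # flat control: nothing matches
        p, morph, idx = model.match({"fcp": 0.0, "fcpn01": 0.01})
        assert (p, idx) == (0.12, -1)

    def test_json_round_trip(self, tmp_path):
        model = default_planted_model()
        path = tmp_path / "model.json"
        model.to_json(path)
        assert PlantedModel.from_json(path) == model

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            PlantedRule(["fcp", ">", 0.1], p_diff=1.4, morph="round")
        with pytest.raises(ValueError):
            PlantedRule(["fcp", ">", 0.1], p_diff=0.5, morph="oblong")


def constant_model(p_diff: float, morph: str = "spread") -> PlantedModel:
    return PlantedModel(rules=(PlantedRule(["fcp", ">=", -1.0], p_diff, morph),),
                        baseline_p=0.0)


class TestSimulateUnit:
    def test_cell_count_range_and_determinism(self):
        model = default_planted_model()
        for seed in range(5):
            cells = simulate_unit({"fcp": 0.0}, model, seed=seed)
            assert 5 <= len(cells) <= 25
        a = simulate_unit({"fcp": 0.0}, model, seed=9)
        b = simulate_unit({"fcp": 0.0}, model, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_probability_never_differentiates(self):
        model = constant_model(0.0)
        cells = pd.concat([simulate_unit({"fcp": 1.0}, model, seed=s)
                           for s in range(30)])
        assert not cells["true_diff"].any()

    def test_spread_class_mean_area(self):
        """At p_diff = 1 with spread morphology, the log-normal mean
        (median 1800, sigma 0.3 -> mean ~1883) lands in [1500, 2200]."""
        model = constant_model(1.0, "spread")
        cells = pd.concat([simulate_unit({"fcp": 1.0}, model, seed=s)
                           for s in range(80)])
        assert cells["true_diff"].all()
        assert 1500 <= cells["area_um2"].mean() <= 2200

    def test_isoperimetric_identity(self):
        """Perimeter is constructed from (area, roundness):
        4*pi*A/P^2 == roundness exactly."""
        model = default_planted_model()
        cells = pd.concat([simulate_unit({"fcp": 0.3, "circ_diam": 9.0},
                                         model, seed=s) for s in range(10)])
        r = 4 * math.pi * cells["area_um2"] / cells["perimeter_um"] ** 2
        assert np.allclose(r, cells["roundness"], atol=1e-9)
        # isoperimetric bound: P >= 2*sqrt(pi*A)
        assert (cells["perimeter_um"] >=
                2 * np.sqrt(math.pi * cells["area_um2"]) - 1e-9).all()

    def test_mfi_bimodality_recovers_planted_rate(self):
        """Over ~10000 baseline cells, the MFI > 270 rule recovers the
        planted 12% within 3 binomial SE (misclassification < 0.5%)."""
        model = default_planted_model()
        cells = pd.concat([simulate_unit({"fcp": 0.0}, model, seed=s)
                           for s in range(670)])
        n = len(cells)
        assert n >= 9000
        frac = (cells["tgm1_mfi"] > 270).mean()
        expected = 0.12 * (1 - 0.00305)  # Phi(-2.75) low tail of the bright mode
        se = math.sqrt(0.12 * 0.88 / n)
        assert abs(frac - expected) <= 3 * se
        # misclassification across the cutoff is rare in both directions
        diff = cells["true_diff"]
        assert ((cells.loc[diff, "tgm1_mfi"] <= 270).mean()) < 0.005
        assert ((cells.loc[~diff, "tgm1_mfi"] > 270).mean()) < 0.005

    def test_nucleus_spacing(self):
        cells = simulate_unit({"fcp": 0.0}, default_planted_model(), seed=3)
        pts = cells[["nx_um", "ny_um"]].to_numpy()
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= 20.0 ** 2 - 1e-9

    def test_planted_rate_recovery_per_stratum(self):
        """Realized differentiation fractions match each rule's planted
        probability within 3 binomial SE over >= 50 units per stratum."""
        model = default_planted_model()
        strata = {
            0.5: {"fcp": 0.3, "circ_diam": 10.0},
            0.45: {"fcp": 0.1, "line_len": 10.0, "fcpn01": 0.1},
            0.12: {"fcp": 0.0},
        }
        for p, dv in strata.items():
            cells = pd.concat([simulate_unit(dv, model, seed=[17, s])
                               for s in range(60)])
            frac = cells["true_diff"].mean()
            se = math.sqrt(p * (1 - p) / len(cells))
            assert abs(frac - p) <= 3 * se


class TestSimulateScreen:
    def test_deterministic(self, mini_screen):
        cells2, truth2 = ts.simulate_screen(
            mini_screen["library"], mini_screen["layout"], mini_screen["model"],
            seed=3, descriptors=mini_screen["descriptors"])
        pd.testing.assert_frame_equal(mini_screen["cells"], cells2)
        pd.testing.assert_frame_equal(mini_screen["truth"], truth2)

    def test_duplicates_share_truth_but_not_cells(self, mini_screen):
        truth, cells = mini_screen["truth"], mini_screen["cells"]
        for design_id, grp in truth.groupby("design_id"):
            assert len(grp) == 2
            assert grp["p_diff"].nunique() == 1
            assert grp["morph"].nunique() == 1
        # realized tables of the two duplicates differ somewhere
        diffs = 0
        for design_id, grp in cells.groupby("design_id"):
            units = grp.groupby(["row", "col"])["area_um2"].sum()
            if len(units) == 2 and units.iloc[0] != units.iloc[1]:
                diffs += 1
        assert diffs > 0

    def test_flat_control_gets_baseline(self, mini_screen):
        flat = mini_screen["truth"].query("design_id == 'FLAT'")
        assert (flat["p_diff"] == mini_screen["model"].baseline_p).all()
        assert (flat["rule_index"] == -1).all()


class TestRenderUnit:
    def test_label_raster_counts_cells(self, rendered_unit):
        cells, stack = rendered_unit
        labels = np.unique(stack.labels)
        assert len(labels[labels > 0]) == len(cells)

    def test_tgm1_median_equals_mfi(self, rendered_unit):
        cells, stack = rendered_unit
        for i, cell in cells.reset_index(drop=True).iterrows():
            region = stack.labels == i + 1
            assert np.median(stack.tgm1[region]) == pytest.approx(
                cell["tgm1_mfi"])

    def test_ellipse_pixel_area_matches(self):
        """A rendered isolated cell's pixel footprint matches its drawn area
        within 3% at 0.5 um/px."""
        cells = pd.DataFrame([{
            "cell_id": 1, "true_diff": True, "true_morph": "spread",
            "area_um2": 1800.0, "roundness": 0.3,
            "perimeter_um": math.sqrt(4 * math.pi * 1800 / 0.3),
            "tgm1_mfi": 600.0, "nx_um": 150.0, "ny_um": 150.0,
        }])
        mask = ts.rasterize(TopoUnitDesign("flat", ()))
        stack = ts.render_unit(cells, mask, noise_sd=0.0, seed=0)
        pixel_area = (stack.labels == 1).sum() * 0.5 ** 2
        assert abs(pixel_area - 1800.0) / 1800.0 < 0.03

    def test_stack_io_round_trip(self, tmp_path, rendered_unit):
        _, stack = rendered_unit
        path = tmp_path / "unit.tif"
        write_stack(stack, path)
        loaded = read_stack(path)
        assert np.allclose(loaded.tgm1, stack.tgm1, atol=1e-4)
        np.testing.assert_array_equal(loaded.labels, stack.labels)
        assert loaded.resolution == stack.resolution
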