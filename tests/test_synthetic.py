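"""Synthetic panel generator: copula calibration, planted signal, round trips."""

import math

import numpy as np
import pandas as pd
import pytest

from rospanel.dose_response import fit_ic25, normalize_viability
from rospanel.errors import ValidationError
from rospanel.expression import (
    average_replicates,
    filter_annotated,
    housekeeping_normalize,
)
from rospanel.screen import screen, spearman
from rospanel.sensitivity import rank_sensitivity
from rospanel.synthetic import (
    PlantedSet,
    SimulationConfig,
    TreatmentDesign,
    simulate_dose_response,
    simulate_expression,
    simulate_ic25,
    simulate_latent,
    simulate_panel,
    spearman_to_pearson,
    write_panel,
)


class TestCopula:
    def test_closed_form_conversion(self):
        # 2*sin(pi*0.64/6) evaluated independently
        assert spearman_to_pearson(0.64) == pytest.approx(
            2 * math.sin(math.pi * 0.64 / 6), abs=1e-15
        )
        assert spearman_to_pearson(0.64) == pytest.approx(0.6577, abs=5e-5)
        assert spearman_to_pearson(0.0) == 0.0
        assert spearman_to_pearson(1.0) == pytest.approx(1.0)

    def test_independent_pair_mean_near_zero(self):
        rs = []
        for seed in range(200):
            cfg = SimulationConfig(seed=seed)
            lat = simulate_latent(cfg)
            rs.append(spearman(lat["h2o2"], lat["hocl"]).r)  # target 0.02
        assert abs(np.mean(rs) - 0.02) < 0.05

    def test_determinism(self):
        cfg = SimulationConfig(seed=7)
        a = simulate_latent(cfg)
        b = simulate_latent(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_non_psd_target_rejected_with_eigenvalue(self):
        cfg = SimulationConfig(
            spearman_target=(
                (1.0, 0.95, -0.95),
                (0.95, 1.0, 0.95),
                (-0.95, 0.95, 1.0),
            )
        )
        with pytest.raises(ValidationError, match="eigenvalue"):
            simulate_latent(cfg)

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            simulate_latent(SimulationConfig(
                spearman_target=((1.0, 0.5, 0.0), (0.2, 1.0, 0.0), (0.0, 0.0, 1.0))))
        with pytest.raises(ValidationError, match="diagonal"):
            simulate_latent(SimulationConfig(
                spearman_target=((0.9, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))))


class TestSimulateIC25:
    def test_minmax_anchoring(self):
        cfg = SimulationConfig(
            treatments=(TreatmentDesign("ox", "uM", (1.0, 10.0, 100.0), (0.0, 3.0)),),
            spearman_target=((1.0,),), planted_sets=(), n_genes=10,
        )
        latent = pd.DataFrame({"ox": [-1.2, 0.3, 2.0]}, index=["A", "B", "C"])
        ic25 = simulate_ic25(latent, cfg)
        assert ic25.loc["A", "ox"] == pytest.approx(1.0)  # min -> 10^0
        assert ic25.loc["C", "ox"] == pytest.approx(1000.0)  # max -> 10^3

    def test_degenerate_latent_maps_to_midpoint(self):
        cfg = SimulationConfig(
            treatments=(TreatmentDesign("ox", "uM", (1.0, 10.0), (1.0, 3.0)),),
            spearman_target=((1.0,),), planted_sets=(), n_genes=10,
        )
        latent = pd.DataFrame({"ox": [0.5, 0.5, 0.5]}, index=["A", "B", "C"])
        assert np.allclose(simulate_ic25(latent, cfg)["ox"], 100.0)

    def test_monotone_in_latent(self):
        cfg = SimulationConfig(seed=3)
        latent = simulate_latent(cfg)
        ic25 = simulate_ic25(latent, cfg)
        for trt in cfg.treatment_names:
            order_latent = latent[trt].sort_values().index
            order_ic25 = ic25[trt].sort_values().index
            assert list(order_latent) == list(order_ic25)

    def test_bad_range_rejected(self):
        with pytest.raises(ValidationError, match="lo"):
            SimulationConfig(
                treatments=(TreatmentDesign("ox", "uM", (1.0, 10.0), (3.0, 1.0)),),
                spearman_target=((1.0,),), planted_sets=(), n_genes=10,
            ).validate()


def _prep(samples, sheet, annotation, hk="RPL13A"):
    return filter_annotated(
        housekeeping_normalize(average_replicates(samples, sheet), hk), annotation
    )


class TestSimulateExpression:
    def test_null_effect_size_behaves_like_background(self):
        cfg = SimulationConfig(
            seed=12, n_genes=1200,
            planted_sets=(PlantedSet(("plasma",), 200, 0.0, +1),),
            unannotated_fraction=0.0,
        )
        lat = simulate_latent(cfg)
        samples, sheet, ann, truth = simulate_expression(lat, cfg)
        mat = _prep(samples, sheet, ann)
        res = screen(mat, truth.true_ic25["plasma"], "plasma")
        planted = truth.planted_gene_table["gene"]
        hit_rate = (res.records.set_index("gene").loc[planted, "p"] < 0.05).mean()
        assert abs(hit_rate - 0.05) < 0.05

    def test_strong_noiseless_planting_ranks_above_background(self):
        cfg = SimulationConfig(
            seed=4, n_genes=200, expression_noise_sd=0.0,
            planted_sets=(PlantedSet(("plasma", "h2o2"), 10, 0.9, +1),),
            unannotated_fraction=0.0,
        )
        lat = simulate_latent(cfg)
        samples, sheet, ann, truth = simulate_expression(lat, cfg)
        mat = _prep(samples, sheet, ann)
        planted = set(truth.planted_gene_table["gene"])
        for trt in ("plasma", "h2o2"):
            rec = screen(mat, truth.true_ic25[trt], trt).records
            top10 = set(rec.nsmallest(10, "p")["gene"])
            assert top10 == planted

    def test_housekeeping_row_zero_after_normalization(self, small_panel):
        mat = housekeeping_normalize(
            average_replicates(small_panel.expression_samples, small_panel.sample_sheet),
            small_panel.config.housekeeping_gene,
        )
        assert np.allclose(mat.values.loc["RPL13A"], 0.0)

    def test_planted_genes_each_appear_once(self, small_panel):
        table = small_panel.truth.planted_gene_table
        assert table["gene"].is_unique
        assert len(table) == sum(ps.n_genes for ps in small_panel.config.planted_sets)

    def test_excess_effect_size_rejected(self):
        with pytest.raises(ValidationError, match="rho"):
            SimulationConfig(planted_sets=(PlantedSet(("plasma",), 5, 1.0, +1),)).validate()


class TestSimulateDoseResponse:
    def test_noiseless_round_trip(self):
        cfg = SimulationConfig(seed=5, viability_cv=0.0, planted_sets=(), n_genes=10)
        lat = simulate_latent(cfg)
        ic25 = simulate_ic25(lat, cfg)
        curves = normalize_viability(simulate_dose_response(ic25, cfg))
        for (line, trt), curve in curves.items():
            est = fit_ic25(curve)
            assert est.ic25 == pytest.approx(ic25.loc[line, trt], rel=1e-3)

    def test_noiseless_roundtrip_preserves_ranking(self):
        cfg = SimulationConfig(seed=6, viability_cv=0.0, planted_sets=(), n_genes=10)
        lat = simulate_latent(cfg)
        ic25 = simulate_ic25(lat, cfg)
        curves = normalize_viability(simulate_dose_response(ic25, cfg))
        for trt in cfg.treatment_names:
            fitted = pd.Series({
                line: fit_ic25(c).ic25
                for (line, t), c in curves.items() if t == trt
            })
            assert rank_sensitivity(fitted).equals(rank_sensitivity(ic25[trt]))

    def test_grid_far_above_ic25_flags_extrapolated(self):
        cfg = SimulationConfig(
            seed=8, viability_cv=0.0, planted_sets=(), n_genes=10,
            treatments=(TreatmentDesign("ox", "uM", (100.0, 300.0, 1000.0), (0.0, 0.5)),),
            spearman_target=((1.0,),),
        )
        lat = simulate_latent(cfg)
        ic25 = simulate_ic25(lat, cfg)  # IC25 in [1, 3.16], grid >= 100 = >10x above
        curves = normalize_viability(simulate_dose_response(ic25, cfg))
        for curve in curves.values():
            est = fit_ic25(curve)
            if est.converged:
                assert est.extrapolated

    def test_determinism_of_full_panel(self, small_config):
        a = simulate_panel(small_config)
        b = simulate_panel(small_config)
        pd.testing.assert_frame_equal(a.dose_response, b.dose_response)
        pd.testing.assert_frame_equal(a.expression_samples, b.expression_samples)
        pd.testing.assert_frame_equal(a.annotation, b.annotation)

    def test_control_rows_present(self, small_panel):
        dr = small_panel.dose_response
        for (line, trt), grp in dr.groupby(["cell_line", "treatment"]):
            assert (grp["dose"] == 0).any()


class TestWritePanel(object):
    def test_files_written_and_readable(self, small_panel, tmp_path):
        from rospanel import io

        paths = write_panel(small_panel, tmp_path)
        assert set(paths) == {
            "dose_response", "expression", "sample_sheet",
            "annotation", "ground_truth", "config",
        }
        df = io.read_dose_response(paths["dose_response"])
        pd.testing.assert_frame_equal(
            df, small_panel.dose_response, check_dtype=False
        )
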