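"""Tests of the length-class / MSE / ANOVA-LSD-BH validation pipeline."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from entocalib import (
    InsectRecord,
    SizeRange,
    ThermalSummationParams,
    bin_by_length,
    compare_models,
    compare_models_anova,
    default_spec,
    extreme_subset,
    fit_three_models,
    generate,
    mse,
    read_records,
    write_records,
)
from entocalib.validation import ConstantLine, snap_half_mm


def _rec(length, k, species="test"):
    return InsectRecord(species=species, length_mm=length, true_k=k)


class TestBinning:
    def test_snap_half_mm_grid(self):
        assert list(snap_half_mm([15.2, 15.25, 15.3, 15.74, 15.75])) == [
            15.0, 15.5, 15.5, 15.5, 16.0,
        ]

    def test_singleton_classes(self):
        classes = bin_by_length([_rec(15.0, 400.0), _rec(16.0, 390.0)])
        assert [(c.length_mm, c.median, c.count) for c in classes] == [
            (15.0, 400.0, 1), (16.0, 390.0, 1),
        ]

    def test_medians_are_order_statistics(self):
        records = (
            [_rec(15.0, k) for k in (400, 410, 420)]
            + [_rec(15.5, k) for k in (500, 520)]
        )
        classes = bin_by_length(records)
        assert classes[0].median == 410
        assert classes[1].median == 510

    def test_full_grid_class_count_c_maxillosus(self):
        # Half-mm coverage of 15-24 mm gives (24-15)/0.5 + 1 = 19 classes.
        records = [_rec(l, 400.0) for l in np.arange(15.0, 24.01, 0.5)]
        assert len(bin_by_length(records)) == 19

    def test_missing_true_k_excluded_with_warning(self):
        records = [_rec(15.0, 400.0), InsectRecord("test", 15.5)]
        with pytest.warns(UserWarning, match="without a true-k"):
            classes = bin_by_length(records)
        assert len(classes) == 1


class TestMse:
    def test_perfect_fit(self):
        classes = bin_by_length([_rec(15, 400.0), _rec(16, 400.0)])
        assert mse(classes, ConstantLine(400.0)) == 0.0

    def test_single_class_squared_residual(self):
        classes = bin_by_length([_rec(15, 403.0)])
        assert mse(classes, ConstantLine(400.0)) == 9.0

    def test_mean_of_squared_residuals(self):
        classes = bin_by_length([_rec(15, 403.0), _rec(16, 399.0)])
        assert mse(classes, ConstantLine(400.0)) == 5.0


class TestFitThreeModels:
    def test_noise_free_classes_on_calibration_line(self, nlit_params):
        size_range = SizeRange(15, 25)
        from entocalib import calibration_line

        line = calibration_line(nlit_params, size_range)
        lengths = np.arange(15.0, 25.01, 0.5)
        records = [_rec(float(l), float(line.predict(l))) for l in lengths]
        classes = bin_by_length(records)
        models = fit_three_models(classes, nlit_params, size_range)
        assert models.rma.slope == pytest.approx(models.k_c.slope, abs=1e-6)
        assert mse(classes, models.k_c) == pytest.approx(0.0, abs=1e-18)
        assert mse(classes, models.constant) > mse(classes, models.rma)

    def test_flat_medians_favour_constant_k(self, nlit_params):
        lengths = np.arange(15.0, 25.01, 0.5)
        records = [_rec(float(l), nlit_params.k) for l in lengths]
        classes = bin_by_length(records)
        from entocalib import calibration_line

        k_c = calibration_line(nlit_params, SizeRange(15, 25))
        assert mse(classes, ConstantLine(nlit_params.k)) == 0.0
        assert mse(classes, k_c) > 0.0

    def test_synthetic_emulation_mse_ordering(self, nlit_params):
        records = generate(default_spec("N_littoralis", seed=1))
        classes = bin_by_length(records)
        models = fit_three_models(classes, nlit_params)
        errs = {
            "RMA": mse(classes, models.rma),
            "K_c": mse(classes, models.k_c),
            "constant_k": mse(classes, models.constant),
        }
        assert errs["RMA"] < errs["constant_k"]
        assert errs["K_c"] < errs["constant_k"]

    def test_rma_loss_minimal_among_same_sign_centroid_lines(self, nlit_params):
        # RMA passes through the data centroid by construction; among
        # centroid lines with the same slope sign its product loss is
        # minimal (the defining optimality of the model-II fit).
        from entocalib import rma_loss

        records = generate(default_spec("N_littoralis", seed=5))
        classes = bin_by_length(records)
        models = fit_three_models(classes, nlit_params)
        lengths = np.array([c.length_mm for c in classes])
        medians = np.array([c.median for c in classes])
        cx, cy = lengths.mean(), medians.mean()
        base = rma_loss(lengths, medians, models.rma)
        for slope in np.linspace(0.2 * models.rma.slope, 3 * models.rma.slope, 200):
            trial = type(models.rma)(
                slope=float(slope), intercept=float(cy - slope * cx),
                n=models.rma.n, correlation=models.rma.correlation,
                sd_x=models.rma.sd_x, sd_y=models.rma.sd_y,
            )
            assert rma_loss(lengths, medians, trial) >= base - 1e-9


class TestExtremeSubset:
    def test_matches_percentile_definition_on_1_to_100(self):
        records = [_rec(float(l), 0.0) for l in range(1, 101)]
        sub = extreme_subset(records)
        lengths = sorted(r.length_mm for r in sub.records)
        low = float(np.percentile(np.arange(1.0, 101.0), 33))
        high = float(np.percentile(np.arange(1.0, 101.0), 66))
        assert sub.low_threshold == low and sub.high_threshold == high
        assert lengths == [l for l in range(1, 101) if l < low or l > high]

    def test_identical_lengths_give_empty_subset_error(self):
        records = [_rec(15.0, 1.0) for _ in range(10)]
        with pytest.raises(ValueError, match="empty"):
            extreme_subset(records)

    def test_c_maxillosus_emulation_thresholds(self):
        # Thresholds land near the 19/21 mm cutoffs of the source analysis.
        records = generate(default_spec("C_maxillosus", seed=2))
        sub = extreme_subset(records)
        assert abs(sub.low_threshold - 19.0) <= 1.5
        assert abs(sub.high_threshold - 21.0) <= 1.5

    def test_invalid_percentiles_rejected(self):
        records = [_rec(float(l), 0.0) for l in range(1, 10)]
        with pytest.raises(ValueError):
            extreme_subset(records, 66, 33)


class TestAnovaLsdBh:
    def test_identical_groups_give_f_zero_p_one(self):
        g = np.array([1.0, 2.0, 3.0])
        comp = compare_models_anova({"RMA": g, "K_c": g, "constant_k": g})
        assert comp.anova_f == 0.0
        assert comp.anova_p == 1.0
        assert all(pc.p_adjusted == 1.0 for pc in comp.pairwise)

    def test_bh_closed_form_step_up(self):
        adjusted = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert list(np.round(adjusted, 10)) == [0.03, 0.03, 0.03]
        # From-scratch step-up oracle: p_(i) * n / i with cumulative minimum
        # from the largest rank downward.
        raw = np.array([0.01, 0.02, 0.03])
        scaled = raw * 3 / np.arange(1, 4)
        stepped = np.minimum.accumulate(scaled[::-1])[::-1]
        assert np.allclose(adjusted, stepped)

    def test_textbook_anova_oracle(self):
        # Hand computation for (1,2,3), (1,2,3), (7,8,9):
        # SSB = 72, SSW = 6, F = 36 on (2, 6) df.
        from scipy import stats

        comp = compare_models_anova(
            {"RMA": [1, 2, 3], "K_c": [1, 2, 3], "constant_k": [7, 8, 9]}
        )
        assert comp.anova_f == pytest.approx(36.0)
        assert comp.anova_p == pytest.approx(float(stats.f.sf(36.0, 2, 6)))
        by_pair = {(pc.model_a, pc.model_b): pc for pc in comp.pairwise}
        equal = by_pair[("RMA", "K_c")]
        assert equal.t_statistic == pytest.approx(0.0)
        assert equal.p_raw == pytest.approx(1.0)
        # LSD t for means 2 vs 8 with MSW = 1: t = -6 / sqrt(2/3), df = 6.
        t_expected = -6.0 / np.sqrt(2.0 / 3.0)
        diff = by_pair[("RMA", "constant_k")]
        assert diff.t_statistic == pytest.approx(t_expected)
        assert diff.p_raw == pytest.approx(
            float(2 * stats.t.sf(abs(t_expected), 6))
        )

    def test_adjusted_p_at_least_raw_and_order_invariant(self):
        rng = np.random.default_rng(3)
        groups = {
            "RMA": rng.exponential(1.0, 8),
            "K_c": rng.exponential(1.5, 8),
            "constant_k": rng.exponential(8.0, 8),
        }
        comp = compare_models_anova(groups)
        for pc in comp.pairwise:
            assert pc.p_adjusted >= pc.p_raw - 1e-15
        reordered = compare_models_anova(
            {k: groups[k] for k in ["constant_k", "RMA", "K_c"]}
        )
        original = {
            frozenset((pc.model_a, pc.model_b)): pc.p_adjusted
            for pc in comp.pairwise
        }
        for pc in reordered.pairwise:
            assert original[frozenset((pc.model_a, pc.model_b))] == pytest.approx(
                pc.p_adjusted
            )

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_models_anova({"RMA": [1.0], "K_c": [1.0], "constant_k": [1.0]})


class TestPipeline:
    def test_deterministic_end_to_end(self, nlit_params):
        records = generate(default_spec("N_littoralis", seed=9))
        a = compare_models(records, nlit_params, extremes=True)
        b = compare_models(records, nlit_params, extremes=True)
        assert a.mse_ == b.mse_
        assert a.anova_f == b.anova_f
        assert [pc.p_adjusted for pc in a.pairwise] == [
            pc.p_adjusted for pc in b.pairwise
        ]

    def test_summary_reports_all_models(self, nlit_params):
        records = generate(default_spec("N_littoralis", seed=9))
        text = compare_models(records, nlit_params, extremes=True).summary()
        for token in ("RMA", "K_c", "constant_k", "ANOVA", "Benjamini"):
            assert token in text

    def test_records_csv_round_trip(self, tmp_path):
        records = generate(default_spec("C_maxillosus", seed=4))[:20]
        path = tmp_path / "records.csv"
        write_records(records, path)
        back = read_records(path)
        assert len(back) == 20
        assert back[0].length_mm == records[0].length_mm
        assert back[0].true_k == pytest.approx(records[0].true_k)
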