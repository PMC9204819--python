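import numpy as np
import pandas as pd
import pytest

from notchbench import (
    FilterSchema,
    GroundTruth,
    SimParams,
    aggregate,
    apply_filters,
    classify_and_score,
    compare_notch_filtering,
    fit_moderated_test,
    notch_exposure,
    run_grid,
    simulate_experiment,
)
from notchbench.exceptions import IntegrityError


def _truth(features):
    species = {f: s for f, s in features.items()}
    expected = {
        ("2x_vs_1x", "yeast"): 1.0,
        ("2x_vs_1x", "human"): float(np.log2(90 / 95)),
        ("6x_vs_1x", "yeast"): float(np.log2(6)),
        ("6x_vs_1x", "human"): float(np.log2(70 / 95)),
    }
    return GroundTruth(protein_species=species, peptide_species={}, expected=expected)


def _results(rows, contrast="6x_vs_1x"):
    return pd.DataFrame(
        [{"feature_id": f, "contrast": contrast, "log2fc": fc, "q": q} for f, fc, q in rows]
    )


class TestClassifyAndScore:
    def test_closed_form_counts(self):
        truth = _truth({"Y1": "yeast", "Y2": "yeast", "H1": "human"})
        res = _results([("Y1", 2.5, 0.001), ("Y2", -1.0, 0.001), ("H1", -0.4, 0.5)])
        s = classify_and_score(res, truth)
        assert (s.tp, s.fp, s.fn) == (1, 1, 1)
        assert s.precision == s.recall == s.f1 == 0.5

    def test_perfect_classifier(self):
        truth = _truth({"Y1": "yeast", "H1": "human"})
        res = _results([("Y1", 2.5, 0.0), ("H1", -0.4, 0.0)])
        s = classify_and_score(res, truth)
        assert s.precision == s.recall == s.f1 == 1.0

    def test_threshold_is_strict(self):
        truth = _truth({"Y1": "yeast"})
        res = _results([("Y1", 2.5, 0.01)])  # q exactly at the 1% threshold
        s = classify_and_score(res, truth)
        assert (s.tp, s.fn) == (0, 1)

    def test_fold_change_error_uses_species_truth(self):
        truth = _truth({"Y1": "yeast", "H1": "human"})
        res = _results([("Y1", 2.0, 0.0), ("H1", -0.5, 0.0)])
        s = classify_and_score(res, truth)
        assert s.median_abs_error["yeast"] == pytest.approx(abs(2.0 - np.log2(6)))
        assert s.median_abs_error["human"] == pytest.approx(abs(-0.5 - np.log2(70 / 95)))

    def test_permutation_invariance(self):
        truth = _truth({f"Y{i}": "yeast" for i in range(6)})
        rows = [(f"Y{i}", 2.5 + 0.1 * i, 0.001 * (i + 1)) for i in range(6)]
        a = classify_and_score(_results(rows), truth)
        b = classify_and_score(_results(rows[::-1]), truth)
        assert (a.tp, a.fp, a.fn, a.f1) == (b.tp, b.fp, b.fn, b.f1)

    def test_unknown_species_raises(self):
        truth = _truth({"Y1": "yeast"})
        with pytest.raises(IntegrityError):
            classify_and_score(_results([("ZZ", 1.0, 0.0)]), truth)


@pytest.fixture(scope="module")
def grid_out(design):
    from notchbench import NotchRegion, center_median_normalize

    params = SimParams(seed=11, n_yeast_proteins=60, n_human_proteins=180,
                       psm_per_protein=(4.0, 0.5))
    table, truth = simulate_experiment(design, params)
    table = center_median_normalize(table)
    return table, truth, run_grid(table, NotchRegion(), truth)


class TestRunGrid:
    def test_output_shape_36_schemas_by_2_contrasts(self, grid_out):
        _, _, summaries = grid_out
        assert len(summaries) == 36 * 2
        assert summaries["schema"].nunique() == 36

    def test_notch_removal_never_gains_features(self, grid_out):
        _, _, summaries = grid_out
        wide = summaries[summaries.contrast == "6x_vs_1x"].set_index("schema")["n_features"]
        for name in wide.index:
            if name.endswith("notchkeep"):
                partner = name.replace("notchkeep", "notchremove")
                assert wide[partner] <= wide[name]

    def test_grid_deterministic(self, grid_out, design, notch):
        table, truth, summaries = grid_out
        again = run_grid(table, notch, truth)
        pd.testing.assert_frame_equal(summaries, again)

    def test_noise_free_f1_is_one(self, design, notch):
        params = SimParams(seed=0, n_yeast_proteins=15, n_human_proteins=30,
                           reporter_noise_sd=0.0, interference_dist=0.0,
                           notch=None, missing_rate=0.0)
        table, truth = simulate_experiment(design, params)
        matrix = aggregate(table, "protein")
        fit = fit_moderated_test(matrix.log2_values(), table.channels.group_of(),
                                 ["6x_vs_1x"])
        s = classify_and_score(fit.for_contrast("6x_vs_1x"), truth)
        assert s.f1 == 1.0


class TestCompareNotchFiltering:
    def test_unaffected_features_excluded_and_identical_runs_zero(self):
        truth = _truth({"Y1": "yeast", "Y2": "yeast"})
        res = _results([("Y1", 2.0, 0.001), ("Y2", 2.4, 0.001)])
        deltas, lost = compare_notch_filtering(res, res, truth, affected={"Y1"})
        assert deltas["feature_id"].tolist() == ["Y1"]
        assert deltas["delta"].tolist() == [0.0]
        assert lost == []

    def test_lost_features_reported_separately(self):
        truth = _truth({"Y1": "yeast", "Y2": "yeast"})
        without = _results([("Y1", 2.0, 0.001), ("Y2", 2.4, 0.001)])
        with_f = _results([("Y1", 2.1, 0.001)])
        deltas, lost = compare_notch_filtering(with_f, without, truth,
                                               affected={"Y1", "Y2"})
        assert deltas["feature_id"].tolist() == ["Y1"]
        assert lost == ["Y2"]

    def test_delta_sign_convention(self):
        # without-filtering estimate closer to truth -> delta negative
        truth = _truth({"Y1": "yeast"})
        without = _results([("Y1", float(np.log2(6)) - 0.05, 0.001)])
        with_f = _results([("Y1", float(np.log2(6)) - 0.30, 0.001)])
        deltas, _ = compare_notch_filtering(with_f, without, truth, affected={"Y1"})
        assert deltas["delta"].iloc[0] == pytest.approx(0.05 - 0.30)

    def test_simulated_direction_filtering_hurts(self, design, notch):
        params = SimParams(seed=11)
        table, truth = simulate_experiment(design, params)
        from notchbench import center_median_normalize

        table = center_median_normalize(table)
        keep, _ = apply_filters(table, FilterSchema(0.5, 10.0, 10.0, False), notch)
        rem, _ = apply_filters(table, FilterSchema(0.5, 10.0, 10.0, True), notch)
        fk, fr = aggregate(keep), aggregate(rem)
        expo = notch_exposure(keep, fk, notch)
        affected = set(expo.index[expo["max_fraction"] > 0])
        groups = table.channels.group_of()
        fit_k = fit_moderated_test(fk.log2_values(), groups, ["6x_vs_1x"])
        fit_r = fit_moderated_test(fr.log2_values(), groups, ["6x_vs_1x"])
        deltas, _ = compare_notch_filtering(
            fit_r.for_contrast("6x_vs_1x"), fit_k.for_contrast("6x_vs_1x"), truth, affected
        )
        yeast = deltas[deltas.species == "yeast"]
        assert len(yeast) > 0
        assert yeast["delta"].median() < 0
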