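import numpy as np
import pytest

from notchbench import (
    NotchRegion,
    apply_notch_artifact,
    detect_notch,
    notch_stats,
    predict_expected,
    tag_vs_comparator,
    underestimation_fraction,
)
from notchbench.exceptions import ParameterError


class TestNotchStats:
    def test_all_above_upper_gives_zero(self, make_table, notch):
        table = make_table([{"intensities": [2**6.0] * 10}] * 3)
        stats = notch_stats(table, notch)
        assert (stats["frac_below_upper"] == 0).all()

    def test_direct_count(self, make_table, notch):
        # 2 PSMs x 10 channels = 20 values, 3 below the upper boundary
        low, high = 2**5.0, 2**8.0
        table = make_table(
            [
                {"intensities": [low, low, high, high, high, high, high, high, high, high]},
                {"intensities": [high, low, high, high, high, high, high, high, high, high]},
            ]
        )
        stats = notch_stats(table, notch)
        assert stats.loc["overall", "frac_below_upper"] == pytest.approx(3 / 20)
        assert stats.loc["overall", "frac_in_band"] == pytest.approx(3 / 20)
        assert stats.loc[table.channels.labels[0], "frac_below_upper"] == pytest.approx(0.5)

    def test_missing_excluded_from_denominator(self, make_table, notch):
        table = make_table([{"intensities": [2**5.0] + [None] * 9}])
        stats = notch_stats(table, notch)
        assert stats.loc["overall", "n"] == 1
        assert stats.loc["overall", "frac_below_upper"] == 1.0

    def test_simulated_artifact_fraction_positive(self, sim_small, notch):
        table, _ = sim_small
        stats = notch_stats(table, notch)
        assert stats.loc["overall", "frac_below_upper"] > 0

    def test_invariant_under_global_scaling(self, sim_small, notch):
        table, _ = sim_small
        stats = notch_stats(table, notch)
        scaled = table.with_data(
            table.data.assign(**{l: table.data[l] * 8.0 for l in table.channels.labels})
        )
        shifted = NotchRegion(notch.lower + 3.0, notch.upper + 3.0)
        stats_scaled = notch_stats(scaled, shifted)
        assert np.allclose(
            stats["frac_below_upper"], stats_scaled["frac_below_upper"]
        )


class TestDetectNotch:
    def test_recovers_simulated_boundaries(self, notch):
        rng = np.random.default_rng(0)
        log2x = rng.normal(10.0, 2.2, 50_000)
        log2x = apply_notch_artifact(log2x, notch, slope=1.5)
        region = detect_notch(2.0**log2x)
        assert region is not None
        assert abs(region.lower - notch.lower) <= 0.25
        assert abs(region.upper - notch.upper) <= 0.25

    def test_replicate_recovery_rate(self, notch):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            log2x = apply_notch_artifact(rng.normal(10.0, 2.2, 20_000), notch, slope=1.5)
            region = detect_notch(2.0**log2x)
            if (
                region is not None
                and abs(region.lower - notch.lower) <= 0.25
                and abs(region.upper - notch.upper) <= 0.25
            ):
                hits += 1
        assert hits >= 45  # >= 90% of 50 seeded replicates

    def test_unimodal_sample_yields_none(self):
        rng = np.random.default_rng(1)
        assert detect_notch(2.0 ** rng.normal(10.0, 2.0, 50_000)) is None

    def test_carved_band_detected_inside_bounds(self):
        rng = np.random.default_rng(2)
        log2x = rng.normal(7.0, 2.0, 50_000)
        log2x = log2x[(log2x <= 4.0) | (log2x >= 6.0)]
        region = detect_notch(2.0**log2x)
        assert region is not None
        assert region.lower >= 4.0 - 0.15 and region.upper <= 6.0 + 0.15

    def test_empty_input_raises(self):
        with pytest.raises(ParameterError):
            detect_notch(np.array([]))

    def test_small_sample_warns(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="unstable"):
            detect_notch(2.0 ** rng.normal(10, 2, 500))


class TestPredictExpected:
    def test_hand_computed_group(self, make_table):
        table = make_table(
            [
                {"sequence": "AAA",
                 "intensities": [100.0, 200.0, 300.0] + [None] * 7},
                {"sequence": "AAA",
                 "intensities": [60.0, 90.0, None] + [None] * 7},
            ]
        )
        # top PSM has missing channels -> group dropped entirely
        assert predict_expected(table).entries.empty

        table = make_table(
            [
                {"sequence": "AAA", "intensities": [100.0, 200.0, 300.0] * 3 + [100.0]},
                {"sequence": "AAA",
                 "intensities": [60.0, 90.0, None] + [None] * 7},
            ]
        )
        preds = predict_expected(table)
        e = preds.entries
        assert len(e) == 2
        # r = (60 + 90) / (100 + 200) = 0.5 -> predictions 50 and 100
        assert e["predicted"].tolist() == [50.0, 100.0]
        assert e["observed"].tolist() == [60.0, 90.0]
        assert preds.groups["top_psm_id"].tolist() == ["psm0"]

    def test_singleton_groups_contribute_nothing(self, make_table):
        table = make_table([{"sequence": "AAA"}, {"sequence": "BBB"}])
        preds = predict_expected(table)
        assert preds.entries.empty and preds.groups.empty

    def test_proportional_psm_predicted_exactly(self, make_table):
        base = np.linspace(100, 1000, 10)
        table = make_table(
            [
                {"sequence": "AAA", "intensities": list(base)},
                {"sequence": "AAA", "intensities": list(0.5 * base)},
            ]
        )
        e = predict_expected(table).entries
        assert np.allclose(e["observed"], e["predicted"])

    def test_scale_equivariance(self, make_table):
        rng = np.random.default_rng(4)
        rows = []
        for seq in ("AAA", "BBB"):
            for _ in range(3):
                rows.append({"sequence": seq, "intensities": list(rng.uniform(50, 500, 10))})
        table = make_table(rows)
        e1 = predict_expected(table).entries

        k = 0.5  # keeps the scaled PSM non-top
        data = table.data.copy()
        target = e1[e1.sequence == "AAA"]["psm_id"].iloc[0]
        mask = data["psm_id"] == target
        for label in table.channels.labels:
            data.loc[mask, label] *= k
        e2 = predict_expected(table.with_data(data)).entries

        scaled = e2[e2.psm_id == target]["predicted"].to_numpy()
        orig = e1[e1.psm_id == target]["predicted"].to_numpy()
        assert np.allclose(scaled, k * orig)
        other = e1[e1.sequence == "BBB"]["predicted"].to_numpy()
        other2 = e2[e2.sequence == "BBB"]["predicted"].to_numpy()
        assert np.allclose(other, other2)


class TestUnderestimationFraction:
    def test_tie_counts_as_not_below(self, make_table):
        base = [float(x) for x in np.linspace(100, 1000, 10)]
        table = make_table(
            [
                {"sequence": "AAA", "intensities": base},
                {"sequence": "AAA", "intensities": [0.5 * x for x in base]},
            ]
        )
        preds = predict_expected(table)  # proportional -> observed == predicted
        out = underestimation_fraction(preds, bin_width=0.5)
        assert (out["frac_below"] == 0).all()

    def test_symmetric_noise_near_half(self, sim_small_nonotch):
        table, _ = sim_small_nonotch
        preds = predict_expected(table)
        out = underestimation_fraction(preds, bin_width=0.5)
        big = out[out["n"] >= 200]
        pooled = (big["n"] * big["frac_below"]).sum() / big["n"].sum()
        assert 0.45 < pooled < 0.55

    def test_notch_bins_predominantly_underestimated(self, sim_small, notch):
        table, _ = sim_small
        preds = predict_expected(table)
        out = underestimation_fraction(preds, bin_width=0.5)
        sub = out[(out["bin_right"] <= notch.upper) & (out["n"] >= 20)]
        pooled = (sub["n"] * sub["frac_below"]).sum() / sub["n"].sum()
        assert pooled > 0.55  # clearly above the 0.5 no-artifact baseline

    def test_invalid_bin_width(self, sim_small):
        table, _ = sim_small
        with pytest.raises(ParameterError):
            underestimation_fraction(predict_expected(table), bin_width=0.0)


class TestTagVsComparator:
    def test_identical_channels_give_zero(self, make_table, channels):
        table = make_table([{"intensities": [250.0] * 10}])
        entries, _ = tag_vs_comparator(
            table, channels.group_channels("6x"), channels.group_channels("1x")
        )
        assert np.allclose(entries["diff"], 0.0)

    def test_noise_free_design_ratio(self, design, channels):
        from notchbench import SimParams, simulate_experiment

        params = SimParams(seed=0, n_yeast_proteins=5, n_human_proteins=5,
                           reporter_noise_sd=0.0, interference_dist=0.0,
                           notch=None, missing_rate=0.0)
        table, _ = simulate_experiment(design, params)
        yeast = table.with_data(table.data[table.data.species == "yeast"])
        entries, _ = tag_vs_comparator(
            yeast, channels.group_channels("6x"), channels.group_channels("1x")
        )
        assert np.allclose(entries["diff"], np.log2(6))

    def test_overlapping_channel_sets_raise(self, make_table, channels):
        table = make_table([{}])
        with pytest.raises(ParameterError):
            tag_vs_comparator(table, channels.labels[:2], channels.labels[1:3])

    def test_notch_inflates_low_intensity_differences(self, sim_small, channels, notch):
        table, _ = sim_small
        yeast = table.with_data(table.data[table.data.species == "yeast"])
        entries, _ = tag_vs_comparator(
            yeast, channels.group_channels("6x"), channels.group_channels("1x")
        )
        sub = entries[entries["target_log2"] < notch.upper]
        assert len(sub) > 0
        assert sub["diff"].median() > np.log2(6)
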