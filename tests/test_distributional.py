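"""Delta-plots, quantile binning, CAFs, Simon summaries."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simondelta.distributional import (
    bin_quartiles,
    conditional_accuracy,
    delta_plot,
    segment_slope,
    select_caf_trials,
    simon_summary,
)

from conftest import make_trials


def brute_force_bins(rts, trial_indices, n_bins):
    """Independent oracle: stable sort + explicit index arithmetic."""
    order = sorted(range(len(rts)), key=lambda i: (rts[i], trial_indices[i]))
    bins = [0] * len(rts)
    for pos, idx in enumerate(order):
        bins[idx] = pos * n_bins // len(rts) + 1
    return bins


class TestBinQuartiles:
    def test_eight_distinct_rts_four_even_bins(self):
        cell = pd.DataFrame({"rt_ms": [310, 300, 340, 330, 350, 320, 370, 360],
                             "trial_index": range(1, 9)})
        ba = bin_quartiles(cell, 4)
        assert ba.bin_counts == [2, 2, 2, 2]
        assert set(cell.index[ba.bin_of_trial == 1]) == {0, 1}

    def test_ten_rts_floor_rule_counts(self):
        cell = pd.DataFrame({"rt_ms": np.arange(10) * 10.0 + 300,
                             "trial_index": range(1, 11)})
        ba = bin_quartiles(cell, 4)
        assert ba.bin_counts == [3, 2, 3, 2]

    def test_all_ties_broken_by_trial_index(self):
        tied = pd.DataFrame({"rt_ms": [400.0] * 7, "trial_index": range(1, 8)})
        distinct = pd.DataFrame({"rt_ms": np.arange(7) + 400.0,
                                 "trial_index": range(1, 8)})
        assert (bin_quartiles(tied, 4).bin_of_trial
                == bin_quartiles(distinct, 4).bin_of_trial).all()

    def test_too_few_trials_raises(self):
        cell = pd.DataFrame({"rt_ms": [400.0, 410.0], "trial_index": [1, 2]})
        with pytest.raises(ValueError, match="bins"):
            bin_quartiles(cell, 4)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(min_value=2, max_value=12))
        n_bins = data.draw(st.integers(min_value=2, max_value=n))
        rts = data.draw(st.lists(
            st.floats(min_value=100, max_value=1000, allow_nan=False),
            min_size=n, max_size=n))
        cell = pd.DataFrame({"rt_ms": rts, "trial_index": range(1, n + 1)})
        ba = bin_quartiles(cell, n_bins)
        assert ba.bin_of_trial.tolist() == brute_force_bins(
            rts, list(range(1, n + 1)), n_bins)
        assert sorted(ba.bin_counts, reverse=True)[0] \
            - sorted(ba.bin_counts)[0] <= 1


class TestSimonSummary:
    def test_two_stage_mean_matches_hand_arithmetic(self):
        # subject s01: congruent (400, 420) -> 410; incongruent (450, 470) -> 460
        # subject s02: congruent (300, 340) -> 320; incongruent (330, 350) -> 340
        rows = []
        for sid, cong, rts in [("s01", "congruent", (400, 420)),
                               ("s01", "incongruent", (450, 470)),
                               ("s02", "congruent", (300, 340)),
                               ("s02", "incongruent", (330, 350))]:
            rows += [{"subject_id": sid, "congruence": cong, "rt_ms": float(r)}
                     for r in rts]
        out = simon_summary(make_trials(rows))
        assert out["mean_rt_congruent"].item() == pytest.approx((410 + 320) / 2)
        assert out["mean_rt_incongruent"].item() == pytest.approx((460 + 340) / 2)
        assert out["effect_ms"].item() == pytest.approx(400 - 365)

    def test_identical_distributions_zero_effect(self):
        rows = [{"congruence": c, "rt_ms": float(r)}
                for c in ("congruent", "incongruent") for r in (400, 500, 600)]
        out = simon_summary(make_trials(rows))
        assert out["effect_ms"].item() == 0.0

    def test_missing_level_cell_flagged_undefined(self, caplog):
        rows = [{"congruence": "congruent", "rt_ms": 400.0}]
        with caplog.at_level(logging.WARNING, logger="simondelta"):
            out = simon_summary(make_trials(rows))
        assert np.isnan(out["effect_ms"].item())
        assert out["n_subjects"].item() == 0


def table_with_bin_means(con_means, inc_means, subject="s01", n_per_bin=2,
                         spread=4.0):
    """Trials whose per-bin means are forced to the given values."""
    rows = []
    for cong, means in (("congruent", con_means), ("incongruent", inc_means)):
        for m in means:
            rows.append({"subject_id": subject, "congruence": cong,
                         "rt_ms": m - spread / 2})
            rows.append({"subject_id": subject, "congruence": cong,
                         "rt_ms": m + spread / 2})
    return make_trials(rows)


class TestDeltaPlot:
    def test_forced_bin_means_give_exact_deltas(self):
        table = table_with_bin_means((400, 450, 500, 550),
                                     (430, 480, 520, 560))
        dp = delta_plot(table, n_bins=4)
        ps = dp.per_subject.sort_values("bin")
        assert ps["delta_ms"].tolist() == [30, 30, 20, 10]
        assert ps["x_ms"].tolist() == [415, 465, 510, 555]

    def test_identical_distributions_all_zero(self):
        table = table_with_bin_means((400, 450, 500, 550),
                                     (400, 450, 500, 550))
        dp = delta_plot(table, n_bins=4)
        assert (dp.per_subject["delta_ms"] == 0).all()
        slopes = segment_slope(dp, 3, 4)
        assert (slopes.per_subject["slope"] == 0).all()

    def test_subject_level_delta_identity(self, exp2_table):
        from simondelta.preprocess import apply_exclusions

        clean, _ = apply_exclusions(exp2_table)
        dp = delta_plot(clean)
        np.testing.assert_allclose(
            dp.per_subject["delta_ms"],
            dp.per_subject["rt_incongruent"] - dp.per_subject["rt_congruent"])
        np.testing.assert_allclose(
            dp.per_subject["x_ms"],
            (dp.per_subject["rt_incongruent"]
             + dp.per_subject["rt_congruent"]) / 2)

    def test_insufficient_trials_drops_subject_with_warning(self, caplog):
        table = pd.concat([
            table_with_bin_means((400, 450, 500, 550), (430, 480, 520, 560),
                                 subject="s01"),
            make_trials([{"subject_id": "s02", "congruence": "congruent",
                          "rt_ms": 400.0}]),
        ], ignore_index=True)
        with caplog.at_level(logging.WARNING, logger="simondelta"):
            dp = delta_plot(table, n_bins=4)
        assert dp.per_subject["subject_id"].unique().tolist() == ["s01"]
        assert "s02" in caplog.text

    def test_pooled_scope_single_series(self, exp1_table):
        from simondelta.preprocess import apply_exclusions

        clean, _ = apply_exclusions(exp1_table)
        dp = delta_plot(clean, scope="pooled")
        assert len(dp.per_subject) == 0
        assert set(dp.group["bin"]) == {1, 2, 3, 4}


class TestSegmentSlope:
    def test_hand_arithmetic(self):
        table = table_with_bin_means((400, 450, 500, 550),
                                     (430, 480, 520, 560))
        slopes = segment_slope(delta_plot(table, n_bins=4), 3, 4)
        assert slopes.per_subject["slope"].item() == pytest.approx(
            (10 - 20) / (555 - 510))
        assert round(slopes.group["slope_mean"].item(), 3) == -0.222

    def test_invalid_bin_pair_raises(self):
        table = table_with_bin_means((400, 450, 500, 550),
                                     (430, 480, 520, 560))
        dp = delta_plot(table, n_bins=4)
        with pytest.raises(ValueError):
            segment_slope(dp, 4, 3)


class TestCAF:
    def test_two_fastest_flagged_ke(self):
        rows = [{"congruence": "incongruent", "rt_ms": 300.0 + 10 * i,
                 "ke": i < 2} for i in range(8)]
        caf = conditional_accuracy(make_trials(rows), n_bins=4)
        assert caf.per_subject.sort_values("bin")["accuracy"].tolist() \
            == [0.0, 1.0, 1.0, 1.0]

    def test_no_ke_all_ones(self):
        rows = [{"congruence": "incongruent", "rt_ms": 300.0 + i}
                for i in range(8)]
        caf = conditional_accuracy(make_trials(rows), n_bins=4)
        assert (caf.per_subject["accuracy"] == 1.0).all()

    def test_all_ke_all_zeros(self):
        rows = [{"congruence": "incongruent", "rt_ms": 300.0 + i, "ke": True}
                for i in range(8)]
        caf = conditional_accuracy(make_trials(rows), n_bins=4)
        assert (caf.per_subject["accuracy"] == 0.0).all()

    def test_rejects_congruent_trials_and_empty_input(self):
        with pytest.raises(ValueError):
            conditional_accuracy(make_trials([{"congruence": "congruent",
                                               "rt_ms": 400.0}]))
        with pytest.raises(ValueError):
            conditional_accuracy(make_trials([]))

    def test_select_caf_trials_keeps_ke_drops_me(self, exp2_table):
        pool = select_caf_trials(exp2_table)
        assert (pool["congruence"] == "incongruent").all()
        assert pool["ke"].any()
        assert not pool["me"].any()
        assert pool["rt_ms"].between(100, 2000).all()

    def test_reproducible_and_bounded(self, exp2_table):
        pool = select_caf_trials(exp2_table)
        caf1 = conditional_accuracy(pool)
        caf2 = conditional_accuracy(pool)
        pd.testing.assert_frame_equal(caf1.per_subject, caf2.per_subject)
        assert caf1.per_subject["accuracy"].between(0, 1).all()
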