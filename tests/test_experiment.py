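import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from joinprod.segmented import round_half_away

from joinprod.experiment import (
    DELTA_Q_BINS,
    DELTA_R_BINS,
    BiasRecord,
    delta_q_bin,
    delta_r_bin,
    relative_bias,
    run_study,
    summarize_tables,
)


class TestRelativeBias:
    @pytest.mark.parametrize(
        "estimate,truth,expected",
        [(0.6, 0.5, 0.2), (0.5, 0.5, 0.0), (33.0, 32.0, 0.03125), (-2.0, 4.0, -1.5)],
    )
    def test_arithmetic(self, estimate, truth, expected):
        assert relative_bias(estimate, truth) == pytest.approx(expected)

    def test_zero_truth_raises(self):
        with pytest.raises(ZeroDivisionError):
            relative_bias(1.0, 0.0)


class TestBins:
    @pytest.mark.parametrize(
        "dr,expected",
        [
            (0.0, DELTA_R_BINS[0]),
            (0.20, DELTA_R_BINS[0]),   # closed on the right
            (0.2000001, DELTA_R_BINS[1]),
            (0.45, DELTA_R_BINS[1]),
            (0.46, DELTA_R_BINS[2]),
            (0.70, DELTA_R_BINS[2]),
        ],
    )
    def test_delta_r_boundaries(self, dr, expected):
        assert delta_r_bin(dr) == expected

    @pytest.mark.parametrize(
        "dq,expected",
        [
            (-2.0e-5, DELTA_Q_BINS[0]),
            (-1.5e-5, DELTA_Q_BINS[0]),
            (-1.0e-5, DELTA_Q_BINS[1]),
            (-5.0e-6, DELTA_Q_BINS[1]),
            (-4.9e-6, DELTA_Q_BINS[2]),
            (0.5e-5, DELTA_Q_BINS[2]),
        ],
    )
    def test_delta_q_boundaries(self, dq, expected):
        assert delta_q_bin(dq) == expected


def _record(sim_id, dr_bin=DELTA_R_BINS[0], dq_bin=DELTA_Q_BINS[2], biases=None):
    return BiasRecord(
        sim_id=sim_id,
        r1=0.6, r2=0.5, q1=2e-5, q2=2e-5,
        delta_r=0.1, delta_q=0.0,
        delta_r_bin=dr_bin, delta_q_bin=dq_bin,
        t1_star=32.0, t2_star=39.0, t_star=32, transition=7.0,
        n_converged_inits=5,
        biases=biases or {},
    )


class TestSummarizeTables:
    def test_unbiased_estimates_give_zero_columns(self):
        recs = [
            _record(i, biases={"s1_r1": 0.0, "s1_q1": 0.0}) for i in range(4)
        ]
        summ = summarize_tables(recs)
        col = summ.tables["r1"]["scenario1_mean"]
        assert col.iloc[0] == pytest.approx(0.0)

    def test_two_point_sample_mean_and_sd(self):
        recs = [
            _record(0, biases={"s1_r1": 0.10}),
            _record(1, biases={"s1_r1": -0.10}),
        ]
        tab = summarize_tables(recs).tables["r1"]
        assert tab["scenario1_mean"].iloc[0] == pytest.approx(0.0)
        assert tab["scenario1_sd"].iloc[0] == pytest.approx(14.142135, rel=1e-6)

    def test_empty_bins_are_missing_not_zero(self):
        recs = [_record(0, biases={"s1_r1": 0.2})]
        tab = summarize_tables(recs).tables["r1"]
        assert np.isnan(tab["scenario1_mean"].iloc[1])
        assert np.isnan(tab["scenario1_mean"].iloc[2])

    def test_bin_means_aggregate_to_overall_mean(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(30):
            dr_bin = DELTA_R_BINS[i % 3]
            recs.append(_record(i, dr_bin=dr_bin, biases={"s3_r1": rng.normal()}))
        summ = summarize_tables(recs)
        tab = summ.tables["r1"]
        counts = pd.Series([10, 10, 10], index=tab.index)
        weighted = (tab["scenario3_mean"] * counts).sum() / counts.sum()
        overall = np.mean([r.biases["s3_r1"] for r in recs]) * 100
        assert weighted == pytest.approx(overall)

    def test_joinpoint_statistics_and_ci(self):
        recs = [_record(i) for i in range(3)]
        recs[0].t1_star, recs[1].t1_star, recs[2].t1_star = 31.0, 32.0, 33.0
        summ = summarize_tables(recs)
        assert summ.t1_mean == pytest.approx(32.0)
        assert summ.t1_var == pytest.approx(1.0)
        lo, hi = summ.t1_relbias_ci
        assert lo < summ.t1_relbias_mean < hi

    def test_no_records_raises(self):
        with pytest.raises(ValueError):
            summarize_tables([])


class TestRunStudy:
    def test_reproducible_under_master_seed(self):
        recs_a, summ_a = run_study(n_sims=8, seed=123)
        recs_b, summ_b = run_study(n_sims=8, seed=123)
        df_a = pd.DataFrame([r.to_row() for r in recs_a])
        df_b = pd.DataFrame([r.to_row() for r in recs_b])
        pd.testing.assert_frame_equal(df_a, df_b)
        assert summ_a.n_rejected == summ_b.n_rejected

    def test_resumable_from_checkpoint(self, tmp_path):
        ck = tmp_path / "state.json"
        run_study(n_sims=6, seed=77, checkpoint_path=ck, checkpoint_every=3)
        assert ck.exists()
        recs_resumed, _ = run_study(
            n_sims=10, seed=77, checkpoint_path=ck, checkpoint_every=3
        )
        recs_direct, _ = run_study(n_sims=10, seed=77)
        df_a = pd.DataFrame([r.to_row() for r in recs_resumed])
        df_b = pd.DataFrame([r.to_row() for r in recs_direct])
        pd.testing.assert_frame_equal(df_a, df_b)

    def test_featureless_series_all_rejected(self):
        # no regime change and no noise: every joinpoint fit degenerates and
        # the rejection ceiling trips with zero accepted simulations
        overrides = dict(
            r1=0.6, r2=0.6, q1=2.0e-5, q2=2.0e-5, catch_noise_var=0.0
        )
        with pytest.raises(RuntimeError, match="ceiling"):
            run_study(
                n_sims=5, seed=1, param_overrides=overrides, max_reject_factor=4
            )

    def test_rejections_are_counted(self):
        _, summ = run_study(n_sims=5, seed=3)
        assert summ.n_accepted == 5
        assert summ.n_rejected >= 0

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            run_study(n_sims=1, seed=1, scenarios=(4,))


class TestProperties:
    """Algebraic invariants of the bias/binning plumbing."""

    @given(st.floats(-1e6, 1e6).filter(lambda x: abs(x) > 1e-9))
    @settings(derandomize=True, max_examples=200)
    def test_relative_bias_vanishes_at_truth(self, x):
        assert relative_bias(x, x) == 0.0

    @given(
        st.floats(-1e3, 1e3),
        st.floats(1e-3, 1e3),
        st.floats(1e-3, 1e3),
    )
    @settings(derandomize=True, max_examples=200)
    def test_relative_bias_is_scale_invariant(self, est, truth, scale):
        a = relative_bias(est, truth)
        b = relative_bias(est * scale, truth * scale)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    @given(st.floats(0.0, 0.70))
    @settings(derandomize=True, max_examples=200)
    def test_delta_r_bins_partition_the_design_range(self, dr):
        assert delta_r_bin(dr) in DELTA_R_BINS

    @given(st.floats(-2.0e-5, 0.5e-5))
    @settings(derandomize=True, max_examples=200)
    def test_delta_q_bins_partition_the_design_range(self, dq):
        assert delta_q_bin(dq) in DELTA_Q_BINS

    @given(st.floats(-1e6, 1e6))
    @settings(derandomize=True, max_examples=200)
    def test_rounding_stays_within_half_a_year(self, x):
        assert abs(round_half_away(x) - x) <= 0.5
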