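import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromodot.classify import (CellStateSeries, ClassifierConfig, DotState,
                                DotTimecourse, StateCall, assign_phase,
                                classify_series, classify_timepoint, correct_z,
                                phase_compare, proportions_over_time,
                                rolling_mean_smooth, separation_asymmetry,
                                smooth_proportions)

CFG = ClassifierConfig()


def pts(*coords):
    return np.array(coords, dtype=float).reshape(-1, 3)


class TestZCorrection:
    def test_refractive_scaling_of_nominal_step(self):
        assert float(correct_z(1)) == pytest.approx(0.6375)
        assert round(float(correct_z(1)), 2) == 0.64

    def test_unit_scale_is_identity(self):
        cfg = ClassifierConfig(z_scale=1.0)
        np.testing.assert_allclose(correct_z([0, 1, 2], cfg), [0, 0.75, 1.5])

    def test_two_step_axial_distance(self):
        a = [0.0, 0.0, float(correct_z(0))]
        b = [0.0, 0.0, float(correct_z(2))]
        assert np.linalg.norm(np.subtract(a, b)) == pytest.approx(1.275)


class TestClassifyTimepoint:
    def test_single_plus_separated_doublet_is_brown_with_channel(self):
        call = classify_timepoint(pts((0, 0, 0)),
                                  pts((0, 0, 0), (1.2, 0, 0)), CFG)
        assert call.state is DotState.BROWN and call.separated_channel == "lacO"
        call = classify_timepoint(pts((0, 0, 0), (0, 1.2, 0)), pts((0, 0, 0)), CFG)
        assert call.state is DotState.BROWN and call.separated_channel == "tetO"

    def test_two_singles_are_blue(self):
        assert classify_timepoint(pts((0, 0, 0)), pts((0.5, 0, 0)),
                                  CFG).state is DotState.BLUE

    def test_boundary_separation_counts_as_nonresolved(self):
        call = classify_timepoint(pts((0, 0, 0)),
                                  pts((0, 0, 0), (0.85, 0, 0)), CFG)
        assert call.state is DotState.BLUE

    def test_subthreshold_doublet_treated_as_single(self):
        call = classify_timepoint(pts((0, 0, 0), (0.4, 0, 0)),
                                  pts((0, 0, 0), (0, 1.0, 0)), CFG)
        assert call.state is DotState.BROWN and call.separated_channel == "lacO"

    def test_red_needs_both_pairings_colocalized_else_pink(self):
        tet = pts((0, 0, 0), (2.0, 0, 0))
        lac_red = pts((0.1, 0, 0), (2.1, 0, 0))
        assert classify_timepoint(tet, lac_red, CFG).state is DotState.RED
        lac_pink = pts((1.0, 0, 0), (2.1, 0, 0))  # first pairing 1.0 um off
        assert classify_timepoint(tet, lac_pink, CFG).state is DotState.PINK

    def test_pairing_minimizes_total_distance(self):
        # listed order is crossed; correct pairing still finds colocalization
        tet = pts((0, 0, 0), (2.0, 0, 0))
        lac = pts((2.1, 0, 0), (0.1, 0, 0))
        assert classify_timepoint(tet, lac, CFG).state is DotState.RED

    def test_missing_channel_is_undetermined(self):
        assert classify_timepoint(pts(), pts((0, 0, 0)),
                                  CFG).state is DotState.UNDETERMINED

    def test_three_dots_rejected(self):
        with pytest.raises(ValueError):
            classify_timepoint(pts((0, 0, 0), (1, 0, 0), (2, 0, 0)),
                               pts((0, 0, 0)), CFG)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           shift=st.tuples(*[st.floats(-50, 50) for _ in range(3)]))
    def test_invariant_to_dot_order_and_rigid_translation(self, seed, shift):
        rng = np.random.default_rng(seed)
        tet = rng.uniform(0, 3, size=(rng.integers(1, 3), 3))
        lac = rng.uniform(0, 3, size=(rng.integers(1, 3), 3))
        base = classify_timepoint(tet, lac, CFG)
        flipped = classify_timepoint(tet[::-1], lac[::-1], CFG)
        moved = classify_timepoint(tet + shift, lac + shift, CFG)
        assert base == flipped
        assert base.state == moved.state
        assert base.separated_channel == moved.separated_channel


def _blue_point():
    return pts((0, 0, 0)), pts((0.6, 0, 0))


def _coloc_point():
    # every pairwise distance <= 0.4: sub-threshold doublets on both channels
    return (pts((0, 0, 0), (0.2, 0, 0)), pts((0.1, 0.1, 0), (0.1, -0.1, 0)))


def _make_cell(per_timepoint, nebd=0.0, cell_id="c1", end_of_s=None):
    times = np.arange(len(per_timepoint), dtype=float) + nebd - 5
    tet = [p[0] for p in per_timepoint]
    lac = [p[1] for p in per_timepoint]
    return DotTimecourse(cell_id=cell_id, times=times, tetO=tet, lacO=lac,
                         nebd_min=nebd, end_of_s_min=end_of_s)


class TestClassifySeries:
    def test_black_relabelling_requires_five_consecutive_points(self):
        # t_rel runs -5..+6; all-colocalized from t=0 onwards
        points = [_blue_point()] * 5 + [_coloc_point()] * 7
        series = classify_series(_make_cell(points), CFG)
        assert series.states() == ["BLUE"] * 5 + ["BLACK"] * 7

        points4 = [_blue_point()] * 8 + [_coloc_point()] * 4
        series4 = classify_series(_make_cell(points4), CFG)
        # a 4-point run is too short: the base (blue-like) calls stand
        assert series4.states() == ["BLUE"] * 12

    def test_black_run_straddling_nebd_counts_only_the_post_nebd_part(self):
        # colocalized t=-3..+3: post-NEBD portion is 4 points -> no relabel
        points = ([_blue_point()] * 2 + [_coloc_point()] * 7
                  + [_blue_point()] * 3)
        series = classify_series(_make_cell(points), CFG)
        assert "BLACK" not in series.states()
        # extend to t=-3..+4: post-NEBD portion is 5 points -> those go black
        points = ([_blue_point()] * 2 + [_coloc_point()] * 8
                  + [_blue_point()] * 2)
        series = classify_series(_make_cell(points), CFG)
        states = series.states()
        assert states[2:5] == ["BLUE"] * 3  # pre-NEBD part of the run
        assert states[5:10] == ["BLACK"] * 5

    def test_all_blue_input_stays_blue_and_alignment_is_exact(self):
        series = classify_series(_make_cell([_blue_point()] * 10, nebd=123.0), CFG)
        assert series.states() == ["BLUE"] * 10
        assert series.t_rel[0] == -5.0 and 0.0 in series.t_rel

    def test_missing_nebd_rejected(self):
        cell = _make_cell([_blue_point()] * 3)
        cell.nebd_min = float("nan")
        with pytest.raises(ValueError):
            classify_series(cell, CFG)


class TestProportions:
    def test_counts_and_denominators(self):
        cells = []
        for i, st_seq in enumerate((["BLUE"] * 3, ["BLUE", "PINK", "UNDETERMINED"],
                                    ["PINK", "PINK", "RED"])):
            calls = [StateCall(DotState(s)) for s in st_seq]
            cells.append(CellStateSeries(cell_id=f"c{i}",
                                         t_rel=np.array([0.0, 1.0, 2.0]),
                                         calls=calls))
        obs = proportions_over_time(cells)
        t0 = obs.table.set_index("time_min").loc[0.0]
        assert t0["n_blue"] == 2 and t0["n_pink"] == 1
        assert t0["p_blue"] == pytest.approx(2 / 3)
        t2 = obs.table.set_index("time_min").loc[2.0]
        # the undetermined call is excluded from the denominator
        assert t2["n_classified"] == 2
        assert t2["p_blue"] == pytest.approx(0.5)
        assert t2["p_red"] == pytest.approx(0.5)

    def test_smoothing_preserves_unit_sum(self):
        rng = np.random.default_rng(0)
        raw = rng.dirichlet(np.ones(5), size=30)
        df = pd.DataFrame(raw, columns=["p_blue", "p_brown", "p_pink", "p_red",
                                        "p_black"])
        sm = rolling_mean_smooth(df, 9)
        np.testing.assert_allclose(sm.sum(axis=1), 1.0, atol=1e-12)


class TestSmoothing:
    def test_hand_computed_window_three(self):
        s = pd.Series([0.0, 0.0, 1.0, 0.0, 0.0])
        np.testing.assert_allclose(rolling_mean_smooth(s, 3),
                                   [0, 1 / 3, 1 / 3, 1 / 3, 0])

    def test_window_one_is_identity_and_constant_unchanged(self):
        s = pd.Series([0.2, 0.5, 0.3])
        np.testing.assert_allclose(rolling_mean_smooth(s, 1), s)
        c = pd.Series([0.4] * 11)
        np.testing.assert_allclose(rolling_mean_smooth(c, 9), c)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            rolling_mean_smooth(pd.Series([1.0, 2.0]), 4)


class TestPhases:
    @pytest.mark.parametrize("t,expected", [
        (-10.0, "prophase"),      # inside the 20-min pre-NEBD window
        (-30.0, "late G2"),
        (-140.0, "late G2"),
        (-370.0, "late S"),       # 10 min before end of S
        (-300.0, "early G2"),
        (-500.0, "other"),
        (45.0, "other"),
    ])
    def test_phase_windows(self, t, expected):
        assert assign_phase(t, nebd=0.0, end_of_s=-360.0) == expected

    def test_inconsistent_times_rejected(self):
        with pytest.raises(ValueError):
            assign_phase(0.0, nebd=0.0, end_of_s=10.0)


class TestPhaseCompare:
    def test_identical_distributions_give_zero_statistic(self):
        stat, p, dof = phase_compare([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert dof == 1

    def test_hand_computed_pearson_statistic(self):
        # [[30,10],[10,30]]: all expected counts are 20, sum (O-E)^2/E = 4*100/20
        stat, p, dof = phase_compare([[30, 10], [10, 30]])
        assert stat == pytest.approx(20.0)
        assert dof == 1
        assert p < 1e-4

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            phase_compare([[0, 0], [10, 30]])


class TestSeparationAsymmetry:
    def _cells(self, channels):
        calls = [StateCall(DotState.BROWN, separated_channel=ch) for ch in channels]
        t = np.arange(-len(channels), 0, dtype=float)  # late G2 / prophase times
        return [CellStateSeries(cell_id="c", t_rel=t, calls=calls)]

    def test_all_teto_separated(self):
        res = separation_asymmetry(self._cells(["tetO"] * 6), "prophase")
        assert res["tetO"] == 1.0 and res["lacO"] == 0.0 and res["n"] == 6

    def test_fractions_sum_to_one(self):
        res = separation_asymmetry(self._cells(["tetO", "lacO", "tetO"]), "prophase")
        assert res["tetO"] + res["lacO"] == pytest.approx(1.0)

    def test_no_brown_calls_yields_empty_result(self):
        cells = [CellStateSeries(cell_id="c", t_rel=np.array([-5.0]),
                                 calls=[StateCall(DotState.BLUE)])]
        res = separation_asymmetry(cells, "prophase")
        assert res["n"] == 0 and np.isnan(res["tetO"])
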