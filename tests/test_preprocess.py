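"""ΔF/F, QC gates, trial extraction windows, and day-pair z-scoring."""

import numpy as np
import pandas as pd
import pytest

from caldrift import SessionRecording, dff, extract_trials, qc_mask, zscore_day_pair
from caldrift.preprocess import TRIAL_COLUMNS, _window_frames


class TestDff:
    def test_hand_arithmetic(self):
        np.testing.assert_allclose(
            dff(np.array([90.0, 100.0, 110.0])), [-0.1, 0.0, 0.1]
        )

    def test_constant_trace_is_zero(self):
        np.testing.assert_array_equal(dff(np.full(50, 100.0)), np.zeros(50))

    def test_scale_invariance(self, rng):
        trace = rng.uniform(50, 150, 200)
        np.testing.assert_allclose(dff(trace), dff(2.0 * trace))

    def test_median_is_centered_at_zero(self, rng):
        trace = rng.uniform(50, 150, 201)
        assert np.median(dff(trace)) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError, match="median"):
            dff(np.array([-5.0, 0.0, 1.0]))


class TestQcMask:
    @pytest.mark.parametrize(
        "compactness,skewness,keep",
        [
            (0.9, 2.0, True),
            (0.8, 2.0, False),   # boundary: strict inequality
            (0.9, 1.1, False),   # boundary: strict inequality
            (0.81, 1.11, True),
            (np.nan, 2.0, False),
        ],
    )
    def test_gates(self, compactness, skewness, keep):
        assert qc_mask(np.array([[compactness, skewness]]))[0] == keep


def make_session(n_neurons=2, n_frames=200, onsets=((30, 0), (60, 1)),
                 rate=3.0, loco_frames=(), traces=None, roi_stats=None):
    if traces is None:
        traces = np.full((n_neurons, n_frames), 100.0)
    loco = np.zeros(n_frames, bool)
    loco[list(loco_frames)] = True
    return SessionRecording(
        traces=traces,
        frame_rate_hz=rate,
        events=np.array(onsets),
        locomotion_mask=loco,
        day_index=0,
        roi_stats=roi_stats,
    )


class TestExtractTrials:
    def test_response_window_frames_at_3_fps(self):
        # frames with start time in [0, 1.5) of onset 30 are 30..34;
        # put ΔF/F = 0.2 exactly there and check the mean comes back
        traces = np.full((1, 200), 100.0)
        traces[0, 30:35] = 120.0
        t = extract_trials(make_session(n_neurons=1, traces=traces))
        row = t[(t.stimulus_id == 0)].iloc[0]
        assert row.response_mag == pytest.approx(0.2)
        assert row.prestim_mag == pytest.approx(0.0)

    def test_frame_past_window_edge_not_counted(self):
        traces = np.full((1, 200), 100.0)
        traces[0, 35] = 200.0  # start time exactly 1.66 s, outside [0, 1.5)
        t = extract_trials(make_session(n_neurons=1, traces=traces))
        assert t[(t.stimulus_id == 0)].iloc[0].response_mag == pytest.approx(0.0, abs=1e-9)

    def test_window_frame_arithmetic(self):
        np.testing.assert_array_equal(
            _window_frames(30, 0.0, 1.5, 3.0), [30, 31, 32, 33, 34]
        )
        np.testing.assert_array_equal(
            _window_frames(30, -1.5, 0.0, 3.0), [26, 27, 28, 29]
        )

    def test_locomotion_overlap_excludes_trial(self):
        t = extract_trials(make_session(loco_frames=[32]))
        assert t[t.stimulus_id == 0].excluded.all()
        assert (t[t.stimulus_id == 0].reason == "locomotion").all()
        assert not t[t.stimulus_id == 1].excluded.any()

    def test_edge_onset_excluded(self):
        t = extract_trials(make_session(onsets=((2, 0), (198, 1), (60, 2))))
        assert (t[t.stimulus_id == 0].reason == "edge").all()
        assert (t[t.stimulus_id == 1].reason == "edge").all()
        assert not t[t.stimulus_id == 2].excluded.any()

    def test_trial_count_conservation(self, small_experiment):
        _, stimuli, sessions, _ = small_experiment
        s = sessions[0]
        t = extract_trials(s)
        assert list(t.columns) == TRIAL_COLUMNS
        assert len(t) == s.n_neurons * len(s.events)
        assert (t.excluded | (t.reason == "")).all()

    def test_qc_failed_neuron_rows_flagged(self):
        roi = np.array([[0.9, 2.0], [0.5, 2.0]])
        t = extract_trials(make_session(roi_stats=roi))
        assert not t[t.neuron_id == 0].excluded.any()
        assert (t[t.neuron_id == 1].reason == "qc").all()


class TestZscoreDayPair:
    @staticmethod
    def table(values, days):
        return pd.DataFrame(
            {
                "neuron_id": 0,
                "day": days,
                "stimulus_id": 0,
                "trial": range(len(values)),
                "response_mag": values,
                "prestim_mag": 0.0,
                "excluded": False,
                "reason": "",
            }
        )

    def test_hand_example_population_sd(self):
        t = self.table([1.0, 1.0, 3.0, 3.0], [0, 0, 1, 1])
        z = zscore_day_pair(t)
        np.testing.assert_allclose(z.response_mag, [-1.0, -1.0, 1.0, 1.0])

    def test_pool_standardized(self, rng):
        vals = rng.normal(3.0, 2.0, 40)
        z = zscore_day_pair(self.table(vals, [0] * 20 + [1] * 20))
        assert z.response_mag.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.response_mag.std(ddof=0) == pytest.approx(1.0)

    def test_identical_days_have_equal_means(self, rng):
        vals = rng.normal(0, 1, 10)
        z = zscore_day_pair(self.table(np.tile(vals, 2), [0] * 10 + [1] * 10))
        assert z[z.day == 0].response_mag.mean() == pytest.approx(
            z[z.day == 1].response_mag.mean()
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            zscore_day_pair(self.table([2.0, 2.0, 2.0, 2.0], [0, 0, 1, 1]))

    def test_wrong_day_count_rejected(self):
        with pytest.raises(ValueError, match="days"):
            zscore_day_pair(self.table([1.0, 2.0], [0, 0]))
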