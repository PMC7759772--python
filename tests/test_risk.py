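"""Risk engine: moving-average and threshold-crossing oracles, AUC equivalence
with the all-pairs Mann-Whitney statistic, confusion tables, lead times."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import surgmon as sm
from surgmon.risk import ProbabilitySeries


def brute_average(x, window):
    out = np.full(len(x), np.nan)
    for i in range(window - 1, len(x)):
        out[i] = np.mean(x[i - window + 1: i + 1])
    return out


def mann_whitney_auc(scores, labels):
    """Concordant-pair fraction over all (positive, negative) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = concordant = 0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                concordant += 1
            elif p == n:
                concordant += 0.5
    return concordant / total


def first_crossing(dt, thr):
    for i, v in enumerate(dt):
        if not np.isnan(v) and v >= thr:
            return i
    return None


class TestMovingAverage:
    def test_matches_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 40))
            w = int(rng.integers(1, 12))
            x = rng.random(n)
            got = sm.moving_average(x, w)
            expect = brute_average(x, w)
            assert np.allclose(got, expect, equal_nan=True)

    def test_window_of_ten_defines_tenth_second(self):
        """Nine zeros then a one: the first defined average is 0.1."""
        x = np.array([0.0] * 9 + [1.0])
        avg = sm.moving_average(x, 10)
        assert np.isnan(avg[:9]).all()
        assert avg[9] == pytest.approx(0.1)

    def test_constant_and_degenerate_window(self, rng):
        x = np.full(20, 0.37)
        avg = sm.moving_average(x, 10)
        assert np.allclose(avg[9:], 0.37)
        y = rng.random(15)
        assert np.allclose(sm.moving_average(y, 1), y)

    def test_impulse_spreads_window_wide(self):
        x = np.zeros(30)
        x[15] = 1.0
        avg = sm.moving_average(x, 10)
        nz = np.flatnonzero(np.nan_to_num(avg) > 0)
        assert len(nz) == 10
        assert np.allclose(avg[nz], 0.1)

    def test_output_range_within_input_range(self, rng):
        x = rng.uniform(0.2, 0.8, 50)
        avg = sm.moving_average(x, 10)
        defined = avg[~np.isnan(avg)]
        assert defined.min() >= 0.2 and defined.max() <= 0.8

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            sm.moving_average(np.array([]), 10)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50),
           st.integers(1, 12))
    def test_property_matches_brute_force(self, xs, window):
        x = np.asarray(xs)
        assert np.allclose(sm.moving_average(x, window), brute_average(x, window),
                           equal_nan=True)


class TestRiskLevel:
    def test_products(self):
        pa = np.array([0.9, 1.0, 0.5])
        ta = np.array([0.8, 0.3, 0.0])
        dt = sm.risk_level(pa, ta)
        assert dt == pytest.approx([0.72, 0.3, 0.0])
        assert np.allclose(sm.risk_level(np.ones(3), ta), ta)
        assert np.allclose(sm.risk_level(pa, np.zeros(3)), 0.0)

    def test_index_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sm.risk_level(np.ones(3), np.ones(4))


class TestProblemTime:
    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(100):
            dt = rng.random(int(rng.integers(1, 40)))
            dt[: min(9, len(dt))] = np.nan
            thr = float(rng.random())
            assert sm.estimate_problem_time(dt, thr) == first_crossing(dt, thr)

    def test_examples_and_boundaries(self):
        dt = np.array([0.1, 0.2, 0.9, 0.95])
        assert sm.estimate_problem_time(dt, 0.5) == 2
        assert sm.estimate_problem_time(np.array([0.1, 0.2]), 0.9) is None
        assert sm.estimate_problem_time(dt, 0.0) == 0
        # >= convention: a perfect score fires at threshold 1.0
        assert sm.estimate_problem_time(np.array([0.5, 1.0]), 1.0) == 1

    def test_threshold_monotonicity(self, rng):
        dt = rng.random(50)
        times = []
        for thr in np.linspace(0, 1, 11):
            times.append(sm.estimate_problem_time(dt, float(thr)))
        cleaned = [t for t in times if t is not None]
        assert cleaned == sorted(cleaned)
        # once the estimate disappears it stays absent at higher thresholds
        seen_none = False
        for t in times:
            if t is None:
                seen_none = True
            else:
                assert not seen_none


class TestVideoScore:
    def test_max_semantics(self, rng):
        dt = np.full(20, 0.3)
        assert sm.video_score(dt) == pytest.approx(0.3)
        mono = np.linspace(0, 0.9, 15)
        assert sm.video_score(mono) == pytest.approx(0.9)
        x = rng.random(30)
        assert sm.video_score(x) == sm.video_score(x[rng.permutation(30)])
        with pytest.raises(ValueError):
            sm.video_score(np.full(5, np.nan))


class TestRocAuc:
    def test_separated_and_uninformative(self):
        _, auc, _ = sm.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == pytest.approx(1.0)
        _, auc, _ = sm.roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)
        with pytest.raises(ValueError):
            sm.roc_auc([0.1, 0.9], [1, 1])

    def test_equals_mann_whitney_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 21))
            scores = rng.random(n).round(2)   # duplicates exercise tie handling
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            _, auc, _ = sm.roc_auc(scores, labels)
            assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-9)

    def test_youden_threshold_separates(self):
        scores = [0.1, 0.15, 0.2, 0.7, 0.8, 0.9]
        labels = [0, 0, 0, 1, 1, 1]
        _, _, thr = sm.roc_auc(scores, labels)
        pred = (np.array(scores) >= thr).astype(int)
        assert np.array_equal(pred, labels)


class TestFrameConfusion:
    def test_hand_tally(self):
        labels = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1])
        preds = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 0])
        rep = sm.frame_confusion(preds, labels)
        assert rep["counts"].tolist() == [[5, 1], [1, 3]]
        assert rep["per_class_percent"]["other"] == pytest.approx(5 / 6 * 100)
        assert rep["per_class_percent"]["important"] == pytest.approx(75.0)
        assert rep["mean_percent"] == pytest.approx(80.0)

    def test_perfect_and_flipped(self):
        labels = np.array([0, 1] * 5)
        perfect = sm.frame_confusion(labels, labels)
        assert np.allclose(np.diag(perfect["rates_percent"]), 100.0)
        flipped = sm.frame_confusion(1 - labels, labels)
        assert np.allclose(np.diag(flipped["rates_percent"]), 0.0)


class TestLeadTime:
    def test_sign_convention_and_conservation(self):
        out = sm.lead_time_histogram([30.0, 100.0, 60.0], [60.0, 100.0, 50.0])
        assert out["differences"].tolist() == [-30.0, 0.0, 10.0]
        assert out["hist"].sum() == 3
        with pytest.raises(ValueError):
            sm.lead_time_histogram([1.0], [1.0, 2.0])


class TestDetectionReport:
    def test_assembles_and_plots(self, tmp_path, rng):
        labels = rng.integers(0, 2, 30)
        frame_preds = np.where(rng.random(30) < 0.9, labels, 1 - labels)
        video_labels = np.array([0, 0, 0, 1, 1, 1])
        video_scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        rep = sm.detection_report(frame_preds, labels, frame_preds, labels,
                                  video_scores, video_labels,
                                  [50.0, 70.0], [60.0, 60.0])
        assert rep.auc == pytest.approx(1.0)
        assert rep.lead_times["differences"].tolist() == [-10.0, 10.0]
        d = rep.to_dict()
        assert 0 <= d["operating_threshold"] <= 1
        sm.plot_roc(rep.roc_points, rep.auc, tmp_path / "roc.png")
        sm.plot_lead_times(rep.lead_times, tmp_path / "lead.png")
        assert (tmp_path / "roc.png").stat().st_size > 0
        assert (tmp_path / "lead.png").stat().st_size > 0


class TestFusion:
    def test_compute_risk_on_clean_step_stream(self):
        """A clean problem onset crosses the threshold within one window."""
        t_total, onset = 120, 60
        p_problem = np.where(np.arange(t_total) >= onset, 0.9, 0.1)
        p_phase = np.full(t_total, 0.95)
        rs = sm.compute_risk(
            ProbabilitySeries("v", np.column_stack([1 - p_phase, p_phase])),
            ProbabilitySeries("v", np.column_stack([1 - p_problem, p_problem])),
            threshold=0.5)
        assert rs.estimated_time is not None
        assert onset <= rs.estimated_time <= onset + 10
        assert 0.0 <= rs.score <= 1.0

    def test_probability_series_validation(self):
        with pytest.raises(ValueError):
            ProbabilitySeries("v", np.array([[0.5, 0.3]]))

    def test_no_problem_stream_never_alerts(self):
        p = np.full(100, 0.1)
        phase = np.full(100, 0.9)
        rs = sm.compute_risk(
            ProbabilitySeries("v", np.column_stack([1 - phase, phase])),
            ProbabilitySeries("v", np.column_stack([1 - p, p])), threshold=0.5)
        assert rs.estimated_time is None
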