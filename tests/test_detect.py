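"""Probability smoothing, run-length event extraction, matching and scoring."""

import itertools

import numpy as np
import pytest

from monoseize import (
    DetectionParams,
    EventSet,
    ProbabilityTrace,
    Recording,
    SeizureAnnotation,
    event_metrics,
    extract_events,
    match_events,
    savgol_smooth,
    sliding_probabilities,
    tune_postprocessing,
)
from monoseize.detect import MatchResult
from monoseize.errors import MonoseizeError


def _trace(probs, step=1.0, window=4.0, source="t"):
    probs = np.asarray(probs, dtype=float)
    return ProbabilityTrace(times=np.arange(len(probs)) * step, probs=probs,
                            step_s=step, window_s=window, source_id=source)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def savgol_oracle(y, window=10, order=3):
    """Per-point local least-squares polynomial fit via np.polyfit."""
    n = len(y)
    left, right = window // 2, window - window // 2 - 1
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - left), min(n - 1, i + right)
        xs = np.arange(lo, hi + 1) - i
        coeffs = np.polyfit(xs, y[lo:hi + 1], order)
        out[i] = np.polyval(coeffs, 0.0)
    return np.clip(out, 0.0, 1.0)


def extract_events_oracle(probs, th, run_length, window_s=4.0, merge_gap=10.0):
    """Enumerate maximal runs with groupby, then merge pairwise until fixed
    point (independent of the implementation's single-pass merge)."""
    events = []
    pos = 0
    for above, grp in itertools.groupby(probs > th):
        n = len(list(grp))
        if above and n >= run_length:
            events.append([float(pos), float(pos + n - 1 + window_s)])
        pos += n
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(events)), 2):
            a, b = events[i], events[j]
            gap = max(a[0], b[0]) - min(a[1], b[1])
            if gap < merge_gap:
                events[i] = [min(a[0], b[0]), max(a[1], b[1])]
                del events[j]
                changed = True
                break
    return sorted(tuple(e) for e in events)


def match_oracle(detected, annotated):
    correct = sum(
        1 for s in annotated
        if any(d[0] < s[1] and s[0] < d[1] for d in detected)
    )
    fas = sum(
        1 for d in detected
        if not any(d[0] < s[1] and s[0] < d[1] for s in annotated)
    )
    return correct, len(annotated) - correct, fas


# ---------------------------------------------------------------------------
# sliding probabilities
# ---------------------------------------------------------------------------

class TestSlidingProbabilities:
    def test_ten_second_recording_gives_seven_steps(self, trained_toy_model):
        rng = np.random.default_rng(0)
        rec = Recording(["ch"], 256.0, rng.normal(size=(1, 2560)))
        trace = sliding_probabilities(trained_toy_model, rec)
        assert len(trace) == 7
        np.testing.assert_allclose(trace.times, np.arange(7.0))

    def test_one_hour_recording_gives_3597_steps(self, trained_toy_model):
        rec = Recording(["ch"], 256.0,
                        np.zeros((1, 3600 * 256)) + 1.0)
        trace = sliding_probabilities(trained_toy_model, rec)
        assert len(trace) == 3597

    def test_constant_signal_constant_probabilities(self, trained_toy_model):
        rec = Recording(["ch"], 256.0, np.full((1, 20 * 256), 3.0))
        trace = sliding_probabilities(trained_toy_model, rec)
        assert np.ptp(trace.probs) < 1e-6

    def test_too_short_recording_rejected(self, trained_toy_model):
        rec = Recording(["ch"], 256.0, np.ones((1, 512)))
        with pytest.raises(MonoseizeError):
            sliding_probabilities(trained_toy_model, rec)


# ---------------------------------------------------------------------------
# Savitzky-Golay smoothing (even window 10, order 3)
# ---------------------------------------------------------------------------

class TestSavgolSmooth:
    def test_cubic_is_reproduced_exactly_in_interior(self):
        x = np.arange(40.0)
        y = 1e-5 * (x - 20) ** 3 + 0.5  # cubic staying inside [0, 1]
        sm = savgol_smooth(_trace(np.clip(y, 0, 1)), DetectionParams())
        np.testing.assert_allclose(sm.probs[5:-4], y[5:-4], atol=1e-9)

    def test_constant_trace_unchanged(self):
        sm = savgol_smooth(_trace(np.full(30, 0.37)), DetectionParams())
        np.testing.assert_allclose(sm.probs, 0.37, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_local_fit(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0, 1, size=rng.integers(12, 60))
        sm = savgol_smooth(_trace(y), DetectionParams())
        np.testing.assert_allclose(sm.probs, savgol_oracle(y), atol=1e-9)

    def test_trace_shorter_than_window_rejected(self):
        with pytest.raises(MonoseizeError):
            savgol_smooth(_trace(np.zeros(9)), DetectionParams())


# ---------------------------------------------------------------------------
# Event extraction
# ---------------------------------------------------------------------------

class TestExtractEvents:
    P = DetectionParams(th=0.5, run_length=5)

    def test_all_zero_trace_yields_no_events(self):
        assert len(extract_events(_trace(np.zeros(50)), self.P)) == 0

    def test_run_length_boundary(self):
        short = np.zeros(30)
        short[10:14] = 0.9            # 4 steps: one short of L=5
        assert len(extract_events(_trace(short), self.P)) == 0
        exact = np.zeros(30)
        exact[10:15] = 0.9            # exactly L=5
        events = extract_events(_trace(exact), self.P)
        assert events.intervals == ((10.0, 18.0),)

    def test_threshold_is_strict(self):
        at = np.zeros(30)
        at[5:15] = 0.5                # exactly Th: not "exceeding"
        assert len(extract_events(_trace(at), self.P)) == 0

    def test_two_runs_with_short_gap_merge(self):
        y = np.zeros(40)
        y[0:6] = 0.9                  # event [0, 9)
        y[14:20] = 0.9                # event [14, 23): gap 5 s < 10 s
        events = extract_events(_trace(y), self.P)
        assert events.intervals == ((0.0, 23.0),)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumerator(self, seed):
        rng = np.random.default_rng(seed)
        y = (rng.uniform(size=60) > 0.5) * 0.9
        th = rng.choice([0.2, 0.5, 0.8])
        L = int(rng.integers(2, 8))
        params = DetectionParams(th=th, run_length=L)
        ours = [tuple(iv) for iv in extract_events(_trace(y), params).intervals]
        assert ours == extract_events_oracle(y, th, L)

    @pytest.mark.parametrize("seed", range(10))
    def test_invariants_no_overlap_and_min_gap(self, seed):
        rng = np.random.default_rng(100 + seed)
        y = rng.uniform(size=200)
        events = extract_events(_trace(y), self.P)
        ivs = events.intervals
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            assert a1 - b0 >= self.P.merge_gap_s

    def test_run_counts_monotone_in_run_length(self):
        # pre-merge supra-threshold run counts shrink as L grows; merging
        # can only reduce the count further for a fixed L
        rng = np.random.default_rng(4)
        y = rng.uniform(size=300)
        run_counts, event_counts = [], []
        for L in range(1, 12):
            runs = extract_events_oracle(y, 0.5, L, merge_gap=-np.inf)
            run_counts.append(len(runs))
            event_counts.append(len(extract_events(
                _trace(y), DetectionParams(th=0.5, run_length=L))))
        assert run_counts == sorted(run_counts, reverse=True)
        assert all(e <= r for e, r in zip(event_counts, run_counts))

    def test_threshold_above_trace_maximum_gives_nothing(self):
        y = np.random.default_rng(5).uniform(0, 0.6, size=100)
        assert len(extract_events(_trace(y), DetectionParams(th=0.7,
                                                             run_length=1))) == 0


# ---------------------------------------------------------------------------
# Matching and metrics
# ---------------------------------------------------------------------------

class TestMatchEvents:
    def test_direct_overlap_latency(self):
        m = match_events(EventSet([[115, 140]], "s"),
                         SeizureAnnotation([[110, 150]], "s"))
        assert (m.correct, m.missed, m.false_alarms) == (1, 0, 0)
        assert m.latencies_s == (5.0,)

    def test_disjoint_detection_is_false_alarm_and_miss(self):
        m = match_events(EventSet([[200, 210]], "s"),
                         SeizureAnnotation([[110, 150]], "s"))
        assert (m.correct, m.missed, m.false_alarms) == (0, 1, 1)

    def test_double_overlap_credits_both_without_false_alarm(self):
        m = match_events(EventSet([[95, 125]], "s"),
                         SeizureAnnotation([[90, 100], [120, 130]], "s"))
        assert (m.correct, m.missed, m.false_alarms) == (2, 0, 0)
        assert m.latencies_s == (5.0, -25.0)

    def test_source_mismatch_rejected(self):
        with pytest.raises(MonoseizeError):
            match_events(EventSet([[1, 2]], "a"),
                         SeizureAnnotation([[1, 2]], "b"))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_all_pairs_oracle_and_conservation(self, seed):
        rng = np.random.default_rng(seed)

        def random_intervals(n):
            out, t = [], 0.0
            for _ in range(n):
                t += rng.uniform(1, 30)
                length = rng.uniform(1, 20)
                out.append((t, t + length))
                t += length
            return out

        det = random_intervals(rng.integers(0, 6))
        ann = random_intervals(rng.integers(0, 6))
        m = match_events(EventSet(det, "s"), SeizureAnnotation(ann, "s"))
        assert (m.correct, m.missed, m.false_alarms) == match_oracle(det, ann)
        assert m.correct + m.missed == len(ann)
        assert m.false_alarms <= len(det)
        assert m.correct <= len(ann)


class TestEventMetrics:
    def test_basic_arithmetic(self):
        m = MatchResult(3, 1, 2, (1.0, 2.0, 3.0))
        em = event_metrics(m, 10.0)
        assert em.sensitivity == 75.0
        assert em.far_per_h == pytest.approx(0.2)
        assert em.mean_latency_s == pytest.approx(2.0)

    def test_perfect_detection(self):
        em = event_metrics(MatchResult(4, 0, 0, (0.0,) * 4), 5.0)
        assert em.sensitivity == 100.0 and em.far_per_h == 0.0

    def test_no_seizures_and_no_misses_is_full_sensitivity(self):
        em = event_metrics(MatchResult(0, 0, 1, ()), 2.0)
        assert em.sensitivity == 100.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(MonoseizeError):
            event_metrics(MatchResult(1, 0, 0, (0.0,)), 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_recount_from_interval_lists(self, seed):
        rng = np.random.default_rng(seed)
        det = [(10 * i + 1, 10 * i + 4) for i in range(rng.integers(1, 5))]
        ann = [(10 * i + 2, 10 * i + 6) for i in range(rng.integers(1, 5))]
        m = match_events(EventSet(det, "s"), SeizureAnnotation(ann, "s"))
        em = event_metrics(m, 3.0)
        c, miss, fa = match_oracle(det, ann)
        assert em.sensitivity == pytest.approx(100 * c / len(ann))
        assert em.far_per_h == pytest.approx(fa / 3.0)


# ---------------------------------------------------------------------------
# (Th, L) tuning
# ---------------------------------------------------------------------------

def _tuning_instance(seed):
    """A smoothed-looking random trace with one genuine plateau."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(0, 0.45, size=120)
    a = rng.integers(20, 80)
    y[a:a + rng.integers(8, 20)] = rng.uniform(0.75, 0.95)
    ann = SeizureAnnotation([[float(a), float(a + 10)]], "t")
    return _trace(y), ann


class TestTunePostprocessing:
    def test_dominant_optimum_selected(self):
        trace, ann = _tuning_instance(0)
        params = tune_postprocessing([trace], [ann])
        m = match_events(extract_events(savgol_smooth(trace, params), params), ann)
        assert m.correct == 1 and m.false_alarms == 0

    def test_far_tie_break_prefers_fewer_false_alarms(self):
        # long plateau plus an isolated short blip: small L keeps the blip
        # as a false alarm, large L rejects it at equal sensitivity
        y = np.zeros(200)
        y[20:50] = 0.95
        y[100:106] = 0.95
        ann = SeizureAnnotation([[20.0, 50.0]], "t")
        trace = _trace(y)
        chosen = tune_postprocessing([trace], [ann], th_grid=(0.5,),
                                     run_length_grid=(5, 10))

        def score(L):
            p = DetectionParams(th=0.5, run_length=L)
            m = match_events(extract_events(savgol_smooth(trace, p), p), ann)
            return m.correct, m.false_alarms

        scores = {L: score(L) for L in (5, 10)}
        assert scores[5][1] > scores[10][1]  # the blip really is an FA at L=5
        best_sens = max(s[0] for s in scores.values())
        min_fa = min(s[1] for L, s in scores.items() if s[0] == best_sens)
        assert scores[chosen.run_length] == (best_sens, min_fa)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_grid_recount(self, seed):
        traces, anns = zip(*[_tuning_instance(10 * seed + i) for i in range(2)])
        th_grid = tuple(np.round(np.arange(0.2, 0.91, 0.1), 2))
        l_grid = tuple(range(5, 11))
        chosen = tune_postprocessing(list(traces), list(anns),
                                     th_grid=th_grid, run_length_grid=l_grid)
        hours = sum((len(t) - 1) * 1.0 + 4.0 for t in traces) / 3600.0
        best_key, best = None, None
        for th in th_grid:
            for L in l_grid:
                p = DetectionParams(th=th, run_length=L)
                c = n = f = 0
                for tr, ann in zip(traces, anns):
                    m = match_events(
                        extract_events(savgol_smooth(tr, p), p), ann)
                    c += m.correct
                    n += m.correct + m.missed
                    f += m.false_alarms
                key = (c / n, -f / hours, L, th)
                if best_key is None or key > best_key:
                    best_key, best = key, (th, L)
        assert (chosen.th, chosen.run_length) == best

    def test_empty_grid_rejected(self):
        trace, ann = _tuning_instance(1)
        with pytest.raises(MonoseizeError):
            tune_postprocessing([trace], [ann], th_grid=())
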