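"""The sliding-SD duration algorithm: transform, detection, pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egmdur import (
    DurationParams,
    EgmTrace,
    detect_onset_offset,
    egm_duration,
    map_durations,
    sliding_sd,
)
from egmdur.duration import SdCurve, sliding_sd_matrix, window_samples
from egmdur.errors import ParameterError
from egmdur.synthetic import generate_egm, random_morphology


def naive_sliding_sd(x, win):
    """Independent reference: explicit per-window population SD."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    left, right = (win - 1) // 2, win // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - left), min(n, i + right + 1)
        if hi - lo < 2:  # truncated edge windows keep at least 2 samples
            if lo == 0:
                hi = 2
            else:
                lo = hi - 2
        w = x[lo:hi]
        out[i] = np.sqrt(np.mean((w - w.mean()) ** 2))
    return out


class TestSlidingSd:
    def test_constant_trace_gives_zero_curve(self):
        curve = sliding_sd(EgmTrace("c", np.full(100, 0.7)), 5.0)
        assert np.allclose(curve.values, 0.0)
        assert len(curve.values) == 100

    def test_hand_computed_center_value(self):
        # window {0, 1, 0} at index 2: population SD = sqrt(2/9)
        curve = sliding_sd(EgmTrace("t", [0, 0, 1, 0, 0]), 3.0)
        assert curve.values[2] == pytest.approx(np.sqrt(2 / 9), abs=1e-12)

    def test_matches_naive_recomputation(self, rng):
        for _ in range(20):
            x = rng.normal(size=300)
            win = int(rng.integers(2, 60))
            fast = sliding_sd_matrix(x, win)[0]
            slow = naive_sliding_sd(x, win)
            np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-12)

    def test_window_bounds_enforced(self):
        tr = EgmTrace("t", np.arange(10.0))
        with pytest.raises(ParameterError):
            sliding_sd(tr, 1.0)  # < 2 samples
        with pytest.raises(ParameterError):
            sliding_sd(tr, 20.0)  # longer than trace

    def test_window_ms_rounds_half_up(self):
        assert window_samples(2.5, 1000.0) == 3
        assert window_samples(40.0, 1000.0) == 40
        assert window_samples(3.4, 1000.0) == 3


class TestDetection:
    def test_triangular_curve_crossings(self):
        curve = SdCurve(np.array([0, 1, 2, 3, 2, 1, 0.0]), 3.0)
        assert detect_onset_offset(curve, 0.5) == (2, 4)

    def test_vanishing_threshold_spans_support(self):
        curve = SdCurve(np.array([0.2, 0.5, 0.9, 0.4]), 3.0)
        assert detect_onset_offset(curve, 1e-9) == (0, 3)

    def test_threshold_one_hits_unique_maximum(self):
        curve = SdCurve(np.array([0.1, 0.9, 0.3]), 3.0)
        assert detect_onset_offset(curve, 1.0) == (1, 1)

    def test_zero_curve_is_degenerate_not_error(self):
        assert detect_onset_offset(SdCurve(np.zeros(10), 3.0), 0.15) is None


class TestEgmDuration:
    def test_all_zero_trace_degenerate(self):
        res = egm_duration(EgmTrace("z", np.zeros(1000)))
        assert res.degenerate and res.duration_ms == 0.0 and not res.prolonged

    def test_burst_recovered_within_window_tolerance(self, rng):
        m = random_morphology("border", rng)
        tr, onset, offset = generate_egm(m, rng=rng, noise_mv=0.0)
        res = egm_duration(tr)
        assert abs(res.duration_ms - (offset - onset)) <= 40.0
        assert abs(res.onset_ms - onset) <= 20.0

    def test_prolonged_uses_strict_inequality(self, rng):
        # a synthetic burst evaluated against a cutoff equal to its duration
        tr, *_ = generate_egm(random_morphology("border", rng), rng=rng, noise_mv=0.0)
        res = egm_duration(tr)
        exact = egm_duration(tr, DurationParams(duration_cutoff_ms=res.duration_ms))
        assert not exact.prolonged
        below = egm_duration(tr, DurationParams(duration_cutoff_ms=res.duration_ms - 1))
        assert below.prolonged

    def test_threshold_monotonicity_on_bursts(self, rng):
        for _ in range(10):
            tr, *_ = generate_egm(random_morphology("border", rng), rng=rng)
            prev = np.inf
            for theta in np.arange(0.10, 0.51, 0.05):
                d = egm_duration(tr, DurationParams(20.0, float(theta), 70.0)).duration_ms
                assert d <= prev + 1e-12
                prev = d

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=2**16))
    def test_amplitude_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        tr, *_ = generate_egm(random_morphology("healthy", rng), rng=rng)
        base = egm_duration(tr)
        scaled = egm_duration(EgmTrace("s", tr.samples * scale))
        assert scaled.onset_ms == base.onset_ms
        assert scaled.offset_ms == base.offset_ms

    @settings(deadline=None, max_examples=20)
    @given(shift=st.integers(min_value=-40, max_value=40),
           seed=st.integers(min_value=0, max_value=2**16))
    def test_time_shift_equivariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        tr, *_ = generate_egm(random_morphology("healthy", rng), rng=rng, noise_mv=0.0)
        rolled = EgmTrace("r", np.roll(tr.samples, shift))
        base = egm_duration(tr, filter_spec=None)
        moved = egm_duration(rolled, filter_spec=None)
        assert moved.duration_ms == base.duration_ms
        assert moved.onset_ms == base.onset_ms + shift

    def test_duration_bounded_by_trace_length(self, rng):
        for cls in ("healthy", "border", "dense"):
            tr, *_ = generate_egm(random_morphology(cls, rng), rng=rng)
            res = egm_duration(tr)
            assert 0.0 <= res.duration_ms <= tr.duration_ms


class TestMapDurations:
    def test_composition_matches_per_point_calls(self, small_cohort):
        emap = small_cohort[0][0]
        batch = map_durations(emap)
        by_id = {p.point_id: p for p in emap.points}
        for row in batch.sample(15, random_state=0).itertuples():
            single = egm_duration(by_id[row.point_id].trace)
            assert single.duration_ms == pytest.approx(row.duration_ms)
            assert single.onset_ms == pytest.approx(row.onset_ms)

    def test_invariant_to_point_order(self, small_cohort):
        from egmdur.model import ElectroanatomicMap
        emap = small_cohort[0][0]
        shuffled = ElectroanatomicMap(
            patient_id=emap.patient_id,
            points=list(reversed(emap.points)),
            landmarks=emap.landmarks,
            mesh=emap.mesh,
            lesions=emap.lesions,
        )
        a = map_durations(emap)
        b = map_durations(shuffled)
        assert a.equals(b)

    def test_degenerate_points_counted(self):
        from egmdur.model import ElectroanatomicMap, Landmarks, MapPoint
        lm = Landmarks([0, 0, -45], [0, 0, 36], [1, 0, 0])
        rng = np.random.default_rng(0)
        pts = []
        for i, samples in enumerate([rng.normal(size=400), np.zeros(400), rng.normal(size=400)]):
            pts.append(MapPoint(f"p{i}", [i, 0, 0], 1.0, EgmTrace(f"p{i}", samples)))
        emap = ElectroanatomicMap("t", pts, lm)
        df = map_durations(emap)
        assert len(df) == 3 and int(df["degenerate"].sum()) == 1
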