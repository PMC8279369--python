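"""Synthetic cohort generator: determinism, class bands, ground-truth recovery."""

import numpy as np
import pytest

from egmdur import (
    CohortSpec,
    assign_segments,
    classify_voltage,
    generate_cohort,
    generate_egm,
    generate_geometry,
    random_morphology,
)
from egmdur.errors import ParameterError
from egmdur.synthetic import sample_surface


class TestGeometry:
    def test_deterministic(self):
        m1, lm1 = generate_geometry()
        m2, lm2 = generate_geometry()
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.faces, m2.faces)
        assert np.array_equal(lm1.apex, lm2.apex)

    def test_vertices_within_bounding_box(self):
        mesh, _ = generate_geometry()
        assert np.all(np.abs(mesh.vertices[:, :2]) <= 25.0 + 1e-9)
        assert mesh.vertices[:, 2].min() >= -45.0 - 1e-9
        assert mesh.vertices[:, 2].max() <= 36.0 + 1e-9

    def test_all_17_segments_reachable(self):
        mesh, lm = generate_geometry()
        segs = assign_segments(mesh.vertices, lm)
        assert set(segs.tolist()) == set(range(1, 18))

    def test_surface_sampling_stays_on_shell(self, rng):
        mesh, _ = generate_geometry()
        pts = sample_surface(mesh, 500, rng)
        # points on the triangulated ellipsoid satisfy its implicit equation
        # approximately (facets are chords, so allow a small sag tolerance)
        val = (pts[:, 0] / 25) ** 2 + (pts[:, 1] / 25) ** 2 + (pts[:, 2] / 45) ** 2
        assert np.all(val <= 1.0 + 1e-6)
        assert np.all(val >= 0.9)


class TestGenerateEgm:
    def test_deterministic_given_seed(self):
        m = random_morphology("border", np.random.default_rng(0))
        t1, *_ = generate_egm(m, rng=1)
        t2, *_ = generate_egm(m, rng=1)
        assert np.array_equal(t1.samples, t2.samples)

    def test_noiseless_peak_to_peak_is_exact(self, rng):
        m = random_morphology("healthy", rng)
        tr, *_ = generate_egm(m, rng=rng, noise_mv=0.0)
        p2p = tr.samples.max() - tr.samples.min()
        assert p2p == pytest.approx(m.amplitude_mv, abs=1e-9)

    def test_truth_interval_centered_and_spanning(self, rng):
        m = random_morphology("border", rng)
        tr, onset, offset = generate_egm(m, trace_ms=400.0, rng=rng)
        assert offset - onset == pytest.approx(m.true_duration_ms)
        assert onset + offset == pytest.approx(400.0)

    def test_signal_confined_to_truth_support(self, rng):
        m = random_morphology("border", rng)
        tr, onset, offset = generate_egm(m, rng=rng, noise_mv=0.0)
        t = tr.times_ms()
        outside = (t < onset - 1) | (t > offset + 1)
        peak = np.abs(tr.samples).max()
        # support is defined at 1% of the continuous-time peak; the sampled
        # peak can undershoot it, so allow a 2% envelope outside the interval
        assert np.abs(tr.samples[outside]).max() <= 0.02 * peak

    def test_infeasible_duration_rejected(self, rng):
        m = random_morphology("dense", rng)
        with pytest.raises(ParameterError):
            generate_egm(m, trace_ms=m.true_duration_ms + 50.0, rng=rng)

    def test_class_bands_respected(self, rng):
        for cls, (amp_ok, dur_ok) in {
            "healthy": (lambda a: a > 1.0, lambda d: d < 50),
            "border": (lambda a: 0.2 <= a <= 1.0, lambda d: 70 <= d <= 160),
            "dense": (lambda a: a < 0.2, lambda d: 70 <= d <= 200),
        }.items():
            for _ in range(20):
                m = random_morphology(cls, rng)
                assert amp_ok(m.amplitude_mv) and dur_ok(m.true_duration_ms)


class TestGenerateCohort:
    def test_reproducible_from_seed(self):
        spec = CohortSpec(n_patients=1, points_per_map=40, seed=9)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        assert np.array_equal(a[0].trace_matrix(), b[0].trace_matrix())
        assert np.array_equal(a[0].positions(), b[0].positions())
        assert np.array_equal(a[0].lesion_positions(), b[0].lesion_positions())

    def test_voltage_classes_follow_segment_roles(self, small_cohort):
        maps, truths = small_cohort
        for emap, truth in zip(maps, truths):
            volts = dict(zip(emap.point_ids(), emap.voltages()))
            for row in truth.itertuples():
                v = volts[row.point_id]
                if row.egm_class == "healthy":
                    assert v > 1.0
                elif row.egm_class == "border":
                    assert 0.2 <= v <= 1.0
                else:
                    assert v < 0.2
                assert classify_voltage(v) == row.egm_class

    def test_scar_spec_and_halo_recovered(self):
        spec = CohortSpec(n_patients=1, points_per_map=1500,
                          scar_segments=(4,), seed=5)
        maps, truths = generate_cohort(spec, return_truth=True)
        truth = truths[0]
        by_seg = truth.groupby("segment")["egm_class"].agg(lambda s: s.mode()[0])
        assert by_seg.loc[4] == "dense"
        from egmdur.aha17 import SEGMENT_NEIGHBORS
        for n in SEGMENT_NEIGHBORS[4]:
            assert by_seg.loc[n] == "border"
        remote = set(range(1, 18)) - {4} - SEGMENT_NEIGHBORS[4]
        for n in remote:
            if n in by_seg.index:
                assert by_seg.loc[n] == "healthy"

    def test_lesions_present_and_on_map_points(self, small_cohort):
        maps, _ = small_cohort
        for emap in maps:
            assert len(emap.lesions) > 0
            pos = emap.positions()
            for lesion in emap.lesions:
                d = np.linalg.norm(pos - lesion.position, axis=1).min()
                assert d < 1e-9  # lesions sit on sampled points

    def test_scar_only_with_empty_scar_rejected(self):
        with pytest.raises(ParameterError):
            CohortSpec(scar_segments=(), ablate_on="scar_only")
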