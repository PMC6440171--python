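import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinesym.core import TaskAnnotation
from kinesym.dyskinesia import (
    LidConfig,
    lid_sensor_selection,
    lid_task_score,
    magnitude_window_energies,
    prune_energy_outliers,
    segment_window_energies,
)

from conftest import make_recording

RATE = 32.0


def oracle_cap(values, q=0.75, k=1.5):
    """Brute-force capping oracle: sort, interpolated quartiles by hand,
    cap above Q3 + k*IQR to the largest acceptable value."""
    xs = sorted(values)
    n = len(xs)

    def quantile(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    q1, q3 = quantile(1 - q), quantile(q)
    threshold = q3 + k * (q3 - q1)
    acceptable = [x for x in xs if x <= threshold]
    cap = max(acceptable)
    out = [x if x <= threshold else cap for x in values]
    n_capped = sum(1 for x in values if x > threshold)
    return np.array(out), n_capped


class TestSensorSelection:
    def test_sitting_excludes_arms(self, layout):
        sel = lid_sensor_selection(layout, "sitting")
        assert len(sel) == 11
        assert not set(sel) & set(layout.arm_sensors)
        assert set(layout.leg_sensors) <= set(sel)

    @pytest.mark.parametrize("posture", ["standing", "walking"])
    def test_upright_excludes_legs(self, layout, posture):
        sel = lid_sensor_selection(layout, posture)
        assert len(sel) == 11
        assert not set(sel) & set(layout.leg_sensors)
        assert set(layout.arm_sensors) <= set(sel)

    def test_unknown_posture_fatal(self, layout):
        with pytest.raises(ValueError, match="flying"):
            lid_sensor_selection(layout, "flying")


class TestWindowEnergies:
    def test_sinusoid_magnitude_energy(self):
        # Parseval oracle on the magnitude-series pathway
        t = np.arange(0, 10, 1 / RATE)
        v = 2.5
        energies, _ = magnitude_window_energies(v * np.sin(2 * np.pi * 2.0 * t), RATE)
        assert len(energies) == 10
        np.testing.assert_allclose(energies, v**2 / 2, rtol=0.05)

    def test_zero_recording_zero_energies(self, layout, zero_recording):
        ann = TaskAnnotation("T", "sitting", 0.0, 10.0)
        _, matrix, _ = segment_window_energies(zero_recording, ann, layout)
        np.testing.assert_allclose(matrix, 0.0)

    def test_segment_mean_dilution(self, layout):
        # one leg sensor active among the 3 of its segment: the segment
        # energy is the sensor energy / 3
        rec = make_recording(layout, duration_s=10.0, rate=RATE)
        t = np.arange(rec.n_samples) / RATE
        # quadrature pair -> magnitude = const + tone stays in band after bp
        rec.gyro["thigh_l"][:, 0] = 3.0 * np.sin(2 * np.pi * 2.0 * t)
        ann = TaskAnnotation("T", "sitting", 0.0, 10.0)
        segments, matrix, _ = segment_window_energies(rec, ann, layout)
        i = segments.index("leg_l")
        single, _ = magnitude_window_energies(
            np.abs(3.0 * np.sin(2 * np.pi * 2.0 * t)), RATE
        )
        # interior windows only: the band-pass edge transient inflates the
        # first/last window relative to the unfiltered oracle
        np.testing.assert_allclose(matrix[i][1:-1], single[1:-1] / 3.0, rtol=0.05)
        j = segments.index("head")
        np.testing.assert_allclose(matrix[j], 0.0, atol=1e-12)

    def test_out_of_band_component_ignored(self, layout):
        rec = make_recording(layout, duration_s=10.0, rate=RATE)
        t = np.arange(rec.n_samples) / RATE
        rec.gyro["trunk_mid"][:, 1] = 2.0 * np.sin(2 * np.pi * 2.0 * t)
        ann = TaskAnnotation("T", "sitting", 0.0, 10.0)
        _, base, _ = segment_window_energies(rec, ann, layout)
        rec.gyro["trunk_mid"][:, 1] += 2.0 * np.sin(2 * np.pi * 6.0 * t)
        _, with6, _ = segment_window_energies(rec, ann, layout)
        assert np.sum(with6) == pytest.approx(np.sum(base), rel=0.05)

    def test_short_span_empty_with_warning(self, layout, zero_recording):
        ann = TaskAnnotation("T", "sitting", 0.0, 0.9)
        with pytest.warns(UserWarning):
            _, matrix, _ = segment_window_energies(zero_recording, ann, layout)
        assert matrix.size == 0


class TestPruning:
    def test_spec_example(self):
        capped, n = prune_energy_outliers(np.array([1.0, 2, 3, 4, 100]))
        np.testing.assert_allclose(capped, [1, 2, 3, 4, 4])
        assert n == 1

    def test_all_equal_untouched(self):
        capped, n = prune_energy_outliers(np.full(8, 3.3))
        np.testing.assert_allclose(capped, 3.3)
        assert n == 0

    def test_identity_when_no_outliers(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        capped, n = prune_energy_outliers(x)
        np.testing.assert_array_equal(capped, x)
        assert n == 0

    def test_too_few_windows_warns(self):
        x = np.array([1.0, 2.0, 300.0])
        with pytest.warns(UserWarning, match="fewer than 4"):
            capped, n = prune_energy_outliers(x)
        np.testing.assert_array_equal(capped, x)
        assert n == 0

    def test_idempotent(self, rng):
        x = rng.exponential(1.0, 50)
        once, _ = prune_energy_outliers(x)
        twice, n2 = prune_energy_outliers(once)
        np.testing.assert_array_equal(once, twice)
        assert n2 == 0

    def test_never_increases(self, rng):
        x = rng.exponential(1.0, 40)
        capped, _ = prune_energy_outliers(x)
        assert np.all(capped <= x)

    @given(st.integers(0, 2**32 - 1), st.integers(4, 100))
    @settings(max_examples=100, deadline=None)
    def test_equals_brute_force_oracle(self, seed, n):
        x = np.random.default_rng(seed).exponential(1.0, n)
        capped, count = prune_energy_outliers(x)
        expect, expect_count = oracle_cap(x)
        np.testing.assert_array_equal(capped, expect)
        assert count == expect_count


class TestTaskScore:
    def test_zero_recording_zero_score(self, layout, zero_recording):
        ann = TaskAnnotation("T", "sitting", 0.0, 10.0)
        assert lid_task_score(zero_recording, ann, layout).score == 0.0

    def test_segment_additivity(self, layout):
        rec = make_recording(layout, duration_s=10.0, rate=RATE)
        t = np.arange(rec.n_samples) / RATE
        rec.gyro["head"][:, 0] = 1.5 * np.sin(2 * np.pi * 2.0 * t)
        ann = TaskAnnotation("T", "sitting", 0.0, 10.0)
        res = lid_task_score(rec, ann, layout, LidConfig(cap_outliers=False))
        segments, matrix, _ = segment_window_energies(rec, ann, layout)
        assert res.score == pytest.approx(float(np.sum(matrix.mean(axis=1))))

    def test_posture_changes_selection_only(self, layout, rng):
        rec = make_recording(layout, duration_s=10.0, rate=RATE)
        for s in layout.placements:
            rec.gyro[s][:] = rng.normal(0, 1.0, rec.gyro[s].shape)
        sit = lid_task_score(rec, TaskAnnotation("T", "sitting", 0, 10), layout)
        stand = lid_task_score(rec, TaskAnnotation("T", "standing", 0, 10), layout)
        assert set(sit.segments) ^ set(stand.segments) == {"arm_l", "arm_r", "leg_l", "leg_r"}
        shared = set(sit.segments) & set(stand.segments)
        for seg in shared:
            i, j = sit.segments.index(seg), stand.segments.index(seg)
            np.testing.assert_allclose(sit.energies[i], stand.energies[j])

    def test_override_exempts_window_from_cap(self, layout):
        rec = make_recording(layout, duration_s=10.0, rate=RATE)
        t = np.arange(rec.n_samples) / RATE
        burst = np.zeros_like(t)
        burst[: int(RATE)] = 1.0  # big movement only in window 0
        rec.gyro["head"][:, 0] = 0.2 * np.sin(2 * np.pi * 2 * t) + \
            5.0 * burst * np.sin(2 * np.pi * 2 * t)
        ann = TaskAnnotation("T", "sitting", 0.0, 10.0)
        capped = lid_task_score(rec, ann, layout)
        exempted = lid_task_score(rec, ann, layout, override_windows={("head", 0)})
        assert capped.pruned_count >= 1
        assert exempted.score > capped.score
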