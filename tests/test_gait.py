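"""Stride detection, templating and DTW, checked against brute-force oracles."""
import functools

import numpy as np
import pytest

from psap.datamodel import DataError
from psap.gait import (
    GaitParams,
    build_template,
    detect_toe_off,
    dtw_alignment,
    dtw_distance,
    regularity,
    resample_stride,
    segment_strides,
    stride_set,
)
from psap.io import synchronize
from psap.orientation import build_alignment
from psap.synth import TandemGenParams, gen_tandem

RATE = 100.0


def dtw_oracle_recursive(a, b):
    """Independent top-down recursive definition of the accumulated DTW cost."""
    a = tuple(a)
    b = tuple(b)

    @functools.lru_cache(maxsize=None)
    def d(i, j):
        c = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return c
        best = np.inf
        if i > 0 and j > 0:
            best = min(best, d(i - 1, j - 1))
        if i > 0:
            best = min(best, d(i - 1, j))
        if j > 0:
            best = min(best, d(i, j - 1))
        return c + best

    return d(len(a) - 1, len(b) - 1)


def dtw_oracle_enumerate(a, b):
    """Exhaustive enumeration of every monotone warping path (tiny inputs)."""
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(a[i] - b[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


class TestDtw:
    def test_identity_distance_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(size=rng.integers(2, 50))
            assert dtw_distance(x, x) == 0.0

    def test_two_by_two_hand_computed(self):
        cost, path_len = dtw_alignment([0.0, 1.0], [1.0, 0.0])
        assert cost == 2.0
        assert path_len == 2
        assert dtw_distance([0, 1], [1, 0]) == 1.0

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a = rng.integers(0, 10, rng.integers(1, 12)).astype(float)
            b = rng.integers(0, 10, rng.integers(1, 12)).astype(float)
            ab, _ = dtw_alignment(a, b)
            ba, _ = dtw_alignment(b, a)
            assert ab == ba >= 0.0

    def test_matches_recursive_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a = rng.integers(0, 20, rng.integers(1, 11)).astype(float)
            b = rng.integers(0, 20, rng.integers(1, 11)).astype(float)
            assert dtw_alignment(a, b)[0] == dtw_oracle_recursive(a, b)

    def test_matches_full_path_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a = rng.integers(0, 10, rng.integers(1, 7)).astype(float)
            b = rng.integers(0, 10, rng.integers(1, 7)).astype(float)
            assert dtw_alignment(a, b)[0] == dtw_oracle_enumerate(a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            dtw_distance([], [1.0])


class TestDetectToeOff:
    def test_flat_signal_gives_no_events(self):
        assert len(detect_toe_off(np.zeros(500), RATE)) == 0

    def test_refractory_merges_close_peaks(self):
        t = np.arange(0, 4, 1 / RATE)
        x = (200 * np.exp(-((t - 2.0) / 0.03) ** 2)
             + 180 * np.exp(-((t - 2.1) / 0.03) ** 2))
        events = detect_toe_off(x, RATE, GaitParams(refractory_s=0.6))
        assert len(events) == 1

    def test_synthetic_train_recovered(self, clean_tandem):
        from psap.orientation import aligned_gyro

        sset, truth, align = clean_tandem
        walk = sset.meta.phase("walk")
        for foot in ("left", "right"):
            rec = sset[f"{foot}_ankle"].slice_seconds(*walk)
            sag = aligned_gyro(rec, align, f"{foot}_ankle")[:, 1]
            events = detect_toe_off(sag, rec.rate_hz)
            times = rec.time[events]
            expected = truth.toe_off_times_s[foot]
            assert len(times) == len(expected)
            assert np.max(np.abs(times - expected)) <= 0.020


class TestSegmentation:
    def test_event_count_arithmetic(self):
        events = np.arange(13) * 100
        strides = segment_strides(np.zeros(1300), events)
        assert len(strides) == 12

    def test_segment_lengths(self):
        strides = segment_strides(np.arange(300.0), [0, 100, 250])
        assert [len(s) for s in strides] == [100, 150]

    def test_single_event_rejected(self):
        with pytest.raises(DataError, match="insufficient"):
            segment_strides(np.zeros(100), [10])


class TestTemplate:
    def test_identical_strides_reproduced(self):
        stride = np.sin(np.linspace(0, np.pi, 100))
        template, sd = build_template([stride] * 5, length=100)
        np.testing.assert_allclose(template, stride, atol=1e-9)
        np.testing.assert_allclose(sd, 0.0, atol=1e-9)

    def test_symmetric_strides_cancel(self):
        a = np.sin(np.linspace(0, 2 * np.pi, 80))
        template, _ = build_template([a, -a, np.zeros(80)], length=100)
        np.testing.assert_allclose(template, 0.0, atol=1e-9)

    def test_unequal_lengths_resampled_to_contract_length(self):
        strides = [np.ones(90), np.ones(100), np.ones(110)]
        template, _ = build_template(strides, length=100)
        assert len(template) == 100

    def test_fewer_than_three_rejected(self):
        with pytest.raises(DataError):
            build_template([np.ones(10), np.ones(10)])


class TestRegularity:
    def test_clean_gait_below_noise_floor(self, clean_tandem):
        sset, _, align = clean_tandem
        for foot in ("left", "right"):
            res = regularity(sset, align, foot)
            assert res.n_strides == 11
            assert res.mean < 0.05 * 200.0  # < 5% of the peak angular velocity

    def test_jitter_monotonicity(self):
        """Median regularity mean strictly increases with stride jitter."""
        medians = []
        for jitter in (0.0, 0.05, 0.15):
            means = []
            for seed in range(20):
                sset, _ = gen_tandem(TandemGenParams(
                    seed=seed, timing_jitter_frac=jitter,
                    amplitude_jitter_frac=jitter))
                sset = synchronize(sset)
                align = build_alignment(sset, sset.meta.phase("calib"))
                means.append(regularity(sset, align, "right").mean)
            medians.append(np.median(means))
        assert medians[0] < medians[1] < medians[2]

    def test_corrupted_stride_dominates_range(self):
        rng = np.random.default_rng(8)
        t = np.arange(0, 16, 1 / RATE)
        centers = 1.0 + np.arange(12) * 1.25
        x = np.zeros_like(t)
        for k, c in enumerate(centers):
            amp = 200.0 * (3.0 if k == 6 else 1.0)
            m = np.abs(t - c) <= 0.3
            x[m] += amp * 0.5 * (1 + np.cos(2 * np.pi * (t[m] - c) / 0.6))
        x += rng.normal(0, 0.5, x.shape)
        ss = stride_set(x, RATE, "right")
        d = ss.distances
        # the two strides sharing the corrupted pulse attain the maximum
        assert np.argmax(d) in (5, 6)
        assert d.max() - d.min() > 2 * d.std(ddof=1)

    def test_left_right_exchangeable(self):
        """Mirroring the generator's feet swaps per-foot results exactly."""
        results = {}
        for lead in ("right", "left"):
            sset, _ = gen_tandem(TandemGenParams(
                seed=4, lead_foot=lead, noise_acc=0.0, noise_gyro=0.0))
            sset = synchronize(sset)
            align = build_alignment(sset, sset.meta.phase("calib"))
            results[lead] = {f: regularity(sset, align, f) for f in
                             ("left", "right")}
        def nums(res):
            return (res.mean, res.sd, res.range, res.n_strides)

        assert nums(results["right"]["right"]) == nums(results["left"]["left"])
        assert nums(results["right"]["left"]) == nums(results["left"]["right"])

    def test_too_few_strides_reports_count(self, clean_tandem):
        sset, _, align = clean_tandem
        import dataclasses

        meta = dataclasses.replace(
            sset.meta, phases={**sset.meta.phases, "walk": (3.0, 6.0)})
        from psap.datamodel import SensorSet

        short = SensorSet(sensors=dict(sset.sensors), meta=meta)
        with pytest.raises(DataError, match="stride"):
            regularity(short, align, "right")
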