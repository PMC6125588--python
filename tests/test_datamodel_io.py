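import numpy as np
import pytest

from psap.datamodel import DataError, ImuRecording, SensorSet, TrialMeta
from psap.io import read_trial, synchronize, write_trial
from psap.synth import TandemGenParams, gen_tandem


def random_sensor_set(rng, with_quat=False, n=60, rate=100.0, t0=0.0):
    sensors = {}
    sites = rng.choice(["head", "trunk", "pelvis", "left_ankle", "right_ankle"],
                       size=rng.integers(1, 6), replace=False)
    t = t0 + np.arange(n) / rate
    for site in sites:
        quat = None
        if with_quat:
            quat = rng.normal(size=(n, 4))
            quat /= np.linalg.norm(quat, axis=1, keepdims=True)
        sensors[site] = ImuRecording(
            time=t, acc=rng.normal(0, 5, (n, 3)), gyro=rng.normal(0, 50, (n, 3)),
            mag=rng.normal(size=(n, 3)) if rng.random() < 0.5 else None,
            quat=quat, rate_hz=rate)
    meta = TrialMeta(subject_id="s1", cohort="crew", session="pre",
                     days_elapsed=0.0, test="tandem",
                     phases={"walk": (0.0, n / rate / 2)})
    return SensorSet(sensors=sensors, meta=meta)


def assert_sets_equal(a, b, tol=1e-9):
    assert sorted(a.sensors) == sorted(b.sensors)
    for site in a.sensors:
        ra, rb = a[site], b[site]
        np.testing.assert_allclose(ra.time, rb.time, atol=tol)
        np.testing.assert_allclose(ra.acc, rb.acc, atol=tol)
        np.testing.assert_allclose(ra.gyro, rb.gyro, atol=tol)
        assert (ra.mag is None) == (rb.mag is None)
        if ra.mag is not None:
            np.testing.assert_allclose(ra.mag, rb.mag, atol=tol)
        assert (ra.quat is None) == (rb.quat is None)
        if ra.quat is not None:
            np.testing.assert_allclose(ra.quat, rb.quat, atol=tol)


class TestRecordingInvariants:
    def test_channel_length_mismatch_rejected(self):
        t = np.arange(10) / 100.0
        with pytest.raises(DataError):
            ImuRecording(time=t, acc=np.zeros((9, 3)), gyro=np.zeros((10, 3)),
                         rate_hz=100.0)

    def test_nonuniform_time_rejected(self):
        t = np.arange(10) / 100.0
        t[5] += 0.002
        with pytest.raises(DataError):
            ImuRecording(time=t, acc=np.zeros((10, 3)),
                         gyro=np.zeros((10, 3)), rate_hz=100.0)

    def test_non_unit_quaternion_rejected(self):
        t = np.arange(10) / 100.0
        q = np.tile([1.0, 0.0, 0.0, 0.1], (10, 1))
        with pytest.raises(DataError):
            ImuRecording(time=t, acc=np.zeros((10, 3)),
                         gyro=np.zeros((10, 3)), quat=q, rate_hz=100.0)

    def test_phase_must_not_end_before_start(self):
        with pytest.raises(DataError):
            TrialMeta(subject_id="s", cohort="crew", session="pre",
                      days_elapsed=0, test="tandem", phases={"walk": (2, 1)})


class TestRoundTrip:
    def test_write_read_roundtrip_randomized(self, tmp_path):
        rng = np.random.default_rng(42)
        for i in range(50):
            sset = random_sensor_set(rng, with_quat=bool(i % 2))
            manifest = write_trial(sset, tmp_path / f"trial{i}")
            back = read_trial(manifest)
            assert_sets_equal(sset, back)
            assert back.meta.phases == sset.meta.phases

    def test_missing_optional_sensor_is_absent_not_zero(self, tmp_path):
        sset, _ = gen_tandem(TandemGenParams(seed=0, n_strides=3))
        del sset.sensors["head"]
        back = read_trial(write_trial(sset, tmp_path))
        assert "head" not in back
        assert len(back.sensors) == 4

    def test_duplicated_timestamp_is_data_error(self, tmp_path):
        sset, _ = gen_tandem(TandemGenParams(seed=0, n_strides=3))
        manifest = write_trial(sset, tmp_path)
        csv = next(tmp_path.glob("*_head.csv"))
        lines = csv.read_text().splitlines()
        lines[2] = lines[1]  # duplicate the first timestamp
        csv.write_text("\n".join(lines) + "\n")
        with pytest.raises(DataError):
            read_trial(manifest)

    def test_missing_column_names_file_and_column(self, tmp_path):
        sset, _ = gen_tandem(TandemGenParams(seed=0, n_strides=3))
        manifest = write_trial(sset, tmp_path)
        csv = next(tmp_path.glob("*_trunk.csv"))
        import pandas as pd

        df = pd.read_csv(csv).drop(columns=["gz"])
        df.to_csv(csv, index=False)
        with pytest.raises(Exception, match="gz"):
            read_trial(manifest)

    def test_wrong_units_rejected(self, tmp_path):
        import json

        sset, _ = gen_tandem(TandemGenParams(seed=0, n_strides=3))
        manifest = write_trial(sset, tmp_path)
        man = json.loads(manifest.read_text())
        man["units"]["gyro"] = "rad/s"
        manifest.write_text(json.dumps(man))
        with pytest.raises(Exception, match="units"):
            read_trial(manifest)

    def test_empty_sensor_map_rejected(self):
        meta = TrialMeta(subject_id="s", cohort="crew", session="pre",
                         days_elapsed=0, test="tandem")
        with pytest.raises(DataError):
            SensorSet(sensors={}, meta=meta)


class TestSynchronize:
    def test_aligned_input_unchanged(self):
        rng = np.random.default_rng(0)
        sset = random_sensor_set(rng)
        out = synchronize(sset)
        assert_sets_equal(sset, out)

    def test_offset_overlap_arithmetic(self):
        # two sensors, one offset by +0.01 s: overlap = 0.59 s at 100 Hz
        # -> floor(0.59 * 100) + 1 = 60 output samples
        rng = np.random.default_rng(1)
        n, rate = 60, 100.0
        a = ImuRecording(time=np.arange(n) / rate,
                         acc=rng.normal(size=(n, 3)),
                         gyro=rng.normal(size=(n, 3)), rate_hz=rate)
        b = ImuRecording(time=0.01 + np.arange(n) / rate,
                         acc=rng.normal(size=(n, 3)),
                         gyro=rng.normal(size=(n, 3)), rate_hz=rate)
        meta = TrialMeta(subject_id="s", cohort="crew", session="pre",
                         days_elapsed=0, test="tandem")
        out = synchronize(SensorSet(sensors={"trunk": a, "pelvis": b}, meta=meta))
        expected = int(np.floor((a.time[-1] - b.time[0]) * rate + 1e-9)) + 1
        for site in out.sensors:
            assert out[site].n_samples == expected
            assert abs(out[site].time[0] - 0.01) < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        sset = random_sensor_set(rng, with_quat=True, t0=0.003)
        once = synchronize(sset)
        twice = synchronize(once)
        assert_sets_equal(once, twice, tol=0.0)

    def test_disjoint_recordings_rejected(self):
        rng = np.random.default_rng(3)
        n, rate = 50, 100.0
        a = ImuRecording(time=np.arange(n) / rate, acc=np.zeros((n, 3)),
                         gyro=np.zeros((n, 3)), rate_hz=rate)
        b = ImuRecording(time=10.0 + np.arange(n) / rate, acc=np.zeros((n, 3)),
                         gyro=np.zeros((n, 3)), rate_hz=rate)
        meta = TrialMeta(subject_id="s", cohort="crew", session="pre",
                         days_elapsed=0, test="tandem")
        with pytest.raises(DataError):
            synchronize(SensorSet(sensors={"trunk": a, "pelvis": b}, meta=meta))

    def test_quaternions_renormalized(self):
        rng = np.random.default_rng(4)
        sset = random_sensor_set(rng, with_quat=True, t0=0.004)
        out = synchronize(sset)
        for rec in out.sensors.values():
            np.testing.assert_allclose(
                np.linalg.norm(rec.quat, axis=1), 1.0, atol=1e-12)
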