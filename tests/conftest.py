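import numpy as np
import pytest

from psap.io import synchronize
from psap.orientation import build_alignment
from psap.synth import TandemGenParams, gen_tandem


def make_static_recording(acc_vec, n=300, rate=100.0, gyro_dps=0.0, seed=0):
    """Static recording with a fixed specific-force vector (plus optional gyro)."""
    from psap.datamodel import ImuRecording

    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    acc = np.tile(np.asarray(acc_vec, float), (n, 1))
    gyro = rng.normal(0, gyro_dps, (n, 3)) if gyro_dps else np.zeros((n, 3))
    return ImuRecording(time=t, acc=acc, gyro=gyro, rate_hz=rate)


@pytest.fixture(scope="session")
def clean_tandem():
    """Noise-free, jitter-free tandem trial plus its truth and alignment."""
    sset, truth = gen_tandem(TandemGenParams(
        seed=7, noise_acc=0.0, noise_gyro=0.0))
    sset = synchronize(sset)
    align = build_alignment(sset, sset.meta.phase("calib"))
    return sset, truth, align


@pytest.fixture(scope="session")
def noisy_tandem():
    """Default-noise tandem trial with per-site tilts, plus truth/alignment."""
    sset, truth = gen_tandem(TandemGenParams(
        seed=11, tilt_deg={"head": 10, "trunk": 20, "pelvis": 5,
                           "left_ankle": 25, "right_ankle": 15}))
    sset = synchronize(sset)
    align = build_alignment(sset, sset.meta.phase("calib"))
    return sset, truth, align
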