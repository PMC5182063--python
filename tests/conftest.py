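import numpy as np
import pytest

from strobopalm import (
    AcquisitionSettings,
    EffectiveOnTime,
    KineticParams,
    LocalizationTable,
)
from strobopalm.dwelltime import fit_effective_ontime
from strobopalm.synthetic import frames_for_density, simulate_track_lengths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def table_from_points(frames, xy, sigma_nm=15.0):
    """LocalizationTable from explicit frame indices and (n, 2) positions."""
    xy = np.asarray(xy, dtype=float)
    return LocalizationTable.from_arrays(
        frame=np.asarray(frames, dtype=np.int64),
        x_nm=xy[:, 0],
        y_nm=xy[:, 1],
        sigma_nm=sigma_nm,
    )


def effective_ontime_points(
    tau_off_ms,
    tau_bleach_ms,
    rate_per_frame,
    n_molecules,
    strobe_intervals_ms,
    seed,
    tau_int_ms=30.0,
):
    """Simulate per-condition track lengths and fit the effective on-time."""
    kin = KineticParams(tau_off_ms, tau_bleach_ms, rate_per_frame)
    rng = np.random.default_rng(seed)
    points = []
    for tau_tl in strobe_intervals_ms:
        acq = AcquisitionSettings(
            tau_int_ms, tau_tl, frames_for_density(n_molecules, rate_per_frame)
        )
        sample = simulate_track_lengths(kin, acq, n_molecules, rng)
        points.append(fit_effective_ontime(sample.histogram(), tau_tl_ms=tau_tl))
    return points


def noiseless_points(model_frames, strobe_intervals_ms):
    """EffectiveOnTime points generated exactly by a frames-model callable."""
    return [
        EffectiveOnTime(tl, float(model_frames(tl)), 0.0, 10_000)
        for tl in strobe_intervals_ms
    ]
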