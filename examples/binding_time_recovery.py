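"""Recover a polar binding time from a simulated strobed tracking campaign.

Ground truth: binding lifetime 300 ms, photobleaching lifetime 50 ms under
continuous 30 ms exposures — the bleaching-limited regime where the dwell
time cannot be read off directly and strobing plus model fitting is needed.
Activation is kept sparse (0.02 molecules/frame) as appropriate for a
quantitative recovery experiment.
"""

import numpy as np

from strobopalm import (
    AcquisitionSettings,
    KineticParams,
    bootstrap_confidence,
    compare_conditions,
    fit_effective_ontime,
    fit_plateau_model,
    simulate_track_lengths,
)
from strobopalm.synthetic import frames_for_density

TAU_INT = 30.0
GRID = (30.0, 60.0, 120.0, 240.0, 480.0, 1920.0, 7680.0)


def campaign(tau_off_ms, seed):
    kin = KineticParams(tau_off_ms, 50.0, activation_rate_per_frame=0.02)
    rng = np.random.default_rng(seed)
    points = []
    for tau_tl in GRID:
        acq = AcquisitionSettings(TAU_INT, tau_tl, frames_for_density(5_000, 0.02))
        sample = simulate_track_lengths(kin, acq, 5_000, rng)
        points.append(fit_effective_ontime(sample.histogram(), tau_tl_ms=tau_tl))
    return points


points = campaign(300.0, seed=42)
fit = fit_plateau_model(points, TAU_INT)
ci = bootstrap_confidence(points, "plateau", TAU_INT, n_boot=200, seed=42)
lo, hi = ci["tau_off_ms"]
print(f"true binding time      : 300.0 ms")
print(f"recovered binding time : {fit.tau_off_ms:.1f} ms  (95% CI {lo:.0f}-{hi:.0f})")
print(f"recovered bleach time  : {fit.tau_bleach_ms:.1f} ms  (true 50.0)")

# two conditions, as when comparing strains: 5 replicate campaigns each
a = [fit_plateau_model(campaign(300.0, s), TAU_INT).tau_off_ms for s in range(5)]
b = [fit_plateau_model(campaign(100.0, 50 + s), TAU_INT).tau_off_ms for s in range(5)]
t, p = compare_conditions(a, b)
print(f"\ncondition A replicates : {np.round(a, 1)}")
print(f"condition B replicates : {np.round(b, 1)}")
print(f"Welch t-test           : t = {t:.2f}, p = {p:.2g}")
print("A shorter binding time in condition B (as when the polar matrix is")
print("missing) is decisively detected from replicate campaign fits.")
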