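"""Show the minimum-measurable-on-time plateau of strobed tracking.

Simulates one acquisition campaign (5,000 photoactivated molecules per strobe
condition at a pole, 30 ms exposures) and compares the observed effective
on-time in frames with the hyperbolic prediction.  At short strobe intervals
the observation follows the hyperbola; at intervals far beyond the binding
time the observation flattens at a floor of ~0.35 frames while the hyperbola
keeps falling — the artifact the plateau fitting model corrects for.
"""

import numpy as np

from strobopalm import (
    AcquisitionSettings,
    KineticParams,
    fit_effective_ontime,
    fit_gebhardt,
    fit_plateau_model,
    predict_observed_ontime,
    simulate_track_lengths,
)
from strobopalm.synthetic import frames_for_density

TAU_INT = 30.0
GRID = (30.0, 60.0, 120.0, 240.0, 480.0, 1920.0, 7680.0)

kin = KineticParams(tau_off_ms=300.0, tau_bleach_ms=50.0, activation_rate_per_frame=0.08)
rng = np.random.default_rng(1)

points = []
print("tau_tl[ms]  observed n_eff[frames]  hyperbolic prediction")
for tau_tl in GRID:
    acq = AcquisitionSettings(TAU_INT, tau_tl, frames_for_density(5_000, 0.08))
    sample = simulate_track_lengths(kin, acq, 5_000, rng)
    pt = fit_effective_ontime(sample.histogram(), tau_tl_ms=tau_tl)
    points.append(pt)
    eq3 = predict_observed_ontime(kin, acq).frames
    print(f"{tau_tl:9.0f}  {pt.n_eff_frames:21.3f}  {eq3:21.3f}")

geb = fit_gebhardt(points, TAU_INT)
plat = fit_plateau_model(points, TAU_INT)
print(f"\nhyperbolic fit : tau_off = {geb.tau_off_ms:6.1f} ms   rss = {geb.rss:.4f}")
print(f"plateau fit    : tau_off = {plat.tau_off_ms:6.1f} ms   rss = {plat.rss:.4f}"
      f"   floor = {plat.n_min_frames:.3f} frames")
print("\nThe plateau model absorbs the long-interval floor and its residuals")
print("are far smaller; the hyperbolic fit is biased by the flattened points.")
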