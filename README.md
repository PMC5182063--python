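# strobopalm

Stroboscopic single-particle-tracking PALM analysis for membrane-protein
polar binding kinetics, plus nanoscale cluster-morphology quantification of
localization point clouds.  Built for the kind of question raised by polar
scaffold proteins in *Caulobacter*: how long does a tagged protein reside at
a cell pole, and is the polar assembly it forms a genuinely extended
structure or a point source inflated by localization noise?

## The two measurements

**Binding time.**  A tracked molecule is visible only while bound and
unbleached, so the effective on-time convolves binding and bleaching:
1/τ_eff = 1/τ_off + 1/τ_b.  Stroboscopic illumination (exposure τ_int,
frame period τ_tl) stretches the bleaching lifetime to τ_b·τ_tl/τ_int,
giving the hyperbolic model

τ_eff(τ_tl) = (1/τ_off + τ_int/(τ_b·τ_tl))⁻¹

fitted by non-linear least squares across strobe conditions.  Because a
track can never be shorter than one frame, the observed on-time (in frames)
flattens at long τ_tl at a minimum measurable floor n_min instead of
following the hyperbola; `strobopalm` fits the revised plateau model
n_obs = max(τ_eff/τ_tl, n_min), which removes the large systematic bias the
plain hyperbolic fit suffers in that regime.  See `docs/methods.md` for the
mechanism behind the floor and all estimator details.

**Cluster morphology.**  Localizations are segmented by DBSCAN, rasterized
(15 nm pixels), morphologically closed, and measured: area, perimeter,
circularity 4πA/p², solidity A/H, eccentricity (minor/major axis).  Observed
areas are compared against a simulated *zero-area baseline* — point sources
with matched photon count, background and localization number pushed through
the identical pipeline — using Mood's median test.

A fast synthetic-data module generates both strobed binding/bleaching
campaigns (closed-form, no per-frame loops) and point/disk/arc localization
clouds, so every estimator ships with end-to-end parameter-recovery tests.

## Worked example

`examples/plateau_artifact.py` simulates a full campaign (5,000 molecules
per strobe condition, τ_off = 300 ms, τ_b = 50 ms, 30 ms exposures) and
prints:

```
tau_tl[ms]  observed n_eff[frames]  hyperbolic prediction
       30                  1.605                  1.429
       60                  1.334                  1.250
      120                  1.109                  1.000
      240                  0.835                  0.714
      480                  0.538                  0.455
     1920                  0.358                  0.143
     7680                  0.354                  0.038

hyperbolic fit : tau_off =  416.1 ms   rss = 0.1295
plateau fit    : tau_off =  356.4 ms   rss = 0.0047   floor = 0.356 frames
```

The observed on-time tracks the hyperbola at short strobe intervals and
flattens near 0.35 frames at long ones; the plateau model absorbs the floor
(27× smaller residuals here) where the plain hyperbolic fit is biased.
`examples/binding_time_recovery.py` runs the sparse-activation recovery
protocol (recovered 343.7 ms, 95% CI 279–429, for a 300 ms truth) and a
Welch test separating two conditions; `examples/cluster_morphology.py`
measures a 150-nm disk cluster (area 7.6 × 10⁴ nm² vs a 0.7 × 10⁴ nm²
zero-area baseline, Mood's p ≈ 10⁻³⁸); `examples/render_image.py` renders a
gamma-adjusted PALM image.

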